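"""Discrete patch encoder: a desk-scale vector-quantized autoencoder.

The encoder maps an RGB patch (values scaled to [-1, 1]) to a grid of
discrete codeword indices — the latent grid that the indexing pipeline
pools into an integer key.  Quantization snaps each encoder output vector
to its nearest codebook entry in Euclidean norm:

    z_q(x) = e_k,  k = argmin_j || z_e(x) - e_j ||

Training minimises the three-term objective

    || x_hat - x ||^2  +  || sg[z_e(x)] - e ||^2  +  alpha || z_e(x) - sg[e] ||^2

where ``sg`` is the stop-gradient operator: the first term trains encoder
and decoder (gradients pass straight through the quantizer), the second
moves codewords toward encoder outputs, and the third (weight ``alpha``,
default 1) commits the encoder to the codebook.

The architecture is deliberately small: each non-overlapping 16x16 pixel
block is encoded by a linear map to a D-dimensional vector (x16 spatial
downsampling, so a 1024x1024 patch yields a 64x64 latent grid) and decoded
by a linear map back to pixels.  Training uses Adam (lr 1e-3, betas
0.9/0.999, eps 1e-8) with gradient clipping at norm 1.0, batch size 4,
10 epochs by default, and is deterministic given the config seed.

After training the codebook is re-ordered by the codewords' scores on the
first principal component of the codebook matrix, so that nearby codeword
indices correspond to nearby codewords and the pooled sums vary smoothly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Codebook",
    "VqvaeConfig",
    "VqvaeModel",
    "quantize",
    "train_vqvae",
    "reorder_codebook",
    "mock_encode",
    "MockEncoderParams",
]

BLOCK = 16  # pixels per latent cell along each axis (x16 downsampling)


@dataclass
class Codebook:
    """K x D matrix of learnable codeword vectors."""

    vectors: np.ndarray

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2 or self.vectors.shape[0] < 2:
            raise ValueError("codebook must be K x D with K >= 2")

    @property
    def K(self) -> int:
        return self.vectors.shape[0]

    @property
    def D(self) -> int:
        return self.vectors.shape[1]


@dataclass
class VqvaeConfig:
    K: int = 128
    D: int = 256
    alpha: float = 1.0
    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    batch_size: int = 4
    epochs: int = 10
    grad_clip: float = 1.0
    seed: int = 0


@dataclass
class VqvaeModel:
    """Linear block encoder/decoder plus codebook."""

    w_enc: np.ndarray  # (3*BLOCK*BLOCK, D)
    b_enc: np.ndarray  # (D,)
    w_dec: np.ndarray  # (D, 3*BLOCK*BLOCK)
    b_dec: np.ndarray  # (3*BLOCK*BLOCK,)
    codebook: Codebook
    config: VqvaeConfig = field(default_factory=VqvaeConfig)
    permutation: np.ndarray | None = None  # old index -> new index, if re-ordered

    def encode_features(self, image: np.ndarray) -> np.ndarray:
        """Continuous encoder output z_e as a (G, G, D) tensor."""
        x = _to_blocks(_normalize(image))  # (G*G, 3*BLOCK*BLOCK)
        g = int(np.sqrt(x.shape[0]))
        z = x @ self.w_enc + self.b_enc
        return z.reshape(g, g, -1)

    def encode(self, image: np.ndarray) -> np.ndarray:
        """Latent grid of codeword indices for one patch."""
        return quantize(self.encode_features(image), self.codebook)

    def reconstruct(self, image: np.ndarray) -> np.ndarray:
        grid = self.encode(image)
        zq = self.codebook.vectors[grid.ravel()]
        blocks = zq @ self.w_dec + self.b_dec
        g = grid.shape[0]
        return _from_blocks(blocks, g)


def _normalize(image: np.ndarray) -> np.ndarray:
    """Scale an RGB (or grayscale, replicated) image into [-1, 1]."""
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 2:
        img = img[..., None].repeat(3, axis=2)
    if img.shape[2] != 3:
        raise ValueError("expected RGB image")
    if img.max() > 1.5:  # 8-bit range
        img = img / 255.0 * 2.0 - 1.0
    elif img.min() >= 0.0:  # unit range
        img = img * 2.0 - 1.0
    return img


def _to_blocks(img: np.ndarray) -> np.ndarray:
    h, w, c = img.shape
    if h != w or h % BLOCK:
        raise ValueError(f"image side must be a multiple of {BLOCK} and square")
    g = h // BLOCK
    return (
        img.reshape(g, BLOCK, g, BLOCK, c)
        .transpose(0, 2, 1, 3, 4)
        .reshape(g * g, BLOCK * BLOCK * c)
    )


def _from_blocks(blocks: np.ndarray, g: int) -> np.ndarray:
    return (
        blocks.reshape(g, g, BLOCK, BLOCK, 3)
        .transpose(0, 2, 1, 3, 4)
        .reshape(g * BLOCK, g * BLOCK, 3)
    )


def quantize(features: np.ndarray, codebook: Codebook) -> np.ndarray:
    """Nearest-codeword index for every cell of a (G, G, D) feature tensor."""
    feats = np.asarray(features, dtype=np.float64)
    if feats.ndim != 3:
        raise ValueError("features must be G x G x D")
    if feats.shape[2] != codebook.D:
        raise ValueError(
            f"feature depth {feats.shape[2]} != codeword dimension {codebook.D}"
        )
    flat = feats.reshape(-1, codebook.D)
    # ||z - e||^2 = ||z||^2 - 2 z.e + ||e||^2 ; ||z||^2 constant per row
    d2 = (
        -2.0 * flat @ codebook.vectors.T
        + (codebook.vectors**2).sum(axis=1)[None, :]
    )
    idx = np.argmin(d2, axis=1)
    return idx.reshape(feats.shape[0], feats.shape[1]).astype(np.int64)


class _Adam:
    def __init__(self, shapes, lr, beta1, beta2, eps):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        out = []
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            out.append(p - self.lr * mhat / (np.sqrt(vhat) + self.eps))
        return out


def _clip_gradients(grads, max_norm):
    total = np.sqrt(sum(float((g**2).sum()) for g in grads))
    if total > max_norm:
        scale = max_norm / (total + 1e-12)
        grads = [g * scale for g in grads]
    return grads


def train_vqvae(patches, config: VqvaeConfig | None = None):
    """Train the quantized autoencoder on a collection of square RGB patches.

    Returns ``(model, loss_history)`` where ``loss_history`` holds the mean
    per-epoch training loss (reconstruction + codebook + commitment).
    """
    config = config or VqvaeConfig()
    patches = list(patches)
    if not patches:
        raise ValueError("training set is empty")
    rng = np.random.default_rng(config.seed)
    in_dim = 3 * BLOCK * BLOCK

    w_enc = rng.standard_normal((in_dim, config.D)) * (1.0 / np.sqrt(in_dim))
    b_enc = np.zeros(config.D)
    w_dec = rng.standard_normal((config.D, in_dim)) * (1.0 / np.sqrt(config.D))
    b_dec = np.zeros(in_dim)
    codebook = rng.standard_normal((config.K, config.D)) * 0.1

    params = [w_enc, b_enc, w_dec, b_dec, codebook]
    opt = _Adam([p.shape for p in params], config.lr, config.beta1, config.beta2, config.eps)

    blocks = np.stack([_to_blocks(_normalize(p)) for p in patches])  # (N, B, in)
    n = blocks.shape[0]
    history = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            batch = blocks[order[start : start + config.batch_size]]
            x = batch.reshape(-1, in_dim)
            w_enc, b_enc, w_dec, b_dec, codebook = params

            ze = x @ w_enc + b_enc
            d2 = -2.0 * ze @ codebook.T + (codebook**2).sum(axis=1)[None, :]
            k = np.argmin(d2, axis=1)
            ek = codebook[k]
            xhat = ek @ w_dec + b_dec  # straight-through: decoder sees e_k

            diff = xhat - x
            recon = float((diff**2).mean())
            codebook_loss = float(((ek - ze) ** 2).mean())
            commit = codebook_loss  # identical value; gradients differ by sg
            loss = recon + codebook_loss + config.alpha * commit
            epoch_losses.append(loss)

            m = x.shape[0] * in_dim
            dxhat = 2.0 * diff / m
            g_wdec = ek.T @ dxhat
            g_bdec = dxhat.sum(axis=0)
            dzq = dxhat @ w_dec.T
            # straight-through estimator: recon gradient copied to z_e
            mz = ze.size
            dze = dzq + config.alpha * 2.0 * (ze - ek) / mz
            g_wenc = x.T @ dze
            g_benc = dze.sum(axis=0)
            g_code = np.zeros_like(codebook)
            np.add.at(g_code, k, 2.0 * (ek - ze) / mz)

            grads = _clip_gradients([g_wenc, g_benc, g_wdec, g_bdec, g_code], config.grad_clip)
            params = opt.step(params, grads)
        history.append(float(np.mean(epoch_losses)))

    w_enc, b_enc, w_dec, b_dec, codebook = params
    model = VqvaeModel(w_enc, b_enc, w_dec, b_dec, Codebook(codebook), config)
    return model, history


def reorder_codebook(model: VqvaeModel):
    """Sort codewords by their first-principal-component score.

    Returns ``(model, permutation)`` where ``permutation[old] = new`` maps
    previously emitted latent codes onto the re-ordered codebook.  The
    component is oriented so that its largest-magnitude loading is
    positive, making the ordering reproducible; a zero-variance codebook
    yields the identity permutation with a warning.
    """
    import warnings

    vecs = model.codebook.vectors
    centered = vecs - vecs.mean(axis=0)
    if not np.any(centered):
        warnings.warn("degenerate codebook (zero variance); keeping original order")
        perm = np.arange(vecs.shape[0])
        model.permutation = perm
        return model, perm
    # first right singular vector of the centered codebook = first PC
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    pc1 = vt[0]
    if pc1[np.argmax(np.abs(pc1))] < 0:
        pc1 = -pc1
    scores = centered @ pc1
    order = np.argsort(scores, kind="stable")  # order[new] = old
    perm = np.empty_like(order)
    perm[order] = np.arange(order.size)  # perm[old] = new
    model.codebook = Codebook(vecs[order])
    model.permutation = perm
    return model, perm


def save_model(model: VqvaeModel, path) -> None:
    """Single-file checkpoint: parameters, codebook, permutation, config."""
    import json

    cfg = json.dumps(model.config.__dict__)
    np.savez(
        path,
        w_enc=model.w_enc,
        b_enc=model.b_enc,
        w_dec=model.w_dec,
        b_dec=model.b_dec,
        codebook=model.codebook.vectors,
        permutation=model.permutation if model.permutation is not None else np.array([]),
        config=np.frombuffer(cfg.encode(), dtype=np.uint8),
    )


def load_model(path) -> VqvaeModel:
    import json

    with np.load(path) as data:
        cfg = VqvaeConfig(**json.loads(bytes(data["config"]).decode()))
        perm = data["permutation"]
        return VqvaeModel(
            w_enc=data["w_enc"],
            b_enc=data["b_enc"],
            w_dec=data["w_dec"],
            b_dec=data["b_dec"],
            codebook=Codebook(data["codebook"]),
            config=cfg,
            permutation=perm if perm.size else None,
        )


@dataclass
class MockEncoderParams:
    """Class-conditional settings for the deterministic test encoder."""

    grid_side: int = 64
    n_codewords: int = 128
    class_sum_means: dict = field(default_factory=dict)  # label -> mean grid sum
    class_sum_sds: dict = field(default_factory=dict)  # label -> sd of grid sum
    seed: int = 0


def mock_encode(patch_id: int, class_label, params: MockEncoderParams) -> np.ndarray:
    """Deterministic latent grid whose total sum follows a class distribution.

    A stand-in for the neural encoder in tests and synthetic cohorts: the
    grid sum is drawn from a per-class normal distribution seeded by
    ``(seed, class, patch_id)``, so class structure propagates through the
    pooling pipeline into index space.
    """
    g = params.grid_side
    kmax = params.n_codewords - 1
    mean = float(params.class_sum_means[class_label])
    sd = float(params.class_sum_sds.get(class_label, 0.0))
    label_hash = zlib.crc32(str(class_label).encode("utf-8"))
    seed = np.random.SeedSequence([params.seed, label_hash, int(patch_id)])
    rng = np.random.default_rng(seed)
    total = mean if sd == 0 else rng.normal(mean, sd)
    total = int(np.clip(round(total), 0, kmax * g * g))
    base, rem = divmod(total, g * g)
    grid = np.full((g, g), base, dtype=np.int64)
    if rem:
        flat = grid.ravel()
        flat[:rem] += 1
    return grid
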