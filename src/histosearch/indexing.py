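"""Patch indices and binary texture codes.

Every mosaic patch is summarised by a tuple ``(p, h)``:

* ``p`` — a single integer built from the patch's discrete latent grid.
  The grid of codeword indices is average-pooled three times with 2x2
  windows; the cell sums of the three pooled grids are packed into
  disjoint decimal digit ranges::

      p = floor(s1) + floor(s2) * 10**6 + floor(s3) * 10**11

  With 64x64 grids and codeword indices in [0, 127] the three sums are
  bounded by 130048, 32512 and 8128, so the digit blocks never collide
  and every index fits below the universe constant M = 2**50.

* ``h`` — a binary code obtained from a real-valued texture descriptor by
  the sequential comparison rule: walking the vector left to right
  starting from +infinity, emit 0 when the value drops below its
  predecessor and 1 otherwise.  Patch similarity is the Hamming distance
  between codes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .veb import UNIVERSE_SIZE

__all__ = [
    "S1_MAX",
    "S2_MAX",
    "S3_MAX",
    "PatchKey",
    "pooled_sums",
    "compose_index",
    "decompose_index",
    "max_index",
    "universe_constant",
    "binarize",
    "hamming",
    "texture_feature",
    "IntensityStatsDescriptor",
]

# Pooled-sum maxima for a 64x64 grid of values in [0, 127].
S1_MAX = 130048
S2_MAX = 32512
S3_MAX = 8128


@dataclass(frozen=True)
class PatchKey:
    """Index/code pair identifying one mosaic patch in the search space."""

    p: int
    h: np.ndarray  # uint8 vector of 0/1, length L (default 1024)
    coords: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if not (0 <= self.p < UNIVERSE_SIZE):
            raise ValueError(f"index {self.p} outside universe [0, {UNIVERSE_SIZE})")
        object.__setattr__(self, "h", np.ascontiguousarray(self.h, dtype=np.uint8))


def pooled_sums(grid: np.ndarray) -> tuple[float, float, float]:
    """Sums of the latent grid after one, two and three 2x2 average pools.

    The grid side must be divisible by 8 so that all three poolings are
    well defined.  Because a 2x2 average pool followed by a total sum
    divides the total by exactly 4, ``s_k`` equals ``grid.sum() / 4**k``;
    the explicit pooling is kept so the arithmetic matches the pipeline
    definition cell for cell.
    """
    grid = np.asarray(grid, dtype=np.float64)
    if grid.ndim != 2 or grid.shape[0] != grid.shape[1]:
        raise ValueError("latent grid must be square")
    if grid.shape[0] % 8:
        raise ValueError("grid side must be divisible by 8")
    sums = []
    pooled = grid
    for _ in range(3):
        g = pooled.shape[0]
        pooled = pooled.reshape(g // 2, 2, g // 2, 2).mean(axis=(1, 3))
        sums.append(float(pooled.sum()))
    return sums[0], sums[1], sums[2]


def compose_index(s1: float, s2: float, s3: float) -> int:
    """Pack the three pooled sums into one integer index.

    Sums are floored to integers before the decimal shift so the result is
    a valid tree key; the digit blocks stay disjoint for all valid grids.
    """
    if not (0 <= s1 <= S1_MAX and 0 <= s2 <= S2_MAX and 0 <= s3 <= S3_MAX):
        raise ValueError(f"pooled sums ({s1}, {s2}, {s3}) out of range")
    return int(s1) + int(s2) * 10**6 + int(s3) * 10**11


def decompose_index(p: int) -> tuple[int, int, int]:
    """Recover the floored pooled sums from an index (inverse of compose)."""
    if not (0 <= p < UNIVERSE_SIZE):
        raise ValueError("index outside universe")
    s3, rest = divmod(p, 10**11)
    s2, s1 = divmod(rest, 10**6)
    return int(s1), int(s2), int(s3)


def grid_index(grid: np.ndarray) -> int:
    """Full pipeline: latent grid -> pooled sums -> integer index."""
    return compose_index(*pooled_sums(grid))


def max_index() -> int:
    """Largest index composable from a valid grid (all cells at 127)."""
    return compose_index(S1_MAX, S2_MAX, S3_MAX)


def universe_constant() -> int:
    """Smallest power of two strictly greater than the maximum index."""
    m = 1
    while m <= max_index():
        m <<= 1
    return m


def binarize(v: np.ndarray) -> np.ndarray:
    """Binary code of a real vector by sequential comparison.

    Bit ``j`` is 0 when ``v[j]`` is smaller than its predecessor and 1
    otherwise; the predecessor of the first element is +infinity, so bit 0
    is always 0.  The code has the same length as the input and is
    invariant under strictly increasing affine transforms of ``v``.
    """
    v = np.asarray(v, dtype=np.float64)
    if v.ndim != 1 or v.size < 1:
        raise ValueError("input must be a non-empty 1-D vector")
    if np.isnan(v).any():
        raise ValueError("input contains NaN")
    prev = np.concatenate(([np.inf], v[:-1]))
    return (v >= prev).astype(np.uint8)


def hamming(h1: np.ndarray, h2: np.ndarray) -> int:
    """Number of differing positions between two equal-length bit vectors."""
    h1 = np.asarray(h1)
    h2 = np.asarray(h2)
    if h1.shape != h2.shape:
        raise ValueError("bit vectors must have equal length")
    return int(np.count_nonzero(h1 != h2))


class IntensityStatsDescriptor:
    """Default texture descriptor: multiscale intensity statistics.

    Per colour channel and at four dyadic scales it collects a 32-bin
    intensity histogram together with mean, standard deviation and mean
    absolute horizontal/vertical differences, then maps the concatenation
    through a fixed-seed Gaussian projection to ``n_features`` dimensions.
    Deterministic by construction; any extractor producing a fixed-length
    vector (e.g. a DenseNet121 embedding) can be plugged in instead.
    """

    def __init__(self, n_features: int = 1024, seed: int = 13) -> None:
        self.n_features = n_features
        self.seed = seed
        self._proj: np.ndarray | None = None

    def _projection(self, in_dim: int) -> np.ndarray:
        if self._proj is None or self._proj.shape[0] != in_dim:
            rng = np.random.default_rng(self.seed)
            self._proj = rng.standard_normal((in_dim, self.n_features)) / np.sqrt(in_dim)
        return self._proj

    def __call__(self, image: np.ndarray) -> np.ndarray:
        img = np.asarray(image, dtype=np.float64)
        if img.ndim == 2:
            img = img[..., None].repeat(3, axis=2)
        if img.max() > 1.5:  # 8-bit input
            img = img / 255.0
        feats = []
        for level in range(4):
            if level:
                h, w = img.shape[0] // 2, img.shape[1] // 2
                if h < 2 or w < 2:
                    break
                img = img[: 2 * h, : 2 * w].reshape(h, 2, w, 2, -1).mean(axis=(1, 3))
            for c in range(img.shape[2]):
                ch = img[..., c]
                hist, _ = np.histogram(ch, bins=32, range=(0.0, 1.0))
                hist = hist / ch.size
                feats.append(hist)
                feats.append(
                    np.array(
                        [
                            ch.mean(),
                            ch.std(),
                            np.abs(np.diff(ch, axis=0)).mean() if ch.shape[0] > 1 else 0.0,
                            np.abs(np.diff(ch, axis=1)).mean() if ch.shape[1] > 1 else 0.0,
                        ]
                    )
                )
        raw = np.concatenate(feats)
        return raw @ self._projection(raw.size)


def texture_feature(patch: np.ndarray, descriptor=None) -> np.ndarray:
    """Real-valued texture vector of a patch under a pluggable descriptor."""
    if descriptor is None:
        descriptor = IntensityStatsDescriptor()
    return np.asarray(descriptor(patch), dtype=np.float64)
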