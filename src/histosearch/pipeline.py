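"""End-to-end build and query workflows over the library modules.

Slide sources are either a tiled/pyramidal TIFF readable by ``tifffile``,
a plain raster image, or a directory of patch images (PNG/JPEG), in
which case each image is treated as one pre-cut x20 tile and the
segmentation/tiling stages are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .database import SlideDatabase, SlideInfo
from .indexing import IntensityStatsDescriptor, PatchKey, binarize, grid_index
from .mosaic import (
    DebrisClassifier,
    MosaicParams,
    build_mosaic,
    filter_mosaic,
    read_tile,
    rgb_histogram_feature,
    segment_tissue,
    tile_slide,
)
from .vqvae import VqvaeModel

__all__ = ["SlideSource", "load_slide_image", "encode_patches", "build_slide_keys",
           "build_database_from_manifest", "read_manifest", "patch_query"]

THUMB_DOWNSAMPLE = 32


@dataclass
class SlideSource:
    slide_name: str
    patient_id: str
    diagnosis: str
    site: str
    path: Path
    native_mag: float = 20.0

    @property
    def slide_format(self) -> str:
        return "directory" if self.path.is_dir() else self.path.suffix.lstrip(".").lower()


def read_manifest(path) -> list[SlideSource]:
    """CSV manifest: slide_name, patient_id, diagnosis, site, path[, mag]."""
    df = pd.read_csv(path)
    required = {"slide_name", "patient_id", "diagnosis", "site", "path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if df["slide_name"].duplicated().any():
        dupes = df.loc[df["slide_name"].duplicated(), "slide_name"].tolist()
        raise ValueError(f"duplicate slide names in manifest: {dupes}")
    sources = []
    for row in df.itertuples(index=False):
        sources.append(
            SlideSource(
                slide_name=str(row.slide_name),
                patient_id=str(row.patient_id),
                diagnosis=str(row.diagnosis),
                site=str(row.site),
                path=Path(row.path),
                native_mag=float(getattr(row, "mag", 20.0)),
            )
        )
    return sources


def load_slide_image(path: Path) -> np.ndarray:
    """Read a slide raster (tiled TIFF via tifffile, else Pillow)."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff", ".svs"}:
        import tifffile

        return np.asarray(tifffile.imread(path))
    from PIL import Image

    return np.asarray(Image.open(path).convert("RGB"))


def _load_patch_dir(path: Path) -> list[np.ndarray]:
    from PIL import Image

    files = sorted(
        p for p in path.iterdir() if p.suffix.lower() in {".png", ".jpg", ".jpeg"}
    )
    if not files:
        raise ValueError(f"no patch images found in {path}")
    return [np.asarray(Image.open(f).convert("RGB")) for f in files]


def encode_patches(
    patches, encoder: VqvaeModel | None, descriptor=None
) -> list[PatchKey]:
    """Patch images -> (index, binary code) keys.

    With ``encoder`` None the patch's own mean-intensity grid stands in
    for the latent grid (useful for white-box tests); normally the
    trained quantized autoencoder produces the latent grid.
    """
    descriptor = descriptor or IntensityStatsDescriptor()
    keys = []
    for patch in patches:
        if encoder is not None:
            grid = encoder.encode(patch)
            if encoder.permutation is not None:
                grid = encoder.permutation[grid]
        else:
            grid = _intensity_grid(patch)
        p = grid_index(_ensure_poolable(grid))
        h = binarize(descriptor(patch))
        keys.append(PatchKey(p, h))
    return keys


def _intensity_grid(patch: np.ndarray, side: int = 64) -> np.ndarray:
    img = np.asarray(patch, dtype=np.float64)
    if img.ndim == 3:
        img = img.mean(axis=2)
    h, w = img.shape
    bh, bw = max(1, h // side), max(1, w // side)
    g = img[: bh * side, : bw * side].reshape(side, bh, side, bw).mean(axis=(1, 3))
    return np.clip(g / 2.0, 0, 127).astype(np.int64)  # map 0-255 onto 0-127


def _ensure_poolable(grid: np.ndarray) -> np.ndarray:
    side = grid.shape[0]
    if side % 8 == 0:
        return grid
    pad = 8 - side % 8
    return np.pad(grid, ((0, pad), (0, pad)))


def build_slide_keys(
    source: SlideSource,
    encoder: VqvaeModel | None,
    params: MosaicParams | None = None,
    debris_classifier: DebrisClassifier | None = None,
    descriptor=None,
):
    """Mosaic -> filter -> encode pipeline for one slide.

    Returns ``(keys, coords)``: PatchKeys with x20 tile coordinates.
    """
    params = params or MosaicParams()
    if source.path.is_dir():
        patches = _load_patch_dir(source.path)
        coords = [(i, 0) for i in range(len(patches))]
    else:
        slide = load_slide_image(source.path)
        thumb = slide[::THUMB_DOWNSAMPLE, ::THUMB_DOWNSAMPLE]
        mask = segment_tissue(thumb, params)
        coords = tile_slide(slide.shape[:2], mask, THUMB_DOWNSAMPLE, source.native_mag, params)
        if not coords:
            return [], []
        patches = [read_tile(slide, c, source.native_mag) for c in coords]
    feats = np.stack([rgb_histogram_feature(p, params.hist_bins) for p in patches])
    chosen = build_mosaic(coords, feats, params)
    chosen = filter_mosaic(chosen, [patches[i] for i in chosen], debris_classifier, params)
    mosaic_patches = [patches[i] for i in chosen]
    mosaic_coords = [coords[i] for i in chosen]
    keys = encode_patches(mosaic_patches, encoder, descriptor)
    keys = [
        PatchKey(k.p, k.h, coords=tuple(c)) for k, c in zip(keys, mosaic_coords)
    ]
    return keys, mosaic_coords


def build_database_from_manifest(
    sources: list[SlideSource],
    encoder: VqvaeModel | None = None,
    params: MosaicParams | None = None,
    code_length: int = 1024,
    debris_classifier: DebrisClassifier | None = None,
    skip_errors: bool = False,
) -> SlideDatabase:
    db = SlideDatabase(code_length=code_length)
    for source in sources:
        try:
            keys, _ = build_slide_keys(source, encoder, params, debris_classifier)
        except Exception:
            if skip_errors:
                continue
            raise
        db.add_slide(
            keys,
            SlideInfo(
                slide_name=source.slide_name,
                patient_id=source.patient_id,
                diagnosis=source.diagnosis,
                site=source.site,
                slide_format=source.slide_format,
            ),
        )
    return db


def patch_query(patch: np.ndarray, db: SlideDatabase, encoder=None, descriptor=None,
                search_params=None, top_k: int = 5):
    """Single-patch retrieval: a one-patch mosaic, no ranking module.

    Hits are sorted by Hamming distance and the top ``top_k`` returned
    with full provenance (slide, coordinates, distance).
    """
    from .search import SearchParams, guided_search

    key = encode_patches([patch], encoder, descriptor)[0]
    hits = guided_search(key.p, key.h, db, search_params or SearchParams())
    return hits[:top_k]
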