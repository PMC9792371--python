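"""Whole-slide distillation into a mosaic of representative patches.

Gigapixel slides are too large to compare region by region, so each
slide is summarised by a small set of tiles (its *mosaic*):

1. *Tissue segmentation* — threshold the saturation channel of a
   downsampled thumbnail in HSV space, median-blur and morphologically
   close the mask, and drop foreground components and cavities below an
   area threshold.
2. *Tiling* — cover the tissue with non-overlapping 1024 x 1024 tiles in
   the x20 reference frame (a x40 slide is tiled at 2048 and downsampled
   2x, giving equivalent tiles); a tile is kept when enough of it lies on
   tissue.
3. *Two-stage K-means selection* — cluster the tiles' RGB colour
   histograms into (up to) 9 colour groups, then cluster the tile
   coordinates within each group, keeping 5% of the group (all of it
   when 5% falls below one tile).  The tiles nearest the spatial centers
   form the mosaic.
4. *Filtering* — remove mosaic entries that a local-binary-pattern +
   logistic-regression classifier labels as debris/pen smudge, and
   entries whose near-white pixels (grayscale >= 235) cover more than
   90% of the patch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage import color, filters, morphology
from skimage.feature import local_binary_pattern
from sklearn.cluster import KMeans
from sklearn.linear_model import LogisticRegression

__all__ = [
    "MosaicParams",
    "segment_tissue",
    "tile_slide",
    "read_tile",
    "rgb_histogram_feature",
    "build_mosaic",
    "DebrisClassifier",
    "is_mostly_white",
    "filter_mosaic",
]

TILE_SIDE = 1024  # pixels at the x20 reference frame


@dataclass
class MosaicParams:
    sat_threshold: float = 0.08  # HSV saturation cut for tissue
    median_size: int = 7
    closing_size: int = 4
    min_area_fraction: float = 0.001  # of the thumbnail area
    coverage: float = 0.5  # tissue fraction required to keep a tile
    k_rgb: int = 9  # stage-1 colour clusters
    sample_fraction: float = 0.05  # stage-2 share of each cluster
    hist_bins: int = 64  # per-channel bins of the stage-1 feature
    white_threshold: int = 235
    white_fraction: float = 0.9
    lbp_points: int = 8
    lbp_radius: float = 1.0
    lbp_bins: int = 128
    seed: int = 0
    kmeans_restarts: int = 10


def segment_tissue(thumbnail: np.ndarray, params: MosaicParams | None = None) -> np.ndarray:
    """Binary tissue mask of a thumbnail image.

    Saturation threshold in HSV space, median blur, morphological
    closing, then removal of small objects and small holes (cavities).
    An all-background image yields an empty mask.
    """
    params = params or MosaicParams()
    img = np.asarray(thumbnail)
    if img.size == 0:
        raise ValueError("empty thumbnail")
    if img.dtype != np.uint8:
        img = np.clip(img, 0, 255).astype(np.uint8) if img.max() > 1.5 else (
            np.clip(img, 0, 1) * 255
        ).astype(np.uint8)
    sat = color.rgb2hsv(img)[..., 1]
    mask = sat > params.sat_threshold
    mask = filters.median(mask, morphology.footprint_rectangle((params.median_size,) * 2))
    mask = morphology.closing(mask, morphology.footprint_rectangle((params.closing_size,) * 2))
    min_area = max(1, int(params.min_area_fraction * mask.size))
    # max_size removes components <= the value; min_area - 1 keeps the
    # "strictly smaller than min_area" rule
    mask = morphology.remove_small_objects(mask, max_size=min_area - 1)
    mask = morphology.remove_small_holes(mask, max_size=min_area - 1)
    return mask


def tile_slide(
    slide_shape: tuple[int, int],
    mask: np.ndarray,
    mask_downsample: float,
    native_mag: float = 20.0,
    params: MosaicParams | None = None,
) -> list[tuple[int, int]]:
    """Non-overlapping tissue tile coordinates in the x20 reference frame.

    ``slide_shape`` is (height, width) at native magnification and
    ``mask_downsample`` the factor between native pixels and the mask.
    On x40 slides the native tile is 2048 px (downsampled 2x on read), so
    the returned x20 coordinates line up with the x20 tiling of the same
    tissue footprint.  Coordinates are 0-based (x, y) top-left corners.
    """
    params = params or MosaicParams()
    if native_mag not in (20.0, 40.0):
        raise ValueError("native magnification must be 20 or 40")
    scale = native_mag / 20.0  # native px per x20 px
    native_tile = int(TILE_SIDE * scale)
    h, w = slide_shape[:2]
    tiles = []
    for y0 in range(0, h - native_tile + 1, native_tile):
        for x0 in range(0, w - native_tile + 1, native_tile):
            my0 = int(y0 / mask_downsample)
            my1 = max(my0 + 1, int(math.ceil((y0 + native_tile) / mask_downsample)))
            mx0 = int(x0 / mask_downsample)
            mx1 = max(mx0 + 1, int(math.ceil((x0 + native_tile) / mask_downsample)))
            window = mask[my0:my1, mx0:mx1]
            if window.size and window.mean() >= params.coverage:
                tiles.append((int(x0 / scale), int(y0 / scale)))
    return tiles


def read_tile(
    slide: np.ndarray, coord: tuple[int, int], native_mag: float = 20.0
) -> np.ndarray:
    """Extract the 1024 x 1024 x20-equivalent patch at a tile coordinate."""
    scale = native_mag / 20.0
    x0, y0 = int(coord[0] * scale), int(coord[1] * scale)
    side = int(TILE_SIDE * scale)
    patch = slide[y0 : y0 + side, x0 : x0 + side]
    if scale > 1:
        s = int(scale)
        patch = patch.reshape(
            patch.shape[0] // s, s, patch.shape[1] // s, s, -1
        ).mean(axis=(1, 3))
        patch = np.clip(patch, 0, 255).astype(np.uint8)
    return patch


def rgb_histogram_feature(patch: np.ndarray, bins: int = 64) -> np.ndarray:
    """Concatenated per-channel colour histogram, L1-normalised."""
    img = np.asarray(patch)
    if img.max() <= 1.5 and img.dtype != np.uint8:
        img = (img * 255).astype(np.uint8)
    feats = [
        np.histogram(img[..., c], bins=bins, range=(0, 256))[0] for c in range(3)
    ]
    vec = np.concatenate(feats).astype(np.float64)
    total = vec.sum()
    return vec / total if total else vec


def build_mosaic(
    tiles: list[tuple[int, int]],
    features: np.ndarray,
    params: MosaicParams | None = None,
) -> list[int]:
    """Indices of the tiles selected into the mosaic.

    Stage 1 clusters the RGB histogram features into ``min(k_rgb, n)``
    colour groups; stage 2 clusters tile coordinates within each group.
    A group contributing fewer than one tile at the 5% rate is taken
    whole; otherwise ``ceil(0.05 * group size)`` spatial centers are
    found and the nearest tile to each center (Euclidean distance, ties
    by row-major order) enters the mosaic.
    """
    params = params or MosaicParams()
    n = len(tiles)
    if n == 0:
        raise ValueError("no tiles to build a mosaic from")
    if n == 1:
        return [0]
    feats = np.asarray(features, dtype=np.float64)
    coords = np.asarray(tiles, dtype=np.float64)
    k1 = min(params.k_rgb, n)
    stage1 = KMeans(
        n_clusters=k1, n_init=params.kmeans_restarts, random_state=params.seed
    ).fit_predict(feats)
    selected: list[int] = []
    for cluster_id in range(k1):
        members = np.flatnonzero(stage1 == cluster_id)
        if members.size == 0:
            continue
        if params.sample_fraction * members.size < 1:
            selected.extend(int(i) for i in members)
            continue
        k2 = math.ceil(params.sample_fraction * members.size)
        centers = KMeans(
            n_clusters=k2, n_init=params.kmeans_restarts, random_state=params.seed
        ).fit(coords[members]).cluster_centers_
        taken: set[int] = set()
        for center in centers:
            d = np.linalg.norm(coords[members] - center, axis=1)
            order = np.lexsort((members, d))  # distance, then row-major tile order
            for j in order:
                idx = int(members[j])
                if idx not in taken:
                    taken.add(idx)
                    selected.append(idx)
                    break
    return sorted(set(selected))


class DebrisClassifier:
    """LBP-histogram + logistic-regression debris/pen-smudge detector.

    Uses the rotation-invariant local binary pattern (P=8, R=1) with a
    128-bin histogram as the texture feature; label 1 marks debris.
    """

    def __init__(self, params: MosaicParams | None = None):
        self.params = params or MosaicParams()
        self._clf: LogisticRegression | None = None

    def _feature(self, patch: np.ndarray) -> np.ndarray:
        img = np.asarray(patch)
        gray = color.rgb2gray(img) if img.ndim == 3 else img.astype(np.float64)
        gray = (gray * 255).astype(np.uint8) if gray.max() <= 1.5 else gray.astype(np.uint8)
        lbp = local_binary_pattern(
            gray, self.params.lbp_points, self.params.lbp_radius, method="ror"
        )
        hist, _ = np.histogram(lbp, bins=self.params.lbp_bins, range=(0, 256))
        return hist / max(1, hist.sum())

    def fit(self, patches, labels) -> "DebrisClassifier":
        X = np.stack([self._feature(p) for p in patches])
        self._clf = LogisticRegression(max_iter=1000, random_state=self.params.seed)
        self._clf.fit(X, np.asarray(labels))
        return self

    @property
    def is_trained(self) -> bool:
        return self._clf is not None

    def predict(self, patches) -> np.ndarray:
        if self._clf is None:
            raise RuntimeError("debris classifier is not trained")
        X = np.stack([self._feature(p) for p in patches])
        return self._clf.predict(X)


def is_mostly_white(patch: np.ndarray, params: MosaicParams | None = None) -> bool:
    """True when near-white pixels exceed the configured fraction."""
    params = params or MosaicParams()
    img = np.asarray(patch)
    gray = color.rgb2gray(img) * 255 if img.ndim == 3 else img
    return float((gray >= params.white_threshold).mean()) > params.white_fraction


def filter_mosaic(
    entries: list[int],
    patches,
    classifier: DebrisClassifier | None = None,
    params: MosaicParams | None = None,
) -> list[int]:
    """Drop white-background and debris entries from a mosaic.

    ``patches[i]`` is the image of ``entries[i]``.  Without a trained
    classifier only the white filter applies (white-filter-only mode).
    """
    params = params or MosaicParams()
    if classifier is not None and not classifier.is_trained:
        raise RuntimeError("debris classifier provided but not trained")
    kept = []
    debris = (
        classifier.predict(patches) if classifier is not None and len(entries) else []
    )
    for i, entry in enumerate(entries):
        if is_mostly_white(patches[i], params):
            continue
        if classifier is not None and debris[i] == 1:
            continue
        kept.append(entry)
    return kept
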