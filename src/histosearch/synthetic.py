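"""Synthetic cohorts and patch images for end-to-end testing.

Real slide archives are enormous; these generators create miniature
cohorts that carry exactly the statistical structure the search engine
exploits, so every stage is testable without external data:

* *Index locality* — each class draws its patches' latent-grid sums from
  a class-specific normal distribution (via the deterministic mock
  encoder), so same-class patches land near each other in the integer
  index universe.
* *Hamming similarity* — each class owns a random binary prototype of
  length ``L``; a patch's code is the prototype with i.i.d. bit flips at
  rate ``epsilon``.  Expected within-class pairwise distance is
  ``2 eps (1 - eps) L``, cross-class distance about ``L / 2``.
* *Patients* — slides are grouped into multi-slide patients so
  leave-one-patient-out exclusion is exercised.

Patch *images* (tissue texture / near-white / debris smudge) exercise the
mosaic filters and the autoencoder without any photorealism ambition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .database import SlideDatabase, SlideInfo
from .indexing import PatchKey, grid_index
from .vqvae import MockEncoderParams, mock_encode

__all__ = [
    "CohortSpec",
    "SlideRecord",
    "generate_cohort",
    "build_database",
    "generate_query_set",
    "generate_patch_images",
]


@dataclass
class CohortSpec:
    """Study conditions of a synthetic cohort."""

    n_classes: int = 4
    slides_per_class: tuple[int, ...] | int = 50
    slides_per_patient: int = 2
    mosaic_size_range: tuple[int, int] = (8, 12)
    code_length: int = 1024
    bit_flip_rate: float = 0.02  # epsilon
    grid_side: int = 64
    # grid-sum distribution per class; defaults spread classes far apart
    class_sum_means: tuple[float, ...] | None = None
    class_sum_sd: float = 2000.0
    site: str = "synthetic_site"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.bit_flip_rate < 0.5):
            raise ValueError("bit flip rate must be in [0, 0.5)")
        if isinstance(self.slides_per_class, int):
            self.slides_per_class = (self.slides_per_class,) * self.n_classes
        if len(self.slides_per_class) != self.n_classes:
            raise ValueError("slides_per_class length must equal n_classes")
        if self.class_sum_means is None:
            # spaced by ~100k grid-sum units: ~25 sd gaps at the default sd
            self.class_sum_means = tuple(
                60_000.0 + 100_000.0 * c for c in range(self.n_classes)
            )

    @property
    def labels(self) -> list[str]:
        return [f"class_{c}" for c in range(self.n_classes)]


@dataclass
class SlideRecord:
    """One synthetic slide: manifest entry plus its mosaic patch keys."""

    info: SlideInfo
    keys: list[PatchKey]

    @property
    def slide_name(self) -> str:
        return self.info.slide_name

    @property
    def patient_id(self) -> str:
        return self.info.patient_id

    @property
    def diagnosis(self) -> str:
        return self.info.diagnosis


def generate_cohort(spec: CohortSpec) -> list[SlideRecord]:
    """Per-slide patch keys and manifest entries, reproducible by seed."""
    rng = np.random.default_rng(spec.seed)
    enc = MockEncoderParams(
        grid_side=spec.grid_side,
        class_sum_means={
            lb: m for lb, m in zip(spec.labels, spec.class_sum_means)
        },
        class_sum_sds={lb: spec.class_sum_sd for lb in spec.labels},
        seed=spec.seed,
    )
    prototypes = {
        lb: rng.integers(0, 2, size=spec.code_length).astype(np.uint8)
        for lb in spec.labels
    }
    records = []
    patch_counter = 0
    slide_counter = 0
    for c, label in enumerate(spec.labels):
        n_slides = spec.slides_per_class[c]
        for s in range(n_slides):
            slide_name = f"slide_{slide_counter:04d}"
            patient_id = f"patient_{c}_{s // spec.slides_per_patient:03d}"
            n_patches = int(rng.integers(spec.mosaic_size_range[0], spec.mosaic_size_range[1] + 1))
            keys = []
            for j in range(n_patches):
                grid = mock_encode(patch_counter, label, enc)
                p = grid_index(grid)
                flips = rng.random(spec.code_length) < spec.bit_flip_rate
                h = np.where(flips, 1 - prototypes[label], prototypes[label]).astype(np.uint8)
                keys.append(PatchKey(p, h, coords=(j * 1024, 0)))
                patch_counter += 1
            records.append(
                SlideRecord(
                    info=SlideInfo(
                        slide_name=slide_name,
                        patient_id=patient_id,
                        diagnosis=label,
                        site=spec.site,
                    ),
                    keys=keys,
                )
            )
            slide_counter += 1
    return records


def build_database(records: list[SlideRecord], code_length: int = 1024) -> SlideDatabase:
    db = SlideDatabase(code_length=code_length)
    for rec in records:
        db.add_slide(rec.keys, rec.info)
    return db


@dataclass
class Query:
    slide_name: str
    patient_id: str
    diagnosis: str
    keys: list[PatchKey]


def generate_query_set(
    records: list[SlideRecord], holdout_fraction: float = 0.0, seed: int = 0
) -> tuple[list[SlideRecord], list[Query]]:
    """Split a cohort into database records and labelled queries.

    With ``holdout_fraction`` 0 every slide is both stored and queried
    (self-search; leave-one-patient-out masks its own patient at query
    time).  Otherwise the requested fraction of each class is held out as
    queries and the remainder forms the database.
    """
    if holdout_fraction == 0.0:
        queries = [
            Query(r.slide_name, r.patient_id, r.diagnosis, r.keys) for r in records
        ]
        return records, queries
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[SlideRecord]] = {}
    for r in records:
        by_class.setdefault(r.diagnosis, []).append(r)
    db_records, queries = [], []
    for label in sorted(by_class):
        group = by_class[label]
        n_hold = max(1, int(round(holdout_fraction * len(group))))
        held = set(rng.choice(len(group), size=n_hold, replace=False).tolist())
        for i, r in enumerate(group):
            if i in held:
                queries.append(Query(r.slide_name, r.patient_id, r.diagnosis, r.keys))
            else:
                db_records.append(r)
    return db_records, queries


def generate_patch_images(kind: str, n: int, seed: int = 0, side: int = 64):
    """Seeded RGB uint8 images of a given kind.

    ``tissue``: pinkish periodic texture with noise (two sub-styles keyed
    by the seed make texture classes separable); ``white``: near-uniform
    images with every pixel >= 235; ``debris``: dark smudge blobs on a
    light ground.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:side, 0:side]
    images = []
    for _ in range(n):
        if kind == "tissue":
            fx = rng.uniform(0.2, 0.6)
            fy = rng.uniform(0.2, 0.6)
            base = 0.5 + 0.5 * np.sin(fx * xx) * np.cos(fy * yy)
            noise = rng.normal(0, 0.08, size=(side, side))
            r = np.clip(200 + 40 * base + 25 * noise, 0, 255)
            g = np.clip(120 + 60 * base + 25 * noise, 0, 255)
            b = np.clip(170 + 50 * base + 25 * noise, 0, 255)
            img = np.stack([r, g, b], axis=2).astype(np.uint8)
        elif kind == "white":
            level = rng.integers(243, 253)
            img = np.clip(
                level + rng.normal(0, 1.5, size=(side, side, 3)), 236, 255
            ).astype(np.uint8)
        elif kind == "debris":
            img = np.full((side, side, 3), 210, dtype=np.uint8)
            for _blob in range(int(rng.integers(3, 7))):
                cx, cy = rng.uniform(0, side, 2)
                rad = rng.uniform(side / 10, side / 4)
                blob = (xx - cx) ** 2 + (yy - cy) ** 2 < rad**2
                shade = rng.integers(10, 70, size=3)
                for ch in range(3):
                    channel = img[..., ch]
                    channel[blob] = shade[ch]
        else:
            raise ValueError(f"unknown image kind {kind!r}")
        images.append(img)
    return images
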