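"""The searchable slide store.

A database couples a van Emde Boas tree holding every distinct patch
index with a hash table ``H`` mapping each index to the list of patch
metadata records that share it (different patches can land on the same
key).  Slide-level bookkeeping lives in a manifest keyed by slide name;
``D_inv`` — the reciprocal of each diagnosis' slide count, used by the
ranking module to de-emphasise over-represented diagnoses — is derived
from the manifest on demand.

Persistence is a two-file archive: an HDF5 file with the numeric payload
(indices, packed bit codes, coordinates) and a JSON sidecar with slide
labels and configuration, so the archive is inspectable and portable.
The tree itself is never serialised; it is rebuilt from the key set on
restore.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .indexing import PatchKey
from .veb import UNIVERSE_BITS, VebTree

__all__ = ["PatchMeta", "SlideInfo", "SlideDatabase"]

ARCHIVE_VERSION = 1


@dataclass
class PatchMeta:
    """Metadata stored for one mosaic patch (the value entries of H)."""

    slide_name: str
    patient_id: str
    diagnosis: str
    site: str
    coords: tuple[int, int]
    slide_format: str
    h: np.ndarray  # uint8 0/1 texture code
    hamming_dist: int | None = None  # populated in search results only


@dataclass
class SlideInfo:
    slide_name: str
    patient_id: str
    diagnosis: str
    site: str = ""
    slide_format: str = "synthetic"
    indices: list[int] = field(default_factory=list)


class SlideDatabase:
    def __init__(self, code_length: int = 1024, universe_bits: int = UNIVERSE_BITS):
        self.code_length = code_length
        self.tree = VebTree(universe_bits)
        self.H: dict[int, list[PatchMeta]] = {}
        self.manifest: dict[str, SlideInfo] = {}

    # -- bookkeeping -------------------------------------------------------
    @property
    def n_slides(self) -> int:
        return len(self.manifest)

    @property
    def n_patches(self) -> int:
        return sum(len(v) for v in self.H.values())

    def diagnosis_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for info in self.manifest.values():
            counts[info.diagnosis] = counts.get(info.diagnosis, 0) + 1
        return counts

    def d_inv(self) -> dict[str, float]:
        """Reciprocal slide count per diagnosis (un-normalised weights)."""
        return {d: 1.0 / c for d, c in self.diagnosis_counts().items()}

    # -- mutation ------------------------------------------------------------
    def add_slide(self, keys: list[PatchKey], info: SlideInfo) -> None:
        if info.slide_name in self.manifest:
            raise ValueError(f"slide {info.slide_name!r} already present")
        stored = replace(info, indices=[])
        for key in keys:
            if key.h.size != self.code_length:
                raise ValueError(
                    f"bit code length {key.h.size} != database length {self.code_length}"
                )
            meta = PatchMeta(
                slide_name=info.slide_name,
                patient_id=info.patient_id,
                diagnosis=info.diagnosis,
                site=info.site,
                coords=tuple(key.coords),
                slide_format=info.slide_format,
                h=key.h,
            )
            self.tree.insert(key.p)
            self.H.setdefault(key.p, []).append(meta)
            stored.indices.append(key.p)
        self.manifest[info.slide_name] = stored

    def remove_slide(self, slide_name: str) -> None:
        info = self.manifest.pop(slide_name, None)
        if info is None:
            raise KeyError(f"slide {slide_name!r} not in database")
        for p in info.indices:
            metas = self.H.get(p, [])
            metas = [m for m in metas if m.slide_name != slide_name]
            if metas:
                self.H[p] = metas
            else:
                self.H.pop(p, None)
                self.tree.delete(p)

    # -- persistence -----------------------------------------------------
    def persist(self, path) -> None:
        """Write the archive as ``<path>.h5`` + ``<path>.json``."""
        import h5py

        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        slide_order = list(self.manifest)
        indices, bits, coords, slide_idx = [], [], [], []
        for s, name in enumerate(slide_order):
            info = self.manifest[name]
            # keep per-slide insertion order; locate each patch's metadata
            remaining = {p: [m for m in self.H[p] if m.slide_name == name] for p in set(info.indices)}
            for p in info.indices:
                meta = remaining[p].pop(0)
                indices.append(p)
                bits.append(np.packbits(meta.h))
                coords.append(meta.coords)
                slide_idx.append(s)
        with h5py.File(path.with_suffix(".h5"), "w") as f:
            kw = dict(track_times=False)
            f.create_dataset("indices", data=np.array(indices, dtype=np.uint64), **kw)
            f.create_dataset(
                "bits",
                data=np.array(bits, dtype=np.uint8).reshape(len(bits), -1)
                if bits
                else np.zeros((0, self.code_length // 8), dtype=np.uint8),
                **kw,
            )
            f.create_dataset(
                "coords",
                data=np.array(coords, dtype=np.int64).reshape(len(coords), 2)
                if coords
                else np.zeros((0, 2), dtype=np.int64),
                **kw,
            )
            f.create_dataset("slide_idx", data=np.array(slide_idx, dtype=np.int32), **kw)
        sidecar = {
            "version": ARCHIVE_VERSION,
            "code_length": self.code_length,
            "universe_bits": self.tree.bits,
            "slides": [
                {
                    "slide_name": self.manifest[n].slide_name,
                    "patient_id": self.manifest[n].patient_id,
                    "diagnosis": self.manifest[n].diagnosis,
                    "site": self.manifest[n].site,
                    "slide_format": self.manifest[n].slide_format,
                }
                for n in slide_order
            ],
        }
        path.with_suffix(".json").write_text(
            json.dumps(sidecar, indent=1, sort_keys=True) + "\n"
        )

    @classmethod
    def restore(cls, path) -> "SlideDatabase":
        import h5py

        path = Path(path)
        h5_path, json_path = path.with_suffix(".h5"), path.with_suffix(".json")
        if not h5_path.exists() or not json_path.exists():
            raise FileNotFoundError(f"archive {path} incomplete")
        try:
            sidecar = json.loads(json_path.read_text())
        except json.JSONDecodeError as exc:
            raise ValueError(f"corrupt archive manifest: {exc}") from exc
        if sidecar.get("version") != ARCHIVE_VERSION:
            raise ValueError(
                f"archive version {sidecar.get('version')} != {ARCHIVE_VERSION}"
            )
        db = cls(code_length=sidecar["code_length"], universe_bits=sidecar["universe_bits"])
        try:
            with h5py.File(h5_path, "r") as f:
                indices = f["indices"][:]
                bits = f["bits"][:]
                coords = f["coords"][:]
                slide_idx = f["slide_idx"][:]
        except OSError as exc:
            raise ValueError(f"corrupt archive payload: {exc}") from exc
        slides = sidecar["slides"]
        per_slide: dict[int, list[PatchKey]] = {s: [] for s in range(len(slides))}
        for p, packed, (x, y), s in zip(indices, bits, coords, slide_idx):
            h = np.unpackbits(packed)[: db.code_length]
            per_slide[int(s)].append(PatchKey(int(p), h, (int(x), int(y))))
        for s, entry in enumerate(slides):
            db.add_slide(
                per_slide.get(s, []),
                SlideInfo(
                    slide_name=entry["slide_name"],
                    patient_id=entry["patient_id"],
                    diagnosis=entry["diagnosis"],
                    site=entry["site"],
                    slide_format=entry["slide_format"],
                ),
            )
        return db

    # -- structural equality (tests, round-trips) ---------------------------
    def structurally_equal(self, other: "SlideDatabase") -> bool:
        if self.code_length != other.code_length:
            return False
        if set(self.H) != set(other.H):
            return False
        if sorted(self.manifest) != sorted(other.manifest):
            return False
        for name in self.manifest:
            a, b = self.manifest[name], other.manifest[name]
            if (a.patient_id, a.diagnosis, a.site, sorted(a.indices)) != (
                b.patient_id,
                b.diagnosis,
                b.site,
                sorted(b.indices),
            ):
                return False
        for p, metas in self.H.items():
            others = other.H[p]
            if len(metas) != len(others):
                return False
            key = lambda m: (m.slide_name, m.coords)
            for ma, mb in zip(sorted(metas, key=key), sorted(others, key=key)):
                if ma.slide_name != mb.slide_name or ma.coords != mb.coords:
                    return False
                if not np.array_equal(ma.h, mb.h):
                    return False
        return True
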