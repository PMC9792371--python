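"""Entropy-based ranking of per-patch retrieval results.

Guided search returns one result set ``r_i`` per query-mosaic patch.
Not every patch is equally informative: a patch whose hits span many
diagnoses says little about the slide.  The ranking module scores each
``r_i`` by a weighted label entropy, discards outlier patches, filters
patches that disagree with a pseudo-label consensus, and assembles the
final top-K slide list.

Stages (each independently switchable for ablation):

1. *Weighted uncertainty* — each hit contributes
   ``D_inv[diagnosis] / position`` to its diagnosis' occurrence count,
   where ``D_inv`` is the reciprocal slide count of the diagnosis
   normalised to sum to ``N`` (10 for fixed-site, 30 for anatomic-site
   retrieval) and position is the 1-based rank of the hit.  Counts below
   1 are clamped to 1; the entropy (base 2, over the normalised counts)
   is the patch's uncertainty.
2. *Clean* — drop result sets whose length falls outside the [5%, 95%]
   quantiles (only when at least 3 distinct lengths exist), derive a
   distance threshold ``theta_h'`` as the mean over surviving sets of the
   mean top-5 hit distance, drop sets above it, and sort ascending by
   entropy.
3. *Filter by prediction* — sum weighted occurrences over the ``k_f``
   most certain sets to get a pseudo-label, then remove sets whose own
   top diagnosis disagrees; if that would remove all of them, fall back
   to the next pseudo-label.
4. *Assembly* — walk the surviving sets in entropy order; take all hits
   of zero-entropy sets and only hits with distance <= ``theta_h'``
   otherwise; deduplicate slide names on first appearance; sort by
   (entropy ascending, distance descending) and return the first K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .database import PatchMeta

__all__ = [
    "RankingConfig",
    "CleanParams",
    "RankedSlide",
    "normalize_weights",
    "weighted_uncertainty",
    "clean",
    "filter_by_prediction",
    "rank_slides",
]


@dataclass
class CleanParams:
    o_l: float = 0.05  # low length quantile
    o_h: float = 0.95  # high length quantile
    k_top: int = 5  # hits entering the mean-distance threshold
    min_unique_lengths: int = 3

    def __post_init__(self) -> None:
        if not (0 <= self.o_l < self.o_h <= 1):
            raise ValueError("quantiles must satisfy 0 <= o_l < o_h <= 1")


@dataclass
class RankingConfig:
    N: float = 10.0  # weight normalisation constant (10 fixed site, 30 anatomic)
    K: int = 5  # slides returned (5 subtype, 10 anatomic site)
    k_f: int = 5  # consensus size for filter-by-prediction
    clean_params: CleanParams = field(default_factory=CleanParams)
    use_weighted_count: bool = True  # False = "Naive" unit counts
    use_clean: bool = True
    use_filter: bool = True
    distance_tie_descending: bool = True  # final sort tie-break direction


@dataclass
class RankedSlide:
    slide_name: str
    diagnosis: str
    entropy: float
    hamming_dist: int


@dataclass
class _SummaryEntry:
    """One S_m record: (patch index, entropy, hit distances, result length)."""

    i: int
    ent: float
    dist: list[int]
    length: int


def normalize_weights(d_inv: dict[str, float], n: float) -> dict[str, float]:
    """Scale the reciprocal diagnosis counts so they sum to ``n``."""
    total = sum(d_inv.values())
    if total <= 0:
        raise ValueError("weights must have positive sum")
    return {d: w * n / total for d, w in d_inv.items()}


def _entropy(counts: dict[str, float]) -> float:
    total = sum(counts.values())
    ent = 0.0
    for c in counts.values():
        if c > 0:
            p = c / total
            ent -= p * math.log2(p)
    return ent


def weighted_uncertainty(
    r_i: list[PatchMeta], d_inv: dict[str, float], weighted: bool = True
):
    """Entropy, weighted occurrence table and distances of one result set.

    ``r_i`` must be sorted ascending by Hamming distance; positions are
    1-based, so earlier (closer) hits weigh more.  With ``weighted`` off,
    every hit contributes a unit count (the naive ablation) and no
    clamping applies.
    """
    label_cnt: dict[str, float] = {}
    dist: list[int] = []
    for pos, meta in enumerate(r_i, start=1):
        d = meta.diagnosis
        if weighted:
            label_cnt[d] = label_cnt.get(d, 0.0) + d_inv[d] / pos
        else:
            label_cnt[d] = label_cnt.get(d, 0.0) + 1.0
        dist.append(int(meta.hamming_dist))
    if weighted:
        for lb, cnt in label_cnt.items():
            if cnt < 1.0:
                label_cnt[lb] = 1.0
    return _entropy(label_cnt), label_cnt, dist


def _quantile(values: list[int], q: float) -> float:
    # linear interpolation between order statistics
    import numpy as np

    return float(np.quantile(np.asarray(values, dtype=np.float64), q))


def _mean_top(dist: list[int], k: int) -> float:
    head = dist[:k]
    return sum(head) / len(head) if head else math.inf


def clean(s_m: list[_SummaryEntry], s_l: list[int], params: CleanParams):
    """Outlier removal; returns (surviving entries sorted by entropy, theta_h')."""
    if not s_m:
        return [], None
    survivors = []
    tmp = []
    if len(set(s_l)) >= params.min_unique_lengths:
        lo = _quantile(s_l, params.o_l)
        hi = _quantile(s_l, params.o_h)
        for res in s_m:
            if res.length <= lo or res.length >= hi:
                continue
            survivors.append(res)
            tmp.append(_mean_top(res.dist, params.k_top))
    else:
        survivors = list(s_m)
        tmp = [_mean_top(res.dist, params.k_top) for res in s_m]
    if not survivors:
        return [], None
    theta_h_prime = sum(tmp) / len(tmp)
    survivors = [
        res for res in survivors if _mean_top(res.dist, params.k_top) <= theta_h_prime
    ]
    survivors.sort(key=lambda res: (res.ent, res.i))
    return survivors, theta_h_prime


def filter_by_prediction(
    s_m: list[_SummaryEntry], s_lb: dict[int, dict[str, float]], k_f: int = 5
) -> set[int]:
    """Indices of the top-``k_f`` entries disagreeing with the pseudo-label.

    The pseudo-label is the diagnosis with the largest summed weighted
    occurrence over the ``k_f`` most certain entries; if removing the
    disagreeing entries would empty that head, the next-best pseudo-label
    is tried instead (and so on), so the filter can never remove every
    candidate.
    """
    if not s_m:
        return set()
    head = s_m[:k_f]
    cnt: dict[str, float] = {}
    for entry in head:
        for d, w in s_lb[entry.i].items():
            cnt[d] = cnt.get(d, 0.0) + w
    # deterministic ordering: score descending, label ascending on ties
    plb_list = sorted(cnt, key=lambda d: (-cnt[d], d))
    for plb in plb_list:
        removed = set()
        for entry in head:
            table = s_lb[entry.i]
            pred = sorted(table, key=lambda d: (-table[d], d))[0]
            if pred != plb:
                removed.add(entry.i)
        if len(removed) != len(head):
            return removed
    return set()


def rank_slides(
    r_all: list[list[PatchMeta]],
    d_inv: dict[str, float],
    config: RankingConfig | None = None,
) -> list[RankedSlide]:
    """Assemble the final top-K slides from all per-patch result sets."""
    config = config or RankingConfig()
    if not r_all or all(not r for r in r_all):
        return []
    d_inv = normalize_weights(d_inv, config.N)

    s_m: list[_SummaryEntry] = []
    s_l: list[int] = []
    s_lb: dict[int, dict[str, float]] = {}
    for i, r_i in enumerate(r_all):
        if not r_i:
            continue
        ent, label_cnt, dist = weighted_uncertainty(
            r_i, d_inv, weighted=config.use_weighted_count
        )
        s_lb[i] = label_cnt
        s_m.append(_SummaryEntry(i=i, ent=ent, dist=dist, length=len(r_i)))
        s_l.append(len(r_i))

    theta_h_prime = None
    if config.use_clean:
        s_m, theta_h_prime = clean(s_m, s_l, config.clean_params)
    else:
        s_m = sorted(s_m, key=lambda res: (res.ent, res.i))
    if not s_m:
        return []

    removed = (
        filter_by_prediction(s_m, s_lb, config.k_f) if config.use_filter else set()
    )

    ranked: list[RankedSlide] = []
    seen: set[str] = set()
    for entry in s_m:
        if entry.i in removed:
            continue
        for meta in r_all[entry.i]:
            if meta.slide_name in seen:
                continue
            if entry.ent > 0 and theta_h_prime is not None and meta.hamming_dist > theta_h_prime:
                continue
            ranked.append(
                RankedSlide(
                    slide_name=meta.slide_name,
                    diagnosis=meta.diagnosis,
                    entropy=entry.ent,
                    hamming_dist=int(meta.hamming_dist),
                )
            )
            seen.add(meta.slide_name)
    sign = -1 if config.distance_tie_descending else 1
    ranked.sort(key=lambda r: (r.entropy, sign * r.hamming_dist, r.slide_name))
    return ranked[: config.K]
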