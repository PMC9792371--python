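"""Leave-one-patient-out retrieval evaluation.

Queries are slides with known diagnosis; every slide sharing the query's
patient is excluded from the database view before scoring.  Two metrics
are reported per cancer subtype:

* ``mMV@k`` — fraction of the subtype's queries whose top-``k``
  majority-vote label equals the ground truth.  Vote ties are broken in
  favour of the tied label with the smallest mean hit distance.
* ``mAP@k`` — mean average precision, with the average-precision
  denominator adapted to ``min(k, n_match)`` where ``n_match`` is the
  number of label-matching slides actually available after patient
  exclusion, so the score stays on a [0, 1] scale for rare subtypes.

Also produced: a confusion matrix of majority-vote predictions versus
ground truth, and a Hamming-distance matrix where each retrieved slide
adds its hit distance to its own diagnosis column and ``theta_h + 1``
(one past the largest distance the search can return) to every other
column, row-normalised by the site's query count.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .ranking import RankedSlide

__all__ = [
    "EvalReport",
    "majority_vote",
    "mmv_at_k",
    "map_at_k",
    "result_matrices",
    "run_search",
    "rank_all",
    "evaluate_retrieval",
]

ABSTAIN = "__abstain__"


@dataclass
class EvalReport:
    mmv: dict[int, dict[str, float]]  # k -> subtype -> accuracy
    macro_mmv: dict[int, float]  # k -> macro average
    map5: dict[str, float]  # subtype -> mAP@5
    macro_map5: float
    confusion: np.ndarray
    distance_matrix: np.ndarray
    labels: list[str]
    query_counts: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "mmv": {str(k): v for k, v in self.mmv.items()},
            "macro_mmv": {str(k): v for k, v in self.macro_mmv.items()},
            "map5": self.map5,
            "macro_map5": self.macro_map5,
            "labels": self.labels,
            "query_counts": self.query_counts,
            "confusion": self.confusion.tolist(),
            "distance_matrix": self.distance_matrix.tolist(),
        }


def majority_vote(retrieval: list[RankedSlide], k: int) -> str:
    """Most frequent label among the top-k slides.

    Ties are broken by the tied label with the smallest mean hit
    distance; an empty retrieval abstains (always counted incorrect).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    head = retrieval[:k]
    if not head:
        return ABSTAIN
    counts = Counter(r.diagnosis for r in head)
    top = max(counts.values())
    tied = [lb for lb, c in counts.items() if c == top]
    if len(tied) == 1:
        return tied[0]
    mean_dist = {
        lb: np.mean([r.hamming_dist for r in head if r.diagnosis == lb]) for lb in tied
    }
    return min(tied, key=lambda lb: (mean_dist[lb], lb))


def mmv_at_k(queries, retrievals, k: int) -> dict[str, float]:
    """Per-subtype majority-vote accuracy at cutoff ``k``.

    ``queries`` is a sequence of objects with a ``diagnosis`` attribute,
    aligned with ``retrievals`` (lists of RankedSlide).
    """
    import warnings

    correct: dict[str, int] = {}
    total: dict[str, int] = {}
    for query, ret in zip(queries, retrievals):
        lb = query.diagnosis
        total[lb] = total.get(lb, 0) + 1
        if majority_vote(ret, k) == lb:
            correct[lb] = correct.get(lb, 0) + 1
    out = {}
    for lb, q in total.items():
        if q == 0:
            warnings.warn(f"subtype {lb!r} has no queries; excluded")
            continue
        out[lb] = correct.get(lb, 0) / q
    return out


def average_precision_at_k(labels: list[str], query_label: str, k: int, n_match: int) -> float:
    """AvP@k with the denominator adapted to the available relevant slides."""
    if n_match <= 0:
        raise ValueError("no label-matching slide available")
    hits = 0
    score = 0.0
    for i, lb in enumerate(labels[:k], start=1):
        rel = 1 if lb == query_label else 0
        hits += rel
        score += rel * hits / i
    return score / min(k, n_match)


def map_at_k(queries, retrievals, k: int, n_match_fn) -> dict[str, float]:
    """Per-subtype mean average precision at ``k``.

    ``n_match_fn(query)`` must return the number of database slides whose
    label matches the query's after patient exclusion; queries with no
    matching slide are skipped with a warning.
    """
    import warnings

    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for query, ret in zip(queries, retrievals):
        lb = query.diagnosis
        n_match = n_match_fn(query)
        if n_match <= 0:
            warnings.warn(f"query {getattr(query, 'slide_name', '?')} has no matching slide; skipped")
            continue
        labels = [r.diagnosis for r in ret]
        sums[lb] = sums.get(lb, 0.0) + average_precision_at_k(labels, lb, k, n_match)
        counts[lb] = counts.get(lb, 0) + 1
    return {lb: sums[lb] / counts[lb] for lb in sums}


def result_matrices(queries, retrievals, k: int, theta_h: int = 128, labels=None):
    """Confusion and Hamming-distance matrices over the evaluation run.

    Rows index ground truth, columns predictions (confusion) or
    diagnosis columns (distance).  Each retrieved slide contributes its
    hit distance to its own diagnosis column and ``theta_h + 1`` to every
    other; the distance matrix is divided by the number of query slides.
    """
    if labels is None:
        labels = sorted({q.diagnosis for q in queries})
    index = {lb: i for i, lb in enumerate(labels)}
    n = len(labels)
    confusion = np.zeros((n, n), dtype=np.int64)
    dist = np.zeros((n, n), dtype=np.float64)
    inf = theta_h + 1
    n_queries = len(list(queries))
    for query, ret in zip(queries, retrievals):
        gt = index[query.diagnosis]
        pred = majority_vote(ret, k)
        if pred in index:
            confusion[gt, index[pred]] += 1
        for slide in ret[:k]:
            row = np.full(n, inf, dtype=np.float64)
            row[index[slide.diagnosis]] = slide.hamming_dist
            dist[gt] += row
    if n_queries:
        dist /= n_queries
    return confusion, dist


def run_search(db, queries, search_params=None):
    """Leave-one-patient-out guided search for every query slide.

    Returns one list of per-patch result sets per query; ranking can then
    be applied repeatedly (e.g. under ablation settings) without
    re-running the search.
    """
    from .search import SearchParams, guided_search

    search_params = search_params or SearchParams()
    return [
        [
            guided_search(
                key.p, key.h, db, search_params, exclude_patient=query.patient_id
            )
            for key in query.keys
        ]
        for query in queries
    ]


def rank_all(db, queries, search_results, ranking_config=None):
    """Apply the ranking module to precomputed per-query search results."""
    from .ranking import RankingConfig, rank_slides

    ranking_config = ranking_config or RankingConfig()
    retrievals = []
    for query, r_all in zip(queries, search_results):
        ranked = rank_slides(r_all, db.d_inv(), ranking_config)
        assert all(
            db.manifest[r.slide_name].patient_id != query.patient_id for r in ranked
        ), "leave-one-patient-out violated"
        retrievals.append(ranked)
    return retrievals


def evaluate_retrieval(
    db,
    queries,
    search_params=None,
    ranking_config=None,
    k_values=(1, 3, 5, 10),
    map_k: int = 5,
    search_results=None,
):
    """Run leave-one-patient-out search + ranking for every query slide.

    ``queries`` are objects with slide_name, patient_id, diagnosis and a
    ``keys`` list of PatchKey.  Returns (EvalReport, retrievals).
    """
    from .search import SearchParams

    search_params = search_params or SearchParams()
    if search_results is None:
        search_results = run_search(db, queries, search_params)
    retrievals = rank_all(db, queries, search_results, ranking_config)

    def n_match(query):
        return sum(
            1
            for info in db.manifest.values()
            if info.diagnosis == query.diagnosis and info.patient_id != query.patient_id
        )

    mmv = {k: mmv_at_k(queries, retrievals, k) for k in k_values}
    macro_mmv = {k: float(np.mean(list(v.values()))) if v else 0.0 for k, v in mmv.items()}
    map5 = map_at_k(queries, retrievals, map_k, n_match)
    macro_map5 = float(np.mean(list(map5.values()))) if map5 else 0.0
    labels = sorted({q.diagnosis for q in queries})
    confusion, dist = result_matrices(
        queries, retrievals, k=map_k, theta_h=search_params.theta_h, labels=labels
    )
    counts = Counter(q.diagnosis for q in queries)
    report = EvalReport(
        mmv=mmv,
        macro_mmv=macro_mmv,
        map5=map5,
        macro_map5=macro_map5,
        confusion=confusion,
        distance_matrix=dist,
        labels=labels,
        query_counts=dict(counts),
    )
    return report, retrievals
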