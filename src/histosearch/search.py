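"""Guided neighbor-walk search.

A query patch is a pair ``(m_i, h_i)``: integer index and binary texture
code.  Because the index packs the coarsest pooled sum into the highest
decimal block, two visually similar patches can differ by a whole 10**11
step; the search therefore first expands the query index into candidate
anchors ``m_i ± t*C`` for ``t = 1..T`` and then walks a bounded number of
tree successors (forward) and predecessors (backward) from each anchor.
At every stored key it keeps the metadata entry with the smallest Hamming
distance to ``h_i``, retaining it only when that distance is below the
threshold ``theta_h``.  A visited set shared across the forward and
backward passes stops overlapping walks early and prevents duplicate
hits.

Leave-one-patient-out is enforced at query time: metadata whose patient
matches the excluded patient is masked, and a key whose metadata list is
fully masked is skipped without consuming walk budget, exactly as an
empty hash-table entry.

Work per query patch is bounded by the fixed walk budgets, never by the
database size — the constant-time search property.  All ``2T + 1``
anchors are membership-checked, but successor walks start only from the
``T`` lowest ascending anchors (the farthest anchor is checked, not
walked), so total walk work is at most ``T * (k_succ + k_pred)`` steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .database import PatchMeta, SlideDatabase
from .indexing import hamming

__all__ = ["SearchParams", "SearchCounters", "expand_candidates", "forward_search",
           "backward_search", "guided_search"]


@dataclass
class SearchParams:
    """Walk-budget constants of the guided search."""

    C: int = 50 * 10**11  # candidate step in index space
    T: int = 10  # expansions on each side
    theta_h: int = 128  # Hamming acceptance threshold
    k_succ: int = 375  # successor budget per forward anchor
    k_pred: int = 375  # predecessor budget per backward anchor

    def __post_init__(self) -> None:
        if min(self.C, self.T, self.theta_h, self.k_succ, self.k_pred) <= 0:
            raise ValueError("all search parameters must be positive")


@dataclass
class SearchCounters:
    """Instrumentation: how many keys one query examined."""

    budget_steps: int = 0  # successor/predecessor calls that consumed budget
    anchor_checks: int = 0  # direct membership probes of candidate anchors

    @property
    def total(self) -> int:
        return self.budget_steps + self.anchor_checks


def expand_candidates(m_i: int, params: SearchParams, universe_size: int):
    """Ascending and descending candidate anchor sets around ``m_i``.

    Returns ``(ascending, descending)`` where the ascending set contains
    ``m_i`` itself plus ``m_i + t*C`` and the descending set ``m_i - t*C``
    (t = 1..T); anchors outside ``[0, universe)`` are clipped out.
    """
    if not (0 <= m_i < universe_size):
        raise ValueError("query index outside universe")
    up = [m_i] + [m_i + t * params.C for t in range(1, params.T + 1)]
    down = [m_i - t * params.C for t in range(1, params.T + 1)]
    return (
        [m for m in up if 0 <= m < universe_size],
        [m for m in down if 0 <= m < universe_size],
    )


def _best_match(metas: list[PatchMeta], h_i: np.ndarray, exclude_patient):
    """(distance, meta) of the closest non-masked entry, or None."""
    best = None
    any_visible = False
    for meta in metas:
        if exclude_patient is not None and meta.patient_id == exclude_patient:
            continue
        any_visible = True
        d = hamming(h_i, meta.h)
        if best is None or d < best[0]:
            best = (d, meta)
    return best, any_visible


def _directional_search(
    anchors, h_i, db, visited, params, exclude_patient, forward, counters
):
    step = db.tree.successor if forward else db.tree.predecessor
    budget = params.k_succ if forward else params.k_pred
    hits = []
    for anchor in anchors:
        cnt, prev = 0, anchor
        while cnt < budget:
            key = step(prev)
            if counters is not None:
                counters.budget_steps += 1
            if key is None or key in visited:
                break
            metas = db.H.get(key, [])
            best, any_visible = _best_match(metas, h_i, exclude_patient)
            if not any_visible:
                # fully masked key (query patient): skip without spending budget
                prev = key
                if counters is not None:
                    counters.budget_steps -= 1
                continue
            dist, meta = best
            if dist < params.theta_h:
                visited.add(key)
                hits.append((dist, key, meta))
            cnt, prev = cnt + 1, key
    return hits


def forward_search(candidates, h_i, db, visited, params, exclude_patient=None,
                   counters=None):
    """Successor walks from each ascending anchor; returns (hits, visited)."""
    hits = _directional_search(
        candidates, h_i, db, visited, params, exclude_patient, True, counters
    )
    return hits, visited


def backward_search(candidates, h_i, db, visited, params, exclude_patient=None,
                    counters=None):
    """Predecessor walks from each descending anchor."""
    return _directional_search(
        candidates, h_i, db, visited, params, exclude_patient, False, counters
    )


def _anchor_hits(anchors, h_i, db, visited, params, exclude_patient, counters):
    """Score anchors that are themselves stored keys.

    Successor/predecessor walks are strict, so a database entry exactly at
    a candidate index would otherwise be invisible.
    """
    hits = []
    for anchor in anchors:
        if counters is not None:
            counters.anchor_checks += 1
        if anchor in visited or not db.tree.member(anchor):
            continue
        best, any_visible = _best_match(db.H.get(anchor, []), h_i, exclude_patient)
        if not any_visible:
            continue
        dist, meta = best
        if dist < params.theta_h:
            visited.add(anchor)
            hits.append((dist, anchor, meta))
    return hits


def guided_search(
    m_i: int,
    h_i: np.ndarray,
    db: SlideDatabase,
    params: SearchParams | None = None,
    exclude_patient: str | None = None,
    counters: SearchCounters | None = None,
):
    """Full candidate expansion + bidirectional walk for one query patch.

    Returns a list of ``PatchMeta`` with ``hamming_dist`` populated,
    sorted ascending by distance (ties broken by slide name then
    coordinates for reproducibility).  Every distance is < ``theta_h``;
    no hit belongs to ``exclude_patient``.
    """
    from dataclasses import replace

    params = params or SearchParams()
    up, down = expand_candidates(m_i, params, db.tree.universe_size)
    visited: set[int] = set()

    hits = _anchor_hits(up + down, h_i, db, visited, params, exclude_patient, counters)
    # Walk only the T lowest ascending anchors: the farthest anchor is
    # membership-checked above but not walked, which caps total walk work
    # at T * (k_succ + k_pred) steps per query patch.
    fwd, visited = forward_search(
        up[: params.T], h_i, db, visited, params, exclude_patient, counters
    )
    bwd = backward_search(down, h_i, db, visited, params, exclude_patient, counters)
    hits = hits + fwd + bwd
    hits.sort(key=lambda t: (t[0], t[2].slide_name, t[2].coords))
    return [replace(meta, hamming_dist=dist) for dist, _key, meta in hits]
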