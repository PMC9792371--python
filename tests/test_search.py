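"""Guided search: candidate expansion, walks, oracle equivalence."""

import numpy as np
import pytest

from histosearch.database import SlideDatabase, SlideInfo
from histosearch.indexing import PatchKey, decompose_index, hamming
from histosearch.search import (
    SearchCounters,
    SearchParams,
    backward_search,
    expand_candidates,
    forward_search,
    guided_search,
)

L = 64


def _db_from_keys(entries, code_length=L):
    """entries: list of (p, bits, slide_name, patient, diagnosis)."""
    db = SlideDatabase(code_length=code_length)
    by_slide = {}
    for i, (p, bits, slide, patient, diag) in enumerate(entries):
        by_slide.setdefault((slide, patient, diag), []).append(
            PatchKey(p, np.asarray(bits, dtype=np.uint8), coords=(i, 0))
        )
    for (slide, patient, diag), keys in by_slide.items():
        db.add_slide(keys, SlideInfo(slide, patient, diag, "site"))
    return db


def _bits(rng):
    return rng.integers(0, 2, size=L).astype(np.uint8)


class TestExpandCandidates:
    def test_interior_counts(self):
        params = SearchParams()
        up, down = expand_candidates(500 * 10**11, params, 1 << 50)
        assert len(up) + len(down) == 2 * params.T + 1
        assert up[0] == 500 * 10**11

    def test_zero_query_clips_descending(self):
        up, down = expand_candidates(0, SearchParams(), 1 << 50)
        assert down == []
        assert len(up) == 11

    def test_candidates_shift_only_the_top_digit_block(self):
        m = 123_456 + 7_890 * 10**6 + 1_000 * 10**11
        s1, s2, s3 = decompose_index(m)
        up, down = expand_candidates(m, SearchParams(), 1 << 50)
        for cand in up + down:
            c1, c2, c3 = decompose_index(cand)
            assert (c1, c2) == (s1, s2)
            assert abs(c3 - s3) <= SearchParams().T * 50


class TestWalks:
    def test_empty_database_returns_no_hits(self, rng):
        db = SlideDatabase(code_length=L)
        h = _bits(rng)
        params = SearchParams()
        up, down = expand_candidates(10**12, params, db.tree.universe_size)
        hits, _ = forward_search(up, h, db, set(), params)
        assert hits == []
        assert backward_search(down, h, db, set(), params) == []

    def test_identical_feature_above_query_found_at_distance_zero(self, rng):
        h = _bits(rng)
        db = _db_from_keys([(10**12 + 5, h, "s1", "p1", "A")])
        params = SearchParams()
        hits, _ = forward_search([10**12], h, db, set(), params)
        assert len(hits) == 1
        assert hits[0][0] == 0

    def test_visited_keys_stop_backward_walk(self, rng):
        h = _bits(rng)
        db = _db_from_keys(
            [(100, h, "s1", "p1", "A"), (200, h, "s2", "p2", "A")]
        )
        params = SearchParams(C=10, T=2, k_succ=10, k_pred=10, theta_h=L)
        visited = {200, 100}
        hits = backward_search([300], h, db, visited, params)
        assert hits == []  # first predecessor already visited: walk breaks

    def test_forward_backward_symmetry_on_mirrored_keys(self, rng):
        base = 10**12
        keys = [base + d for d in (3, 8, 21)]
        h = _bits(rng)
        entries = [(k, h, f"s{i}", f"p{i}", "A") for i, k in enumerate(keys)]
        db_fwd = _db_from_keys(entries)
        mirror = [2 * base - k for k in keys]
        entries_m = [(k, h, f"s{i}", f"p{i}", "A") for i, k in enumerate(mirror)]
        db_bwd = _db_from_keys(entries_m)
        params = SearchParams(k_succ=100, k_pred=100)
        fwd, _ = forward_search([base], h, db_fwd, set(), params)
        bwd = backward_search([base], h, db_bwd, set(), params)
        assert sorted(d for d, *_ in fwd) == sorted(d for d, *_ in bwd)


def _exhaustive_oracle(db, h_i, theta_h, exclude_patient=None):
    """(slide, coords, dist) of the closest visible metadata per key.

    Ties inside a key's metadata list are broken by first occurrence,
    matching the walk's argmin.
    """
    expected = set()
    for p, metas in db.H.items():
        best = None
        for meta in metas:
            if exclude_patient is not None and meta.patient_id == exclude_patient:
                continue
            d = hamming(h_i, meta.h)
            if best is None or d < best[0]:
                best = (d, meta.slide_name, meta.coords)
        if best is not None and best[0] < theta_h:
            expected.add((best[1], best[2], best[0]))
    return expected


def _full_coverage_params(n_keys, theta_h):
    """Budgets under which the guided walk provably covers every key.

    With a unit candidate step every integer in [m_i - T, m_i] is
    membership-checked directly, the forward walk from m_i spans all
    stored keys above, and the backward walk from m_i - T spans all
    below.
    """
    return SearchParams(C=1, T=10, theta_h=theta_h, k_succ=n_keys + 1,
                        k_pred=n_keys + 1)


class TestGuidedSearch:
    def _random_db(self, rng, n=250):
        entries = []
        for i in range(n):
            p = int(rng.integers(0, 5000 * 10**11))
            entries.append(
                (p, _bits(rng), f"s{i % 40}", f"p{i % 20}", "A" if i % 2 else "B")
            )
        return _db_from_keys(entries)

    def test_exact_key_with_identical_feature_is_first_hit(self, rng):
        h = _bits(rng)
        db = _db_from_keys(
            [(10**12, h, "s1", "p1", "A"), (10**12 + 3, 1 - h, "s2", "p2", "B")]
        )
        hits = guided_search(10**12, h, db, SearchParams(theta_h=L))
        assert hits[0].hamming_dist == 0
        assert hits[0].slide_name == "s1"

    def test_all_features_beyond_threshold_yield_empty_result(self, rng):
        h = np.zeros(L, dtype=np.uint8)
        far = np.ones(L, dtype=np.uint8)
        db = _db_from_keys([(10**12 + i, far, f"s{i}", f"p{i}", "A") for i in range(5)])
        assert guided_search(10**12, h, db, SearchParams(theta_h=16)) == []

    def test_equals_exhaustive_scan_with_generous_budgets(self, rng):
        db = self._random_db(rng)
        params = _full_coverage_params(db.n_patches, theta_h=20)
        for _ in range(5):
            h = _bits(rng)
            hits = guided_search(int(rng.integers(0, 5000 * 10**11)), h, db, params)
            got = {(m.slide_name, m.coords, m.hamming_dist) for m in hits}
            assert got == _exhaustive_oracle(db, h, params.theta_h)

    def test_patient_exclusion_respected(self, rng):
        db = self._random_db(rng)
        params = _full_coverage_params(db.n_patches, theta_h=33)
        h = _bits(rng)
        hits = guided_search(10**13, h, db, params, exclude_patient="p3")
        assert all(m.patient_id != "p3" for m in hits)
        got = {(m.slide_name, m.coords, m.hamming_dist) for m in hits}
        assert got == _exhaustive_oracle(db, h, params.theta_h, exclude_patient="p3")

    def test_results_sorted_ascending_and_deterministic(self, rng):
        db = self._random_db(rng)
        params = SearchParams(theta_h=30)
        h = _bits(rng)
        hits1 = guided_search(10**13, h, db, params)
        hits2 = guided_search(10**13, h, db, params)
        dists = [m.hamming_dist for m in hits1]
        assert dists == sorted(dists)
        assert [(m.slide_name, m.coords) for m in hits1] == [
            (m.slide_name, m.coords) for m in hits2
        ]

    def test_work_bounded_by_walk_budgets(self, rng):
        db = self._random_db(rng)
        params = SearchParams()
        bound = (2 * params.T + 1) + params.T * (params.k_succ + params.k_pred)
        for _ in range(5):
            counters = SearchCounters()
            guided_search(
                int(rng.integers(0, 5000 * 10**11)), _bits(rng), db, params,
                counters=counters,
            )
            assert counters.total <= bound
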