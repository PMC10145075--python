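"""Greedy identification panels: discernibility counts, oracles, fingerprints."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from edvsnp import (
    discernibility,
    fingerprint_table,
    greedy_panel,
    pair_distinguished,
)
from edvsnp.panel import fingerprint_strings, panel_table

from conftest import make_matrix, random_matrix


def brute_discernibility(matrix, panel):
    n = matrix.n_samples
    count = 0
    for i in range(n):
        for j in range(i + 1, n):
            for k in panel:
                x, y = matrix.calls[i, k], matrix.calls[j, k]
                if x >= 0 and y >= 0 and x != y:
                    count += 1
                    break
    return count


class TestPairDistinguished:
    def test_clones_never_distinguished(self):
        row = [0, 1, 2, 1]
        m = make_matrix([row, row])
        assert not pair_distinguished(m, [0, 1, 2, 3], 0, 1)

    def test_single_differing_locus(self):
        m = make_matrix([[0, 1], [0, 2]])
        assert pair_distinguished(m, [1], 0, 1)
        assert not pair_distinguished(m, [0], 0, 1)

    def test_missing_cannot_distinguish(self):
        m = make_matrix([[0], [-1]])
        assert not pair_distinguished(m, [0], 0, 1)

    def test_agrees_with_nd_restricted_to_panel(self, rng):
        m = random_matrix(rng, 6, 12, miss_rate=0.2)
        panel = [1, 4, 7]
        sub = m.subset(loci=panel)
        from edvsnp import gs_pair

        for i in range(6):
            for j in range(i + 1, 6):
                assert pair_distinguished(m, panel, i, j) == (
                    gs_pair(sub, i, j).nd > 0
                )


class TestDiscernibility:
    def test_combinatorial_count(self):
        # classes [0, 0, 1, 2]: 6 pairs, 1 within-class -> 5 distinguished
        m = make_matrix([[0], [0], [1], [2]])
        assert discernibility(m, [0]) == 5

    def test_identical_samples_zero(self):
        m = make_matrix([[1, 1]] * 4)
        assert discernibility(m, [0, 1]) == 0

    def test_class_count_formula(self, rng):
        """Single-locus discernibility = C(n,2) - sum C(n_j,2) - missing pairs."""
        m = random_matrix(rng, 30, 1, miss_rate=0.2)
        col = m.calls[:, 0]
        n = len(col)
        n_missing = int((col < 0).sum())
        within = sum(
            int((col == c).sum()) * (int((col == c).sum()) - 1) // 2
            for c in (0, 1, 2)
        )
        miss_pairs = n_missing * (n - n_missing) + n_missing * (n_missing - 1) // 2
        expected = n * (n - 1) // 2 - within - miss_pairs
        assert discernibility(m, [0]) == expected

    @given(st.integers(0, 200))
    def test_matches_all_pairs_scan(self, seed):
        rng = np.random.default_rng(seed)
        m = random_matrix(rng, 8, 6, miss_rate=0.2)
        panel = [0, 2, 5]
        assert discernibility(m, panel) == brute_discernibility(m, panel)


class TestGreedyPanel:
    def test_two_locus_completion(self):
        # locus A separates {12,34}x, locus B separates the rest
        m = make_matrix([[0, 0], [0, 2], [2, 0], [2, 2]])
        res = greedy_panel(m)
        assert res.size == 2
        assert res.max_discernibility == 6
        assert res.discernibility_trace == [4, 6]

    def test_single_all_distinct_locus(self):
        m = make_matrix([[0, 0], [1, 0], [2, 0]])
        res = greedy_panel(m)
        assert res.selected == ["Chr1_1000"]
        assert res.size == 1

    def test_clones_reported_not_fatal(self):
        row = [0, 1, 2, 0, 1]
        other = [2, 0, 1, 1, 0]
        m = make_matrix([row, row, other])
        res = greedy_panel(m)
        assert res.max_discernibility == 2  # clone pair is invisible
        assert ("S1", "S2") in res.indistinguishable_pairs
        assert res.discernibility_trace[-1] == res.max_discernibility

    def test_pic_tie_break(self):
        # both loci distinguish the same single pair; higher PIC wins
        m = make_matrix([[0, 0], [1, 2]])
        res = greedy_panel(m, pic={"Chr1_1000": 0.1, "Chr1_2000": 0.3})
        assert res.selected[0] == "Chr1_2000"

    def test_lexicographic_tie_break(self):
        m = make_matrix([[0, 0], [1, 1]])
        res = greedy_panel(m, pic={"Chr1_1000": 0.2, "Chr1_2000": 0.2})
        assert res.selected[0] == "Chr1_1000"

    def test_deterministic(self, rng):
        m = random_matrix(rng, 12, 15, miss_rate=0.1)
        r1 = greedy_panel(m)
        r2 = greedy_panel(m)
        assert r1.selected == r2.selected
        assert r1.discernibility_trace == r2.discernibility_trace

    def test_trace_strictly_increasing_reaches_max(self, rng):
        m = random_matrix(rng, 15, 25, miss_rate=0.1)
        res = greedy_panel(m)
        assert all(
            b > a
            for a, b in zip(res.discernibility_trace, res.discernibility_trace[1:])
        )
        assert res.discernibility_trace[-1] == res.max_discernibility

    def test_sample_subset_target(self, rng):
        m = random_matrix(rng, 10, 20, miss_rate=0.1)
        subset = m.sample_ids[:5]
        res = greedy_panel(m, samples=subset)
        assert res.n_pairs == 10
        assert set(res.fingerprints) == set(subset)

    @given(st.integers(0, 60))
    def test_exhaustive_subset_oracle(self, seed):
        """Greedy reaches the global maximum over every locus subset."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        L = int(rng.integers(2, 7))
        m = random_matrix(rng, n, L, miss_rate=0.15)
        res = greedy_panel(m)
        best = 0
        for r in range(1, L + 1):
            for combo in itertools.combinations(range(L), r):
                best = max(best, brute_discernibility(m, combo))
        assert res.max_discernibility == best
        assert (
            res.discernibility_trace[-1] if res.discernibility_trace else 0
        ) == best

    def test_no_candidates_rejected(self, rng):
        m = random_matrix(rng, 4, 5)
        with pytest.raises(ValueError):
            greedy_panel(m, candidate_loci=[])


class TestFingerprints:
    def test_single_locus_distinct_strings(self):
        m = make_matrix([[0], [1]])
        fp = fingerprint_strings(m, [0])
        assert fp == {"S1": "0", "S2": "1"}

    def test_clone_pair_identical_strings(self):
        row = [0, 1, 2]
        m = make_matrix([row, row])
        fp = fingerprint_strings(m, [0, 1, 2])
        assert fp["S1"] == fp["S2"]

    def test_distinguished_iff_distinct_ignoring_missing(self, rng):
        """Panel separations match fingerprint differences at co-called sites."""
        m = random_matrix(rng, 12, 8, miss_rate=0.2)
        panel = list(range(8))
        fp = fingerprint_strings(m, panel)
        for i in range(12):
            for j in range(i + 1, 12):
                a, b = fp[m.sample_ids[i]], fp[m.sample_ids[j]]
                differs = any(
                    x != "N" and y != "N" and x != y for x, y in zip(a, b)
                )
                assert differs == pair_distinguished(m, panel, i, j)

    def test_table_and_panel_export(self, rng):
        m = random_matrix(rng, 5, 6, miss_rate=0.1)
        res = greedy_panel(m)
        t = fingerprint_table(m, [0, 1])
        assert t.shape == (5, 2)
        pt = panel_table(res)
        assert list(pt["cumulative_discernibility"]) == res.discernibility_trace
        assert pt["added_discernibility"].sum() == res.max_discernibility
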