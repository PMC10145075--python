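"""Candidate/core SNP filtering: boundary semantics, flanking windows, binning."""

import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from edvsnp import (
    FilterConfig,
    GenotypeMatrix,
    Locus,
    compute_locus_stats,
    filter_candidates,
    flank_unique,
    select_core,
)
from edvsnp.snp_filter import core_table

from conftest import random_matrix


def loci_at(positions, chrom="Chr1"):
    return [Locus(chrom, p, "A", "G") for p in positions]


class TestFlankUnique:
    def test_close_pair_both_dropped(self):
        kept = flank_unique(loci_at([100, 500, 620]), 150)
        assert kept.tolist() == [0]

    def test_single_locus_kept(self):
        assert flank_unique(loci_at([42]), 150).tolist() == [0]

    def test_boundary_distance_excludes(self):
        # distance exactly equal to the window is still a conflict
        assert flank_unique(loci_at([100, 250]), 150).tolist() == []
        assert flank_unique(loci_at([100, 251]), 150).tolist() == [0, 1]

    def test_chromosomes_independent(self):
        loci = loci_at([100, 150]) + loci_at([120], chrom="Chr2")
        assert flank_unique(loci, 150).tolist() == [2]

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            flank_unique(loci_at([500, 100]), 150)
        interleaved = loci_at([100]) + loci_at([50], "Chr2") + loci_at([900])
        with pytest.raises(ValueError, match="contiguous"):
            flank_unique(interleaved, 150)

    @given(st.integers(0, 300))
    def test_matches_all_pairs_scan(self, seed):
        """Adjacent-gap rule equals the O(n^2) all-pairs distance oracle."""
        rng = np.random.default_rng(seed)
        positions = np.unique(rng.integers(1, 20_000, size=200))
        loci = loci_at(positions.tolist())
        kept = set(flank_unique(loci, 150).tolist())
        brute = {
            i
            for i in range(len(positions))
            if all(
                abs(int(positions[i]) - int(positions[j])) > 150
                for j in range(len(positions))
                if j != i
            )
        }
        assert kept == brute


@pytest.fixture
def cohort(rng):
    m = random_matrix(rng, 80, 120, miss_rate=0.05)
    return m, compute_locus_stats(m)


class TestCandidateFilter:
    def test_boundary_maf_excluded(self):
        # MAF exactly at the floor fails the strict inequality
        calls = np.zeros((10, 1), dtype=np.int8)
        calls[0, 0] = 2  # p_alt = 0.1
        m = GenotypeMatrix(
            [f"S{i}" for i in range(10)], loci_at([100]), calls
        )
        stats = compute_locus_stats(m)
        assert stats["maf"].iloc[0] == pytest.approx(0.1)
        assert filter_candidates(m, stats, FilterConfig()).tolist() == []

    def test_clean_isolated_locus_included(self):
        calls = np.array([[0], [1], [2], [1]], dtype=np.int8)
        m = GenotypeMatrix(["a", "b", "c", "d"], loci_at([100]), calls)
        stats = compute_locus_stats(m)
        assert filter_candidates(m, stats, FilterConfig()).tolist() == [0]

    def test_matches_rowwise_recheck(self, cohort):
        m, stats = cohort
        cfg = FilterConfig()
        got = set(filter_candidates(m, stats, cfg).tolist())
        isolated = set(flank_unique(m.loci, cfg.flank_bp).tolist())
        for j in range(m.n_loci):
            row = stats.iloc[j]
            expect = (
                row["maf"] > cfg.candidate_maf_min
                and row["miss_rate"] < cfg.candidate_miss_max
                and j in isolated
            )
            assert (j in got) == expect


class TestCoreSelection:
    def test_inclusive_miss_boundary(self):
        # miss rate exactly 5% is retained (inclusive ceiling)
        calls = np.tile([0, 1, 2, 1], 5).reshape(20, 1).astype(np.int8)
        calls[0, 0] = -1  # 1/20 = 0.05 missing
        m = GenotypeMatrix(
            [f"S{i}" for i in range(20)], loci_at([100]), calls
        )
        stats = compute_locus_stats(m)
        cfg = FilterConfig(min_core_size=1)
        assert stats["miss_rate"].iloc[0] == pytest.approx(0.05)
        assert select_core(m, stats, cfg).tolist() == [0]

    def test_bin_keeps_highest_pic(self, rng):
        # two loci in one 1 Mb bin: the more informative one survives
        calls = np.zeros((20, 2), dtype=np.int8)
        calls[:4, 0] = 2  # maf 0.2
        calls[:10, 1] = 2  # maf 0.5, higher PIC
        m = GenotypeMatrix(
            [f"S{i}" for i in range(20)], loci_at([100, 500_000]), calls
        )
        stats = compute_locus_stats(m)
        cfg = FilterConfig(min_core_size=1, bin_width=1_000_000)
        core = select_core(m, stats, cfg)
        assert core.tolist() == [1]

    def test_bin_occupancy_counts(self, rng):
        """With binning, per-chromosome counts equal occupied bins."""
        m = random_matrix(rng, 100, 400, miss_rate=0.0)
        stats = compute_locus_stats(m)
        cfg = FilterConfig(min_core_size=1, bin_width=50_000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            core = select_core(m, stats, cfg)
        eligible = set(filter_candidates(m, stats, cfg).tolist())
        eligible = {
            j
            for j in eligible
            if stats["maf"].iloc[j] > cfg.core_maf_min
            and stats["miss_rate"].iloc[j] <= cfg.core_miss_max
            and stats["pic_allele"].iloc[j] > cfg.core_pic_min
        }
        occupied = {
            (m.loci[j].chromosome, m.loci[j].position // cfg.bin_width)
            for j in eligible
        }
        assert len(core) == len(occupied)

    def test_core_subset_of_candidates_and_idempotent(self, cohort):
        m, stats = cohort
        cfg = FilterConfig(min_core_size=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            core = select_core(m, stats, cfg)
        cand = filter_candidates(m, stats, cfg)
        assert set(core) <= set(cand)
        # every survivor individually satisfies the core thresholds
        for j in core:
            row = stats.iloc[j]
            assert row["maf"] > cfg.core_maf_min
            assert row["miss_rate"] <= cfg.core_miss_max
            assert row["pic_allele"] > cfg.core_pic_min
        # re-running on the filtered matrix returns everything
        m2 = m.subset(loci=core)
        stats2 = compute_locus_stats(m2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            again = select_core(m2, stats2, cfg)
        assert again.tolist() == list(range(m2.n_loci))

    def test_empty_core_warns_not_crashes(self, cohort):
        m, stats = cohort
        cfg = FilterConfig(core_maf_min=0.499999, core_pic_min=0.374999)
        with pytest.warns(UserWarning):
            core = select_core(m, stats, cfg)
        assert isinstance(core, np.ndarray)

    def test_core_table_columns(self, cohort):
        m, stats = cohort
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            core = select_core(m, stats, FilterConfig(min_core_size=1))
        t = core_table(m, stats, core)
        assert list(t.columns) == ["id", "chrom", "pos", "maf", "miss", "pic"]
        assert len(t) == len(core)


class TestFilterConfig:
    def test_from_file(self, tmp_path):
        p = tmp_path / "filter.cfg"
        p.write_text(
            "# thresholds\ncore_maf_min = 0.2\nbin_width = 1000000\n"
            "min_core_size = 50\n"
        )
        cfg = FilterConfig.from_file(p)
        assert cfg.core_maf_min == 0.2
        assert cfg.bin_width == 1_000_000
        assert cfg.min_core_size == 50
        assert cfg.candidate_maf_min == 0.1  # untouched default

    def test_bad_key_rejected(self, tmp_path):
        p = tmp_path / "filter.cfg"
        p.write_text("nope = 1\n")
        with pytest.raises(ValueError, match="unknown key"):
            FilterConfig.from_file(p)

    def test_validation(self):
        with pytest.raises(ValueError):
            FilterConfig(core_maf_min=1.5)
        with pytest.raises(ValueError):
            FilterConfig(flank_bp=-1)
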