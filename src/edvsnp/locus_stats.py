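"""Per-locus diversity statistics: MAF, missing rate, Ho, GD and PIC.

Gene diversity and polymorphic information content are offered in two
conventions: ``allele`` (frequencies of the two alleles; GD = 2pq <= 0.5,
PIC <= 0.375 for a biallelic SNP) and ``genotype`` (frequencies of the three
genotype classes among called samples; GD <= 2/3, PIC <= 0.593).  The allele
convention is the default.  Missing genotypes are excluded from every
denominator; an all-missing locus yields flagged NaN statistics, never
zeros.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotype_io import ALT_HOM, HET, REF_HOM, GenotypeMatrix


class UndefinedStatisticError(ValueError):
    """Raised when a statistic is requested for a locus with no called genotypes."""


def _counts(matrix: GenotypeMatrix, locus: int) -> tuple[int, int, int]:
    col = matrix.calls[:, locus]
    return (
        int((col == REF_HOM).sum()),
        int((col == HET).sum()),
        int((col == ALT_HOM).sum()),
    )


def _require_called(matrix: GenotypeMatrix, locus: int) -> int:
    n_ref, n_het, n_alt = _counts(matrix, locus)
    n = n_ref + n_het + n_alt
    if n == 0:
        raise UndefinedStatisticError(
            f"locus {matrix.loci[locus].id}: no called genotypes"
        )
    return n


def allele_freq(matrix: GenotypeMatrix, locus: int) -> float:
    """Alternate-allele frequency among called genotypes at ``locus``."""
    n_ref, n_het, n_alt = _counts(matrix, locus)
    n = _require_called(matrix, locus)
    return (n_het + 2 * n_alt) / (2 * n)


def maf(matrix: GenotypeMatrix, locus: int) -> float:
    """Minor-allele frequency: min(p, 1-p) of the alt-allele frequency."""
    p = allele_freq(matrix, locus)
    return min(p, 1.0 - p)


def observed_het(matrix: GenotypeMatrix, locus: int) -> float:
    """Fraction of called genotypes that are heterozygous (Ho)."""
    n_ref, n_het, n_alt = _counts(matrix, locus)
    n = _require_called(matrix, locus)
    return n_het / n


def _freqs(matrix: GenotypeMatrix, locus: int, convention: str) -> np.ndarray:
    n_ref, n_het, n_alt = _counts(matrix, locus)
    n = _require_called(matrix, locus)
    if convention == "allele":
        p = (n_het + 2 * n_alt) / (2 * n)
        return np.array([p, 1.0 - p])
    if convention == "genotype":
        return np.array([n_ref, n_het, n_alt]) / n
    raise ValueError(f"unknown convention {convention!r}")


def gene_diversity(
    matrix: GenotypeMatrix, locus: int, convention: str = "allele"
) -> float:
    """Gene diversity 1 - sum(f_i^2) over allele or genotype-class frequencies."""
    f = _freqs(matrix, locus, convention)
    return float(1.0 - np.sum(f**2))


def pic(matrix: GenotypeMatrix, locus: int, convention: str = "allele") -> float:
    """Botstein polymorphic information content.

    PIC = 1 - sum(f_i^2) - sum_{i<j} 2 f_i^2 f_j^2, over allele frequencies
    (default) or genotype-class frequencies.
    """
    f = _freqs(matrix, locus, convention)
    s2 = float(np.sum(f**2))
    s4 = float(np.sum(f**4))
    return 1.0 - s2 - (s2**2 - s4)


def compute_locus_stats(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Vectorised per-locus statistics table.

    Returns a DataFrame with one row per locus and columns ``locus_id``,
    ``chromosome``, ``position``, ``maf``, ``miss_rate``, ``ho``,
    ``gd_allele``, ``gd_genotype``, ``pic_allele``, ``pic_genotype``.
    All-missing loci carry NaN in every statistic except ``miss_rate``.
    """
    calls = matrix.calls
    n_samples = matrix.n_samples
    n_ref = (calls == REF_HOM).sum(axis=0).astype(float)
    n_het = (calls == HET).sum(axis=0).astype(float)
    n_alt = (calls == ALT_HOM).sum(axis=0).astype(float)
    n_called = n_ref + n_het + n_alt
    defined = n_called > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(defined, (n_het + 2 * n_alt) / (2 * n_called), np.nan)
        ho = np.where(defined, n_het / n_called, np.nan)
        g = np.where(
            defined,
            np.stack([n_ref, n_het, n_alt]) / n_called,
            np.nan,
        )
    q = 1.0 - p
    maf_ = np.minimum(p, q)
    miss = (n_samples - n_called) / n_samples  # exact at decimal boundaries

    def _gd(freqs: np.ndarray) -> np.ndarray:
        return 1.0 - np.sum(freqs**2, axis=0)

    def _pic(freqs: np.ndarray) -> np.ndarray:
        s2 = np.sum(freqs**2, axis=0)
        s4 = np.sum(freqs**4, axis=0)
        return 1.0 - s2 - (s2**2 - s4)

    a = np.stack([p, q])
    return pd.DataFrame(
        {
            "locus_id": matrix.locus_ids,
            "chromosome": [loc.chromosome for loc in matrix.loci],
            "position": [loc.position for loc in matrix.loci],
            "maf": maf_,
            "miss_rate": miss,
            "ho": ho,
            "gd_allele": _gd(a),
            "gd_genotype": _gd(g),
            "pic_allele": _pic(a),
            "pic_genotype": _pic(g),
        }
    )


def summarize(
    stats: pd.DataFrame, thresholds: dict[str, float] | None = None
) -> dict:
    """Cohort summary of a locus-statistics table.

    Returns per-statistic means (over loci with defined values), the
    fraction of defined loci whose statistic exceeds each requested
    threshold, and per-chromosome locus counts.
    """
    if len(stats) == 0:
        raise ValueError("cannot summarise an empty statistics table")
    numeric = [
        c
        for c in (
            "maf",
            "miss_rate",
            "ho",
            "gd_allele",
            "gd_genotype",
            "pic_allele",
            "pic_genotype",
        )
        if c in stats.columns
    ]
    means = {c: float(stats[c].mean(skipna=True)) for c in numeric}
    frac_above = {}
    for col, thr in (thresholds or {}).items():
        vals = stats[col].dropna()
        frac_above[col] = (
            float((vals > thr).mean()) if len(vals) else float("nan")
        )
    per_chrom = (
        stats["chromosome"].value_counts().sort_index().to_dict()
        if "chromosome" in stats.columns
        else {}
    )
    return {
        "n_loci": int(len(stats)),
        "means": means,
        "frac_above": frac_above,
        "thresholds": dict(thresholds or {}),
        "per_chromosome": per_chrom,
    }


def write_stats_table(stats: pd.DataFrame, path) -> None:
    """Write the per-locus table as TSV with panel-style column names."""
    out = stats.rename(
        columns={"locus_id": "SNP", "pic_allele": "PIC", "ho": "Ho", "gd_allele": "GD"}
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")
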