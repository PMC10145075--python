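"""Pairwise genetic similarity and essentially-derived-variety classification.

The genetic similarity coefficient between two samples is

    GS = NS / (NS + ND)

where NS and ND count the co-called loci at which their genotype *classes*
are identical and different, respectively.  A heterozygote therefore
differs from either homozygote, and loci missing in either sample
contribute to neither count (pairwise-complete deletion).

A pair with GS above a putative threshold (0.9 by convention) is treated as
likely essentially derived; pairs at or above an *indisputable* threshold
calibrated from same-variety positive controls (the tail principle: the
two-decimal floor of the smallest control GS) are classified as
indisputable.  Within a classified pair the later-registered member is the
essentially derived variety (EDV) and the earlier one the initial variety
(IV).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, SampleMeta

CATEGORY_NONE = "none"
CATEGORY_PUTATIVE = "putative"
CATEGORY_INDISPUTABLE = "indisputable"


@dataclass(frozen=True)
class SimilarityResult:
    """NS/ND tallies and GS for one unordered sample pair."""

    a: str
    b: str
    ns: int
    nd: int

    @property
    def compared(self) -> int:
        return self.ns + self.nd

    @property
    def gs(self) -> float | None:
        """Genetic similarity; ``None`` when no locus is co-called."""
        if self.compared == 0:
            return None
        return self.ns / self.compared


@dataclass(frozen=True)
class EdvCall:
    """Derivation classification of one sample pair."""

    a: str
    b: str
    gs: float
    category: str
    iv_sample: str | None = None
    edv_sample: str | None = None
    basis: str = "unresolved"


def _pair_counts(calls: np.ndarray, i: int, j: int) -> tuple[int, int]:
    x, y = calls[i], calls[j]
    both = (x >= 0) & (y >= 0)
    ns = int(np.count_nonzero(both & (x == y)))
    return ns, int(np.count_nonzero(both)) - ns


def gs_pair(matrix: GenotypeMatrix, a: int | str, b: int | str) -> SimilarityResult:
    """Similarity of one pair; ``a``/``b`` may be indices or sample ids."""
    i = a if isinstance(a, int) else matrix.sample_index(a)
    j = b if isinstance(b, int) else matrix.sample_index(b)
    if i == j:
        raise ValueError("gs_pair requires two distinct samples")
    ns, nd = _pair_counts(matrix.calls, i, j)
    return SimilarityResult(matrix.sample_ids[i], matrix.sample_ids[j], ns, nd)


class PairwiseSimilarity:
    """All-pairs NS/ND/GS container with symmetric accessors."""

    def __init__(self, sample_ids: Sequence[str], ns: np.ndarray, nd: np.ndarray):
        self.sample_ids = list(sample_ids)
        self.ns = ns
        self.nd = nd
        self._index = {s: i for i, s in enumerate(self.sample_ids)}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_pairs(self) -> int:
        return self.n_samples * (self.n_samples - 1) // 2

    def gs(self) -> np.ndarray:
        """Square GS matrix (NaN where no locus is co-called; 1.0 diagonal)."""
        compared = self.ns + self.nd
        with np.errstate(divide="ignore", invalid="ignore"):
            g = np.where(compared > 0, self.ns / np.maximum(compared, 1), np.nan)
        np.fill_diagonal(g, 1.0)
        return g

    def pair(self, a: str, b: str) -> SimilarityResult:
        i, j = self._index[a], self._index[b]
        if i == j:
            raise ValueError("pair requires two distinct samples")
        return SimilarityResult(a, b, int(self.ns[i, j]), int(self.nd[i, j]))

    def iter_pairs(self) -> Iterator[SimilarityResult]:
        ids = self.sample_ids
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                yield SimilarityResult(
                    ids[i], ids[j], int(self.ns[i, j]), int(self.nd[i, j])
                )

    def to_long(self) -> pd.DataFrame:
        """Long-format pair table (id_a, id_b, ns, nd, compared, gs)."""
        iu = np.triu_indices(self.n_samples, k=1)
        ns = self.ns[iu]
        nd = self.nd[iu]
        compared = ns + nd
        with np.errstate(divide="ignore", invalid="ignore"):
            gs = np.where(compared > 0, ns / np.maximum(compared, 1), np.nan)
        ids = np.asarray(self.sample_ids)
        return pd.DataFrame(
            {
                "id_a": ids[iu[0]],
                "id_b": ids[iu[1]],
                "ns": ns.astype(int),
                "nd": nd.astype(int),
                "compared": compared.astype(int),
                "gs": gs,
            }
        )


def gs_matrix(matrix: GenotypeMatrix) -> PairwiseSimilarity:
    """All-pairs similarity via genotype-class indicator matrix products."""
    if matrix.n_samples < 2:
        raise ValueError("gs_matrix requires at least 2 samples")
    calls = matrix.calls
    called = (calls >= 0).astype(np.float64)
    ns = np.zeros((matrix.n_samples, matrix.n_samples))
    for code in (0, 1, 2):
        ind = (calls == code).astype(np.float64)
        ns += ind @ ind.T
    cocalled = called @ called.T
    nd = cocalled - ns
    return PairwiseSimilarity(
        matrix.sample_ids,
        np.rint(ns).astype(np.int64),
        np.rint(nd).astype(np.int64),
    )


def calibrate_threshold(
    controls: Iterable[SimilarityResult | float],
) -> float:
    """Indisputable-derivation threshold from positive-control similarities.

    Tail principle: the minimum control GS, floored to two decimals, so that
    every same-variety pair sits at or above the threshold.
    """
    gs_values: list[float] = []
    for c in controls:
        g = c if isinstance(c, (int, float)) else c.gs
        if g is None:
            raise ValueError("control pair with no co-called loci")
        gs_values.append(float(g))
    if not gs_values:
        raise ValueError(
            "no positive-control pairs: supply a fixed indisputable threshold"
        )
    lo = min(gs_values)
    # round before flooring so 0.97 (stored as 0.9699999...) stays 0.97
    return math.floor(round(lo * 100, 9)) / 100.0


def classify_gs(
    gs: float, putative_threshold: float, indisputable_threshold: float
) -> str:
    """Category of a GS value under the two-threshold rule."""
    if gs >= indisputable_threshold:
        return CATEGORY_INDISPUTABLE
    if gs > putative_threshold:
        return CATEGORY_PUTATIVE
    return CATEGORY_NONE


def classify_pairs(
    sim: PairwiseSimilarity,
    meta: Sequence[SampleMeta] | Mapping[str, SampleMeta],
    indisputable_threshold: float,
    putative_threshold: float = 0.9,
    include_none: bool = False,
) -> list[EdvCall]:
    """Classify every pair; by default only non-``none`` calls are returned.

    IV/EDV roles are assigned only when both samples carry known, unequal
    registration years (earlier year = IV); otherwise ``basis`` is
    ``unresolved``.
    """
    if not 0.0 < putative_threshold < indisputable_threshold < 1.0 + 1e-12:
        raise ValueError(
            "thresholds must satisfy 0 < putative < indisputable <= 1"
        )
    meta_map = (
        {m.sample_id: m for m in meta} if not isinstance(meta, Mapping) else meta
    )
    calls: list[EdvCall] = []
    iu = np.triu_indices(sim.n_samples, k=1)
    compared = sim.ns + sim.nd
    ids = sim.sample_ids
    for i, j in zip(*iu):
        if compared[i, j] == 0:
            continue
        g = sim.ns[i, j] / compared[i, j]
        cat = classify_gs(g, putative_threshold, indisputable_threshold)
        if cat == CATEGORY_NONE and not include_none:
            continue
        a, b = ids[i], ids[j]
        iv = edv = None
        basis = "unresolved"
        if cat != CATEGORY_NONE:
            ya = getattr(meta_map.get(a), "registration_year", None)
            yb = getattr(meta_map.get(b), "registration_year", None)
            if ya is not None and yb is not None and ya != yb:
                iv, edv = (a, b) if ya < yb else (b, a)
                basis = "registration_year"
        calls.append(EdvCall(a, b, float(g), cat, iv, edv, basis))
    return calls


def summarize_calls(calls: Sequence[EdvCall]) -> dict:
    """Counts of putative / indisputable calls and the flagged EDV samples."""
    putative = [c for c in calls if c.category == CATEGORY_PUTATIVE]
    indis = [c for c in calls if c.category == CATEGORY_INDISPUTABLE]
    return {
        "n_calls": len(putative) + len(indis),
        "n_putative": len(putative),
        "n_indisputable": len(indis),
        "edv_samples": sorted(edv_sample_set(calls)),
    }


def edv_sample_set(calls: Sequence[EdvCall]) -> set[str]:
    """Samples flagged as derived by at least one non-``none`` call.

    When registration years resolve the pair, the designated ``edv_sample``
    is flagged; for unresolved pairs the lexicographically later id is
    flagged so that exactly one member of every derived pair is excluded
    from 'non-EDV' sample sets.
    """
    flagged: set[str] = set()
    for c in calls:
        if c.category == CATEGORY_NONE:
            continue
        flagged.add(c.edv_sample if c.edv_sample is not None else max(c.a, c.b))
    return flagged


def write_gs_matrix(sim: PairwiseSimilarity, path) -> None:
    """Square GS matrix as TSV (samples as both axes)."""
    pd.DataFrame(sim.gs(), index=sim.sample_ids, columns=sim.sample_ids).to_csv(
        path, sep="\t", float_format="%.6f"
    )


def write_pair_table(
    sim: PairwiseSimilarity, calls: Sequence[EdvCall], path
) -> None:
    """Long-format pair table with categories and IV/EDV roles as TSV."""
    df = sim.to_long()
    call_map = {frozenset((c.a, c.b)): c for c in calls}
    cats, ivs, edvs = [], [], []
    for a, b in zip(df["id_a"], df["id_b"]):
        c = call_map.get(frozenset((a, b)))
        cats.append(c.category if c else CATEGORY_NONE)
        ivs.append(c.iv_sample if c else None)
        edvs.append(c.edv_sample if c else None)
    df["category"] = cats
    df["iv"] = ivs
    df["edv"] = edvs
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
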