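"""Greedy minimal SNP identification panels and fingerprints.

A panel distinguishes a sample pair when at least one panel locus is called
in both samples with different genotype classes; a missing call can never
distinguish (conservative rule).  Panel construction is greedy forward
selection: each step adds the locus that distinguishes the most
still-undistinguished pairs, breaking ties by higher PIC and then by locus
id, and stops once the panel separates every pair the full candidate set
can separate.  Clonal duplicates are invisible to any panel and are
reported as indistinguishable rather than blocking termination.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix
from .locus_stats import compute_locus_stats

FINGERPRINT_CODES = {0: "0", 1: "1", 2: "2", -1: "N"}
#: Reading of the fingerprint characters: 0 = reference homozygote (XX),
#: 1 = heterozygote (XY), 2 = alternate homozygote (YY), N = missing.
FINGERPRINT_LEGEND = {"0": "XX", "1": "XY", "2": "YY", "N": "missing"}


@dataclass
class PanelResult:
    """Outcome of greedy panel selection."""

    selected: list[str]
    discernibility_trace: list[int]
    max_discernibility: int
    n_pairs: int
    fingerprints: dict[str, str]
    indistinguishable_pairs: list[tuple[str, str]]

    @property
    def size(self) -> int:
        return len(self.selected)


def pair_distinguished(
    matrix: GenotypeMatrix, panel: Sequence[int], a: int | str, b: int | str
) -> bool:
    """True iff some panel locus is co-called and differs between a and b."""
    i = a if isinstance(a, int) else matrix.sample_index(a)
    j = b if isinstance(b, int) else matrix.sample_index(b)
    if i == j:
        raise ValueError("pair_distinguished requires two distinct samples")
    cols = np.asarray(list(panel), dtype=int)
    x = matrix.calls[i, cols]
    y = matrix.calls[j, cols]
    return bool(np.any((x >= 0) & (y >= 0) & (x != y)))


def _pair_diff_mask(
    calls: np.ndarray, cols: Sequence[int], ia: np.ndarray, ib: np.ndarray
) -> np.ndarray:
    """Boolean mask over pairs distinguished by the given locus columns."""
    out = np.zeros(len(ia), dtype=bool)
    for j in cols:
        col = calls[:, j]
        x, y = col[ia], col[ib]
        out |= (x >= 0) & (y >= 0) & (x != y)
    return out


def discernibility(matrix: GenotypeMatrix, panel: Sequence[int]) -> int:
    """Number of unordered sample pairs the panel distinguishes."""
    if len(panel) == 0:
        raise ValueError("panel must be non-empty")
    ia, ib = np.triu_indices(matrix.n_samples, k=1)
    return int(_pair_diff_mask(matrix.calls, list(panel), ia, ib).sum())


def greedy_panel(
    matrix: GenotypeMatrix,
    candidate_loci: Sequence[int] | None = None,
    pic: Mapping[str, float] | Sequence[float] | None = None,
    samples: Sequence[str] | None = None,
) -> PanelResult:
    """Greedy forward selection of a minimal discriminating locus panel.

    Parameters
    ----------
    candidate_loci
        Locus indices eligible for selection (all loci by default).
    pic
        Tie-break informativeness per candidate locus, as a mapping from
        locus id or a sequence aligned with the matrix columns.  When
        omitted, allele-convention PIC is computed from the matrix.
    samples
        Restrict the discrimination target to this sample subset (e.g. the
        non-EDV samples); all samples by default.
    """
    work = matrix if samples is None else matrix.subset(samples=list(samples))
    if work.n_samples < 2:
        raise ValueError("greedy_panel requires at least 2 samples")
    cand = (
        list(range(work.n_loci))
        if candidate_loci is None
        else list(candidate_loci)
    )
    if not cand:
        raise ValueError("no candidate loci to select from")
    if pic is None:
        stats = compute_locus_stats(matrix)
        pic_by_id = dict(zip(stats["locus_id"], stats["pic_allele"]))
    elif isinstance(pic, Mapping):
        pic_by_id = dict(pic)
    else:
        pic_by_id = dict(zip(matrix.locus_ids, pic))
    pic_arr = np.array(
        [float(np.nan_to_num(pic_by_id.get(matrix.loci[j].id, 0.0))) for j in cand]
    )
    ids = [matrix.loci[j].id for j in cand]

    calls = work.calls
    ia, ib = np.triu_indices(work.n_samples, k=1)
    n_pairs = len(ia)
    full_mask = _pair_diff_mask(calls, cand, ia, ib)
    max_disc = int(full_mask.sum())

    selected: list[str] = []
    selected_cols: list[int] = []
    trace: list[int] = []
    undist = np.arange(n_pairs)  # indices of still-undistinguished pairs
    remaining = list(range(len(cand)))
    covered = 0
    while covered < max_disc and remaining:
        ua, ub = ia[undist], ib[undist]
        best_k = None
        best_key: tuple[int, float, object] | None = None
        for k in remaining:
            col = calls[:, cand[k]]
            x, y = col[ua], col[ub]
            gain = int(np.count_nonzero((x >= 0) & (y >= 0) & (x != y)))
            key = (gain, pic_arr[k], _RevStr(ids[k]))
            if best_key is None or key > best_key:
                best_key, best_k = key, k
        assert best_k is not None and best_key is not None
        gain = best_key[0]
        if gain == 0:
            break
        col = calls[:, cand[best_k]]
        x, y = col[ua], col[ub]
        newly = (x >= 0) & (y >= 0) & (x != y)
        undist = undist[~newly]
        covered += gain
        selected.append(ids[best_k])
        selected_cols.append(cand[best_k])
        trace.append(covered)
        remaining.remove(best_k)

    # Pairs no candidate locus can separate (clones, missing-data shadows).
    resid = undist[~full_mask[undist]] if covered >= max_disc else undist
    indist = [
        (work.sample_ids[ia[p]], work.sample_ids[ib[p]]) for p in resid
    ]
    fingerprints = fingerprint_strings(work, selected_cols)
    return PanelResult(
        selected=selected,
        discernibility_trace=trace,
        max_discernibility=max_disc,
        n_pairs=n_pairs,
        fingerprints=fingerprints,
        indistinguishable_pairs=indist,
    )


class _RevStr(str):
    """Orders strings in reverse, so max() prefers the smaller locus id."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def fingerprint_strings(
    matrix: GenotypeMatrix, panel: Sequence[int]
) -> dict[str, str]:
    """Per-sample genotype-code strings over the panel loci."""
    cols = np.asarray(list(panel), dtype=int)
    return {
        s: "".join(
            FINGERPRINT_CODES[int(c)] for c in matrix.calls[i, cols]
        )
        for i, s in enumerate(matrix.sample_ids)
    }


def fingerprint_table(
    matrix: GenotypeMatrix, panel: Sequence[int]
) -> pd.DataFrame:
    """Samples x panel-loci table of one-character genotype codes."""
    cols = list(panel)
    data = {
        matrix.loci[j].id: [
            FINGERPRINT_CODES[int(c)] for c in matrix.calls[:, j]
        ]
        for j in cols
    }
    return pd.DataFrame(data, index=matrix.sample_ids)


def panel_table(result: PanelResult) -> pd.DataFrame:
    """Rank / locus / added / cumulative discernibility table."""
    added = [
        t - (result.discernibility_trace[i - 1] if i else 0)
        for i, t in enumerate(result.discernibility_trace)
    ]
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(result.selected) + 1),
            "locus_id": result.selected,
            "added_discernibility": added,
            "cumulative_discernibility": result.discernibility_trace,
        }
    )
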