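"""Two-stage SNP filtering for a core marker set.

Stage one (candidates) keeps loci with MAF strictly above a floor, missing
rate strictly below a ceiling, and no neighbouring variant within a flanking
window on the same chromosome (assayable flanks).  Stage two (core) applies
tighter MAF / missing-rate / PIC thresholds and, optionally, thins to the
highest-PIC SNP per fixed-width genomic bin so that the panel covers every
chromosome roughly uniformly.

Inequality directions are deliberately asymmetric: MAF and PIC floors are
strict (``>``), the core missing-rate ceiling is inclusive (``<=``) and the
candidate ceiling strict (``<``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, Locus


@dataclass
class FilterConfig:
    """Thresholds for candidate and core SNP selection.

    All rates are fractions in [0, 1]; ``flank_bp`` and ``bin_width`` are in
    base pairs.  ``bin_width=None`` disables the uniform-coverage thinning.
    """

    candidate_maf_min: float = 0.1
    candidate_miss_max: float = 0.20
    flank_bp: int = 150
    core_maf_min: float = 0.15
    core_miss_max: float = 0.05
    core_pic_min: float = 0.15
    min_core_size: int = 300
    bin_width: int | None = None

    def __post_init__(self) -> None:
        for name in (
            "candidate_maf_min",
            "candidate_miss_max",
            "core_maf_min",
            "core_miss_max",
            "core_pic_min",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.flank_bp < 0:
            raise ValueError("flank_bp must be >= 0")
        if self.min_core_size < 1:
            raise ValueError("min_core_size must be >= 1")
        if self.bin_width is not None and self.bin_width < 1:
            raise ValueError("bin_width must be >= 1 when set")

    @classmethod
    def from_file(cls, path: str | Path) -> "FilterConfig":
        """Parse a simple ``key = value`` config file ('#' starts a comment)."""
        values: dict[str, object] = {}
        valid = {f.name for f in fields(cls)}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, val = (part.strip() for part in line.split("=", 1))
            if key not in valid:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
            if val.lower() in ("none", ""):
                values[key] = None
            elif key in ("flank_bp", "min_core_size", "bin_width"):
                values[key] = int(val)
            else:
                values[key] = float(val)
        return cls(**values)


def flank_unique(loci: Sequence[Locus], flank_bp: int) -> np.ndarray:
    """Indices of loci with no other variant within ``flank_bp`` on the same chromosome.

    Both members of a close pair are dropped (distance <= ``flank_bp``
    excludes).  ``loci`` must be position-sorted within each chromosome and
    each chromosome's loci contiguous (the natural VCF ordering; chromosome
    name order itself is free).
    """
    keys = [loc.key for loc in loci]
    seen_chroms: set[str] = set()
    prev_chrom: str | None = None
    for chrom, pos in keys:
        if chrom != prev_chrom:
            if chrom in seen_chroms:
                raise ValueError(
                    f"loci for chromosome {chrom} are not contiguous"
                )
            seen_chroms.add(chrom)
            prev_chrom = chrom
        elif pos <= prev_pos:
            raise ValueError(
                f"loci must be position-sorted within {chrom}"
            )
        prev_pos = pos
    n = len(loci)
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        if i > 0 and keys[i - 1][0] == keys[i][0]:
            if keys[i][1] - keys[i - 1][1] <= flank_bp:
                keep[i] = keep[i - 1] = False
        # only adjacent neighbours can violate the window on sorted input
    return np.flatnonzero(keep)


def filter_candidates(
    matrix: GenotypeMatrix, stats: pd.DataFrame, config: FilterConfig
) -> np.ndarray:
    """Candidate-SNP indices: MAF > floor, missing rate < ceiling, flanks clear."""
    isolated = np.zeros(matrix.n_loci, dtype=bool)
    isolated[flank_unique(matrix.loci, config.flank_bp)] = True
    ok = (
        (stats["maf"].to_numpy() > config.candidate_maf_min)
        & (stats["miss_rate"].to_numpy() < config.candidate_miss_max)
        & isolated
    )
    return np.flatnonzero(np.nan_to_num(ok, nan=False))


def select_core(
    matrix: GenotypeMatrix,
    stats: pd.DataFrame,
    config: FilterConfig,
    pic_column: str = "pic_allele",
) -> np.ndarray:
    """Core-SNP indices from the candidate set.

    Applies MAF > ``core_maf_min`` (strict), missing rate <=
    ``core_miss_max`` (inclusive) and PIC > ``core_pic_min`` (strict); when
    ``bin_width`` is set, keeps the single highest-PIC SNP per chromosome
    bin (ties by locus id).  Warns, rather than fails, when the result is
    smaller than ``min_core_size`` or empty.
    """
    cand = filter_candidates(matrix, stats, config)
    maf_ = stats["maf"].to_numpy()
    miss = stats["miss_rate"].to_numpy()
    pic_ = stats[pic_column].to_numpy()
    ok = (
        (maf_[cand] > config.core_maf_min)
        & (miss[cand] <= config.core_miss_max)
        & (pic_[cand] > config.core_pic_min)
    )
    core = cand[np.nan_to_num(ok, nan=False)]
    if config.bin_width is not None and len(core):
        best: dict[tuple[str, int], int] = {}
        for j in core:
            loc = matrix.loci[j]
            binkey = (loc.chromosome, loc.position // config.bin_width)
            cur = best.get(binkey)
            if cur is None or (pic_[j], _neg_id(matrix.loci[j].id)) > (
                pic_[cur],
                _neg_id(matrix.loci[cur].id),
            ):
                best[binkey] = j
        core = np.array(sorted(best.values()), dtype=int)
    if len(core) == 0:
        warnings.warn("core SNP selection produced an empty set", stacklevel=2)
    elif len(core) < config.min_core_size:
        warnings.warn(
            f"core SNP set has {len(core)} loci, fewer than the requested "
            f"minimum of {config.min_core_size}",
            stacklevel=2,
        )
    return core


class _neg_id(str):
    """Reverse lexicographic ordering helper (smaller id wins PIC ties)."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def core_table(
    matrix: GenotypeMatrix, stats: pd.DataFrame, core: np.ndarray
) -> pd.DataFrame:
    """Tabular view (id, chrom, pos, maf, miss, pic) of a core index set."""
    sub = stats.iloc[core]
    return pd.DataFrame(
        {
            "id": sub["locus_id"].to_numpy(),
            "chrom": sub["chromosome"].to_numpy(),
            "pos": sub["position"].to_numpy(),
            "maf": sub["maf"].to_numpy(),
            "miss": sub["miss_rate"].to_numpy(),
            "pic": sub["pic_allele"].to_numpy(),
        }
    )
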