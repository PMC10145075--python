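"""Genotype matrices, loci and sample metadata, with VCF and CSV/TSV I/O.

Diploid biallelic calls are held as a dense ``int8`` samples x loci matrix
over a four-code alphabet: ``REF_HOM`` (0), ``HET`` (1), ``ALT_HOM`` (2) and
``MISSING`` (-1).  Every downstream statistic in this package operates on
genotype *classes*, so phase is discarded on read (``0|1`` == ``0/1``) and
half-calls such as ``./1`` are conservatively treated as missing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

REF_HOM: int = 0
HET: int = 1
ALT_HOM: int = 2
MISSING: int = -1

#: Every value a call matrix may contain.
GENOTYPE_CODES: tuple[int, ...] = (REF_HOM, HET, ALT_HOM, MISSING)

_BASES = frozenset("ACGT")
_GRADES = frozenset({"national", "provincial", "landrace", "unknown"})


class VcfParseError(ValueError):
    """Raised when a VCF cannot be decoded into a genotype matrix."""


@dataclass(frozen=True, order=True)
class Locus:
    """A biallelic SNP position.

    Coordinates are 1-based, as in VCF.  The default identifier is
    ``<chromosome>_<position>`` (e.g. ``Chr1_5870698``), the convention used
    for published tea-tree SNP panels.
    """

    chromosome: str
    position: int
    ref_allele: str = "A"
    alt_allele: str = "G"
    id: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.ref_allele not in _BASES or self.alt_allele not in _BASES:
            raise ValueError(
                f"alleles must be single bases in ACGT, got "
                f"{self.ref_allele!r}/{self.alt_allele!r}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        if not self.id:
            object.__setattr__(self, "id", f"{self.chromosome}_{self.position}")

    @property
    def key(self) -> tuple[str, int]:
        return (self.chromosome, self.position)


@dataclass
class SampleMeta:
    """Per-sample passport data.

    ``control_group`` links the two members of a known same-variety pair
    grown at different sites (a positive control for derivation analysis);
    samples sharing a non-empty ``control_group`` form one pair.
    ``membership`` is the admixture membership coefficient of the sample's
    own population.
    """

    sample_id: str
    province: str | None = None
    grade: str = "unknown"
    registration_year: int | None = None
    population: int | None = None
    membership: float | None = None
    control_group: str | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")
        if self.grade not in _GRADES:
            raise ValueError(f"unknown grade {self.grade!r}")
        if self.registration_year is not None and self.grade not in (
            "national",
            "provincial",
        ):
            raise ValueError(
                f"{self.sample_id}: registration_year requires grade "
                "national or provincial"
            )
        if self.membership is not None and not 0.0 <= self.membership <= 1.0:
            raise ValueError(
                f"{self.sample_id}: membership {self.membership} outside [0, 1]"
            )


class GenotypeMatrix:
    """Samples x loci diploid genotype-class matrix.

    Parameters
    ----------
    sample_ids
        Unique, non-empty sample identifiers (row order).
    loci
        Loci in column order, unique by (chromosome, position).
    calls
        ``int8`` array of shape (n_samples, n_loci) over
        :data:`GENOTYPE_CODES`.
    """

    def __init__(
        self,
        sample_ids: Sequence[str],
        loci: Sequence[Locus],
        calls: np.ndarray,
    ) -> None:
        sample_ids = list(sample_ids)
        loci = list(loci)
        if not sample_ids:
            raise ValueError("at least one sample is required")
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("sample_ids must be unique")
        keys = [loc.key for loc in loci]
        if len(set(keys)) != len(keys):
            raise ValueError("loci must be unique by (chromosome, position)")
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(sample_ids), len(loci)):
            raise ValueError(
                f"calls shape {calls.shape} != "
                f"({len(sample_ids)}, {len(loci)})"
            )
        bad = ~np.isin(calls, np.array(GENOTYPE_CODES, dtype=np.int8))
        if bad.any():
            raise ValueError("calls contain codes outside the genotype alphabet")
        self.sample_ids = sample_ids
        self.loci = loci
        self.calls = calls
        self._sample_index = {s: i for i, s in enumerate(sample_ids)}

    # -- basic accessors ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_ids(self) -> list[str]:
        return [loc.id for loc in self.loci]

    def sample_index(self, sample_id: str) -> int:
        return self._sample_index[sample_id]

    def subset(
        self,
        samples: Sequence[str] | None = None,
        loci: Sequence[int] | None = None,
    ) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given samples / locus indices."""
        rows = (
            np.arange(self.n_samples)
            if samples is None
            else np.array([self._sample_index[s] for s in samples])
        )
        cols = np.arange(self.n_loci) if loci is None else np.asarray(loci)
        return GenotypeMatrix(
            [self.sample_ids[i] for i in rows],
            [self.loci[j] for j in cols],
            self.calls[np.ix_(rows, cols)],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.loci == other.loci
            and np.array_equal(self.calls, other.calls)
        )

    def __repr__(self) -> str:
        return f"GenotypeMatrix({self.n_samples} samples x {self.n_loci} loci)"


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def _encode_gt(gt: tuple | None) -> int:
    if gt is None or len(gt) != 2 or gt[0] is None or gt[1] is None:
        return MISSING
    a, b = gt
    if a not in (0, 1) or b not in (0, 1):  # pragma: no cover - guarded upstream
        return MISSING
    return a + b  # 0/0 -> 0, 0/1 or 1/0 -> 1, 1/1 -> 2


def read_vcf(path: str | Path, biallelic_only: bool = True) -> GenotypeMatrix:
    """Read a VCF 4.x with GT calls into a :class:`GenotypeMatrix`.

    Multi-allelic or non-SNP records are skipped when ``biallelic_only`` is
    true and rejected with :class:`VcfParseError` otherwise.  Locus order
    follows the file.  Phasing separators are ignored and half-calls map to
    ``MISSING``.
    """
    path = str(path)
    try:
        vf = pysam.VariantFile(path)
    except (ValueError, OSError) as exc:
        raise VcfParseError(f"cannot parse VCF {path}: {exc}") from exc
    with vf:
        samples = list(vf.header.samples)
        if not samples:
            raise VcfParseError(f"{path}: VCF contains no samples")
        loci: list[Locus] = []
        seen: set[tuple[str, int]] = set()
        columns: list[np.ndarray] = []
        for rec in vf:
            alts = rec.alts or ()
            is_snp = (
                len(alts) == 1
                and len(rec.ref) == 1
                and len(alts[0]) == 1
                and rec.ref in _BASES
                and alts[0] in _BASES
            )
            if not is_snp:
                if biallelic_only:
                    continue
                raise VcfParseError(
                    f"{path}: non-biallelic-SNP record at "
                    f"{rec.chrom}:{rec.pos}"
                )
            key = (rec.chrom, rec.pos)
            if key in seen:
                raise VcfParseError(
                    f"{path}: duplicate locus {rec.chrom}:{rec.pos}"
                )
            seen.add(key)
            rid = rec.id if rec.id not in (None, ".") else ""
            loci.append(
                Locus(rec.chrom, rec.pos, rec.ref, alts[0], id=rid)
            )
            col = np.empty(len(samples), dtype=np.int8)
            for i, s in enumerate(samples):
                col[i] = _encode_gt(rec.samples[s].get("GT"))
            columns.append(col)
    calls = (
        np.stack(columns, axis=1)
        if columns
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(samples, loci, calls)


_GT_TUPLES = {REF_HOM: (0, 0), HET: (0, 1), ALT_HOM: (1, 1), MISSING: (None, None)}


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write ``matrix`` as an uncompressed VCF 4.2 with a GT-only FORMAT.

    ``read_vcf(write_vcf(m))`` reproduces sample ids, loci and calls exactly.
    """
    header = pysam.VariantHeader()
    contigs: list[str] = []
    for loc in matrix.loci:
        if loc.chromosome not in contigs:
            contigs.append(loc.chromosome)
    for chrom in contigs:
        header.contigs.add(chrom)
    header.formats.add("GT", 1, "String", "Genotype")
    for s in matrix.sample_ids:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j, loc in enumerate(matrix.loci):
            rec = out.new_record(
                contig=loc.chromosome,
                start=loc.position - 1,
                alleles=(loc.ref_allele, loc.alt_allele),
                id=loc.id,
            )
            for i, s in enumerate(matrix.sample_ids):
                rec.samples[s]["GT"] = _GT_TUPLES[int(matrix.calls[i, j])]
            out.write(rec)


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

_META_COLUMNS = (
    "sample_id",
    "province",
    "grade",
    "registration_year",
    "population",
    "membership",
    "control_group",
)


def read_sample_meta(path: str | Path) -> list[SampleMeta]:
    """Read a sample-metadata table (CSV, or TSV for a ``.tsv`` extension).

    Only the ``sample_id`` column is required; the remaining recognised
    columns (province, grade, registration_year, population, membership,
    control_group) are optional and unknown columns are preserved in
    ``SampleMeta.extra``.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: missing required column sample_id")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"{path}: duplicate sample_id(s): {dups}")
    extra_cols = [c for c in df.columns if c not in _META_COLUMNS]
    metas: list[SampleMeta] = []
    for _, row in df.iterrows():
        def get(col):
            v = row.get(col)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                return None
            return v

        grade = get("grade")
        year = get("registration_year")
        pop = get("population")
        membership = get("membership")
        metas.append(
            SampleMeta(
                sample_id=str(row["sample_id"]),
                province=None if get("province") is None else str(get("province")),
                grade="unknown" if grade is None else str(grade).strip().lower(),
                registration_year=None if year is None else int(year),
                population=None if pop is None else int(pop),
                membership=None if membership is None else float(membership),
                control_group=(
                    None
                    if get("control_group") is None
                    else str(get("control_group"))
                ),
                extra={c: row[c] for c in extra_cols},
            )
        )
    return metas


def write_sample_meta(metas: Iterable[SampleMeta], path: str | Path) -> None:
    """Write metadata as CSV (TSV for a ``.tsv`` extension)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    rows = []
    for m in metas:
        rows.append(
            {
                "sample_id": m.sample_id,
                "province": m.province,
                "grade": m.grade,
                "registration_year": m.registration_year,
                "population": m.population,
                "membership": m.membership,
                "control_group": m.control_group,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def control_pairs(metas: Sequence[SampleMeta]) -> list[tuple[str, str]]:
    """Return the same-variety positive-control pairs encoded in metadata."""
    groups: dict[str, list[str]] = {}
    for m in metas:
        if m.control_group:
            groups.setdefault(m.control_group, []).append(m.sample_id)
    pairs = []
    for g, members in sorted(groups.items()):
        if len(members) != 2:
            raise ValueError(
                f"control group {g!r} has {len(members)} members, expected 2"
            )
        pairs.append((members[0], members[1]))
    return pairs
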