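"""Synthetic structured-population genotype generator with known truth.

The generator emulates the statistical shape of a clonal-crop germplasm
cohort: several subpopulations with Balding-Nichols-differentiated allele
frequencies, a handful of admixed individuals, clonal derivatives of named
parents accumulating genotype changes at a small per-locus rate, duplicate
same-variety positive-control pairs, and MCAR missing genotypes.  Defaults
mirror a five-population tea-germplasm cohort of 349 trees (population
sizes 159/72/51/50/17, six positive-control pairs, ~6% admixed samples)
genotyped at 1000 SNPs on 15 chromosomes.

Every draw flows from a single root seed, so identical configurations give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, Locus, SampleMeta
from .similarity import CATEGORY_NONE, EdvCall

_PROVINCES = (
    "FJ", "SC", "ZJ", "HN", "CQ", "AH", "GD", "YN", "GZ", "JX", "HB", "GX",
)
_ALLELES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic cohort."""

    n_pops: int = 5
    pop_sizes: tuple[int, ...] = (159, 72, 51, 50, 17)
    n_loci: int = 1000
    n_chromosomes: int = 15
    fst: float = 0.15
    admixed_fraction: float = 0.06
    edv_pairs: int = 12
    edv_mutation_rate: float = 0.02
    control_pairs: int = 6
    control_mutation_rate: float = 0.01
    miss_rate: float = 0.02
    n_close_loci: int = 10  # loci deliberately placed within 150 bp of a neighbour
    min_spacing: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.pop_sizes) != self.n_pops:
            raise ValueError("pop_sizes length must equal n_pops")
        if any(s < 1 for s in self.pop_sizes):
            raise ValueError("population sizes must be positive")
        for name in (
            "fst",
            "admixed_fraction",
            "edv_mutation_rate",
            "control_mutation_rate",
            "miss_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_loci < self.n_chromosomes:
            raise ValueError("n_loci must be >= n_chromosomes")
        n = self.n_samples
        needed = 2 * (self.edv_pairs + self.control_pairs)
        if needed > n:
            raise ValueError(
                f"{self.edv_pairs} derived + {self.control_pairs} control "
                f"pairs need {needed} samples but only {n} are configured"
            )

    @property
    def n_samples(self) -> int:
        return int(sum(self.pop_sizes))


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort."""

    table: pd.DataFrame  # sample_id, role, population, parent_id
    clone_pairs: list[tuple[str, str]] = field(default_factory=list)
    control_pair_ids: list[tuple[str, str]] = field(default_factory=list)


def _make_loci(cfg: SimConfig, rng: np.random.Generator) -> list[Locus]:
    per_chrom = np.full(cfg.n_chromosomes, cfg.n_loci // cfg.n_chromosomes)
    per_chrom[: cfg.n_loci % cfg.n_chromosomes] += 1
    # which loci get a deliberately close left neighbour
    close = set(
        rng.choice(cfg.n_loci, size=min(cfg.n_close_loci, cfg.n_loci), replace=False)
    )
    loci: list[Locus] = []
    idx = 0
    for c in range(cfg.n_chromosomes):
        pos = 0
        for _ in range(int(per_chrom[c])):
            if idx in close and pos > 0:
                gap = int(rng.integers(20, 150))
            else:
                gap = cfg.min_spacing + int(rng.integers(1, 5000))
            pos += gap
            ref, alt = rng.choice(4, size=2, replace=False)
            loci.append(
                Locus(f"Chr{c + 1}", pos, str(_ALLELES[ref]), str(_ALLELES[alt]))
            )
            idx += 1
    return loci


def _mutate_clone(
    genotypes: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Copy a genotype row, resampling each locus to a *different* class w.p. rate."""
    out = genotypes.copy()
    hits = np.flatnonzero(rng.random(out.shape[0]) < rate)
    for j in hits:
        choices = [g for g in (0, 1, 2) if g != out[j]]
        out[j] = choices[int(rng.integers(len(choices)))]
    return out


def simulate(config: SimConfig) -> tuple[GenotypeMatrix, list[SampleMeta], SimTruth]:
    """Generate a cohort: genotypes, passport metadata and ground truth.

    The model: ancestral allele frequencies are Uniform(0.05, 0.95); each
    population draws its own frequency per locus from the Balding-Nichols
    distribution Beta(p(1-F)/F, (1-p)(1-F)/F); founders are Binomial(2, p)
    within populations (Hardy-Weinberg); admixed samples draw from the
    50/50 mean of two populations' frequencies; derived clones copy a
    parent with per-locus class-resampling mutations; control pairs do the
    same at a lower rate; finally genotypes are masked MCAR.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, L = cfg.n_samples, cfg.n_loci

    loci = _make_loci(cfg, rng)
    p_anc = rng.uniform(0.05, 0.95, size=L)
    F = cfg.fst
    if F > 0:
        a = p_anc * (1 - F) / F
        b = (1 - p_anc) * (1 - F) / F
        p_pop = rng.beta(a, b, size=(cfg.n_pops, L))
    else:
        p_pop = np.tile(p_anc, (cfg.n_pops, 1))
    p_pop = np.clip(p_pop, 1e-6, 1 - 1e-6)

    sample_ids = [f"T{i + 1:03d}" for i in range(n)]
    populations = np.repeat(np.arange(1, cfg.n_pops + 1), cfg.pop_sizes)

    # choose admixed individuals (never clone parents/copies, handled below)
    n_admixed = int(round(cfg.admixed_fraction * n))
    admixed = set(rng.choice(n, size=n_admixed, replace=False).tolist())

    # reserve distinct non-admixed slots for derived and control pairs,
    # each pair within one population
    available: dict[int, list[int]] = {}
    for i in range(n):
        if i not in admixed:
            available.setdefault(int(populations[i]), []).append(i)
    pair_slots: list[tuple[int, int]] = []
    pops_cycle = sorted(available, key=lambda p: -len(available[p]))
    need = cfg.edv_pairs + cfg.control_pairs
    k = 0
    while len(pair_slots) < need:
        pop = pops_cycle[k % len(pops_cycle)]
        k += 1
        slots = available[pop]
        if len(slots) < 2:
            continue
        i1 = slots.pop(int(rng.integers(len(slots))))
        i2 = slots.pop(int(rng.integers(len(slots))))
        pair_slots.append((i1, i2))
    edv_slots = pair_slots[: cfg.edv_pairs]
    control_slots = pair_slots[cfg.edv_pairs :]

    # founder / admixed genotypes
    calls = np.empty((n, L), dtype=np.int8)
    roles = np.array(["founder"] * n, dtype=object)
    parent_of = np.array([None] * n, dtype=object)
    admix_partner = {}
    for i in range(n):
        pop = int(populations[i])
        if i in admixed:
            other_choices = [p for p in range(1, cfg.n_pops + 1) if p != pop]
            other = int(rng.choice(other_choices))
            admix_partner[i] = other
            p_i = 0.5 * (p_pop[pop - 1] + p_pop[other - 1])
            roles[i] = "admixed"
        else:
            p_i = p_pop[pop - 1]
        calls[i] = rng.binomial(2, p_i).astype(np.int8)

    # derived clones and control copies overwrite their slot's genotypes
    clone_pairs: list[tuple[str, str]] = []
    control_pair_ids: list[tuple[str, str]] = []
    for parent_i, clone_i in edv_slots:
        calls[clone_i] = _mutate_clone(calls[parent_i], cfg.edv_mutation_rate, rng)
        roles[clone_i] = "edv_clone"
        parent_of[clone_i] = sample_ids[parent_i]
        clone_pairs.append((sample_ids[parent_i], sample_ids[clone_i]))
    for gi, (parent_i, copy_i) in enumerate(control_slots, start=1):
        calls[copy_i] = _mutate_clone(
            calls[parent_i], cfg.control_mutation_rate, rng
        )
        roles[copy_i] = "control_copy"
        parent_of[copy_i] = sample_ids[parent_i]
        clone_pairs.append((sample_ids[parent_i], sample_ids[copy_i]))
        control_pair_ids.append((sample_ids[parent_i], sample_ids[copy_i]))

    # MCAR missingness over the whole matrix
    if cfg.miss_rate > 0:
        mask = rng.random((n, L)) < cfg.miss_rate
        calls[mask] = MISSING

    # passport metadata
    metas: list[SampleMeta] = []
    control_group_of: dict[int, str] = {}
    for gi, (a, b) in enumerate(control_slots, start=1):
        control_group_of[a] = control_group_of[b] = f"CG{gi}"
    year_parent: dict[int, int] = {}
    for parent_i, clone_i in edv_slots:
        year_parent[parent_i] = int(rng.integers(1980, 2006))
    for i in range(n):
        province = str(rng.choice(_PROVINCES))
        membership = (
            float(rng.uniform(0.40, 0.60))
            if roles[i] == "admixed"
            else float(rng.uniform(0.85, 0.99))
        )
        grade, year = "landrace", None
        if i in year_parent:
            grade = str(rng.choice(["national", "provincial"]))
            year = year_parent[i]
        elif roles[i] == "edv_clone":
            grade = str(rng.choice(["national", "provincial"]))
            parent_slot = next(p for p, c in edv_slots if c == i)
            year = year_parent[parent_slot] + int(rng.integers(1, 16))
        elif i in control_group_of:
            grade = "landrace"
        elif rng.random() < 0.35:
            grade = str(rng.choice(["national", "provincial"]))
            year = int(rng.integers(1980, 2021))
        metas.append(
            SampleMeta(
                sample_id=sample_ids[i],
                province=province,
                grade=grade,
                registration_year=year,
                population=int(populations[i]),
                membership=membership,
                control_group=control_group_of.get(i),
            )
        )

    truth_df = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "role": roles,
            "population": populations,
            "parent_id": parent_of,
            "admixed_with": [admix_partner.get(i) for i in range(n)],
        }
    )
    matrix = GenotypeMatrix(sample_ids, loci, calls)
    truth = SimTruth(truth_df, clone_pairs, control_pair_ids)
    return matrix, metas, truth


def truth_eval(
    edv_calls: Sequence[EdvCall], truth: SimTruth
) -> dict:
    """Score classification calls against simulation ground truth.

    Sensitivity: fraction of true clone pairs (derived + control) classified
    putative or indisputable.  False-positive rate: fraction of
    founder-founder pairs (no clonal relationship) carrying a non-``none``
    call.
    """
    if len(truth.table) == 0:
        return {}
    called = {
        frozenset((c.a, c.b))
        for c in edv_calls
        if c.category != CATEGORY_NONE
    }
    clone_sets = [frozenset(p) for p in truth.clone_pairs]
    n_clone = len(clone_sets)
    detected = sum(1 for p in clone_sets if p in called)
    founders = truth.table.loc[
        truth.table["role"] == "founder", "sample_id"
    ].tolist()
    founder_set = set(founders)
    n_founder_pairs = len(founders) * (len(founders) - 1) // 2
    fp = sum(
        1
        for pair in called
        if pair <= founder_set and pair not in clone_sets
    )
    return {
        "n_clone_pairs": n_clone,
        "n_detected": detected,
        "sensitivity": detected / n_clone if n_clone else float("nan"),
        "n_founder_pairs": n_founder_pairs,
        "n_false_positive": fp,
        "false_positive_rate": (
            fp / n_founder_pairs if n_founder_pairs else float("nan")
        ),
    }


def write_truth(truth: SimTruth, path) -> None:
    """Write the truth table as TSV."""
    truth.table.to_csv(path, sep="\t", index=False)
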