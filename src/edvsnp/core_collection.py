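"""Least-distance stepwise selection of core varieties per population.

Within each population, samples are ranked by their total number of
differential genotype classes against the other members (missing calls
contribute nothing); the smaller the total, the closer the sample sits to
the population's genetic centre.  The top fraction (20% by default) of each
population is taken as its core, after excluding heavily admixed samples,
and any selected sample that is the derived member of an already-selected
pair (or the offspring of a selected parent) is replaced by the next-ranked
candidate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import ceil, floor
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, SampleMeta
from .similarity import CATEGORY_INDISPUTABLE, CATEGORY_NONE, EdvCall, gs_matrix

ROUNDINGS = ("half_up", "floor", "ceil")


@dataclass
class PopulationCore:
    """Core-selection outcome for one population."""

    population: int
    size: int
    quota: int
    selected: list[str]
    ranking: list[tuple[str, int, float]]  # (sample_id, diff_total, diff_mean)
    excluded: list[tuple[str, str]] = field(default_factory=list)


def diff_matrix(
    matrix: GenotypeMatrix, samples: Sequence[str] | None = None
) -> pd.DataFrame:
    """Pairwise counts of differing genotype classes (square, symmetric).

    This is the ND count of the similarity module restricted to ``samples``:
    loci missing in either member are treated as null and not counted.
    """
    sub = matrix if samples is None else matrix.subset(samples=list(samples))
    if sub.n_samples < 2:
        raise ValueError("diff_matrix requires at least 2 samples")
    sim = gs_matrix(sub)
    return pd.DataFrame(sim.nd, index=sub.sample_ids, columns=sub.sample_ids)


def _quota(size: int, fraction: float, rounding: str) -> int:
    x = fraction * size
    if rounding == "half_up":
        return int(floor(x + 0.5))
    if rounding == "floor":
        return int(floor(x))
    if rounding == "ceil":
        return int(ceil(x))
    raise ValueError(f"rounding must be one of {ROUNDINGS}, got {rounding!r}")


def select_core_varieties(
    matrix: GenotypeMatrix,
    meta: Sequence[SampleMeta] | Mapping[str, SampleMeta],
    fraction: float = 0.20,
    membership_min: float = 0.8,
    edv_calls: Sequence[EdvCall] = (),
    pedigree: Sequence[tuple[str, str]] = (),
    rounding: str = "half_up",
) -> list[PopulationCore]:
    """Select per-population core varieties by least-distance ranking.

    ``pedigree`` lists known (parent, offspring) pairs.  Quotas are computed
    on the full labelled population size; admixture exclusion
    (``membership < membership_min``) happens before ranking.  Ties in the
    ranking key are broken lexicographically by sample id, so the outcome
    does not depend on input order.
    """
    meta_map = (
        {m.sample_id: m for m in meta} if not isinstance(meta, Mapping) else meta
    )
    unlabelled = [s for s in matrix.sample_ids if getattr(meta_map.get(s), "population", None) is None]
    if unlabelled:
        raise ValueError(f"samples without population label: {unlabelled[:5]}")

    # Lookup of derived-pair calls for the replacement rule.
    call_map: dict[frozenset, EdvCall] = {
        frozenset((c.a, c.b)): c
        for c in edv_calls
        if c.category != CATEGORY_NONE
    }
    offspring_of: dict[str, set[str]] = {}
    for parent, child in pedigree:
        offspring_of.setdefault(child, set()).add(parent)

    pops: dict[int, list[str]] = {}
    for s in matrix.sample_ids:
        pops.setdefault(int(meta_map[s].population), []).append(s)

    results: list[PopulationCore] = []
    for pop in sorted(pops):
        members = sorted(pops[pop])
        excluded: list[tuple[str, str]] = []
        included = []
        for s in members:
            mem = meta_map[s].membership
            if mem is not None and mem < membership_min:
                excluded.append((s, "admixed"))
            else:
                included.append(s)
        quota = _quota(len(members), fraction, rounding)
        if len(included) < 2:
            if included:
                warnings.warn(
                    f"population {pop}: fewer than 2 samples after exclusions;"
                    " returning the sole member",
                    stacklevel=2,
                )
            results.append(
                PopulationCore(pop, len(members), quota, list(included), [
                    (s, 0, 0.0) for s in included
                ], excluded)
            )
            continue
        nd = diff_matrix(matrix, included)
        totals = nd.to_numpy().sum(axis=0)
        means = totals / (len(included) - 1)
        order = sorted(
            range(len(included)), key=lambda i: (totals[i], included[i])
        )
        ranking = [
            (included[i], int(totals[i]), float(means[i])) for i in order
        ]

        selected: list[str] = []
        for sample_id, _, _ in ranking:
            if len(selected) >= quota:
                break
            reason = _rejection_reason(
                sample_id, selected, call_map, offspring_of
            )
            if reason is not None:
                excluded.append((sample_id, reason))
                continue
            selected.append(sample_id)
        results.append(
            PopulationCore(pop, len(members), quota, selected, ranking, excluded)
        )
    return results


def _rejection_reason(
    candidate: str,
    selected: Sequence[str],
    call_map: Mapping[frozenset, EdvCall],
    offspring_of: Mapping[str, set[str]],
) -> str | None:
    parents = offspring_of.get(candidate, set())
    for s in selected:
        if s in parents:
            return "offspring"
        call = call_map.get(frozenset((candidate, s)))
        if call is None:
            continue
        if call.edv_sample == candidate:
            return "edv"
        # Keep indisputable pairs out of the core even when registration
        # years cannot say which member is derived: drop the later-ranked.
        if call.category == CATEGORY_INDISPUTABLE and call.edv_sample is None:
            return "edv"
    return None


def core_table(results: Sequence[PopulationCore]) -> pd.DataFrame:
    """Per-population summary table (population, size, core_count, members)."""
    return pd.DataFrame(
        {
            "population": [r.population for r in results],
            "size": [r.size for r in results],
            "core_count": [len(r.selected) for r in results],
            "core_samples": ["; ".join(r.selected) for r in results],
        }
    )
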