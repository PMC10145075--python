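"""End-to-end pipeline: stats -> core SNPs -> GS -> EDV -> core varieties -> panel.

The pipeline is a pure function of its inputs and configuration; identical
inputs produce byte-identical output files.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from . import core_collection, locus_stats, panel, similarity, snp_filter
from .genotype_io import (
    GenotypeMatrix,
    SampleMeta,
    control_pairs,
    read_sample_meta,
    read_vcf,
    write_vcf,
)

log = logging.getLogger("edvsnp")


def run_pipeline(
    vcf_path: str | Path,
    meta_path: str | Path,
    outdir: str | Path,
    filter_config: snp_filter.FilterConfig | None = None,
    putative_gs: float = 0.9,
    indisputable_gs: float | None = None,
    core_fraction: float = 0.20,
    membership_min: float = 0.8,
    rounding: str = "half_up",
    skip_core_snp: bool = False,
    pedigree: Sequence[tuple[str, str]] = (),
) -> dict:
    """Run every analysis stage and write reports under ``outdir``.

    When ``indisputable_gs`` is None the threshold is calibrated from the
    positive-control pairs in the metadata (an error if there are none).
    Returns the machine-readable run report, also written as
    ``report.json``.
    """
    t0 = time.time()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = filter_config or snp_filter.FilterConfig()

    matrix = read_vcf(vcf_path)
    metas = read_sample_meta(meta_path)
    meta_ids = {m.sample_id for m in metas}
    missing_meta = [s for s in matrix.sample_ids if s not in meta_ids]
    if missing_meta:
        raise ValueError(
            f"samples present in VCF but absent from metadata: {missing_meta}"
        )
    log.info("loaded %s and %d metadata rows", matrix, len(metas))

    # --- per-locus statistics ------------------------------------------
    stats = locus_stats.compute_locus_stats(matrix)
    locus_stats.write_stats_table(stats, outdir / "locus_stats.tsv")
    log.info("locus statistics written (%.1fs)", time.time() - t0)

    # --- core SNP selection --------------------------------------------
    if skip_core_snp:
        core_idx = np.arange(matrix.n_loci)
        candidates = core_idx
    else:
        candidates = snp_filter.filter_candidates(matrix, stats, cfg)
        core_idx = snp_filter.select_core(matrix, stats, cfg)
        snp_filter.core_table(matrix, stats, core_idx).to_csv(
            outdir / "core_snps.tsv", sep="\t", index=False, float_format="%.6g"
        )
        write_vcf(matrix.subset(loci=core_idx), outdir / "core_snps.vcf")
    core_matrix = matrix.subset(loci=core_idx)
    log.info(
        "core SNP selection: %d candidates, %d core (%.1fs)",
        len(candidates),
        len(core_idx),
        time.time() - t0,
    )

    # --- similarity and threshold calibration --------------------------
    sim = similarity.gs_matrix(core_matrix)
    controls = control_pairs(metas)
    control_results = [sim.pair(a, b) for a, b in controls]
    raw_min_control_gs = (
        min(c.gs for c in control_results) if control_results else None
    )
    if indisputable_gs is None:
        threshold = similarity.calibrate_threshold(control_results)
    else:
        threshold = indisputable_gs
    similarity.write_gs_matrix(sim, outdir / "gs_matrix.tsv")
    log.info("GS matrix over %d pairs (%.1fs)", sim.n_pairs, time.time() - t0)

    # --- EDV classification --------------------------------------------
    calls = similarity.classify_pairs(
        sim, metas, indisputable_threshold=threshold,
        putative_threshold=putative_gs,
    )
    similarity.write_pair_table(sim, calls, outdir / "gs_pairs.tsv")
    call_summary = similarity.summarize_calls(calls)

    # --- core varieties -------------------------------------------------
    cores = core_collection.select_core_varieties(
        core_matrix,
        metas,
        fraction=core_fraction,
        membership_min=membership_min,
        edv_calls=calls,
        pedigree=pedigree,
        rounding=rounding,
    )
    core_collection.core_table(cores).to_csv(
        outdir / "core_varieties.tsv", sep="\t", index=False
    )

    # --- identification panels ------------------------------------------
    pic_map = dict(zip(stats["locus_id"], stats["pic_allele"]))
    panel_all = panel.greedy_panel(core_matrix, pic=pic_map)
    panel.panel_table(panel_all).to_csv(
        outdir / "panel.tsv", sep="\t", index=False
    )
    non_edv = [
        s
        for s in core_matrix.sample_ids
        if s not in similarity.edv_sample_set(calls)
    ]
    panel_non_edv = None
    if len(non_edv) >= 2:
        panel_non_edv = panel.greedy_panel(
            core_matrix, pic=pic_map, samples=non_edv
        )
        panel.panel_table(panel_non_edv).to_csv(
            outdir / "panel_nonedv.tsv", sep="\t", index=False
        )
    cols = [core_matrix.locus_ids.index(i) for i in panel_all.selected]
    panel.fingerprint_table(core_matrix, cols).to_csv(
        outdir / "fingerprints.tsv", sep="\t"
    )
    log.info(
        "panels: %d loci (all), %s loci (non-EDV) (%.1fs)",
        panel_all.size,
        panel_non_edv.size if panel_non_edv else "n/a",
        time.time() - t0,
    )

    report = {
        "inputs": {"vcf": str(vcf_path), "meta": str(meta_path)},
        "config": {
            "filter": asdict(cfg),
            "putative_gs": putative_gs,
            "indisputable_gs": threshold,
            "indisputable_gs_calibrated": indisputable_gs is None,
            "raw_min_control_gs": raw_min_control_gs,
            "core_fraction": core_fraction,
            "membership_min": membership_min,
            "rounding": rounding,
            "skip_core_snp": skip_core_snp,
        },
        "counts": {
            "n_samples": matrix.n_samples,
            "n_loci": matrix.n_loci,
            "n_candidates": int(len(candidates)),
            "n_core_snps": int(len(core_idx)),
            "n_pairs": sim.n_pairs,
            "n_putative": call_summary["n_putative"],
            "n_indisputable": call_summary["n_indisputable"],
            "n_edv_samples": len(call_summary["edv_samples"]),
            "core_varieties_per_population": {
                str(c.population): len(c.selected) for c in cores
            },
            "panel_size": panel_all.size,
            "panel_size_non_edv": panel_non_edv.size if panel_non_edv else None,
        },
        "outputs": sorted(p.name for p in outdir.iterdir() if p.is_file()),
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    log.info("pipeline finished in %.1fs", time.time() - t0)
    return report
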