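"""End-to-end pipeline orchestration.

Chains the full analysis on a synthetic study (or user-supplied inputs):
simulate -> qc -> collapse -> discover -> quantify -> precision -> tissue ->
knockdown -> cross-species -> duplication scan -> report.  A single global
seed fans out to per-stage seeds by stable hashing of stage names, so any
stage reproduces its output independently of execution order.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import discover, dupscan, evolve, express, fold, sio, synthio

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed", "evaluate_calls"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    return (global_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineConfig:
    """Everything the pipeline needs; defaults define the built-in demo."""

    seed: int = 0
    outdir: str = "mirburst_out"
    sim: synthio.SimConfig | None = None
    # read processing
    min_copy: int = 3
    # discovery
    max_mismatch: int = 0
    max_hits: int = 5
    extension: int = 110
    n_shuffles: int = 30
    n_perm: int = 100
    target_sn: float = 10.0
    # expression
    tpm_cutoff: float = 10.0
    fdr: float = 0.05
    min_fold: float = 4.0
    # cross-species
    cross_max_mismatch: int = 2
    variant_trim: int = 3
    variant_min_af: float = 0.5
    variant_min_cov: float = 10.0
    # duplication
    evalue_max: float = 1e-5
    min_coverage: float = 0.5
    flank_window: int = 50_000
    flank_min_identity: float = 0.6

    def __post_init__(self):
        if self.sim is None:
            self.sim = synthio.SimConfig(seed=stage_seed(self.seed, "simulate"))


def evaluate_calls(calls, truth: synthio.TruthTable) -> dict:
    """Sensitivity and precision of discovery against planted truth.

    A call recovers a planted precursor when their loci overlap by at least
    half of the truth span.
    """
    truth_rows = list(truth.table.itertuples())
    recovered = set()
    n_true_calls = 0
    for c in calls:
        hit = False
        for row in truth_rows:
            if row.scaffold != c.scaffold:
                continue
            inter = min(row.end, c.end) - max(row.start, c.start)
            if inter >= 0.5 * (row.end - row.start):
                recovered.add(row.mirna_id)
                hit = True
        if hit:
            n_true_calls += 1
    sens = len(recovered) / len(truth_rows) if truth_rows else float("nan")
    prec = n_true_calls / len(calls) if calls else float("nan")
    return {
        "n_calls": len(calls),
        "n_truth": len(truth_rows),
        "n_recovered": len(recovered),
        "sensitivity": sens,
        "precision": prec,
    }


def discover_calls(genome, reads, config: PipelineConfig, references=None):
    """The sequencing-based discovery path on one collapsed read library.

    Returns (calls, candidates, sn_table, cutoff)."""
    mappings, _n_multi = discover.map_reads(
        genome, reads, max_mismatch=config.max_mismatch, max_hits=config.max_hits
    )
    if not mappings:
        return [], [], None, None
    cands = discover.excise_candidates(
        genome,
        mappings,
        extension=config.extension,
        n_shuffles=config.n_shuffles,
        seed=stage_seed(config.seed, "excise"),
    )
    cands = discover.dedupe_candidates(cands)
    if not cands:
        return [], [], None, None
    sn = discover.signal_to_noise(
        cands, n_perm=config.n_perm, seed=stage_seed(config.seed, "sn")
    )
    cutoff = discover.choose_cutoff(sn, target_sn=config.target_sn)
    if cutoff is None:
        kept = []
    else:
        kept = [c for c in cands if c.score.total >= cutoff]
    calls = discover.calls_from_candidates(kept, references)
    return calls, cands, sn, cutoff


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full demo pipeline and write the report bundle.

    Emits GFF3 calls, TSV tables per stage, and a machine-readable summary
    (counts per stage plus the headline statistics); returns the summary.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "stages": {}}
    cfg = config.sim

    # --- simulate -----------------------------------------------------
    genome, truth = synthio.generate_genome(cfg)
    expression = synthio.generate_expression(truth, cfg)
    raw_reads = synthio.generate_reads(genome, truth, cfg, expression)
    references = synthio.reference_matures(truth, genome)
    sio.write_fasta(genome, out / "genome.fa")
    truth.table.to_csv(out / "truth.tsv", sep="\t", index=False)
    summary["stages"]["simulate"] = {
        "n_scaffolds": len(genome),
        "n_planted": len(truth),
        "n_reads": len(raw_reads),
    }

    # --- qc + collapse ------------------------------------------------
    kept, qc_report = sio.filter_reads(raw_reads, adapter=cfg.adapter)
    collapsed = sio.collapse_reads(kept, min_copy=config.min_copy)
    pd.Series(qc_report).to_csv(out / "qc_report.tsv", sep="\t", header=False)
    summary["stages"]["qc"] = dict(qc_report)
    summary["stages"]["collapse"] = {"n_unique": len(collapsed)}

    # --- discovery ----------------------------------------------------
    calls, cands, sn, cutoff = discover_calls(genome, collapsed, config,
                                              references)
    homolog_calls = discover.homolog_scan(genome, references)
    calls, overlap_report = discover.merge_call_sets(calls, homolog_calls)
    calls, removal = discover.filter_annotations(calls, sio.AnnotationIntervals())
    sio.write_gff3(calls, out / "calls.gff3", genome)
    if sn is not None:
        sn.to_csv(out / "signal_to_noise.tsv", sep="\t", index=False)
    perf = evaluate_calls(calls, truth)
    summary["stages"]["discover"] = {
        "n_candidates": len(cands),
        "cutoff": cutoff,
        "n_calls": len(calls),
        "n_homology": len(homolog_calls),
        "annotation_removals": removal,
        **perf,
    }

    # --- quantify + precision -----------------------------------------
    mappings, _ = discover.map_reads(genome, collapsed,
                                     max_mismatch=config.max_mismatch,
                                     max_hits=config.max_hits)
    matrix = express.quantify(calls, {"pool": mappings})
    matrix.counts.to_csv(out / "counts.tsv", sep="\t")
    # processing precision is measured on all mapped reads (min_copy=1):
    # the copy-number floor preferentially discards jittered end variants
    # of lowly expressed miRNAs and would inflate the precision fractions
    all_collapsed = sio.collapse_reads(kept, min_copy=1)
    all_mappings, _ = discover.map_reads(genome, all_collapsed,
                                         max_mismatch=config.max_mismatch,
                                         max_hits=config.max_hits)
    records = []
    for call in calls:
        arm_maps = {"5p": [], "3p": []}
        for m in all_mappings:
            if m.scaffold != call.scaffold or m.strand != call.strand:
                continue
            for arm, span in (("5p", call.mature5), ("3p", call.mature3)):
                if span and abs(m.start - span[0]) <= 3:
                    arm_maps[arm].append(m)
        records.extend(express.end_precision(call, arm_maps))
    if records:
        pd.DataFrame([dataclasses.asdict(r) for r in records]).to_csv(
            out / "precision.tsv", sep="\t", index=False
        )
    mean_p5 = float(np.mean([r.p5 for r in records])) if records else float("nan")
    mean_p3 = float(np.mean([r.p3 for r in records])) if records else float("nan")
    summary["stages"]["precision"] = {
        "n_records": len(records), "mean_p5": mean_p5, "mean_p3": mean_p3,
    }

    # --- tissue specificity -------------------------------------------
    profiles = synthio.generate_tissue_profiles(truth, cfg)
    tmat = express.ExpressionMatrix(profiles.T.groupby(level=0).sum().T)
    tissue = express.tissue_specificity(tmat, fdr=config.fdr,
                                        min_fold=config.min_fold)
    tissue.to_csv(out / "tissue_flags.tsv", sep="\t", index=False)
    flagged = tissue[tissue.flag]
    truth_flags = {
        (r.mirna_id, r.tissue) for r in truth.table.itertuples() if r.tissue_specific
    }
    found_flags = {(r.mirna_id, r.tissue) for r in flagged.itertuples()}
    summary["stages"]["tissue"] = {
        "n_flagged": int(tissue.flag.sum()),
        "n_truth": len(truth_flags),
        "recovered": len(truth_flags & found_flags),
    }

    # --- knockdown ----------------------------------------------------
    base = synthio.make_class_counts(cfg)
    ctrl, kd = synthio.simulate_knockdown(base, cfg)
    kd_res = express.knockdown_analysis(ctrl, kd)
    kd_res["class_means"].to_csv(out / "knockdown_class_means.tsv", sep="\t")
    summary["stages"]["knockdown"] = {
        "class_means": {k: float(v) for k, v in kd_res["class_means"].items()},
        "mwu_p_vs_snoRNA": (
            kd_res["mwu_vs_mirna"]["snoRNA"].pvalue
            if kd_res["mwu_vs_mirna"].get("snoRNA")
            else None
        ),
    }

    # --- cross-species ------------------------------------------------
    sister_genome, truth_v = synthio.mutate_sister(genome, truth, cfg)
    sister_reads_raw = synthio.generate_reads(
        sister_genome, truth_v, cfg, expression, library="sister"
    )
    s_kept, _ = sio.filter_reads(sister_reads_raw, adapter=cfg.adapter)
    s_collapsed = sio.collapse_reads(s_kept, min_copy=config.min_copy)
    precursors = {c.id: c.sequence for c in calls}
    detected, pileups = evolve.cross_species_detect(
        precursors, s_collapsed, max_mismatch=config.cross_max_mismatch
    )
    variant_ids = set()
    n_var_calls = 0
    for c in calls:
        if c.id not in detected or c.mature5 is None:
            continue
        rel = (c.mature5[0] - c.start, c.mature5[1] - c.start)
        if c.strand == "-":
            rel = (c.end - c.mature5[1], c.end - c.mature5[0])
        vcalls = evolve.call_mature_variants(
            pileups[c.id], rel, trim=config.variant_trim,
            min_af=config.variant_min_af, min_cov=config.variant_min_cov,
        )
        if vcalls:
            variant_ids.add(c.id)
            n_var_calls += len(vcalls)
    class_labels = {c.id: c.class_label for c in calls}
    groups = express.expression_group(
        express.tpm(matrix).mean(axis=1), cutoff=config.tpm_cutoff
    ).to_dict()
    tables = evolve.variant_contingency(variant_ids, detected, class_labels,
                                        groups)
    chi2 = evolve.chi2_2x2(tables["class_vs_class"])
    summary["stages"]["evolve"] = {
        "n_detected": len(detected),
        "n_variant_mirnas": len(variant_ids),
        "n_variant_calls": n_var_calls,
        "chi2_stat": chi2.statistic,
        "chi2_p": chi2.pvalue,
    }

    # --- duplication scan ---------------------------------------------
    if len(precursors) >= 2:
        pairs = dupscan.allvsall_similarity(
            precursors, evalue_max=config.evalue_max,
            min_coverage=config.min_coverage,
        )
        families = dupscan.family_cluster(pairs, ids=list(precursors))
        fam_calls = [
            c for c in calls
            if any(len(f) > 1 and c.id in f for f in families)
        ]
        hits = dupscan.flank_scan(
            genome, fam_calls, window=config.flank_window,
            min_identity=config.flank_min_identity,
        )
        counts, dropped = dupscan.distance_histogram(hits)
        div = [dupscan.divergence_rate(h) for h in pairs]
        pd.DataFrame(
            {"bin_start": np.arange(len(counts)) * 5_000, "count": counts}
        ).to_csv(out / "duplication_distances.tsv", sep="\t", index=False)
        summary["stages"]["dupscan"] = {
            "n_similar_pairs": len(pairs),
            "n_families_multi": sum(1 for f in families if len(f) > 1),
            "n_flank_hits": len(hits),
            "distance_bins": [int(x) for x in counts],
            "dropped": dropped,
            "divergence_mean_pct": float(np.mean(div)) if div else None,
        }

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    return summary
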