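"""End-to-end orchestration: simulate -> classify -> link -> enrich ->
nucleosome profiling, with a deterministic run manifest.

Each stage reads only declared inputs and writes its outputs under the
run directory; the manifest records the seed, every threshold actually
applied, and a sha256 per output file, so two runs with identical
configuration produce byte-identical manifests.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import io
from .classify import classify_table, order_sites
from .config import RunConfig, TIMEPOINTS
from .enrichment import (assign_cohorts, cohort_enrichment,
                         percent_with_change, select_control_genes)
from .linkage import gene_change_flags, intersect_change_sets, \
    link_changes_to_genes, annotate_states
from .nucprofile import (aggregate_midpoint_profile, barrier_metrics,
                         compare_conditions, normalize_enrichment,
                         smooth_profile)
from .simulate import simulate_all

log = logging.getLogger("chronolink")

SIM_FILES = {
    "genes": "genes.bed",
    "gene_attrs": "gene_attrs.tsv",
    "expression": "expression.tsv",
    "sites": "sites.tsv",
    "segmentation": "segmentation.bed",
    "fragments": "fragments.bed",
    "fragments_depleted": "fragments_depleted.bed",
    "motifs": "motifs.bed",
}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v)
                for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def run_all(cfg: RunConfig) -> dict:
    """Run every stage; returns (and writes) the manifest."""
    outdir = io.ensure_dir(cfg.outdir)
    logging.basicConfig(level=getattr(logging, cfg.log_level, logging.INFO))
    outputs: dict[str, Path] = {}

    if cfg.input_dir is not None:
        indir = Path(cfg.input_dir)
        missing = [f for f in SIM_FILES.values()
                   if not (indir / f).is_file()]
        if missing:
            raise FileNotFoundError(
                f"simulation disabled but inputs missing from {indir}: "
                f"{missing}")

    # ---------------------------------------------------- simulate --
    try:
        if cfg.input_dir is None:
            data = simulate_all(cfg.sim)
            simdir = io.ensure_dir(outdir / "sim")
            io.write_genes(data.genes, simdir / "genes.bed",
                           simdir / "gene_attrs.tsv")
            io.write_timecourse(data.expression, simdir / "expression.tsv")
            io.write_timecourse(data.sites, simdir / "sites.tsv")
            io.write_segmentation(data.segmentation,
                                  simdir / "segmentation.bed")
            io.write_fragments(data.fragments, simdir / "fragments.bed")
            io.write_fragments(data.fragments_depleted,
                               simdir / "fragments_depleted.bed")
            io.write_bed(data.motifs, simdir / "motifs.bed")
            for key, fname in SIM_FILES.items():
                outputs[f"sim/{fname}"] = simdir / fname
            genes, expression, sites = data.genes, data.expression, data.sites
            segmentation = data.segmentation
            fragments, frag_depl = data.fragments, data.fragments_depleted
            motifs = data.motifs
        else:
            indir = Path(cfg.input_dir)
            genes = io.read_genes(indir / "genes.bed",
                                  indir / "gene_attrs.tsv")
            expression = io.read_expression_timecourse(
                indir / "expression.tsv")
            sites = io.read_site_timecourse(indir / "sites.tsv")
            segmentation = io.read_segmentation(indir / "segmentation.bed")
            fragments = io.read_fragments(indir / "fragments.bed")
            frag_depl = io.read_fragments(indir / "fragments_depleted.bed")
            motifs = io.read_bed(indir / "motifs.bed")
    except Exception as e:  # noqa: BLE001 - stage attribution
        raise StageError("simulate", e) from e

    # ---------------------------------------------------- classify --
    try:
        classified = {}
        for assay, sub in sites.groupby("assay", sort=True):
            thr = cfg.thresholds[assay]
            log.info("classify %s: fc_min=%g fdr_max=%g (n=%d)",
                     assay, thr.fc_min, thr.fdr_max, len(sub))
            cl = classify_table(sub.reset_index(drop=True), thr)
            classified[assay] = order_sites(cl)
        all_classified = pd.concat(classified.values(), ignore_index=True)
        io.write_classification(all_classified,
                                outdir / "classified_sites.bed")
        outputs["classified_sites.bed"] = outdir / "classified_sites.bed"
    except Exception as e:
        raise StageError("classify", e) from e

    # -------------------------------------------------------- link --
    try:
        changed = all_classified[all_classified["direction"] != "none"]
        links = link_changes_to_genes(genes, changed, cfg.windows)
        io.write_table(links, outdir / "linkage.tsv")
        outputs["linkage.tsv"] = outdir / "linkage.tsv"

        acc = classified.get("accessibility", pd.DataFrame())
        ep = classified.get("EP300", pd.DataFrame())
        acc_lost = acc[acc["direction"] == "lost"] if len(acc) else acc
        ep_lost = ep[ep["direction"] == "lost"] if len(ep) else ep
        if len(acc_lost) and len(ep_lost):
            _, _, both = intersect_change_sets(acc_lost, ep_lost)
            dual_ids = set(both["site_id"])
        else:
            dual_ids = set()
        keys = {
            "accessibility_lost": set(acc_lost["site_id"])
            if len(acc_lost) else set(),
            "ep300_lost": set(ep_lost["site_id"]) if len(ep_lost) else set(),
            "dual_lost": dual_ids,
        }
        # per-time decomposition of accessibility loss (stacked bars)
        if len(acc_lost):
            for t in TIMEPOINTS:
                keys[f"accessibility_lost_{t}h"] = set(
                    acc_lost.loc[acc_lost["first_change_time"] == t,
                                 "site_id"])
        flags = gene_change_flags(genes, links, keys, zone="enhancer")
        io.write_table(flags, outdir / "gene_change_flags.tsv")
        outputs["gene_change_flags.tsv"] = outdir / "gene_change_flags.tsv"

        if len(acc_lost):
            states = annotate_states(acc_lost, segmentation)
            io.write_table(states, outdir / "acc_lost_state_fractions.tsv")
            outputs["acc_lost_state_fractions.tsv"] = \
                outdir / "acc_lost_state_fractions.tsv"
    except Exception as e:
        raise StageError("link", e) from e

    # ------------------------------------------------------ enrich --
    try:
        expr = expression
        if "is_histone" in genes.columns and cfg.windows.exclude_histone_genes:
            keep = set(genes.loc[~genes["is_histone"], "gene_id"])
            expr = expression[expression["gene_id"].isin(keep)] \
                .reset_index(drop=True)
        cohorts = assign_cohorts(expr, cfg.scheme)
        control, complete = select_control_genes(expr, cfg.n_control_genes)
        if not complete:
            log.warning("only %d control candidates", len(control))
        io.write_table(cohorts, outdir / "cohorts.tsv")
        io.write_table(control, outdir / "control_genes.tsv")
        flags_expr = flags[flags["gene_id"].isin(set(expr["gene_id"]))] \
            .reset_index(drop=True)
        enr = pd.concat(
            [cohort_enrichment(cohorts, flags_expr, key, control=control)
             for key in ("accessibility_lost", "ep300_lost", "dual_lost")],
            ignore_index=True)
        io.write_table(enr, outdir / "enrichment.tsv")
        pct = percent_with_change(cohorts, flags_expr)
        io.write_table(pct, outdir / "percent_with_change.tsv")
        for f in ("cohorts.tsv", "control_genes.tsv", "enrichment.tsv",
                  "percent_with_change.tsv"):
            outputs[f] = outdir / f
    except Exception as e:
        raise StageError("enrich", e) from e

    # -------------------------------------------------- nucprofile --
    try:
        profiles = {}
        for label, frags in (("t0", fragments), ("depleted", frag_depl)):
            prof = aggregate_midpoint_profile(frags, motifs)
            prof = normalize_enrichment(prof)
            prof = smooth_profile(prof, cfg.smoothing_window)
            profiles[label] = prof
            io.write_profile(prof, outdir / f"profile_{label}.tsv")
            outputs[f"profile_{label}.tsv"] = outdir / f"profile_{label}.tsv"
        metrics = {label: barrier_metrics(p) for label, p in profiles.items()}
        mtab = pd.concat([m.to_frame().assign(condition=label)
                          for label, m in metrics.items()],
                         ignore_index=True)
        io.write_table(mtab, outdir / "barrier_metrics.tsv")
        comp = compare_conditions(profiles["t0"], profiles["depleted"],
                                  metrics=metrics["t0"])
        summary = pd.DataFrame([{
            "central_delta": comp.central_delta,
            "flank_amplitude_delta": comp.flank_amplitude_delta,
        }])
        io.write_table(summary, outdir / "condition_comparison.tsv")
        for f in ("barrier_metrics.tsv", "condition_comparison.tsv"):
            outputs[f] = outdir / f
    except Exception as e:
        raise StageError("nucprofile", e) from e

    manifest = {
        "seed": cfg.sim.seed,
        "config": _jsonable(cfg),
        "files": {name: _sha256(path)
                  for name, path in sorted(outputs.items())},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
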