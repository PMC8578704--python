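"""Synthetic degron time-course data with planted, recoverable structure.

The generator emulates the statistical shape of the tables an upstream
differential toolchain would produce for an acute-depletion time course
(2, 6, 18, 54, 162 h versus 0 h):

* gene models on one chromosome, each carrying a planted expression
  trajectory class (early/late x up/down, or stable);
* per-gene log2 fold changes and FDRs following a step-at-onset model;
* chromatin sites per assay (accessibility, EP300, H3K27ac, H3K27me3):
  sites *coupled* to changed genes inside the enhancer window, plus
  uncoupled background sites both stable and changed;
* nucleosome fragment midpoints around motif sites drawn from a central
  barrier component flanked by phased nucleosome components;
* a chromatin-state segmentation tiling the chromosome.

Every planted truth (class, onset, direction, coupled gene) is recorded so
downstream stages can be scored against it. All randomness flows through
an explicit :class:`numpy.random.Generator`.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ASSAYS, SimConfig, TIMEPOINTS, TRAJECTORY_CLASSES

EARLY_TIMES = (2, 6)
LATE_TIMES = (18, 54, 162)

#: Per-assay |log2FC| applied to changed sites (above every caller gate).
SITE_EFFECT = {
    "accessibility": 1.5,
    "EP300": 1.0,
    "H3K27ac": 1.2,
    "H3K27me3": 1.2,
}


class SimulationError(ValueError):
    pass


def _spaced_positions(rng: np.random.Generator, n: int, length: int,
                      spacing: int, margin: int = 0) -> np.ndarray:
    """n sorted positions in [margin, length - margin) with pairwise gaps
    >= spacing. Uses the standard slack construction: draw n uniform points
    in the length minus the reserved spacing, sort, then re-inflate."""
    if n == 0:
        return np.empty(0, dtype=np.int64)
    usable = length - 2 * margin
    slack = usable - (n - 1) * spacing
    if slack <= 0:
        raise SimulationError(
            f"cannot place {n} positions with spacing {spacing} "
            f"in {usable} bp")
    base = np.sort(rng.integers(0, slack, size=n))
    # enforce uniqueness of the slack draws so spacing is strict
    base += np.arange(n)  # tie-break; slack > 0 keeps range valid after clip
    base = np.minimum(base, slack - 1 + np.arange(n))
    return margin + base + np.arange(n, dtype=np.int64) * spacing


def simulate_genes(config: SimConfig,
                   rng: np.random.Generator) -> pd.DataFrame:
    """Gene models with unique, spaced TSSs and planted trajectory classes.

    Returns columns: gene_id, chrom, tss, strand, is_histone, planted_class.
    """
    n = config.n_genes
    cols = ["gene_id", "chrom", "tss", "strand", "is_histone", "planted_class"]
    if n == 0:
        return pd.DataFrame(columns=cols)
    tss = _spaced_positions(rng, n, config.chrom_length,
                            config.min_tss_spacing,
                            margin=config.enhancer_halfwidth)
    props = [config.trajectory_class_proportions.get(c, 0.0)
             for c in TRAJECTORY_CLASSES]
    classes = rng.choice(TRAJECTORY_CLASSES, size=n, p=props)
    strands = rng.choice(["+", "-"], size=n)
    is_histone = rng.random(n) < config.histone_gene_fraction
    # histone genes sit in dense clusters in real genomes and are excluded
    # from adjacency analyses; planting them as stable keeps the exclusion
    # orthogonal to the trajectory structure.
    classes = np.where(is_histone, "stable", classes)
    return pd.DataFrame({
        "gene_id": [f"g{i:05d}" for i in range(n)],
        "chrom": config.chrom,
        "tss": tss,
        "strand": strands,
        "is_histone": is_histone,
        "planted_class": classes,
    })


def _onset_for_class(rng: np.random.Generator, cls: np.ndarray) -> np.ndarray:
    """Planted onset hour per gene: early classes switch at 2 or 6 h with
    equal probability, late classes at 18/54/162 h uniformly; stable genes
    get +inf (never)."""
    onset = np.full(len(cls), np.inf)
    early = np.isin(cls, ["early_down", "early_up"])
    late = np.isin(cls, ["late_down", "late_up"])
    onset[early] = rng.choice(EARLY_TIMES, size=int(early.sum()))
    onset[late] = rng.choice(LATE_TIMES, size=int(late.sum()))
    return onset


def _changed_fdr(rng: np.random.Generator, size: int, center: float) -> np.ndarray:
    """Log-uniform jitter spanning two decades below to one above center."""
    lo, hi = np.log10(center) - 2.0, np.log10(center) + 1.0
    return 10.0 ** rng.uniform(lo, hi, size=size)


def _stable_fdr(rng: np.random.Generator, size: int, center: float) -> np.ndarray:
    """Null-comparison FDR jitter, skewed toward 1.

    BH-adjusted q-values of genuinely unchanged features pile up near the
    top of the unit interval; a sqrt-shaped draw scaled by ``center``
    reproduces that: for the default center 0.5 the range is [0.1, 1]
    with only ~1% of draws below 0.2."""
    u = np.sqrt(rng.random(size))
    return np.clip(center * (0.2 + 1.8 * u), 0.0, 1.0)


def simulate_expression_timecourse(genes: pd.DataFrame,
                                   config: SimConfig,
                                   rng: np.random.Generator) -> pd.DataFrame:
    """Per-gene log2FC and FDR at each time point under a step-at-onset model.

    log2fc(t) = class effect x 1[t >= onset] + N(0, expression_noise_sd);
    FDR is small (jittered around fdr_when_changed) from the onset onward
    and non-significant (jittered around fdr_when_stable) before it.
    Columns: gene_id, log2fc_<t>, fdr_<t>, planted_class, planted_onset.
    """
    if len(genes) == 0:
        raise SimulationError("genes table is empty")
    cls = genes["planted_class"].to_numpy()
    unknown = set(cls) - set(TRAJECTORY_CLASSES)
    if unknown:
        raise SimulationError(f"unknown trajectory classes: {sorted(unknown)}")
    n = len(genes)
    onset = _onset_for_class(rng, cls)
    effect = np.array([config.effect_size_log2fc.get(c, 0.0) for c in cls])
    out = {"gene_id": genes["gene_id"].to_numpy()}
    for t in TIMEPOINTS:
        active = t >= onset
        noise = (rng.normal(0.0, config.expression_noise_sd, size=n)
                 if config.expression_noise_sd > 0 else np.zeros(n))
        out[f"log2fc_{t}"] = np.where(active, effect, 0.0) + noise
        fdr = _stable_fdr(rng, n, config.fdr_when_stable)
        ch = _changed_fdr(rng, n, config.fdr_when_changed)
        out[f"fdr_{t}"] = np.where(active, ch, fdr)
    out["planted_class"] = cls
    out["planted_onset"] = onset
    return pd.DataFrame(out)


def _site_timecourse_block(rng: np.random.Generator, assay: str,
                           direction: np.ndarray, onset: np.ndarray,
                           config: SimConfig) -> dict[str, np.ndarray]:
    """Shared synthesis of log2fc_<t>/fdr_<t> columns for a site block.

    direction: +1 gained, -1 lost, 0 stable; onset: hour or +inf."""
    n = len(direction)
    effect = SITE_EFFECT[assay] * direction
    cols: dict[str, np.ndarray] = {}
    for t in TIMEPOINTS:
        active = (t >= onset) & (direction != 0)
        noise = (rng.normal(0.0, config.site_noise_sd, size=n)
                 if config.site_noise_sd > 0 else np.zeros(n))
        cols[f"log2fc_{t}"] = np.where(active, effect, 0.0) + noise
        fdr = _stable_fdr(rng, n, config.fdr_when_stable)
        ch = _changed_fdr(rng, n, config.fdr_when_changed)
        cols[f"fdr_{t}"] = np.where(active, ch, fdr)
    return cols


@dataclass
class _SiteBlock:
    assay: str
    center: np.ndarray
    direction: np.ndarray
    onset: np.ndarray
    kind: str
    gene: np.ndarray  # coupled gene_id or ""


def _enhancer_offsets(rng: np.random.Generator, n: int,
                      config: SimConfig) -> np.ndarray:
    """Uniform offsets within the enhancer window, outside the promoter."""
    span = config.enhancer_halfwidth - config.promoter_halfwidth
    mag = rng.integers(config.promoter_halfwidth + config.site_halfwidth,
                       config.enhancer_halfwidth - config.site_halfwidth,
                       size=n) if span > 2 * config.site_halfwidth else \
        np.full(n, config.promoter_halfwidth + config.site_halfwidth)
    sign = rng.choice([-1, 1], size=n)
    return mag * sign


def simulate_site_timecourses(genes: pd.DataFrame, config: SimConfig,
                              rng: np.random.Generator,
                              expression: pd.DataFrame | None = None
                              ) -> pd.DataFrame:
    """Chromatin-site time courses per assay with planted coupling.

    Coupled sites: a ``linked_site_rate`` fraction of changed genes get one
    site placed uniformly in their enhancer window (within the +/-50 kb
    window but outside +/-500 bp of the TSS). Down-regulated genes lose
    accessibility there at the gene's onset; for early-down genes a
    ``dual_loss_fraction`` of those sites additionally lose EP300 (the
    rapid, direct signature). Up-regulated genes gain EP300 and H3K27ac
    near the promoter. Background sites (stable per assay, plus changed
    sites uncoupled to any gene at per-kind rates per Mb) cover the rest
    of the chromosome.

    Returns one row per (site, assay) with columns chrom/start/end/site_id/
    assay, log2fc_<t>, fdr_<t>, and planted truth columns planted_kind,
    planted_direction, planted_time, planted_gene.
    """
    if expression is not None:
        onset_by_gene = dict(zip(expression["gene_id"],
                                 expression["planted_onset"]))
    else:
        onset_by_gene = {}
    blocks: list[_SiteBlock] = []

    if len(genes):
        changed = genes[genes["planted_class"] != "stable"]
        if len(changed):
            linked = rng.random(len(changed)) < config.linked_site_rate
            sel = changed[linked]
            if len(sel):
                cls = sel["planted_class"].to_numpy()
                tss = sel["tss"].to_numpy()
                gid = sel["gene_id"].to_numpy()
                if onset_by_gene:
                    onset = np.array([onset_by_gene[g] for g in gid])
                else:
                    onset = _onset_for_class(rng, cls)
                down = np.isin(cls, ["early_down", "late_down"])
                # down genes: lost-accessibility site in the enhancer window
                d_tss, d_onset, d_gid = tss[down], onset[down], gid[down]
                d_cls = cls[down]
                centers = d_tss + _enhancer_offsets(rng, len(d_tss), config)
                dual = (d_cls == "early_down") & \
                    (rng.random(len(d_tss)) < config.dual_loss_fraction)
                kind = np.where(dual, "coupled_dual", "coupled_acc")
                for k in ("coupled_dual", "coupled_acc"):
                    m = kind == k
                    if m.any():
                        blocks.append(_SiteBlock(
                            "accessibility", centers[m], -np.ones(m.sum()),
                            d_onset[m], k, d_gid[m]))
                if dual.any():
                    blocks.append(_SiteBlock(
                        "EP300", centers[dual], -np.ones(int(dual.sum())),
                        d_onset[dual], "coupled_dual", d_gid[dual]))
                # up genes: gained EP300 + H3K27ac near the promoter
                up = ~down
                u_tss, u_onset, u_gid = tss[up], onset[up], gid[up]
                u_centers = u_tss + rng.integers(-2000, 2001, size=len(u_tss))
                for assay in ("EP300", "H3K27ac"):
                    if len(u_centers):
                        blocks.append(_SiteBlock(
                            assay, u_centers.copy(), np.ones(len(u_centers)),
                            u_onset, "coupled_promoter_gain", u_gid))

    # background: stable sites per assay
    mb = config.chrom_length / 1e6
    lo = config.site_halfwidth
    hi = config.chrom_length - config.site_halfwidth
    for assay in ASSAYS:
        n_bg = rng.poisson(config.background_site_rate * mb)
        if n_bg:
            centers = rng.integers(lo, hi, size=n_bg)
            blocks.append(_SiteBlock(
                assay, centers, np.zeros(n_bg), np.full(n_bg, np.inf),
                "bg_stable", np.full(n_bg, "", dtype=object)))
    # background: changed sites uncoupled to genes
    bg_spec = {
        "accessibility_lost": [("accessibility", -1)],
        "accessibility_gained": [("accessibility", +1)],
        "ep300_lost": [("EP300", -1)],
        "h3k27ac_lost": [("H3K27ac", -1)],
        "dual_lost": [("accessibility", -1), ("EP300", -1)],
    }
    for kind, rate in config.background_change_rate.items():
        if kind not in bg_spec:
            raise SimulationError(f"unknown background change kind {kind!r}")
        n_bg = rng.poisson(rate * mb)
        if not n_bg:
            continue
        centers = rng.integers(lo, hi, size=n_bg)
        onsets = rng.choice(TIMEPOINTS, size=n_bg).astype(float)
        for assay, sign in bg_spec[kind]:
            blocks.append(_SiteBlock(
                assay, centers.copy(), float(sign) * np.ones(n_bg),
                onsets, f"bg_{kind}", np.full(n_bg, "", dtype=object)))

    if not blocks:
        base = ["chrom", "start", "end", "site_id", "assay"]
        tc = [f"{p}_{t}" for t in TIMEPOINTS for p in ("log2fc", "fdr")]
        truth = ["planted_kind", "planted_direction", "planted_time",
                 "planted_gene"]
        return pd.DataFrame(columns=base + tc + truth)

    frames = []
    for b in blocks:
        cols: dict = {
            "chrom": config.chrom,
            "start": b.center - config.site_halfwidth,
            "end": b.center + config.site_halfwidth,
            "assay": b.assay,
        }
        cols.update(_site_timecourse_block(rng, b.assay, b.direction,
                                           b.onset, config))
        dirlab = np.where(b.direction < 0, "lost",
                          np.where(b.direction > 0, "gained", "none"))
        cols["planted_kind"] = b.kind
        cols["planted_direction"] = dirlab
        cols["planted_time"] = np.where(np.isfinite(b.onset),
                                        b.onset, -1).astype(int)
        cols["planted_gene"] = b.gene
        frames.append(pd.DataFrame(cols))
    sites = pd.concat(frames, ignore_index=True)
    sites = sites.sort_values(["chrom", "start", "end", "assay"],
                              kind="mergesort").reset_index(drop=True)
    sites.insert(3, "site_id", [f"s{i:06d}" for i in range(len(sites))])
    return sites


def simulate_state_segmentation(config: SimConfig,
                                rng: np.random.Generator) -> pd.DataFrame:
    """Contiguous chromatin-state segmentation covering the chromosome.

    Segment lengths are exponential with mean ``state_mean_length``;
    labels are drawn i.i.d. from ``state_weights``. Columns:
    chrom, start, end, state (0-based half-open, gap-free tiling).
    """
    L = config.chrom_length
    labels = np.asarray(config.state_labels)
    w = np.asarray(config.state_weights, dtype=float)
    w = w / w.sum()
    if len(labels) == 1:
        return pd.DataFrame({"chrom": [config.chrom], "start": [0],
                             "end": [L], "state": [labels[0]]})
    # draw in batches until the tiling covers the chromosome
    bounds: list[np.ndarray] = []
    total = 0
    while total < L:
        n = max(16, int(1.5 * (L - total) / config.state_mean_length))
        lens = np.maximum(1, rng.exponential(
            config.state_mean_length, size=n).astype(np.int64))
        bounds.append(lens)
        total += int(lens.sum())
    lens = np.concatenate(bounds)
    ends = np.cumsum(lens)
    keep = np.searchsorted(ends, L, side="left") + 1
    lens = lens[:keep]
    ends = np.minimum(ends[:keep], L)
    starts = ends - lens
    starts[0] = 0
    starts[1:] = ends[:-1]
    states = rng.choice(labels, size=keep, p=w)
    return pd.DataFrame({"chrom": config.chrom, "start": starts,
                         "end": ends, "state": states})


def depleted_variant(config: SimConfig) -> SimConfig:
    """Condition emulating the remodeller-depleted state: more reads over
    the factor binding site (central weight up) and degraded flank
    phasing (flank sd doubled)."""
    return config.replace(central_weight=min(1.0, config.central_weight + 0.20),
                          flank_sd=2.0 * config.flank_sd)


def simulate_nucleosome_fragments(config: SimConfig, rng: np.random.Generator,
                                  motifs: pd.DataFrame | None = None
                                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Nucleosome-protected fragments around motif sites.

    Fragment midpoints at each of ``nuc_sites`` motifs follow a mixture:
    a central component N(0, central_sd^2) with weight ``central_weight``
    and flanking components at +/-(d0 + k * nucleosome_repeat), k = 0..2,
    with sd ``flank_sd`` and per-k weights ``flank_decay`` (split evenly
    between sides). Read depth per site is Poisson(nuc_reads_per_site).

    Returns ``(fragments, motifs)``: fragments carry chrom/start/end plus
    the motif id and the signed offset of the midpoint from the motif
    center (strand-mirrored for minus-strand motifs); motifs are BED6-like
    with the center at the interval midpoint. An existing ``motifs`` table
    may be supplied so paired conditions share one motif set.
    """
    frag_cols = ["chrom", "start", "end", "motif_id", "offset"]
    motif_cols = ["chrom", "start", "end", "name", "score", "strand"]
    if motifs is not None:
        centers = ((motifs["start"].to_numpy()
                    + motifs["end"].to_numpy()) // 2).astype(np.int64)
        strands = motifs["strand"].to_numpy()
        n_sites = len(motifs)
    else:
        n_sites = config.nuc_sites
        if n_sites == 0:
            return (pd.DataFrame(columns=frag_cols),
                    pd.DataFrame(columns=motif_cols))
        centers = _spaced_positions(rng, n_sites, config.chrom_length,
                                    spacing=5000, margin=2000)
        strands = rng.choice(["+", "-"], size=n_sites)
    if n_sites == 0:
        return (pd.DataFrame(columns=frag_cols),
                pd.DataFrame(columns=motif_cols))
    d0 = config.effective_flank_distance
    mus = [0.0]
    sds = [config.central_sd]
    weights = [config.central_weight]
    flank_total = 1.0 - config.central_weight
    decay = np.asarray(config.flank_decay, dtype=float)
    decay = decay / decay.sum()
    for sign in (-1, 1):
        for k, dk in enumerate(decay):
            mus.append(sign * (d0 + k * config.nucleosome_repeat))
            sds.append(config.flank_sd)
            weights.append(flank_total / 2.0 * dk)
    mus_a = np.asarray(mus)
    sds_a = np.asarray(sds)
    w = np.asarray(weights)
    w = w / w.sum()

    depths = rng.poisson(config.nuc_reads_per_site, size=n_sites)
    total = int(depths.sum())
    comp = rng.choice(len(w), size=total, p=w)
    offsets = rng.normal(mus_a[comp], sds_a[comp])
    offsets = np.rint(offsets).astype(np.int64)
    site_idx = np.repeat(np.arange(n_sites), depths)
    # minus-strand motifs: the drawn offset is in motif orientation; the
    # genomic offset is mirrored.
    genomic_off = np.where(strands[site_idx] == "-", -offsets, offsets)
    mid = centers[site_idx] + genomic_off
    half = config.fragment_length // 2
    start = mid - half
    end = mid + (config.fragment_length - half)
    keep = (start >= 0) & (end <= config.chrom_length)
    fragments = pd.DataFrame({
        "chrom": config.chrom,
        "start": start[keep],
        "end": end[keep],
        "motif_id": np.char.add("m", site_idx[keep].astype(str)),
        "offset": offsets[keep],
    })
    if motifs is None:
        motifs = pd.DataFrame({
            "chrom": config.chrom,
            "start": centers - 10,
            "end": centers + 10,
            "name": [f"m{i}" for i in range(n_sites)],
            "score": 0,
            "strand": strands,
        })
    return fragments, motifs


@dataclass
class SimulatedData:
    """Bundle of all generator outputs for one seeded run."""

    config: SimConfig
    genes: pd.DataFrame
    expression: pd.DataFrame
    sites: pd.DataFrame
    segmentation: pd.DataFrame
    fragments: pd.DataFrame
    motifs: pd.DataFrame
    fragments_depleted: pd.DataFrame


def simulate_all(config: SimConfig) -> SimulatedData:
    """Run every generator stage from the single seed in ``config``.

    Stages consume independent child streams of one SeedSequence, so any
    stage is reproducible in isolation and the bundle is byte-identical
    across runs with the same config.
    """
    streams = np.random.SeedSequence(config.seed).spawn(6)
    rngs = [np.random.default_rng(s) for s in streams]
    genes = simulate_genes(config, rngs[0])
    expression = simulate_expression_timecourse(genes, config, rngs[1])
    sites = simulate_site_timecourses(genes, config, rngs[2],
                                      expression=expression)
    segmentation = simulate_state_segmentation(config, rngs[3])
    fragments, motifs = simulate_nucleosome_fragments(config, rngs[4])
    frag_depl, _ = simulate_nucleosome_fragments(
        depleted_variant(config), rngs[5], motifs=motifs)
    return SimulatedData(config, genes, expression, sites, segmentation,
                         fragments, motifs, frag_depl)
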