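"""Configuration objects for the simulation and analysis stages.

Every load-bearing constant of the analysis (differential thresholds,
window extents, control-set size, smoothing width, the expression time
grid) is named here with its default, so a run is fully auditable from
its config alone.
"""
from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping

import yaml

#: Hours after depletion at which differential calls versus 0 h exist.
TIMEPOINTS: tuple[int, ...] = (2, 6, 18, 54, 162)

#: Expression trajectory classes planted by the generator.
TRAJECTORY_CLASSES: tuple[str, ...] = (
    "early_down", "early_up", "late_down", "late_up", "stable"
)

ASSAYS: tuple[str, ...] = ("accessibility", "EP300", "H3K27ac", "H3K27me3")


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic degron time-course generator.

    Defaults define the study conditions the pipeline is exercised under:
    a 200 Mb chromosome carrying 2,000 genes whose expression trajectories
    fall into five classes, chromatin sites coupled to changed genes within
    the enhancer window, uncoupled background sites (stable and changed),
    and nucleosome-fragment midpoints around motif sites drawn from a
    central-barrier + phased-flank mixture.
    """

    seed: int = 0
    chrom: str = "chrSim"
    chrom_length: int = 200_000_000
    n_genes: int = 2000
    min_tss_spacing: int = 20_000
    histone_gene_fraction: float = 0.02
    trajectory_class_proportions: Mapping[str, float] = field(
        default_factory=lambda: {
            "early_down": 0.04,
            "early_up": 0.16,
            "late_down": 0.02,
            "late_up": 0.13,
            "stable": 0.65,
        }
    )
    effect_size_log2fc: Mapping[str, float] = field(
        default_factory=lambda: {
            "early_down": -2.0,
            "early_up": 2.0,
            "late_down": -1.5,
            "late_up": 1.5,
            "stable": 0.0,
        }
    )
    expression_noise_sd: float = 0.2
    site_noise_sd: float = 0.15
    fdr_when_changed: float = 1e-7
    fdr_when_stable: float = 0.5
    # Site coupling
    linked_site_rate: float = 0.8
    dual_loss_fraction: float = 0.5
    background_site_rate: float = 20.0  # stable sites per Mb, per assay
    background_change_rate: Mapping[str, float] = field(
        default_factory=lambda: {
            "accessibility_lost": 7.0,
            "accessibility_gained": 2.0,
            "ep300_lost": 7.0,
            "dual_lost": 0.8,
            "h3k27ac_lost": 3.0,
        }
    )
    site_halfwidth: int = 200
    promoter_halfwidth: int = 500
    enhancer_halfwidth: int = 50_000
    # Nucleosome-fragment mixture
    nuc_sites: int = 200
    nuc_reads_per_site: float = 400.0
    central_sd: float = 35.0
    central_weight: float = 0.25
    flank_distance_d0: float | None = None  # derived from central_sd if None
    flank_sd: float = 30.0
    nucleosome_repeat: float = 186.0
    flank_decay: tuple[float, ...] = (0.5, 0.3, 0.2)  # weights over k=0..2
    fragment_length: int = 147
    # Chromatin-state segmentation
    state_labels: tuple[str, ...] = (
        "promoter", "enhancer", "bivalent", "transcribed", "heterochromatin"
    )
    state_weights: tuple[float, ...] = (0.05, 0.10, 0.05, 0.30, 0.50)
    state_mean_length: float = 20_000.0

    def __post_init__(self) -> None:
        _check(self.chrom_length > 0, "chrom_length must be > 0")
        _check(self.n_genes >= 0, "n_genes must be >= 0")
        _check(self.min_tss_spacing > 0, "min_tss_spacing must be > 0")
        _check(0.0 <= self.histone_gene_fraction <= 1.0,
               "histone_gene_fraction must be in [0, 1]")
        props = dict(self.trajectory_class_proportions)
        unknown = set(props) - set(TRAJECTORY_CLASSES)
        _check(not unknown, f"unknown trajectory classes: {sorted(unknown)}")
        _check(all(0.0 <= p <= 1.0 for p in props.values()),
               "class proportions must be in [0, 1]")
        _check(math.isclose(sum(props.values()), 1.0, abs_tol=1e-9),
               "trajectory_class_proportions must sum to 1 within 1e-9")
        for name in ("linked_site_rate", "dual_loss_fraction"):
            v = getattr(self, name)
            _check(0.0 <= v <= 1.0, f"{name} must be in [0, 1]")
        _check(self.background_site_rate >= 0, "background_site_rate < 0")
        _check(all(r >= 0 for r in self.background_change_rate.values()),
               "background change rates must be >= 0")
        for name in ("site_halfwidth", "promoter_halfwidth",
                     "enhancer_halfwidth"):
            _check(getattr(self, name) > 0, f"{name} must be > 0")
        _check(self.nuc_sites >= 0, "nuc_sites must be >= 0")
        _check(self.nuc_reads_per_site >= 0, "nuc_reads_per_site must be >= 0")
        for name in ("central_sd", "flank_sd", "nucleosome_repeat"):
            _check(getattr(self, name) > 0, f"{name} must be > 0")
        if self.flank_distance_d0 is not None:
            _check(self.flank_distance_d0 > 0, "flank_distance_d0 must be > 0")
        _check(0.0 <= self.central_weight <= 1.0,
               "central_weight must be in [0, 1]")
        _check(len(self.state_labels) == len(self.state_weights)
               and len(self.state_labels) > 0,
               "state_labels and state_weights must align and be non-empty")
        _check(self.state_mean_length > 0, "state_mean_length must be > 0")
        _check(not math.isclose(sum(self.state_weights), 0.0),
               "state_weights must not all be zero")

    @property
    def effective_flank_distance(self) -> float:
        """Planted distance from motif center to first flanking dyad.

        When not set explicitly, the flank distance follows the barrier
        model: half-width at half maximum of the central distribution
        (``central_sd * sqrt(2 ln 2)``) plus half a nucleosome and a short
        linker (138.8 bp), i.e. 180 bp at the default 35 bp central sd.
        Wider barriers therefore push flanking nucleosomes farther out.
        """
        if self.flank_distance_d0 is not None:
            return float(self.flank_distance_d0)
        return 1.1774 * self.central_sd + 138.8

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class ThresholdConfig:
    """Differential-call gate for one assay.

    ``fc_min`` is a *linear* fold change; a site qualifies at time t when
    |log2fc(t)| > log2(fc_min) and fdr(t) < fdr_max. Defaults follow the
    upstream callers: fold change > 1.5 with FDR < 1e-5 for accessibility
    and histone marks; fold change > 1.2 with FDR < 0.2 for EP300.
    """

    fc_min: float = 1.5
    fdr_max: float = 1e-5

    def __post_init__(self) -> None:
        _check(self.fc_min > 1.0, "fc_min must be > 1")
        _check(0.0 < self.fdr_max <= 1.0, "fdr_max must be in (0, 1]")

    @property
    def log2fc_min(self) -> float:
        return math.log2(self.fc_min)


DEFAULT_THRESHOLDS: dict[str, ThresholdConfig] = {
    "accessibility": ThresholdConfig(fc_min=1.5, fdr_max=1e-5),
    "EP300": ThresholdConfig(fc_min=1.2, fdr_max=0.2),
    "H3K27ac": ThresholdConfig(fc_min=1.5, fdr_max=1e-5),
    "H3K27me3": ThresholdConfig(fc_min=1.5, fdr_max=1e-5),
}


@dataclass(frozen=True)
class WindowConfig:
    """Promoter/enhancer window extents around each TSS.

    Promoter: [TSS - promoter_halfwidth, TSS + promoter_halfwidth).
    Enhancer: [TSS - enhancer_halfwidth, TSS + enhancer_halfwidth)
    excluding the promoter. Windows are TSS-centred and symmetric, so
    strand does not alter extents.
    """

    promoter_halfwidth: int = 500
    enhancer_halfwidth: int = 50_000
    exclude_histone_genes: bool = True

    def __post_init__(self) -> None:
        _check(0 < self.promoter_halfwidth < self.enhancer_halfwidth,
               "need 0 < promoter_halfwidth < enhancer_halfwidth")


@dataclass(frozen=True)
class RunConfig:
    """Top-level configuration for an end-to-end pipeline run."""

    sim: SimConfig = field(default_factory=SimConfig)
    thresholds: Mapping[str, ThresholdConfig] = field(
        default_factory=lambda: dict(DEFAULT_THRESHOLDS)
    )
    windows: WindowConfig = field(default_factory=WindowConfig)
    scheme: str = "early_late"
    n_control_genes: int = 500
    smoothing_window: int = 30
    outdir: str = "results/run"
    log_level: str = "INFO"
    #: when set, simulation is skipped and inputs are read from this
    #: directory (same file layout the simulate stage writes)
    input_dir: str | None = None

    def __post_init__(self) -> None:
        _check(self.scheme in ("early_late", "first_change"),
               f"unknown scheme {self.scheme!r}")
        _check(self.n_control_genes > 0, "n_control_genes must be > 0")
        _check(self.smoothing_window >= 1, "smoothing_window must be >= 1")


def _dataclass_from_mapping(cls, data: Mapping):
    if not isinstance(data, Mapping):
        raise ConfigError(f"expected a mapping for {cls.__name__}, got {data!r}")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(
            f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kw = dict(data)
    for key in ("flank_decay", "state_labels", "state_weights"):
        if key in kw and isinstance(kw[key], list):
            kw[key] = tuple(kw[key])
    return cls(**kw)


def load_run_config(path) -> RunConfig:
    """Read a YAML run configuration.

    Top-level keys mirror :class:`RunConfig`; ``sim``, ``windows`` and
    ``thresholds`` (a mapping assay -> {fc_min, fdr_max}) are nested.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("run config must be a YAML mapping")
    kw: dict = {}
    if "sim" in raw:
        kw["sim"] = _dataclass_from_mapping(SimConfig, raw.pop("sim"))
    if "windows" in raw:
        kw["windows"] = _dataclass_from_mapping(WindowConfig, raw.pop("windows"))
    if "thresholds" in raw:
        thr = raw.pop("thresholds")
        if not isinstance(thr, Mapping):
            raise ConfigError("thresholds must map assay -> {fc_min, fdr_max}")
        merged = dict(DEFAULT_THRESHOLDS)
        for assay, sub in thr.items():
            merged[assay] = _dataclass_from_mapping(ThresholdConfig, sub)
        kw["thresholds"] = merged
    names = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - names
    if unknown:
        raise ConfigError(f"unknown run-config keys: {sorted(unknown)}")
    kw.update(raw)
    return RunConfig(**kw)
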