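"""Fragment-midpoint metaprofiles and barrier-nucleosome metrics.

The midpoints (dyad proxies) of nucleosome-protected fragments are summed
per base pair across a 2 kb window centred on each transcription-factor
motif, normalised by the number of motif sites and the experiment-wide
read count, and smoothed with a 30 bp moving average. From the smoothed
profile two metrics are extracted per side of the motif:

* w — half-width of the central dyad distribution: the offset at which
  the profile first drops below half of the central maximum (the maximum
  within +/-100 bp of the motif centre);
* d — distance from the motif centre to the adjacent nucleosome: the
  first local maximum beyond w plus a 20 bp guard.

The published figures define what d and w denote but not how they are
measured; half-maximum width and first flanking local maximum are the
operational definitions here, with per-side values exposed alongside the
two-side means so alternative readings can be compared. w is a per-side
half-width (the barrier spans roughly +/-w), not a full width.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

HALFWIDTH_DEFAULT = 1000
CENTRAL_SEARCH = 100  # bp around 0 in which the central maximum is sought
FLANK_GUARD = 20  # bp beyond w before flank peak detection starts


@dataclass
class NucleosomeProfile:
    """Per-base midpoint profile over offsets -halfwidth..+halfwidth.

    ``raw_counts`` are never smoothed in place; normalisation fills
    ``enrichment`` and smoothing fills ``smoothed`` as separate vectors,
    so every downstream step can choose its basis.
    """

    offsets: np.ndarray
    raw_counts: np.ndarray
    n_sites: int
    total_reads: int
    enrichment: np.ndarray | None = None
    smoothed: np.ndarray | None = None
    smoothing_window: int | None = None

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets)
        self.raw_counts = np.asarray(self.raw_counts, dtype=float)
        if self.offsets.shape != self.raw_counts.shape:
            raise ValueError("offsets and raw_counts must align")

    @property
    def halfwidth(self) -> int:
        return int(self.offsets[-1])

    def base_values(self) -> np.ndarray:
        """Unsmoothed basis: enrichment when normalised, else raw."""
        return self.raw_counts if self.enrichment is None else self.enrichment

    def values(self) -> np.ndarray:
        """Most processed vector: smoothed, else enrichment, else raw."""
        return self.base_values() if self.smoothed is None else self.smoothed

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"offset": self.offsets, "raw": self.raw_counts})
        if self.enrichment is not None:
            df["enrichment"] = self.enrichment
        if self.smoothed is not None:
            df["smoothed"] = self.smoothed
        return df


def fragment_midpoints(fragments: pd.DataFrame) -> np.ndarray:
    """Midpoint of each fragment; even-length fragments round down."""
    return (fragments["start"].to_numpy(dtype=np.int64)
            + fragments["end"].to_numpy(dtype=np.int64)) // 2


def aggregate_midpoint_profile(fragments: pd.DataFrame,
                               motif_sites: pd.DataFrame,
                               halfwidth: int = HALFWIDTH_DEFAULT,
                               total_reads: int | None = None,
                               bound_sites: pd.DataFrame | None = None
                               ) -> NucleosomeProfile:
    """Sum fragment midpoints per base across the window at every motif.

    Motif centre = floor of the interval midpoint; minus-strand motifs
    mirror offsets. When ``bound_sites`` intervals are given, motifs are
    restricted to those overlapping them (factor-bound subset).
    ``total_reads`` defaults to the number of fragments supplied, standing
    in for the experiment-wide read count.
    """
    if len(motif_sites) == 0:
        raise ValueError("empty motif set")
    motifs = motif_sites
    if bound_sites is not None:
        motifs = _overlapping_subset(motifs, bound_sites)
        if len(motifs) == 0:
            raise ValueError("no motifs overlap the bound-site list")
    mids = fragment_midpoints(fragments)
    order = np.argsort(mids, kind="mergesort")
    mids_sorted = mids[order]
    frag_chrom = fragments["chrom"].to_numpy()[order]
    counts = np.zeros(2 * halfwidth + 1, dtype=float)
    centers = (motifs["start"].to_numpy(dtype=np.int64)
               + motifs["end"].to_numpy(dtype=np.int64)) // 2
    strands = (motifs["strand"].to_numpy() if "strand" in motifs.columns
               else np.full(len(motifs), "+"))
    chroms = motifs["chrom"].to_numpy()
    for chrom in np.unique(chroms):
        cmask = frag_chrom == chrom
        cm = mids_sorted[cmask]
        for center, strand in zip(centers[chroms == chrom],
                                  strands[chroms == chrom]):
            lo = np.searchsorted(cm, center - halfwidth, side="left")
            hi = np.searchsorted(cm, center + halfwidth, side="right")
            off = cm[lo:hi] - center
            if strand == "-":
                off = -off
            counts += np.bincount(off + halfwidth,
                                  minlength=2 * halfwidth + 1)
    return NucleosomeProfile(
        offsets=np.arange(-halfwidth, halfwidth + 1),
        raw_counts=counts,
        n_sites=len(motifs),
        total_reads=int(total_reads) if total_reads is not None
        else len(fragments),
    )


def _overlapping_subset(motifs: pd.DataFrame,
                        bound: pd.DataFrame) -> pd.DataFrame:
    from .linkage import _site_trees
    trees = _site_trees(bound)
    keep = []
    for row in motifs.itertuples():
        t = trees.get(row.chrom)
        keep.append(t is not None and t.overlaps(row.start, row.end))
    return motifs[np.asarray(keep, dtype=bool)]


def normalize_enrichment(profile: NucleosomeProfile) -> NucleosomeProfile:
    """Per-base enrichment = count / (n_sites x experiment-wide reads)."""
    if profile.n_sites <= 0 or profile.total_reads <= 0:
        raise ValueError("need n_sites > 0 and total_reads > 0")
    enr = profile.raw_counts / (profile.n_sites * profile.total_reads)
    return NucleosomeProfile(profile.offsets, profile.raw_counts,
                             profile.n_sites, profile.total_reads,
                             enrichment=enr)


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centred moving mean; at the edges the window shrinks to the
    available offsets. For even windows the extra position sits on the
    left (window [i - w//2, i + w//2 - 1])."""
    if window < 1 or window > len(x):
        raise ValueError(f"window {window} outside [1, {len(x)}]")
    left = window // 2
    right = window - left - 1
    csum = np.concatenate([[0.0], np.cumsum(x, dtype=float)])
    n = len(x)
    idx = np.arange(n)
    lo = np.maximum(idx - left, 0)
    hi = np.minimum(idx + right, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi + 1 - lo)


def smooth_profile(profile: NucleosomeProfile,
                   window: int = 30) -> NucleosomeProfile:
    """Moving average (default 30 bp) of the profile's unsmoothed basis,
    stored in the ``smoothed`` vector; raw counts and enrichment are kept
    as-is."""
    return NucleosomeProfile(
        profile.offsets, profile.raw_counts,
        profile.n_sites, profile.total_reads,
        enrichment=profile.enrichment,
        smoothed=moving_average(profile.base_values(), window),
        smoothing_window=window)


@dataclass
class BarrierMetrics:
    """Distance d and half-width w of the barrier profile (bp).

    Per-side values plus their means; an undefined flank peak on a side
    leaves that d as NaN (flagged, not an exception).
    """

    d: float
    w: float
    d_left: float
    d_right: float
    w_left: float
    w_right: float
    central_max: float = field(default=math.nan)

    @property
    def valid(self) -> bool:
        return (not math.isnan(self.d)) and 0 < self.w < self.d <= 1000

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])


#: Minimum flank-peak prominence, as a fraction of the central maximum.
#: Guards the "first local maximum" rule against single-bin counting
#: noise in the trough between barrier and flanking nucleosome.
FLANK_PROMINENCE = 0.05


def _side_metrics(outward: np.ndarray, central_max: float,
                  window: int) -> tuple[float, float]:
    """(w, d) for one side given the *raw* outward-oriented half profile
    (index = bp from centre). Smoothing is applied here, identically for
    both sides, so mirroring the input mirrors the metrics exactly."""
    s = moving_average(outward, window)
    half = central_max / 2.0
    below = np.nonzero(s < half)[0]
    if len(below) == 0:
        return math.nan, math.nan
    w = float(below[0])
    start = int(w) + FLANK_GUARD
    peaks, _ = signal.find_peaks(
        s, prominence=FLANK_PROMINENCE * central_max)
    peaks = peaks[peaks >= start]
    d = float(peaks[0]) if len(peaks) else math.nan
    return w, d


def barrier_metrics(profile: NucleosomeProfile,
                    window: int | None = None) -> BarrierMetrics:
    """Extract (d, w) per side from a profile.

    The central maximum is the largest smoothed value within +/-100 bp of
    the motif centre. Each side is processed on its outward-oriented
    *unsmoothed* half-profile smoothed per side with the same moving
    average; the even 30 bp kernel has a half-bin asymmetry on a full
    profile, and per-side smoothing makes the left/right metrics exact
    mirror images for mirrored input.
    """
    if window is None:
        window = profile.smoothing_window or 30
    x = profile.base_values()
    hw = profile.halfwidth
    center = hw  # index of offset 0
    right = x[center:]
    left = x[:center + 1][::-1]
    s_right = moving_average(right, window)
    s_left = moving_average(left, window)
    k = min(CENTRAL_SEARCH, hw)
    central_max = float(max(s_right[:k + 1].max(), s_left[:k + 1].max()))
    w_r, d_r = _side_metrics(right, central_max, window)
    w_l, d_l = _side_metrics(left, central_max, window)
    mean = lambda a, b: math.nan if (math.isnan(a) or math.isnan(b)) \
        else (a + b) / 2.0
    return BarrierMetrics(d=mean(d_l, d_r), w=mean(w_l, w_r),
                          d_left=d_l, d_right=d_r,
                          w_left=w_l, w_right=w_r,
                          central_max=central_max)


@dataclass
class ConditionComparison:
    """Per-offset difference (condition B minus A) and two summaries."""

    difference: np.ndarray
    central_delta: float  # mean difference within +/-w of the centre
    flank_amplitude_delta: float  # change in peak-to-trough range near +/-d


def compare_conditions(profile_a: NucleosomeProfile,
                       profile_b: NucleosomeProfile,
                       metrics: BarrierMetrics | None = None,
                       flank_band: int = 70) -> ConditionComparison:
    """Difference profile B - A with central-gain and phasing summaries.

    ``metrics`` (defaults to the barrier metrics of A) locates the centre
    band (+/-w) and the flank bands (d +/- flank_band). central_delta > 0
    means reads accumulate over the binding site in B;
    flank_amplitude_delta < 0 means the flanking nucleosome peak has lost
    definition (reduced peak-to-trough range).
    """
    if not np.array_equal(profile_a.offsets, profile_b.offsets):
        raise ValueError("profiles are on different offset grids")
    a = profile_a.values()
    b = profile_b.values()
    diff = b - a
    if metrics is None:
        metrics = barrier_metrics(profile_a)
    hw = profile_a.halfwidth
    w = int(metrics.w) if not math.isnan(metrics.w) else 50
    lo, hi = hw - w, hw + w
    central_delta = float(diff[lo:hi + 1].mean())
    if math.isnan(metrics.d):
        flank_delta = math.nan
    else:
        deltas = []
        for sign, d_side in ((-1, metrics.d_left), (1, metrics.d_right)):
            if math.isnan(d_side):
                continue
            c = hw + sign * int(d_side)
            lo_b = max(0, c - flank_band)
            hi_b = min(len(diff) - 1, c + flank_band)
            amp_a = float(a[lo_b:hi_b + 1].max() - a[lo_b:hi_b + 1].min())
            amp_b = float(b[lo_b:hi_b + 1].max() - b[lo_b:hi_b + 1].min())
            deltas.append(amp_b - amp_a)
        flank_delta = float(np.mean(deltas)) if deltas else math.nan
    return ConditionComparison(diff, central_delta, flank_delta)
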