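"""Midpoint metaprofiles, smoothing, and barrier metrics."""
import math

import numpy as np
import pandas as pd
import pytest

from chronolink import (NucleosomeProfile, SimConfig,
                        aggregate_midpoint_profile, barrier_metrics,
                        compare_conditions, moving_average,
                        normalize_enrichment, simulate_nucleosome_fragments,
                        smooth_profile)


def _motifs(*centers, strand="+"):
    return pd.DataFrame({
        "chrom": "chr1",
        "start": [c - 10 for c in centers],
        "end": [c + 10 for c in centers],
        "name": [f"m{i}" for i in range(len(centers))],
        "score": 0,
        "strand": strand,
    })


def _frags(*mids, chrom="chr1"):
    return pd.DataFrame({"chrom": chrom,
                         "start": [m - 73 for m in mids],
                         "end": [m + 74 for m in mids]})


def test_single_fragment_at_center_counts_once():
    prof = aggregate_midpoint_profile(_frags(5000), _motifs(5000))
    assert prof.raw_counts[1000] == 1  # offset 0
    assert prof.raw_counts.sum() == 1
    assert len(prof.raw_counts) == 2001


def test_even_length_fragment_midpoint_rounds_down():
    frag = pd.DataFrame({"chrom": ["chr1"], "start": [4950], "end": [5052]})
    prof = aggregate_midpoint_profile(frag, _motifs(5000))
    assert prof.raw_counts[1000 + 1] == 1  # floor((4950+5052)/2)=5001


def test_duplicate_sites_double_counts():
    frags = _frags(5000, 5100)
    one = aggregate_midpoint_profile(frags, _motifs(5000))
    two = aggregate_midpoint_profile(frags, _motifs(5000, 5000))
    assert np.array_equal(two.raw_counts, 2 * one.raw_counts)


def test_minus_strand_motif_mirrors_offsets():
    prof = aggregate_midpoint_profile(_frags(5100), _motifs(5000, strand="-"))
    assert prof.raw_counts[1000 - 100] == 1


def test_empty_motif_set_raises():
    with pytest.raises(ValueError, match="motif"):
        aggregate_midpoint_profile(_frags(5000), _motifs())


def test_aggregation_matches_quadratic_oracle(rng):
    centers = [20_000, 47_000, 90_000, 130_000, 171_000]
    mids = rng.integers(19_000, 172_000, size=50)
    frags = _frags(*mids)
    prof = aggregate_midpoint_profile(frags, _motifs(*centers))
    expected = np.zeros(2001)
    for c in centers:
        for m in mids:
            if abs(m - c) <= 1000:
                expected[m - c + 1000] += 1
    assert np.array_equal(prof.raw_counts, expected)


def test_bound_subset_restricts_motifs():
    bound = pd.DataFrame({"chrom": ["chr1"], "start": [4990], "end": [5010]})
    prof = aggregate_midpoint_profile(_frags(5000, 9000),
                                      _motifs(5000, 9000), bound_sites=bound)
    assert prof.n_sites == 1
    assert prof.raw_counts.sum() == 1


# ---------------------------------------------------------- normalize --


def test_enrichment_arithmetic():
    prof = NucleosomeProfile(np.arange(-1000, 1001), np.zeros(2001),
                             n_sites=2, total_reads=1000)
    prof.raw_counts[1000] = 2
    out = normalize_enrichment(prof)
    assert out.enrichment[1000] == pytest.approx(0.001)


def test_enrichment_invariant_to_genomewide_duplication():
    base = aggregate_midpoint_profile(_frags(5000, 5100), _motifs(5000),
                                      total_reads=1000)
    dup_frags = pd.concat([_frags(5000, 5100)] * 2, ignore_index=True)
    dup = aggregate_midpoint_profile(dup_frags, _motifs(5000),
                                     total_reads=2000)
    np.testing.assert_allclose(normalize_enrichment(base).enrichment,
                               normalize_enrichment(dup).enrichment)


def test_enrichment_invariant_to_site_duplication():
    """Doubling every site and its local fragments at a fixed
    experiment-wide read count leaves enrichment identical."""
    frags = _frags(5000, 5080, 5160)
    one = aggregate_midpoint_profile(frags, _motifs(5000),
                                     total_reads=10_000)
    clone = _frags(205_000, 205_080, 205_160)
    two = aggregate_midpoint_profile(
        pd.concat([frags, clone], ignore_index=True),
        _motifs(5000, 205_000), total_reads=10_000)
    np.testing.assert_allclose(normalize_enrichment(one).enrichment,
                               normalize_enrichment(two).enrichment)


def test_zero_sites_or_reads_rejected():
    prof = NucleosomeProfile(np.arange(-5, 6), np.ones(11), n_sites=0,
                             total_reads=10)
    with pytest.raises(ValueError):
        normalize_enrichment(prof)


def test_paired_depth_scaling_cancels(rng):
    """Ten-fold deeper sequencing (in-window and genome-wide) leaves the
    normalised profile statistically unchanged."""
    cfg = SimConfig(nuc_sites=100, nuc_reads_per_site=100.0)
    deep = cfg.replace(nuc_reads_per_site=1000.0)
    f1, m1 = simulate_nucleosome_fragments(cfg, np.random.default_rng(3))
    f2, _ = simulate_nucleosome_fragments(deep, np.random.default_rng(3),
                                          motifs=m1)
    p1 = smooth_profile(normalize_enrichment(
        aggregate_midpoint_profile(f1, m1)), 30)
    p2 = smooth_profile(normalize_enrichment(
        aggregate_midpoint_profile(f2, m1)), 30)
    # same shape up to sampling noise: correlation near 1, scale near 1
    r = np.corrcoef(p1.enrichment, p2.enrichment)[0, 1]
    assert r > 0.95
    assert p2.enrichment.sum() == pytest.approx(p1.enrichment.sum(), rel=0.1)


# ------------------------------------------------------------ smooth --


def test_constant_profile_unchanged_by_smoothing():
    x = np.full(2001, 3.7)
    assert np.allclose(moving_average(x, 30), x)


def test_impulse_response_is_one_thirtieth_plateau():
    x = np.zeros(2001)
    x[1000] = 1.0
    s = moving_average(x, 30)
    nz = np.nonzero(s)[0]
    assert len(nz) == 30
    assert np.allclose(s[nz], 1 / 30)


def test_smoothing_window_bounds_checked():
    prof = NucleosomeProfile(np.arange(-5, 6), np.ones(11), 1, 1)
    with pytest.raises(ValueError):
        smooth_profile(prof, 0)
    with pytest.raises(ValueError):
        smooth_profile(prof, 12)


def test_white_noise_variance_reduced_thirtyfold(rng):
    x = rng.normal(0.0, 1.0, size=20_000)
    s = moving_average(x, 30)[100:-100]
    ratio = x.var() / s.var()
    assert 24 < ratio < 37


# ------------------------------------------------------------ barrier --


def _mixture_profile(central_sd=35.0, d0=180.0, flank_sd=30.0,
                     flank_amp=0.8, repeat=186.0, n_flanks=2):
    off = np.arange(-1000, 1001, dtype=float)
    y = np.exp(-off ** 2 / (2 * central_sd ** 2))
    for sign in (-1, 1):
        for k in range(n_flanks):
            mu = sign * (d0 + k * repeat)
            y += flank_amp * np.exp(-(off - mu) ** 2 / (2 * flank_sd ** 2))
    return NucleosomeProfile(np.arange(-1000, 1001), y, n_sites=1,
                             total_reads=1)


def test_symmetric_profile_gives_equal_sides():
    m = barrier_metrics(_mixture_profile(), window=30)
    assert m.d_left == m.d_right
    assert m.w_left == m.w_right


def test_analytic_mixture_recovers_w_and_d():
    """Half-width of a 35 bp Gaussian is 35*sqrt(2 ln 2) = 41.2 bp; the
    flanking peak sits at the planted 180 bp."""
    m = barrier_metrics(_mixture_profile(), window=30)
    assert abs(m.w - 35.0 * math.sqrt(2 * math.log(2))) <= 6.0
    assert abs(m.d - 180.0) <= 10.0
    assert m.valid


def test_missing_flank_flagged_not_raised():
    m = barrier_metrics(_mixture_profile(flank_amp=0.0), window=30)
    assert math.isnan(m.d)
    assert not math.isnan(m.w)


def test_stochastic_generator_recovers_planted_distance():
    """Mean |d - d0| <= 10 bp across 10 seeds at default depth."""
    errs = []
    for seed in range(10):
        cfg = SimConfig(nuc_sites=200, nuc_reads_per_site=400.0)
        frags, motifs = simulate_nucleosome_fragments(
            cfg, np.random.default_rng(100 + seed))
        prof = smooth_profile(normalize_enrichment(
            aggregate_midpoint_profile(frags, motifs)), 30)
        m = barrier_metrics(prof)
        assert m.valid
        errs.append(abs(m.d - cfg.effective_flank_distance))
    assert np.mean(errs) <= 10.0


def test_broad_barrier_pushes_flanks_out():
    """Doubling the central spread increases both w and d (the positive
    d-w relation of barrier-organised nucleosomes)."""
    results = {}
    for label, sd in (("narrow", 35.0), ("broad", 70.0)):
        cfg = SimConfig(nuc_sites=300, nuc_reads_per_site=400.0,
                        central_sd=sd)
        frags, motifs = simulate_nucleosome_fragments(
            cfg, np.random.default_rng(42))
        prof = smooth_profile(normalize_enrichment(
            aggregate_midpoint_profile(frags, motifs)), 30)
        results[label] = barrier_metrics(prof)
    assert results["broad"].w > results["narrow"].w
    assert results["broad"].d > results["narrow"].d


def test_mirrored_data_swaps_side_metrics_exactly():
    """Strand-flipping every motif mirrors the aggregated profile, so
    left/right metrics swap exactly."""
    cfg = SimConfig(nuc_sites=80, nuc_reads_per_site=300.0)
    frags, motifs = simulate_nucleosome_fragments(
        cfg, np.random.default_rng(5))
    flipped = motifs.copy()
    flipped["strand"] = np.where(motifs["strand"] == "+", "-", "+")
    m1 = barrier_metrics(smooth_profile(normalize_enrichment(
        aggregate_midpoint_profile(frags, motifs)), 30))
    m2 = barrier_metrics(smooth_profile(normalize_enrichment(
        aggregate_midpoint_profile(frags, flipped)), 30))
    assert (m1.d_left, m1.w_left) == (m2.d_right, m2.w_right)
    assert (m1.d_right, m1.w_right) == (m2.d_left, m2.w_left)


# ------------------------------------------------------------ compare --


def test_identical_profiles_zero_difference():
    p = normalize_enrichment(_mixture_profile())
    comp = compare_conditions(p, p)
    assert np.all(comp.difference == 0.0)
    assert comp.central_delta == 0.0


def test_swapping_arguments_negates_difference():
    a = normalize_enrichment(_mixture_profile())
    b = normalize_enrichment(_mixture_profile(flank_amp=0.5))
    ab = compare_conditions(a, b)
    ba = compare_conditions(b, a, metrics=barrier_metrics(a))
    np.testing.assert_array_equal(ab.difference, -ba.difference)


def test_grid_mismatch_raises():
    a = NucleosomeProfile(np.arange(-10, 11), np.ones(21), 1, 1)
    b = NucleosomeProfile(np.arange(-5, 6), np.ones(11), 1, 1)
    with pytest.raises(ValueError, match="grid"):
        compare_conditions(a, b)


def test_depleted_condition_gains_center_loses_phasing(default_data):
    """The depleted simulation plants more central reads and blurred
    flanks; the comparison summaries recover both signs."""
    motifs = default_data.motifs
    prof = {}
    for label, frags in (("t0", default_data.fragments),
                         ("depl", default_data.fragments_depleted)):
        p = aggregate_midpoint_profile(frags, motifs)
        prof[label] = smooth_profile(normalize_enrichment(p), 30)
    comp = compare_conditions(prof["t0"], prof["depl"])
    assert comp.central_delta > 0
    assert comp.flank_amplitude_delta < 0
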