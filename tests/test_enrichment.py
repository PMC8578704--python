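"""Cohorts, control selection, and the hypergeometric PMF."""
import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chronolink import (TIMEPOINTS, assign_cohorts, cohort_enrichment,
                        first_sig_time, hypergeometric_log_pmf,
                        hypergeometric_pmf, hypergeometric_pmf_exact,
                        hypergeometric_tail, percent_with_change,
                        select_control_genes)


def enumeration_pmf(x, n, M, N):
    """Oracle: count size-n subsets of {0..N-1} with exactly x of the
    first M elements, over all C(N, n) subsets."""
    marked = set(range(M))
    total = 0
    fav = 0
    for sub in itertools.combinations(range(N), n):
        total += 1
        if len(marked.intersection(sub)) == x:
            fav += 1
    return Fraction(fav, total)


def test_pmf_equals_enumeration_for_all_small_populations():
    for N in range(1, 13):
        for n in range(0, N + 1):
            for M in range(0, N + 1):
                lo = max(0, n - (N - M))
                hi = min(n, M)
                for x in range(lo, hi + 1):
                    assert hypergeometric_pmf_exact(x, n, M, N) == \
                        enumeration_pmf(x, n, M, N), (x, n, M, N)


def test_pmf_worked_example_2_3_4_10():
    assert enumeration_pmf(2, 3, 4, 10) == Fraction(3, 10)
    assert hypergeometric_pmf(2, 3, 4, 10) == 0.3


def test_pmf_empty_draw_is_one():
    assert hypergeometric_pmf(0, 0, 7, 10) == 1.0


def test_pmf_normalizes_small_and_published_scale():
    total = sum(hypergeometric_pmf(x, 5, 6, 12) for x in range(0, 6))
    assert abs(total - 1.0) < 1e-12
    n, M, N = 3089, 5000, 12741
    lo, hi = max(0, n - (N - M)), min(n, M)
    total = math.fsum(math.exp(hypergeometric_log_pmf(x, n, M, N))
                      for x in range(lo, hi + 1))
    assert abs(total - 1.0) < 1e-9


def test_pmf_symmetry_in_n_and_M():
    for (x, n, M, N) in [(2, 5, 8, 20), (0, 3, 3, 9), (4, 6, 7, 30)]:
        assert math.isclose(hypergeometric_pmf(x, n, M, N),
                            hypergeometric_pmf(x, M, n, N), rel_tol=1e-12)


def test_pmf_matches_scipy_at_published_cohort_sizes():
    # independent route: scipy's implementation on the published cohort
    # sizes (N = 12741 transcribed genes; per-time n values)
    N, M = 12741, 5000
    for n in (389, 1169, 908, 3089, 989):
        x = n // 3
        ours = hypergeometric_pmf(x, n, M, N)
        ref = stats.hypergeom.pmf(x, N, M, n)
        assert math.isclose(ours, ref, rel_tol=1e-9)


def test_inconsistent_counts_raise_not_zero():
    with pytest.raises(ValueError):
        hypergeometric_pmf(5, 3, 10, 20)  # x > n
    with pytest.raises(ValueError):
        hypergeometric_pmf(4, 6, 3, 20)  # x > M
    with pytest.raises(ValueError):
        hypergeometric_pmf(0, 6, 17, 20)  # n-x > N-M
    with pytest.raises(ValueError):
        hypergeometric_pmf(1, 2, 30, 20)  # M > N


def test_pmf_maximal_at_mode_and_decreasing_beyond():
    n, M, N = 20, 30, 100
    vals = [hypergeometric_pmf(x, n, M, N) for x in range(0, n + 1)]
    mode = int(np.argmax(vals))
    # unimodal: nondecreasing up to mode, nonincreasing after
    assert all(vals[i] <= vals[i + 1] for i in range(mode))
    assert all(vals[i] >= vals[i + 1] for i in range(mode, n))
    assert vals[n] < vals[mode]  # x = n with M << N is far off-mode


def test_tail_probability_matches_scipy():
    assert math.isclose(hypergeometric_tail(5, 10, 20, 50),
                        stats.hypergeom.sf(4, 50, 20, 10), rel_tol=1e-9)


# ----------------------------------------------------------- control --


def _expr(rows):
    """rows: (gene_id, max_abs_fc, sig_time or None)"""
    recs = []
    for gene_id, fc, sig in rows:
        r = {"gene_id": gene_id}
        for t in TIMEPOINTS:
            r[f"log2fc_{t}"] = fc if t == 162 else fc / 2
            r[f"fdr_{t}"] = 0.01 if (sig is not None and t >= sig) else 0.5
        recs.append(r)
    return pd.DataFrame(recs)


def test_control_selects_flattest_never_significant():
    expr = _expr([("a", 0.1, None), ("b", 0.2, None), ("c", 0.3, None),
                  ("d", 0.4, None), ("e", 0.5, None)])
    sel, complete = select_control_genes(expr, k=3)
    assert sel["gene_id"].tolist() == ["a", "b", "c"]
    assert complete


def test_control_excludes_any_significance():
    expr = _expr([("a", 0.01, 54), ("b", 0.2, None), ("c", 0.3, None)])
    sel, complete = select_control_genes(expr, k=2)
    assert "a" not in set(sel["gene_id"])


def test_control_short_candidate_list_flagged():
    expr = _expr([("a", 0.1, None), ("b", 0.2, 6)])
    sel, complete = select_control_genes(expr, k=5)
    assert sel["gene_id"].tolist() == ["a"]
    assert not complete


def test_control_invariant_under_row_permutation(rng):
    genes = [(f"g{i:04d}", float(rng.uniform(0, 2)),
              (int(rng.choice(TIMEPOINTS)) if rng.random() < 0.3 else None))
             for i in range(1000)]
    expr = _expr(genes)
    sel1, _ = select_control_genes(expr, k=300)
    shuffled = expr.sample(frac=1.0, random_state=8).reset_index(drop=True)
    sel2, _ = select_control_genes(shuffled, k=300)
    assert sel1["gene_id"].tolist() == sel2["gene_id"].tolist()
    # brute-force oracle: python sort over eligible genes
    elig = []
    for gid, fc, sig in genes:
        if sig is None:
            maxsq = max(fc ** 2, (fc / 2) ** 2)
            elig.append((maxsq, gid))
    expected = [g for _, g in sorted(elig)[:300]]
    assert sel1["gene_id"].tolist() == expected


# ----------------------------------------------------------- cohorts --


def _expr_fc(pairs):
    """pairs: (gene_id, log2fc applied at/after onset 2h)."""
    recs = []
    for gene_id, fc in pairs:
        r = {"gene_id": gene_id}
        for t in TIMEPOINTS:
            r[f"log2fc_{t}"] = fc
            r[f"fdr_{t}"] = 0.001
        recs.append(r)
    return pd.DataFrame(recs)


def test_quintiles_of_ten_genes():
    expr = _expr_fc([(f"g{i}", fc) for i, fc in enumerate(range(-5, 5))])
    coh = assign_cohorts(expr, "early_late")
    q1 = set(coh.loc[coh["quintile"] == 1, "gene_id"])
    assert q1 == {"g0", "g1"}  # the two most repressed
    q5 = set(coh.loc[coh["quintile"] == 5, "gene_id"])
    assert q5 == {"g8", "g9"}


def test_quintile_remainder_goes_to_repressed_end():
    expr = _expr_fc([(f"g{i}", float(i)) for i in range(11)])
    coh = assign_cohorts(expr, "early_late")
    sizes = coh["quintile"].value_counts().sort_index().tolist()
    assert sizes == [3, 2, 2, 2, 2]


def test_quintile_sizes_partition_cohort(default_data):
    expr = default_data.expression
    coh = assign_cohorts(expr, "early_late")
    for cohort, sub in coh[coh["cohort"] != "none"].groupby("cohort"):
        sizes = sub["quintile"].value_counts()
        assert sizes.sum() == len(sub)
        assert sizes.max() - sizes.min() <= 1


def test_tiny_cohort_raises():
    expr = _expr_fc([("a", -1.0), ("b", 1.0)])
    with pytest.raises(ValueError, match="quintile"):
        assign_cohorts(expr, "early_late")


def test_first_change_scheme_one_cohort_per_time():
    recs = []
    for i, t_on in enumerate([2, 2, 2, 2, 2, 54, 54, 54, 54, 54]):
        r = {"gene_id": f"g{i}"}
        for t in TIMEPOINTS:
            r[f"log2fc_{t}"] = -1.0 if t >= t_on else 0.0
            r[f"fdr_{t}"] = 0.001 if t >= t_on else 0.9
        recs.append(r)
    coh = assign_cohorts(pd.DataFrame(recs), "first_change")
    assert set(coh["cohort"]) == {"2", "54"}


def test_planted_early_down_lands_in_early_repressed_quintiles(default_data):
    expr = default_data.expression
    coh = assign_cohorts(expr, "early_late")
    merged = coh.merge(expr[["gene_id", "planted_class"]], on="gene_id")
    ed = merged[merged["planted_class"] == "early_down"]
    ok = (ed["cohort"] == "early") & (ed["quintile"] <= 2)
    assert ok.mean() >= 0.95


def test_never_significant_genes_get_no_quintile():
    base = _expr_fc([(f"g{i}", float(i - 3)) for i in range(6)])
    flat = _expr([("x", 0.1, None)])
    expr = pd.concat([base, flat], ignore_index=True)
    coh = assign_cohorts(expr, "early_late")
    row = coh[coh["gene_id"] == "x"].iloc[0]
    assert row["cohort"] == "none" and pd.isna(row["quintile"])


# ------------------------------------------------- percent / scoring --


def _assign(rows):
    return pd.DataFrame(rows, columns=["gene_id", "cohort", "quintile"])


def test_percent_with_change_arithmetic():
    coh = _assign([(f"g{i}", "early", 1) for i in range(4)])
    flags = pd.DataFrame({"gene_id": [f"g{i}" for i in range(4)],
                          "k": [True, True, True, False]})
    out = percent_with_change(coh, flags)
    assert out.loc[0, "percent"] == 75.0


def test_percent_zero_when_nothing_linked():
    coh = _assign([("a", "early", 1), ("b", "early", 1)])
    flags = pd.DataFrame({"gene_id": ["a", "b"], "k": [False, False]})
    assert percent_with_change(coh, flags).loc[0, "percent"] == 0.0


def test_percent_missing_gene_raises():
    coh = _assign([("a", "early", 1)])
    flags = pd.DataFrame({"gene_id": ["b"], "k": [True]})
    with pytest.raises(ValueError, match="missing"):
        percent_with_change(coh, flags)


def test_cohort_enrichment_counts_and_score():
    coh = _assign([(f"g{i}", "early", 1 + i // 4) for i in range(8)])
    flags = pd.DataFrame({"gene_id": [f"g{i}" for i in range(20)],
                          "k": [i < 5 for i in range(20)]})
    out = cohort_enrichment(coh, flags, "k")
    q1 = out[out["quintile"] == 1].iloc[0]
    assert (q1["x"], q1["n"], q1["M"], q1["N"]) == (4, 4, 5, 20)
    assert math.isclose(q1["pmf"], float(hypergeometric_pmf_exact(4, 4, 5, 20)),
                        rel_tol=1e-12)
    assert math.isclose(q1["neg_log10_pmf"], -math.log10(q1["pmf"]),
                        abs_tol=1e-12)
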