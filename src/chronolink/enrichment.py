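"""Gene cohorts, quintiles, control selection, and hypergeometric scoring.

Genes are grouped by when their expression first changes significantly
(FDR < 0.05) after depletion, split into fold-change quintiles (quintile 1
= most repressed 20%, quintile 5 = most activated 20%), and each quintile
is scored for enrichment of linked chromatin changes with the
hypergeometric point probability

    P(X = x) = C(M, x) C(N - M, n - x) / C(N, n)

where x = cohort genes carrying the change, n = cohort size, M = genes
carrying the change among all N transcribed genes. The headline statistic
is the point PMF itself (reported as -log10); the upper-tail p-value is
available as a flagged extra.
"""
from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .config import TIMEPOINTS

FDR_SIGNIFICANT = 0.05  # expression differential gate

EARLY_TIMES = frozenset({2, 6})
LATE_TIMES = frozenset({18, 54, 162})

#: Above this population size the exact rational path switches to
#: log-gamma arithmetic.
EXACT_N_LIMIT = 200


# ---------------------------------------------------------------- PMF --


def _validate_counts(x: int, n: int, M: int, N: int) -> None:
    for name, v in (("x", x), ("n", n), ("M", M), ("N", N)):
        if v < 0 or int(v) != v:
            raise ValueError(f"{name} must be a non-negative integer, got {v}")
    if n > N or M > N:
        raise ValueError(f"need n <= N and M <= N (n={n}, M={M}, N={N})")
    if x > n or x > M:
        raise ValueError(
            f"inconsistent counts: x={x} exceeds n={n} or M={M}")
    if n - x > N - M:
        raise ValueError(
            f"inconsistent counts: n-x={n - x} unmarked draws but only "
            f"{N - M} unmarked genes")


def hypergeometric_pmf_exact(x: int, n: int, M: int, N: int) -> Fraction:
    """Exact rational hypergeometric point probability."""
    _validate_counts(x, n, M, N)
    return Fraction(math.comb(M, x) * math.comb(N - M, n - x),
                    math.comb(N, n))


def hypergeometric_log_pmf(x: int, n: int, M: int, N: int) -> float:
    """Natural log of the point probability via log-gamma arithmetic.

    Survives published parameter scales (N in the tens of thousands,
    n in the thousands) where direct binomial coefficients overflow.
    """
    _validate_counts(x, n, M, N)

    def lchoose(a: int, b: int) -> float:
        return float(gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1))

    return lchoose(M, x) + lchoose(N - M, n - x) - lchoose(N, n)


def hypergeometric_pmf(x: int, n: int, M: int, N: int) -> float:
    """Hypergeometric point probability as a float.

    Uses exact integer arithmetic for small populations (N <= 200) and
    log-gamma arithmetic otherwise. Inconsistent counts (x > n, x > M, or
    more unmarked draws than unmarked genes) raise rather than returning 0.
    """
    if N <= EXACT_N_LIMIT:
        return float(hypergeometric_pmf_exact(x, n, M, N))
    return math.exp(hypergeometric_log_pmf(x, n, M, N))


def neg_log10_pmf(x: int, n: int, M: int, N: int) -> float:
    """-log10 of the point probability, computed in log space."""
    return -hypergeometric_log_pmf(x, n, M, N) / math.log(10)


def hypergeometric_tail(x: int, n: int, M: int, N: int) -> float:
    """Upper-tail probability P(X >= x) (flagged extra; the headline value is the point PMF)."""
    _validate_counts(x, n, M, N)
    hi = min(n, M)
    logs = [hypergeometric_log_pmf(k, n, M, N) for k in range(x, hi + 1)]
    if not logs:
        return 0.0
    m = max(logs)
    return math.exp(m) * float(sum(math.exp(v - m) for v in logs))


# ------------------------------------------------------------ cohorts --


def first_sig_time(expr: pd.DataFrame,
                   fdr_max: float = FDR_SIGNIFICANT) -> pd.Series:
    """Earliest time point with FDR below the gate; NaN when never.

    Uses the FDR alone (no fold-change gate), matching the upstream
    expression caller's definition of differential.
    """
    out = pd.Series(np.nan, index=expr.index)
    for t in reversed(TIMEPOINTS):
        hit = expr[f"fdr_{t}"].to_numpy(dtype=float) < fdr_max
        out[hit] = t
    return out


def select_control_genes(expr: pd.DataFrame, k: int = 500
                         ) -> tuple[pd.DataFrame, bool]:
    """Non-responding control set: never significant, then flattest.

    Candidates are genes with FDR >= 0.05 at every time point, ranked
    ascending by the maximum squared log2 fold change over the course;
    the top ``k`` are returned (ties broken by gene_id). Returns
    ``(table, complete)`` where ``complete`` is False when fewer than
    ``k`` candidates exist (all are then returned).
    """
    if len(expr) == 0:
        raise ValueError("empty expression table")
    never = np.ones(len(expr), dtype=bool)
    for t in TIMEPOINTS:
        never &= expr[f"fdr_{t}"].to_numpy(dtype=float) >= FDR_SIGNIFICANT
    cand = expr[never].copy()
    fc = np.column_stack([cand[f"log2fc_{t}"].to_numpy(dtype=float)
                          for t in TIMEPOINTS])
    cand["max_sq_log2fc"] = (fc ** 2).max(axis=1) if len(cand) else []
    cand = cand.sort_values(["max_sq_log2fc", "gene_id"],
                            kind="mergesort")
    complete = len(cand) >= k
    sel = cand.head(k)[["gene_id", "max_sq_log2fc"]].reset_index(drop=True)
    return sel, complete


def _quintile_sizes(n: int) -> list[int]:
    """Quintile sizes summing to n; remainder genes go to the
    most-repressed end (n=11 -> [3, 2, 2, 2, 2])."""
    base, rem = divmod(n, 5)
    return [base + (1 if i < rem else 0) for i in range(5)]


def _assign_quintiles(sub: pd.DataFrame, fc_col: str) -> pd.Series:
    """Quintile 1..5 by ascending fold change (1 = most repressed)."""
    sub = sub.sort_values([fc_col, "gene_id"], kind="mergesort")
    sizes = _quintile_sizes(len(sub))
    labels = np.repeat(np.arange(1, 6), sizes)
    return pd.Series(labels, index=sub.index)


def assign_cohorts(expr: pd.DataFrame,
                   scheme: str = "early_late") -> pd.DataFrame:
    """Cohort and quintile assignment for differentially expressed genes.

    scheme="early_late": genes first significant at 2 or 6 h form the
    early cohort (quintiles by log2FC at 6 h); genes first significant at
    18/54/162 h the late cohort (quintiles by log2FC at 162 h).
    scheme="first_change": one cohort per first-significant time point,
    quintiles by the log2FC at that time. Never-significant genes get
    cohort "none" and no quintile; the control set is selected separately.

    Raises when a non-empty cohort has fewer than 5 genes (quintiles
    undefined).
    """
    if scheme not in ("early_late", "first_change"):
        raise ValueError(f"unknown scheme {scheme!r}")
    fst = first_sig_time(expr)
    out = pd.DataFrame({
        "gene_id": expr["gene_id"].to_numpy(),
        "scheme": scheme,
        "first_sig_time": fst.to_numpy(),
    })
    cohort = pd.Series("none", index=expr.index, dtype=object)
    quintile = pd.Series(pd.NA, index=expr.index, dtype="Int64")
    if scheme == "early_late":
        groups = {
            "early": (fst.isin(EARLY_TIMES), "log2fc_6"),
            "late": (fst.isin(LATE_TIMES), "log2fc_162"),
        }
    else:
        groups = {str(t): (fst == t, f"log2fc_{t}") for t in TIMEPOINTS}
    for name, (mask, fc_col) in groups.items():
        idx = expr.index[mask]
        if len(idx) == 0:
            continue
        if len(idx) < 5:
            raise ValueError(
                f"cohort {name!r} has {len(idx)} genes; quintiles undefined")
        cohort[idx] = name
        q = _assign_quintiles(expr.loc[idx], fc_col)
        quintile[q.index] = q.to_numpy()  # explicit: setitem is positional
    out["cohort"] = cohort.to_numpy()
    out["quintile"] = quintile.to_numpy()
    return out


def percent_with_change(assignments: pd.DataFrame, flags: pd.DataFrame,
                        keys: list[str] | None = None) -> pd.DataFrame:
    """Percent of genes per (cohort, quintile) with >=1 linked change.

    ``assignments`` is the cohort table (gene_id, cohort, quintile);
    ``flags`` carries gene_id plus boolean columns, one per change key.
    Duplicate linked sites cannot double-count: flags are per-gene
    booleans. Every assigned gene must be present in ``flags``.
    """
    if keys is None:
        keys = [c for c in flags.columns if c != "gene_id"]
    assigned = assignments[assignments["cohort"] != "none"]
    missing = set(assigned["gene_id"]) - set(flags["gene_id"])
    if missing:
        raise ValueError(
            f"{len(missing)} cohort genes missing from flags table, "
            f"e.g. {sorted(missing)[:3]}")
    merged = assigned.merge(flags, on="gene_id", how="left")
    rows = []
    for (cohort, quintile), sub in merged.groupby(["cohort", "quintile"],
                                                  dropna=False, observed=True):
        if len(sub) == 0:
            raise ValueError(f"empty quintile {cohort}/{quintile}")
        for key in keys:
            hits = int(sub[key].sum())
            rows.append((cohort, int(quintile), key, len(sub), hits,
                         100.0 * hits / len(sub)))
    return pd.DataFrame(rows, columns=[
        "cohort", "quintile", "key", "n_genes", "n_with_change", "percent"])


def cohort_enrichment(assignments: pd.DataFrame, flags: pd.DataFrame,
                      key: str,
                      total_genes: int | None = None,
                      total_with_change: int | None = None,
                      control: pd.DataFrame | None = None) -> pd.DataFrame:
    """Hypergeometric enrichment of one change key per quintile.

    x is counted per (cohort, quintile); M defaults to the number of
    flagged genes among the whole flags table (the transcribed universe)
    and N to that table's size — both overridable when reproducing
    published parameter sets. When a ``control`` table (gene_id) is given
    its genes are scored as one extra pseudo-cohort row.
    """
    N = int(total_genes) if total_genes is not None else len(flags)
    flagged = set(flags.loc[flags[key].astype(bool), "gene_id"])
    M = int(total_with_change) if total_with_change is not None \
        else len(flagged)
    pct = percent_with_change(assignments, flags, keys=[key])
    rows = []
    for r in pct.itertuples():
        x, n = r.n_with_change, r.n_genes
        lp = hypergeometric_log_pmf(x, n, M, N)
        rows.append((r.cohort, r.quintile, key, x, n, M, N, r.percent,
                     math.exp(lp), -lp / math.log(10),
                     hypergeometric_tail(x, n, M, N)))
    if control is not None and len(control):
        ctrl_ids = set(control["gene_id"])
        x = len(ctrl_ids & flagged)
        n = len(ctrl_ids)
        lp = hypergeometric_log_pmf(x, n, M, N)
        rows.append(("control", 0, key, x, n, M, N, 100.0 * x / n,
                     math.exp(lp), -lp / math.log(10),
                     hypergeometric_tail(x, n, M, N)))
    return pd.DataFrame(rows, columns=[
        "cohort", "quintile", "key", "x", "n", "M", "N", "percent",
        "pmf", "neg_log10_pmf", "tail_p"])
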