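"""First-change classification of differential site time courses.

Each site carries a log2 fold change and an FDR at every time point of the
depletion course. The site's *first change time* is the earliest time at
which both the fold-change gate (|log2FC| > log2(fc_min)) and the FDR gate
(FDR < fdr_max) are met; its direction (lost/gained) is the sign of the
fold change at that time and is fixed thereafter — later sign reversals do
not reclassify. Sites failing every gate are (none, never).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .config import ThresholdConfig, TIMEPOINTS

NEVER = -1  # sentinel for first_change_time of unchanged sites

_DIRECTION_ORDER = {"lost": 0, "gained": 1, "none": 2}


@dataclass(frozen=True)
class SiteClassification:
    direction: str  # lost / gained / none
    first_change_time: int  # hours, or NEVER


def classify_first_change(log2fc: dict, fdr: dict,
                          thr: ThresholdConfig) -> SiteClassification:
    """Classify a single time course given as time -> value mappings."""
    missing = [t for t in TIMEPOINTS if t not in log2fc or t not in fdr]
    if missing:
        raise ValueError(f"missing time points: {missing}")
    cut = thr.log2fc_min
    for t in TIMEPOINTS:
        if abs(log2fc[t]) > cut and fdr[t] < thr.fdr_max:
            return SiteClassification(
                "lost" if log2fc[t] < 0 else "gained", t)
    return SiteClassification("none", NEVER)


def classify_table(sites: pd.DataFrame,
                   thr: ThresholdConfig) -> pd.DataFrame:
    """Vectorised first-change classification of a site table.

    ``sites`` must carry log2fc_<t> and fdr_<t> columns for every t in the
    time grid. Returns a copy with ``direction`` and ``first_change_time``
    columns appended.
    """
    for t in TIMEPOINTS:
        for p in ("log2fc", "fdr"):
            if f"{p}_{t}" not in sites.columns:
                raise ValueError(f"missing column {p}_{t}")
    n = len(sites)
    first = np.full(n, NEVER, dtype=np.int64)
    direction = np.full(n, "none", dtype=object)
    assigned = np.zeros(n, dtype=bool)
    cut = thr.log2fc_min
    for t in TIMEPOINTS:
        lfc = sites[f"log2fc_{t}"].to_numpy(dtype=float)
        fdr = sites[f"fdr_{t}"].to_numpy(dtype=float)
        hit = (~assigned) & (np.abs(lfc) > cut) & (fdr < thr.fdr_max)
        first[hit] = t
        direction[hit] = np.where(lfc[hit] < 0, "lost", "gained")
        assigned |= hit
    out = sites.copy()
    out["direction"] = direction
    out["first_change_time"] = first
    return out


def order_sites(classified: pd.DataFrame) -> pd.DataFrame:
    """Deterministic display ordering of classified sites.

    Stable sort by (direction group, first change time, chrom, start):
    lost sites first, then gained, then unchanged; within a group earlier
    changes first; ties resolved by genomic coordinate.
    """
    key_dir = classified["direction"].map(_DIRECTION_ORDER)
    if key_dir.isna().any():
        bad = sorted(set(classified["direction"]) - set(_DIRECTION_ORDER))
        raise ValueError(f"unknown directions: {bad}")
    # 'never' (-1) must sort after real times within its group; the none
    # group is the only one containing it, so map it to +inf.
    key_time = classified["first_change_time"].replace(NEVER, np.inf)
    out = classified.assign(_d=key_dir.to_numpy(), _t=key_time.to_numpy())
    # site_id as final tie-break: co-located sites (e.g. a dual-loss pair
    # carried in two assays) would otherwise order arbitrarily
    tail = [c for c in ("site_id",) if c in out.columns]
    out = out.sort_values(["_d", "_t", "chrom", "start", "end"] + tail,
                          kind="mergesort")
    return out.drop(columns=["_d", "_t"]).reset_index(drop=True)


def consensus_filter(replicate_sets: list[pd.DataFrame],
                     min_overlap: int) -> pd.DataFrame:
    """Consensus peaks observed in at least ``min_overlap`` replicates.

    A genomic position supports consensus where peaks from >= min_overlap
    distinct replicate sets cover it (in 1D, pairwise mutual overlap of k
    intervals is equivalent to a shared base). Retained output intervals
    span the union of all peaks that touch a supported core region;
    contributing peaks reaching into two cores merge them.

    Each replicate set needs chrom/start/end columns. Raises if
    ``min_overlap`` exceeds the number of replicate sets.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if min_overlap > len(replicate_sets):
        raise ValueError(
            f"min_overlap={min_overlap} exceeds {len(replicate_sets)} "
            "replicate sets")
    chroms = sorted({c for df in replicate_sets for c in df["chrom"]})
    rows = []
    for chrom in chroms:
        per_rep = []
        for df in replicate_sets:
            sub = df[df["chrom"] == chrom]
            per_rep.append(_merge_intervals(
                sub["start"].to_numpy(), sub["end"].to_numpy()))
        # sweep over replicate-merged intervals counting replicate presence
        events = []
        for merged in per_rep:
            for s, e in merged:
                events.append((s, 1))
                events.append((e, -1))
        if not events:
            continue
        events.sort()
        cores = []
        depth = 0
        core_start = None
        for pos, delta in events:
            prev = depth
            depth += delta
            if prev < min_overlap <= depth:
                core_start = pos
            elif prev >= min_overlap > depth:
                cores.append((core_start, pos))
        if not cores:
            continue
        core_tree = IntervalTree()
        for i, (s, e) in enumerate(cores):
            core_tree[s:e] = i
        # group contributing peaks by the cores they touch (union-find)
        parent = list(range(len(cores)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        span = {i: [c[0], c[1]] for i, c in enumerate(cores)}
        for df in replicate_sets:
            sub = df[df["chrom"] == chrom]
            for s, e in zip(sub["start"], sub["end"]):
                hits = sorted(iv.data for iv in core_tree[s:e])
                if not hits:
                    continue
                root = find(hits[0])
                for h in hits[1:]:
                    r2 = find(h)
                    if r2 != root:
                        span[root][0] = min(span[root][0], span[r2][0])
                        span[root][1] = max(span[root][1], span[r2][1])
                        parent[r2] = root
                span[root][0] = min(span[root][0], int(s))
                span[root][1] = max(span[root][1], int(e))
        roots = {find(i) for i in range(len(cores))}
        for r in sorted(roots, key=lambda i: span[i][0]):
            rows.append((chrom, span[r][0], span[r][1]))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return out.sort_values(["chrom", "start", "end"],
                           kind="mergesort").reset_index(drop=True)


def _merge_intervals(starts: np.ndarray, ends: np.ndarray) -> list[tuple[int, int]]:
    """Union of half-open intervals within one replicate."""
    if len(starts) == 0:
        return []
    order = np.argsort(starts, kind="mergesort")
    merged: list[list[int]] = []
    for s, e in zip(starts[order], ends[order]):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], int(e))
        else:
            merged.append([int(s), int(e)])
    return [tuple(iv) for iv in merged]
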