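"""Interval logic linking chromatin changes to genes and annotations.

Coordinates are 0-based half-open throughout (BED dialect); overlap means
at least one shared base. Promoter and enhancer windows are TSS-centred
and symmetric: a site overlapping [TSS-p, TSS+p) is promoter-linked; a
site overlapping [TSS-E, TSS+E) but not the promoter is enhancer-linked.
A site may link to several genes; linkage for a given (gene, site) pair is
promoter xor enhancer. Histone genes can be excluded (they cluster so
densely that 50 kb windows would swallow unrelated changes).
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .config import WindowConfig


def _site_trees(sites: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in sites.groupby("chrom", sort=False):
        tree = IntervalTree()
        for row in sub.itertuples():
            if row.start >= row.end:
                raise ValueError(
                    f"invalid interval {chrom}:{row.start}-{row.end}")
            tree[row.start:row.end] = row.Index
        trees[chrom] = tree
    return trees


def link_changes_to_genes(genes: pd.DataFrame, sites: pd.DataFrame,
                          win: WindowConfig) -> pd.DataFrame:
    """Assign classified sites to gene promoter/enhancer windows.

    ``genes`` needs gene_id/chrom/tss (and is_histone when exclusion is
    on); ``sites`` needs chrom/start/end/site_id plus, when present,
    direction / first_change_time / assay which are carried through.
    Returns one row per (gene, linked site) with a ``zone`` column
    (promoter or enhancer); genes with no linked site contribute no rows.
    Unknown site chromosomes raise with the offenders listed.
    """
    known = set(genes["chrom"].unique())
    bad = sorted(set(sites["chrom"].unique()) - known)
    if bad:
        raise ValueError(f"sites on chromosomes absent from genes: {bad}")
    sites = sites.reset_index(drop=True)
    trees = _site_trees(sites)
    carry = [c for c in ("assay", "direction", "first_change_time")
             if c in sites.columns]
    rows = []
    for g in genes.itertuples():
        if win.exclude_histone_genes and getattr(g, "is_histone", False):
            continue
        tree = trees.get(g.chrom)
        if tree is None:
            continue
        p_lo, p_hi = g.tss - win.promoter_halfwidth, g.tss + win.promoter_halfwidth
        e_lo, e_hi = g.tss - win.enhancer_halfwidth, g.tss + win.enhancer_halfwidth
        prom = {iv.data for iv in tree[p_lo:p_hi]}
        enh = {iv.data for iv in tree[e_lo:e_hi]} - prom
        for idx in sorted(prom):
            rows.append((g.gene_id, sites.at[idx, "site_id"], "promoter", idx))
        for idx in sorted(enh):
            rows.append((g.gene_id, sites.at[idx, "site_id"], "enhancer", idx))
    out = pd.DataFrame(rows, columns=["gene_id", "site_id", "zone", "_idx"])
    for c in carry:
        out[c] = sites[c].to_numpy()[out["_idx"].to_numpy(dtype=int)] \
            if len(out) else pd.Series(dtype=sites[c].dtype)
    out = out.drop(columns="_idx")
    # canonical order so the result is invariant to input row order
    return out.sort_values(["gene_id", "zone", "site_id"],
                           kind="mergesort").reset_index(drop=True)


def gene_change_flags(genes: pd.DataFrame, links: pd.DataFrame,
                      change_keys: dict[str, set[str]] | None = None,
                      zone: str = "enhancer") -> pd.DataFrame:
    """Per-gene boolean flags: does the gene have >=1 linked site of each key.

    ``change_keys`` maps a key name to the set of site_ids carrying that
    change (e.g. dual-loss sites from an intersection); all genes in
    ``genes`` appear in the output, with False where nothing is linked.
    ``zone`` restricts to promoter- or enhancer-linked sites ("any" keeps
    both).
    """
    sub = links if zone == "any" else links[links["zone"] == zone]
    out = pd.DataFrame({"gene_id": genes["gene_id"].to_numpy()})
    if change_keys is None:
        change_keys = {"any_change": set(sub["site_id"])}
    by_gene = sub.groupby("gene_id")["site_id"].agg(set).to_dict()
    for key, site_ids in change_keys.items():
        hit_genes = {g for g, ids in by_gene.items() if ids & site_ids}
        out[key] = out["gene_id"].isin(hit_genes)
    return out


def intersect_change_sets(set_a: pd.DataFrame, set_b: pd.DataFrame
                          ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Split two interval sets by >=1 bp overlap.

    Returns (a_only, b_only, both) where ``both`` contains the intervals
    of A overlapping any interval of B *and* the intervals of B
    overlapping any interval of A (reported counts are therefore
    per-input-interval, with A's rows first).
    """
    trees_b = _site_trees(set_b) if len(set_b) else {}
    trees_a = _site_trees(set_a) if len(set_a) else {}
    a_hit = np.zeros(len(set_a), dtype=bool)
    for i, row in enumerate(set_a.itertuples()):
        t = trees_b.get(row.chrom)
        if t is not None and t.overlaps(row.start, row.end):
            a_hit[i] = True
    b_hit = np.zeros(len(set_b), dtype=bool)
    for i, row in enumerate(set_b.itertuples()):
        t = trees_a.get(row.chrom)
        if t is not None and t.overlaps(row.start, row.end):
            b_hit[i] = True
    both = pd.concat([set_a[a_hit], set_b[b_hit]], ignore_index=True)
    return (set_a[~a_hit].reset_index(drop=True),
            set_b[~b_hit].reset_index(drop=True),
            both)


def annotate_states(sites: pd.DataFrame,
                    segmentation: pd.DataFrame) -> pd.DataFrame:
    """Fraction of sites per chromatin state, by maximal overlap.

    The segmentation must tile each chromosome without overlap. Each site
    is assigned the state contributing the most overlapping bases; ties
    break to the leftmost overlapping segment. Returns a table
    (state, n_sites, fraction) over the segmentation's state alphabet;
    fractions sum to 1.
    """
    if len(sites) == 0:
        raise ValueError("empty site set")
    seg_by_chrom = {}
    for chrom, sub in segmentation.groupby("chrom", sort=False):
        sub = sub.sort_values("start", kind="mergesort")
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if (starts[1:] != ends[:-1]).any():
            raise ValueError(f"segmentation does not tile {chrom}")
        seg_by_chrom[chrom] = (starts, ends, sub["state"].to_numpy())
    assigned = []
    for row in sites.itertuples():
        if row.chrom not in seg_by_chrom:
            raise ValueError(f"site chromosome {row.chrom!r} absent "
                             "from segmentation")
        starts, ends, states = seg_by_chrom[row.chrom]
        lo = np.searchsorted(ends, row.start, side="right")
        hi = np.searchsorted(starts, row.end, side="left")
        if lo >= hi:
            raise ValueError(
                f"site {row.chrom}:{row.start}-{row.end} outside segmentation")
        ov = np.minimum(ends[lo:hi], row.end) - np.maximum(starts[lo:hi],
                                                           row.start)
        assigned.append(states[lo + int(np.argmax(ov))])  # argmax = leftmost tie
    counts = pd.Series(assigned).value_counts()
    all_states = pd.unique(segmentation["state"])
    n = counts.reindex(all_states, fill_value=0)
    return pd.DataFrame({"state": all_states, "n_sites": n.to_numpy(),
                         "fraction": n.to_numpy() / len(sites)})
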