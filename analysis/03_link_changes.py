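#!/usr/bin/env python
"""Link classified chromatin changes to genes and chromatin states.

Assigns each changed site to promoter windows (±500 bp of the TSS) and
enhancer windows (±50 kb excluding the promoter), intersects lost
accessibility with lost EP300 occupancy to define dual-loss sites, and
annotates lost-accessibility sites with the chromatin-state
segmentation. Writes results/linkage.tsv, results/gene_change_flags.tsv
and results/acc_lost_state_fractions.tsv.
"""
import argparse

import pandas as pd

from chronolink import (DEFAULT_THRESHOLDS, TIMEPOINTS, WindowConfig,
                        annotate_states, classify_table, gene_change_flags,
                        intersect_change_sets, link_changes_to_genes)
from chronolink import io


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--simdir", default="results/sim")
    ap.add_argument("--outdir", default="results")
    args = ap.parse_args()

    genes = io.read_genes(f"{args.simdir}/genes.bed",
                          f"{args.simdir}/gene_attrs.tsv")
    sites = io.read_site_timecourse(f"{args.simdir}/sites.tsv")
    seg = io.read_segmentation(f"{args.simdir}/segmentation.bed")

    classified = {assay: classify_table(sub.reset_index(drop=True),
                                        DEFAULT_THRESHOLDS[assay])
                  for assay, sub in sites.groupby("assay", sort=True)}
    acc = classified["accessibility"]
    acc_lost = acc[acc["direction"] == "lost"]
    ep = classified["EP300"]
    ep_lost = ep[ep["direction"] == "lost"]
    a_only, e_only, both = intersect_change_sets(acc_lost, ep_lost)
    print(f"change-set intersection: {len(a_only)} accessibility-only, "
          f"{len(e_only)} EP300-only, {len(both)} rows in dual-loss loci")

    win = WindowConfig()
    changed = pd.concat([c[c["direction"] != "none"]
                         for c in classified.values()], ignore_index=True)
    links = link_changes_to_genes(genes, changed, win)
    io.write_table(links, f"{args.outdir}/linkage.tsv")

    keys = {"accessibility_lost": set(acc_lost["site_id"]),
            "ep300_lost": set(ep_lost["site_id"]),
            "dual_lost": set(both["site_id"])}
    for t in TIMEPOINTS:
        keys[f"accessibility_lost_{t}h"] = set(
            acc_lost.loc[acc_lost["first_change_time"] == t, "site_id"])
    flags = gene_change_flags(genes, links, keys, zone="enhancer")
    io.write_table(flags, f"{args.outdir}/gene_change_flags.tsv")
    frac = 100 * flags[["accessibility_lost", "ep300_lost",
                        "dual_lost"]].mean()
    print("genes with >=1 enhancer-window change: "
          + ", ".join(f"{k} {v:.1f}%" for k, v in frac.items()))

    states = annotate_states(acc_lost, seg)
    io.write_table(states, f"{args.outdir}/acc_lost_state_fractions.tsv")
    print("lost-accessibility sites by chromatin state:",
          {r.state: round(r.fraction, 3) for r in states.itertuples()})


if __name__ == "__main__":
    main()
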