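#!/usr/bin/env python
"""Score chromatin-change enrichment across expression cohorts.

Builds early/late cohorts of differentially expressed genes (FDR < 0.05),
splits each into fold-change quintiles, selects the 500 flattest
never-significant genes as the control set, and scores each quintile's
chromatin-change burden with the hypergeometric point probability.
Writes results/enrichment.tsv and prints the repression hierarchy.
"""
import argparse

from chronolink import (assign_cohorts, cohort_enrichment,
                        select_control_genes)
from chronolink import io


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--simdir", default="results/sim")
    ap.add_argument("--flags", default="results/gene_change_flags.tsv")
    ap.add_argument("--out", default="results/enrichment.tsv")
    ap.add_argument("--scheme", default="early_late",
                    choices=["early_late", "first_change"])
    args = ap.parse_args()

    genes = io.read_genes(f"{args.simdir}/genes.bed",
                          f"{args.simdir}/gene_attrs.tsv")
    expr = io.read_expression_timecourse(f"{args.simdir}/expression.tsv")
    flags = io.read_table(args.flags)

    transcribed = set(genes.loc[~genes["is_histone"], "gene_id"])
    expr = expr[expr["gene_id"].isin(transcribed)].reset_index(drop=True)
    flags = flags[flags["gene_id"].isin(transcribed)].reset_index(drop=True)

    cohorts = assign_cohorts(expr, args.scheme)
    control, complete = select_control_genes(expr, 500)
    if not complete:
        print(f"note: only {len(control)} control candidates available")

    import pandas as pd
    tables = []
    for key in ("accessibility_lost", "ep300_lost", "dual_lost"):
        tables.append(cohort_enrichment(cohorts, flags, key,
                                        control=control))
    enr = pd.concat(tables, ignore_index=True)
    io.write_table(enr, args.out)

    print(f"N = {len(flags)} transcribed genes; cohort sizes:",
          cohorts[cohorts.cohort != 'none']
          .groupby('cohort').size().to_dict())
    q1 = enr[(enr["cohort"] == "early") & (enr["quintile"] == 1)]
    ctrl = enr[enr["cohort"] == "control"]
    print("most-repressed early quintile (q1) vs control:")
    for key in ("accessibility_lost", "ep300_lost", "dual_lost"):
        a = q1[q1["key"] == key].iloc[0]
        c = ctrl[ctrl["key"] == key].iloc[0]
        print(f"  {key:20s} q1 {a['percent']:5.1f}% "
              f"(-log10 PMF {a['neg_log10_pmf']:5.2f})   "
              f"control {c['percent']:5.1f}% "
              f"(-log10 PMF {c['neg_log10_pmf']:5.2f})")
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
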