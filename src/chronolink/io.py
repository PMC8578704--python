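"""Readers and writers for the pipeline's TSV/BED schemas.

All coordinates are 0-based half-open. Tables are tab-delimited with a
header row except BED files, which are headerless. Readers validate
coordinates and FDR ranges and report offending files with 1-based line
numbers; writers round-trip exactly (floats via repr-precision).
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .config import TIMEPOINTS


class DataError(ValueError):
    """Malformed input data (exit code 3 territory)."""


def _fail(path, line: int | None, msg: str):
    where = f"{path}" if line is None else f"{path}, line {line}"
    raise DataError(f"{where}: {msg}")


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        _fail(path, None, f"missing columns {missing}")


def _check_intervals(df: pd.DataFrame, path, header: bool) -> None:
    offset = 2 if header else 1  # first data row's line number
    bad = df.index[df["start"].to_numpy() >= df["end"].to_numpy()]
    if len(bad):
        i = int(bad[0])
        _fail(path, i + offset,
              f"start >= end ({df.at[i, 'start']} >= {df.at[i, 'end']})")
    neg = df.index[df["start"].to_numpy() < 0]
    if len(neg):
        i = int(neg[0])
        _fail(path, i + offset, f"negative start {df.at[i, 'start']}")


def timecourse_columns() -> list[str]:
    return [f"{p}_{t}" for t in TIMEPOINTS for p in ("log2fc", "fdr")]


def _check_fdr(df: pd.DataFrame, path, header: bool = True) -> None:
    offset = 2 if header else 1
    for t in TIMEPOINTS:
        col = df[f"fdr_{t}"].to_numpy(dtype=float)
        bad = np.nonzero(~((col >= 0.0) & (col <= 1.0)))[0]
        if len(bad):
            i = int(bad[0])
            _fail(path, i + offset,
                  f"fdr_{t} = {col[i]} outside [0, 1]")


# ------------------------------------------------------------ genes --


def write_genes(genes: pd.DataFrame, bed_path, attrs_path) -> None:
    """Gene models as BED6 (TSS as a 1 bp interval) plus attribute TSV."""
    bed = pd.DataFrame({
        "chrom": genes["chrom"],
        "start": genes["tss"],
        "end": genes["tss"] + 1,
        "name": genes["gene_id"],
        "score": 0,
        "strand": genes["strand"],
    })
    bed.to_csv(bed_path, sep="\t", header=False, index=False)
    genes[["gene_id", "is_histone", "planted_class"]].to_csv(
        attrs_path, sep="\t", index=False)


def read_genes(bed_path, attrs_path) -> pd.DataFrame:
    bed = read_bed(bed_path, names=["chrom", "start", "end", "name",
                                    "score", "strand"])
    attrs = pd.read_csv(attrs_path, sep="\t",
                        float_precision="round_trip")
    _require_columns(attrs, ["gene_id", "is_histone", "planted_class"],
                     attrs_path)
    genes = pd.DataFrame({
        "gene_id": bed["name"],
        "chrom": bed["chrom"],
        "tss": bed["start"],
        "strand": bed["strand"],
    }).merge(attrs, on="gene_id", how="left")
    if genes["is_histone"].isna().any():
        _fail(attrs_path, None, "gene ids missing from attribute table")
    genes["is_histone"] = genes["is_histone"].astype(bool)
    return genes


# ------------------------------------------------------- time courses --


def write_timecourse(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_site_timecourse(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    _require_columns(df, ["chrom", "start", "end", "site_id"]
                     + timecourse_columns(), path)
    _check_intervals(df, path, header=True)
    _check_fdr(df, path)
    if "planted_gene" in df.columns:  # uncoupled sites have empty cells
        df["planted_gene"] = df["planted_gene"].fillna("")
    return df


def read_expression_timecourse(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    _require_columns(df, ["gene_id"] + timecourse_columns(), path)
    _check_fdr(df, path)
    return df


# ---------------------------------------------------------------- BED --


def read_bed(path, names=None) -> pd.DataFrame:
    """Headerless BED with >= 3 columns; tolerates a trailing newline."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         skip_blank_lines=True,
                         float_precision="round_trip")
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["chrom", "start", "end"])
    if df.shape[1] < 3 and len(df):
        _fail(path, 1, f"expected >= 3 BED columns, found {df.shape[1]}")
    default = ["chrom", "start", "end", "name", "score", "strand"]
    if names is None:
        names = (default + [f"col{i}" for i in range(6, df.shape[1])]
                 )[:df.shape[1]]
    elif len(names) != df.shape[1] and len(df):
        _fail(path, 1, f"expected {len(names)} columns, found {df.shape[1]}")
    df.columns = names[:df.shape[1]] if len(df) else names
    if len(df) == 0:
        return pd.DataFrame(columns=names)
    for col in ("start", "end"):
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            line = int(bad[0]) + 1 if len(bad) else 1
            _fail(path, line, f"non-numeric {col}")
        df[col] = df[col].astype(np.int64)
    _check_intervals(df, path, header=False)
    return df


def write_bed(df: pd.DataFrame, path, columns=None) -> None:
    cols = columns or [c for c in ("chrom", "start", "end", "name",
                                   "score", "strand") if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def write_fragments(fragments: pd.DataFrame, path) -> None:
    write_bed(fragments, path, columns=["chrom", "start", "end"])


def read_fragments(path) -> pd.DataFrame:
    return read_bed(path, names=["chrom", "start", "end"])


def write_segmentation(seg: pd.DataFrame, path) -> None:
    write_bed(seg, path, columns=["chrom", "start", "end", "state"])


def read_segmentation(path) -> pd.DataFrame:
    return read_bed(path, names=["chrom", "start", "end", "state"])


def write_classification(classified: pd.DataFrame, path) -> None:
    """Classified sites as BED6+2 (direction, first_change_time)."""
    out = pd.DataFrame({
        "chrom": classified["chrom"],
        "start": classified["start"],
        "end": classified["end"],
        "name": classified["site_id"],
        "score": 0,
        "strand": ".",
        "direction": classified["direction"],
        "first_change_time": classified["first_change_time"],
    })
    out.to_csv(path, sep="\t", header=False, index=False)


def read_classification(path) -> pd.DataFrame:
    df = read_bed(path, names=["chrom", "start", "end", "site_id", "score",
                               "strand", "direction", "first_change_time"])
    bad = df.index[~df["direction"].isin(["lost", "gained", "none"])]
    if len(bad):
        _fail(path, int(bad[0]) + 1,
              f"bad direction {df.at[int(bad[0]), 'direction']!r}")
    return df


# --------------------------------------------------------- plain TSVs --


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def write_profile(profile, path) -> None:
    profile.to_frame().to_csv(path, sep="\t", index=False)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
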