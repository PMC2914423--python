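"""Readers and writers for the package's TSV/JSON dialects.

All tables are plain tab-separated text with a header row.  Input
positions are 1-based; segment output is BED-like 0-based half-open.
Validation errors name the offending (1-based, header-inclusive) row.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .probe_combination import PanelFit

__all__ = [
    "read_probe_table",
    "read_signal_table",
    "read_genotypes",
    "write_signal_table",
    "write_segments",
    "write_probe_calls",
    "write_model_report",
    "read_model_report",
    "write_panel_fit",
    "read_panel_fit",
]

PROBE_COLUMNS = [
    "snp_id", "sample_id", "chrom", "pos", "quartet", "allele",
    "pm", "mm", "amplicon_size", "subarray",
]
GENOTYPE_VALUES = {"AA", "AB", "BB", "NC"}


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")


def _check_numeric(df: pd.DataFrame, cols: list[str], path) -> None:
    for c in cols:
        bad = pd.to_numeric(df[c], errors="coerce").isna() & df[c].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header + 1-based
            raise ValueError(f"{path}: non-numeric value in column {c!r} at row {row}")
        df[c] = pd.to_numeric(df[c])


def _check_unique(df: pd.DataFrame, keys: list[str], path) -> None:
    dup = df.duplicated(subset=keys)
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0]) + 2
        raise ValueError(f"{path}: duplicate key {keys} at row {row}")


def read_probe_table(path) -> pd.DataFrame:
    """Quartet-level PM/MM intensity table (one row per SNP x sample x
    quartet x allele); an optional ``amplicon_id`` column marks SNPs
    sharing a PCR amplicon."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    _require_columns(df, PROBE_COLUMNS, path)
    _check_numeric(df, ["pos", "quartet", "pm", "mm", "amplicon_size"], path)
    _check_unique(df, ["snp_id", "sample_id", "quartet", "allele"], path)
    bad = ~df["allele"].isin(["A", "B"])
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise ValueError(f"{path}: allele must be A or B at row {row}")
    return df


def read_signal_table(path) -> pd.DataFrame:
    """Per-probe signal table: (snp_id, chrom, pos, signal), optionally
    with ``genotype`` and ``true_cn`` columns.

    An oligo-CGH style two-channel table with ``test`` and ``reference``
    columns instead of ``signal`` is accepted; the signal is then the
    conventional 2 * test / reference.  Tables without a genotype column
    are treated downstream as Agilent-like (no genotype-based anchoring).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if "probe_id" in df.columns and "snp_id" not in df.columns:
        df = df.rename(columns={"probe_id": "snp_id"})
    if "signal" not in df.columns and {"test", "reference"} <= set(df.columns):
        _check_numeric(df, ["test", "reference"], path)
        df["signal"] = 2.0 * df["test"] / df["reference"]
    _require_columns(df, ["snp_id", "chrom", "pos", "signal"], path)
    _check_numeric(df, ["pos", "signal"], path)
    _check_unique(df, ["snp_id"], path)
    if "genotype" in df.columns:
        bad = ~df["genotype"].isin(GENOTYPE_VALUES)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise ValueError(f"{path}: invalid genotype at row {row}")
    return df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def read_genotypes(path) -> pd.DataFrame:
    """Panel genotype table: (snp_id, sample_id, genotype in AA/AB/BB/NC)."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["snp_id", "sample_id", "genotype"], path)
    _check_unique(df, ["snp_id", "sample_id"], path)
    bad = ~df["genotype"].isin(GENOTYPE_VALUES)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise ValueError(f"{path}: invalid genotype at row {row}")
    return df


def write_signal_table(df: pd.DataFrame, path) -> None:
    cols = [c for c in ("snp_id", "chrom", "pos", "signal", "genotype", "true_cn") if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False)


def write_probe_calls(df: pd.DataFrame, path) -> None:
    """Per-probe calls: snp_id, chrom, pos (1-based), signal, cn."""
    df[["snp_id", "chrom", "pos", "signal", "cn"]].to_csv(path, sep="\t", index=False)


def write_segments(segments: pd.DataFrame, path) -> None:
    """BED-like segment table: chrom, start, end (0-based half-open), cn,
    n_probes, mean_signal."""
    segments.to_csv(path, sep="\t", index=False)


def read_segments(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    _require_columns(df, ["chrom", "start", "end", "cn", "n_probes"], path)
    return df


def write_model_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1, default=float)


def read_model_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_panel_fit(fit: PanelFit, path) -> None:
    with open(path, "w") as fh:
        json.dump(fit.to_dict(), fh, indent=None, default=float)


def read_panel_fit(path) -> PanelFit:
    with open(path) as fh:
        return PanelFit.from_dict(json.load(fh))
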