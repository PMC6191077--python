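"""Delimited-text readers and writers for gene tables, variant tables and results.

All tables are tab-separated with a header line; lines starting with ``#``
are provenance comments and are skipped on read.  P-values are written in
scientific notation with 6 significant digits and other floats with 12, so
a write-read round trip is lossless at that precision.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

GENE_COLUMNS = ["gene", "x1f", "x1p", "x0f", "x0p"]
VARIANT_COLUMNS = ["gene", "variant_id", "consequence", "case_ac", "case_an", "ctrl_ac", "ctrl_an"]


class ParseError(ValueError):
    """Malformed input table; message carries the offending file and detail."""


def read_gene_counts(path: str | Path) -> pd.DataFrame:
    """Read a per-gene count table: ``gene, x1f, x1p, x0f, x0p [, length_kb]``."""
    df = _read_tsv(path)
    missing = [c for c in GENE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    for c in GENE_COLUMNS[1:] + (["length_kb"] if "length_kb" in df.columns else []):
        df[c] = pd.to_numeric(df[c], errors="raise")
        if (df[c] < 0).any():
            bad = df.index[df[c] < 0][0] + 2  # 1-based + header
            raise ParseError(f"{path}: negative value in column {c} near line {bad}")
    return df


def read_variant_table(path: str | Path) -> pd.DataFrame:
    """Read a per-variant table; optional ``ext_af_*`` columns are preserved."""
    df = _read_tsv(path)
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns and c != "variant_id"]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    for c in ["case_ac", "case_an", "ctrl_ac", "ctrl_an"]:
        df[c] = pd.to_numeric(df[c], errors="raise").astype(int)
    for c in df.columns:
        if c.startswith("ext_af"):
            df[c] = pd.to_numeric(df[c], errors="raise")
    return df


def _read_tsv(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame()
    except pd.errors.ParserError as exc:  # carries pandas' line number detail
        raise ParseError(f"{path}: {exc}") from exc


def config_hash(config: Mapping) -> str:
    """Short stable hash of a configuration mapping, for provenance headers."""
    canon = repr(sorted((str(k), str(v)) for k, v in config.items()))
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    *,
    header_lines: Iterable[str] = (),
    pvalue_columns: Iterable[str] = (),
) -> None:
    """Write a results table with ``#``-prefixed provenance header lines.

    Columns named in ``pvalue_columns`` (plus any starting with ``p_``)
    are rendered in scientific notation with 6 significant digits; other
    floats keep 12 significant digits.
    """
    df = df.copy()
    pcols = set(pvalue_columns) | {c for c in df.columns if c.startswith("p_")}
    for c in df.columns:
        if c in pcols:
            df[c] = df[c].map(lambda v: "NA" if pd.isna(v) else f"{v:.6E}")
        elif pd.api.types.is_float_dtype(df[c]):
            df[c] = df[c].map(lambda v: "NA" if pd.isna(v) else f"{v:.12g}")
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)
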