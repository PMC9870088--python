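"""Plain-text readers and writers for the screen's file formats.

All genomic coordinates are 0-based half-open (BED convention). Every writer
has a matching reader and the pair round-trips losslessly; files are written
with ``\n`` line endings and no trailing whitespace so outputs are
byte-reproducible under a fixed seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

GENE_COLUMNS = ["gene_id", "chrom", "strand", "start", "end", "tss"]
GWAS_COLUMNS = ["snp_id", "chrom", "pos", "pvalue"]
BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


# ---------------------------------------------------------------------------
# gene annotation


def write_gene_annotation(genome: pd.DataFrame, path) -> None:
    genome.loc[:, GENE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_gene_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(GENE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"gene annotation {path} lacks columns: {sorted(missing)}")
    return df[GENE_COLUMNS]


# ---------------------------------------------------------------------------
# peaks (BED6, optional 7th column = summit position)


def write_bed(peaks: pd.DataFrame, path) -> None:
    cols = list(BED_COLUMNS)
    if "summit" in peaks.columns:
        cols.append("summit")
    peaks.loc[:, cols].to_csv(path, sep="\t", index=False, header=False)


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, dtype={0: str})
    ncol = df.shape[1]
    if ncol < 3:
        raise ValueError(f"{path}: BED needs at least 3 columns, got {ncol}")
    names = BED_COLUMNS[: min(ncol, 6)]
    if ncol == 7:
        names = BED_COLUMNS + ["summit"]
    df.columns = names + [f"extra{i}" for i in range(ncol - len(names))]
    if "name" not in df.columns:
        df["name"] = [f"peak_{i + 1:06d}" for i in range(len(df))]
    if "score" not in df.columns:
        df["score"] = 0
    if "strand" not in df.columns:
        df["strand"] = "."
    keep = BED_COLUMNS + (["summit"] if "summit" in df.columns else [])
    return df[keep]


# ---------------------------------------------------------------------------
# GWAS summary statistics


def write_gwas(gwas: pd.DataFrame, path) -> None:
    gwas.loc[:, GWAS_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_gwas(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, float_precision="round_trip")
    missing = set(GWAS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"GWAS table {path} lacks columns: {sorted(missing)}")
    bad = df["pvalue"].le(0) | df["pvalue"].gt(1)
    if bad.any():
        raise ValueError(f"{path}: {int(bad.sum())} p-values outside (0, 1]")
    return df[GWAS_COLUMNS]


# ---------------------------------------------------------------------------
# expression matrix (genes x samples; first column gene_id)


def write_expression(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id")


def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


# ---------------------------------------------------------------------------
# counts + condition map


def write_counts(counts: pd.DataFrame, conditions: pd.Series, counts_path, conditions_path) -> None:
    counts.to_csv(counts_path, sep="\t", index_label="peak")
    conditions.rename("condition").to_csv(conditions_path, sep="\t", index_label="sample")


def read_counts(counts_path, conditions_path):
    counts = pd.read_csv(counts_path, sep="\t", index_col="peak")
    conditions = pd.read_csv(conditions_path, sep="\t", index_col="sample")["condition"]
    if list(conditions.index) != list(counts.columns):
        conditions = conditions.reindex(counts.columns)
        if conditions.isna().any():
            raise ValueError("condition map does not cover all count columns")
    return counts, conditions


# ---------------------------------------------------------------------------
# secretome flags


def write_secretome(table: pd.DataFrame, path) -> None:
    out = table.loc[:, ["gene_id", "secreted"]].copy()
    out["secreted"] = out["secreted"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def read_secretome(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["secreted"] = df["secreted"].astype(bool)
    return df[["gene_id", "secreted"]]


# ---------------------------------------------------------------------------
# GMT gene-set libraries


def write_gmt(library: dict, path) -> None:
    with open(path, "w") as fh:
        for name in library:
            genes = sorted(library[name])
            fh.write("\t".join([name, "."] + list(genes)) + "\n")


def read_gmt(path) -> dict:
    library: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: GMT line with fewer than 3 fields")
            library[fields[0]] = set(fields[2:])
    return library


# ---------------------------------------------------------------------------
# JSON helpers


def write_json(obj, path, canonical: bool = True) -> None:
    Path(path).write_text(dumps_canonical(obj) if canonical else json.dumps(obj, indent=2) + "\n")


def dumps_canonical(obj) -> str:
    return json.dumps(obj, sort_keys=True, indent=2, default=_json_default) + "\n"


def _json_default(value):
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, (set, frozenset)):
        return sorted(value)
    raise TypeError(f"not JSON serializable: {type(value)!r}")


def read_json(path):
    return json.loads(Path(path).read_text())
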