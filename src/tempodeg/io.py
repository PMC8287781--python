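"""Tabular input/output for NanoString-style panel analyses.

All interchange is delimited text (CSV or TSV, chosen by file extension).
The central container is :class:`CountTable`: a genes × samples matrix of raw
molecule counts, each gene carrying one of the four nCounter code classes
(``Endogenous``, ``Housekeeping``, ``Positive``, ``Negative``). Sample
metadata, gene annotations, GMT gene sets and precomputed fold-change/p-value
comparison tables all have their own validated readers. Writers prepend a
``# run_id:`` comment when asked; every reader skips ``#`` comment lines.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

CODE_CLASSES = ("Endogenous", "Housekeeping", "Positive", "Negative")
GROUPS = ("sham", "TBI")
TREATMENTS = ("none", "vehicle", "CR2-Crry")
TIMEPOINTS = ("baseline", "d3", "d7", "d28", "y1", "y2")
AGE_CLASSES = ("12wk", "1y", "2y")

SAMPLE_SHEET_COLUMNS = ("sample_id", "group", "treatment", "timepoint", "age_class")


class PanelIOError(ValueError):
    """Structured parse/validation error for panel artifacts."""


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


@dataclass
class CountTable:
    """Raw panel counts with per-gene code class.

    Parameters
    ----------
    counts
        Non-negative integer matrix, genes as rows (index = gene ids),
        samples as columns.
    code_class
        Per-gene code class, index-aligned with ``counts``.
    """

    counts: pd.DataFrame
    code_class: pd.Series

    def __post_init__(self) -> None:
        genes = self.counts.index
        if genes.duplicated().any():
            dup = genes[genes.duplicated()][0]
            raise PanelIOError(f"duplicate gene id: {dup!r}")
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise PanelIOError(f"duplicate sample id: {dup!r}")
        if not genes.equals(self.code_class.index):
            self.code_class = self.code_class.reindex(genes)
        unknown = set(self.code_class.dropna().unique()) - set(CODE_CLASSES)
        if unknown or self.code_class.isna().any():
            raise PanelIOError(
                f"unknown code class(es) {sorted(map(str, unknown))}; "
                f"allowed: {list(CODE_CLASSES)}"
            )
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise PanelIOError("counts must be numeric")
        if (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise PanelIOError(
                f"negative count {arr[r, c]} at gene {genes[r]!r}, "
                f"sample {self.counts.columns[c]!r}"
            )
        if not np.allclose(arr, np.round(arr)):
            r, c = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
            raise PanelIOError(
                f"non-integer count {arr[r, c]} at gene {genes[r]!r}, "
                f"sample {self.counts.columns[c]!r}"
            )
        self.counts = self.counts.astype(np.int64)

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def genes_of_class(self, code_class: str) -> pd.Index:
        return self.counts.index[self.code_class == code_class]

    def require_all_classes(self) -> None:
        """Normalization needs at least one gene of each code class."""
        for cc in CODE_CLASSES:
            if len(self.genes_of_class(cc)) == 0:
                raise PanelIOError(f"no genes with code class {cc!r}")

    def to_frame(self) -> pd.DataFrame:
        out = self.counts.copy()
        out.insert(0, "code_class", self.code_class)
        out.index.name = "gene_id"
        return out.reset_index()


def read_count_table(path: str | Path, sep: str | None = None) -> CountTable:
    """Read a count table (columns: gene_id, code_class, one per sample)."""
    path = Path(path)
    if not path.exists():
        raise PanelIOError(f"count table not found: {path}")
    df = pd.read_csv(path, sep=sep or _sep_for(path), comment="#")
    for col in ("gene_id", "code_class"):
        if col not in df.columns:
            raise PanelIOError(f"count table missing required column {col!r}")
    counts = df.set_index("gene_id").drop(columns=["code_class"])
    return CountTable(counts=counts, code_class=df.set_index("gene_id")["code_class"])


def write_count_table(table: CountTable, path: str | Path, run_id: str | None = None) -> None:
    _write_with_header(table.to_frame(), path, run_id)


def _write_with_header(df: pd.DataFrame, path: str | Path, run_id: str | None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if run_id is not None:
            fh.write(f"# run_id: {run_id}\n")
        df.to_csv(fh, sep=_sep_for(path), index=False)


def validate_sample_sheet(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise PanelIOError(f"sample sheet missing columns: {missing}")
    df = df.loc[:, list(SAMPLE_SHEET_COLUMNS)].copy()
    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
        raise PanelIOError(f"duplicate sample_id: {dup!r}")
    for col, allowed in (
        ("group", GROUPS),
        ("treatment", TREATMENTS),
        ("timepoint", TIMEPOINTS),
        ("age_class", AGE_CLASSES),
    ):
        bad = set(df[col].unique()) - set(allowed)
        if bad:
            raise PanelIOError(
                f"unknown {col} value(s) {sorted(map(str, bad))}; allowed: {list(allowed)}"
            )
    sham_treated = df[(df["group"] == "sham") & (df["treatment"] != "none")]
    if len(sham_treated):
        raise PanelIOError(
            "sham samples must have treatment 'none': "
            + ", ".join(sham_treated["sample_id"].astype(str))
        )
    return df.reset_index(drop=True)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep_for(path), comment="#")
    return validate_sample_sheet(df)


def write_sample_sheet(samples: pd.DataFrame, path: str | Path, run_id: str | None = None) -> None:
    _write_with_header(samples, path, run_id)


def select_samples(samples: pd.DataFrame, **criteria: str | Sequence[str]) -> list[str]:
    """Sample ids matching all criteria (value or list of values per column)."""
    mask = pd.Series(True, index=samples.index)
    for col, val in criteria.items():
        if col not in samples.columns:
            raise PanelIOError(f"unknown sample-sheet column {col!r}")
        if isinstance(val, str):
            mask &= samples[col] == val
        else:
            mask &= samples[col].isin(list(val))
    return samples.loc[mask, "sample_id"].tolist()


def _split_multi(cell: object) -> frozenset[str]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == "":
        return frozenset()
    return frozenset(p for p in re.split(r"[|;]", str(cell)) if p)


def read_gene_annotations(path: str | Path) -> pd.DataFrame:
    """Gene annotation table: pathways and marker classes per gene.

    Expected columns: ``gene_id``, ``pathways`` (``|``-separated), optionally
    ``marker_classes`` (``|``-separated), ``complement_class`` and
    ``complement_pathway``. Multi-membership cells become frozensets.
    """
    df = pd.read_csv(path, sep=_sep_for(path), comment="#")
    if "gene_id" not in df.columns:
        raise PanelIOError("annotation table missing 'gene_id' column")
    out = pd.DataFrame({"gene_id": df["gene_id"].astype(str)})
    out["pathways"] = (
        df["pathways"].map(_split_multi) if "pathways" in df else [frozenset()] * len(df)
    )
    out["marker_classes"] = (
        df["marker_classes"].map(_split_multi)
        if "marker_classes" in df
        else [frozenset()] * len(df)
    )
    for col in ("complement_class", "complement_pathway"):
        out[col] = df[col] if col in df else pd.NA
    if out["gene_id"].duplicated().any():
        dup = out["gene_id"][out["gene_id"].duplicated()].iloc[0]
        raise PanelIOError(f"duplicate gene_id in annotations: {dup!r}")
    return out


def read_gmt(path: str | Path) -> dict[str, frozenset[str]]:
    """Parse a GMT gene-set file (name, description, genes...)."""
    sets: dict[str, frozenset[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise PanelIOError(f"GMT line {lineno}: expected ≥3 tab-separated fields")
            name = fields[0]
            if name in sets:
                raise PanelIOError(f"GMT line {lineno}: duplicate set name {name!r}")
            sets[name] = frozenset(g for g in fields[2:] if g)
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, name] + sorted(genes)) + "\n")


@dataclass
class ComparisonTableSpec:
    """Column mapping for an externally produced fold-change/p-value table.

    ``fc_convention`` is ``"signed"`` (|fc| ≥ 1, negative means down) or
    ``"ratio"`` (plain ratio, converted to the signed convention on read).
    """

    gene: str = "gene_id"
    fold_change: str = "fold_change"
    p_value: str = "p_value"
    fdr: str | None = None
    contrast: str | None = None
    fc_convention: str = "signed"


def read_comparison_table(
    path: str | Path,
    spec: ComparisonTableSpec | None = None,
    contrast_id: str | None = None,
) -> pd.DataFrame:
    """Read a precomputed per-gene comparison table.

    Returns a tidy frame with columns ``gene_id``, ``contrast_id``,
    ``fc_signed``, ``p_value`` and (if supplied) ``fdr``, row order preserved.
    ``contrast_id`` must come either from a contrast column or the argument.
    """
    spec = spec or ComparisonTableSpec()
    df = pd.read_csv(path, sep=_sep_for(path), comment="#")
    for col in (spec.gene, spec.fold_change, spec.p_value):
        if col not in df.columns:
            raise PanelIOError(f"comparison table missing column {col!r}")
    p = pd.to_numeric(df[spec.p_value])
    if ((p < 0) | (p > 1)).any():
        bad = p[(p < 0) | (p > 1)].iloc[0]
        raise PanelIOError(f"p-value outside [0,1]: {bad}")
    fc = pd.to_numeric(df[spec.fold_change]).astype(float)
    if spec.fc_convention == "ratio":
        if (fc <= 0).any():
            raise PanelIOError("ratio fold changes must be positive")
        fc = np.where(fc >= 1.0, fc, -1.0 / fc)
    elif spec.fc_convention == "signed":
        if (np.abs(fc) < 1.0).any():
            bad = fc[np.abs(fc) < 1.0].iloc[0]
            raise PanelIOError(
                f"signed fold change with |fc| < 1: {bad} "
                "(use fc_convention='ratio' for plain ratios)"
            )
    else:
        raise PanelIOError(f"unknown fc_convention {spec.fc_convention!r}")
    if spec.contrast is not None:
        contrast = df[spec.contrast].astype(str)
    elif contrast_id is not None:
        contrast = contrast_id
    else:
        raise PanelIOError("supply contrast_id or a contrast column mapping")
    out = pd.DataFrame(
        {
            "gene_id": df[spec.gene].astype(str),
            "contrast_id": contrast,
            "fc_signed": np.asarray(fc, dtype=float),
            "p_value": p.astype(float),
        }
    )
    if spec.fdr is not None:
        out["fdr"] = pd.to_numeric(df[spec.fdr]).astype(float)
    return out


def write_table(df: pd.DataFrame, path: str | Path, run_id: str | None = None) -> None:
    """Write a tidy result table as delimited text (UTF-8, RFC-4180 quoting).

    Set-valued columns are serialized as ``+``-joined sorted members.
    """
    df = df.copy()
    for col in df.columns:
        if df[col].map(lambda v: isinstance(v, (set, frozenset))).any():
            df[col] = df[col].map(lambda v: "+".join(sorted(v)) if isinstance(v, (set, frozenset)) else v)
    _write_with_header(df, path, run_id)
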