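"""Pathway-level summaries and gene-set over-representation analysis.

Pathway summaries aggregate per-contrast DE results by annotation pathway:
the median *signed linear* fold change over up- and over down-regulated DEGs
(the signed convention puts the null at ±1, so a loss of low-fold-change
DEGs moves the median away from ±1 even as the count drops) and DEG counts,
optionally keyed by temporal pattern label or treatment-effect category.
A gene annotated to k pathways contributes to all k.

Over-representation uses the upper-tail hypergeometric test
P(X ≥ overlap), X ~ Hypergeom(|universe|, |set ∩ universe|, |selected|),
with BH adjustment across the tested sets — the standard ORA any pathway
database front-end performs, run here on user-supplied GMT sets.
"""

from __future__ import annotations

from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .diffexpr import bh_fdr

MARKER_CLASSES = ("A1", "A2", "PAN_reactive", "DAM", "reactive_oligodendrocyte")


def _annotation_pathways(annotations: pd.DataFrame) -> pd.DataFrame:
    """Explode the per-gene pathway sets into (gene_id, pathway) rows."""
    rows = [
        {"gene_id": g, "pathway": p}
        for g, ps in zip(annotations["gene_id"], annotations["pathways"])
        for p in ps
    ]
    return pd.DataFrame(rows, columns=["gene_id", "pathway"])


def pathway_deg_summary(
    results: Mapping[str, pd.DataFrame],
    annotations: pd.DataFrame,
    grouping: str = "timepoint",
    category_by_gene: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-pathway DEG medians and counts.

    ``results`` maps time point → ContrastResult frame. ``grouping`` is
    ``"timepoint"`` (counts split by direction only) or
    ``"effect_category"``/``"pattern"`` with ``category_by_gene`` supplying
    a per-gene label whose tallies are reported per pathway × time point.
    Pathways with no DEGs at a time point report zero counts and no median.
    """
    if grouping not in ("timepoint", "effect_category", "pattern"):
        raise ValueError(f"unknown grouping {grouping!r}")
    if grouping != "timepoint" and category_by_gene is None:
        raise ValueError(f"grouping {grouping!r} needs category_by_gene")
    memb = _annotation_pathways(annotations)
    rows = []
    for tp, res in results.items():
        merged = memb.merge(res, on="gene_id", how="inner")
        for pathway, sub in merged.groupby("pathway", sort=True):
            up = sub[sub["direction"] == "up"]
            down = sub[sub["direction"] == "down"]
            row = {
                "pathway": pathway,
                "timepoint": tp,
                "n_up": len(up),
                "n_down": len(down),
                "median_fc_up": float(up["fc_signed"].median()) if len(up) else np.nan,
                "median_fc_down": float(down["fc_signed"].median()) if len(down) else np.nan,
            }
            if grouping != "timepoint":
                degs = sub[sub["de_flag"]]
                tally = (
                    degs["gene_id"].map(lambda g: category_by_gene.get(g, "unknown"))
                    .value_counts()
                )
                for cat, n in tally.items():
                    row[f"n_{cat}"] = int(n)
            rows.append(row)
    out = pd.DataFrame(rows)
    if grouping != "timepoint":
        count_cols = [c for c in out.columns if c.startswith("n_") and c not in ("n_up", "n_down")]
        out[count_cols] = out[count_cols].fillna(0).astype(int)
    return out.sort_values(["pathway", "timepoint"]).reset_index(drop=True)


def ora_hypergeometric(
    selected: Sequence[str],
    universe: Sequence[str],
    gene_sets: Mapping[str, frozenset[str] | set[str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation per gene set."""
    selected = set(selected)
    universe = set(universe)
    stray = selected - universe
    if stray:
        raise ValueError(f"selected genes outside universe: {sorted(stray)[:10]}")
    M, n = len(universe), len(selected)
    rows = []
    for name, genes in gene_sets.items():
        in_universe = set(genes) & universe
        K = len(in_universe)
        overlap = len(in_universe & selected)
        p = float(hypergeom.sf(overlap - 1, M, K, n)) if K else 1.0
        rows.append(
            {
                "set_name": name,
                "universe_size": M,
                "set_size": K,
                "n_selected": n,
                "overlap": overlap,
                "p_value": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = bh_fdr(out["p_value"].to_numpy())
        out["significant"] = out["fdr"] < alpha
        out = out.sort_values(["p_value", "set_name"], kind="stable").reset_index(drop=True)
    return out


def load_marker_fixture() -> pd.DataFrame:
    """Packaged marker-class gene lists (editable data, columns
    ``marker_class``, ``gene_id``): A1/A2/PAN reactive astrocytes,
    disease-associated microglia, reactive oligodendrocytes."""
    with resources.files("tempodeg.data").joinpath("markers.csv").open() as fh:
        return pd.read_csv(fh, comment="#")


def marker_report(
    level_tests: Mapping[str, pd.DataFrame],
    panel_genes: Sequence[str],
    markers: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per marker class: panel presence and genes with reduced level.

    A gene counts as reduced when its level effect is ``reduced`` at any
    tested time point. Marker genes absent from the panel are tallied, not
    errors.
    """
    markers = markers if markers is not None else load_marker_fixture()
    panel = set(panel_genes)
    reduced: set[str] = set()
    for lt in level_tests.values():
        reduced |= set(lt.loc[lt["level_effect"] == "reduced", "gene_id"])
    rows = []
    for mclass, sub in markers.groupby("marker_class", sort=True):
        genes = set(sub["gene_id"])
        on_panel = genes & panel
        red = sorted(on_panel & reduced)
        rows.append(
            {
                "marker_class": mclass,
                "n_on_panel": len(on_panel),
                "n_absent": len(genes - panel),
                "n_reduced": len(red),
                "reduced_genes": "+".join(red),
            }
        )
    return pd.DataFrame(rows)
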