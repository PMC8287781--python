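"""Two-group differential expression on log2 normalized panel counts.

The testing convention follows the nSolver workflow this package reimplements:
a Welch two-sample t-test per gene on log2 normalized counts (no pseudocount —
background thresholding guarantees positivity), a signed linear fold change
(ratio r reported as r when r ≥ 1, else −1/r, so up- and down-regulation are
symmetric around ±1), and Benjamini–Hochberg FDR per contrast across all panel
genes with **no fold-change cutoff**: a gene is differentially expressed iff
FDR < alpha.

Two FDR variants are provided. ``bh_fdr`` is the standard step-up procedure.
``conditional_bh_fdr`` is a sensitivity-boosting variant used for the
complement-panel and injured-vs-injured contrasts: BH is applied only to the
genes with raw p < 0.05 (m = size of that subset) and every other gene
receives an adjusted value of 1. This is deliberately anti-conservative at
very chronic time points with small n and high intra-group variability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import select_samples

P_SUBSET_CUTOFF = 0.05  # raw-p gate of the conditional FDR variant


def welch_t_test(x, y) -> tuple[float, float]:
    """Welch t statistic (Satterthwaite df) and two-sided p for one gene.

    Degenerate variances follow an explicit convention: both groups constant
    with equal means → (0, 1); both constant with unequal means → (±inf, 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 samples")
    t, p = _vectorized_welch(x[None, :], y[None, :])
    return float(t[0]), float(p[0])


def _vectorized_welch(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Welch test; rows are genes. Handles zero-variance rows."""
    nx, ny = x.shape[1], y.shape[1]
    mx, my = x.mean(axis=1), y.mean(axis=1)
    vx, vy = x.var(axis=1, ddof=1), y.var(axis=1, ddof=1)
    denom2 = vx / nx + vy / ny
    diff = mx - my
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(denom2)
        df = denom2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    degenerate = denom2 == 0
    equal = degenerate & (diff == 0)
    unequal = degenerate & (diff != 0)
    with np.errstate(invalid="ignore"):
        t = np.where(equal, 0.0, t)
        p = np.where(equal, 1.0, p)
        t = np.where(unequal, np.sign(diff) * np.inf, t)
        p = np.where(unequal, 0.0, p)
    return t, p


def signed_fold_change(mean_log2_test, mean_log2_ref):
    """Signed linear fold change from a log2 difference; |result| ≥ 1."""
    diff = np.asarray(mean_log2_test, dtype=float) - np.asarray(mean_log2_ref, dtype=float)
    r = 2.0**diff
    out = np.where(r >= 1.0, r, -1.0 / r)
    return out if out.ndim else float(out)


def log2fc_from_signed(fc_signed):
    """Inverse of :func:`signed_fold_change`."""
    fc = np.asarray(fc_signed, dtype=float)
    out = np.where(fc >= 0, np.log2(np.abs(fc)), -np.log2(np.abs(fc)))
    return out if out.ndim else float(out)


def bh_fdr(p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values, original order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def conditional_bh_fdr(p: Sequence[float], p_cutoff: float = P_SUBSET_CUTOFF) -> np.ndarray:
    """BH restricted to the genes with raw p below ``p_cutoff``.

    Genes outside the subset get adjusted value 1 (never called DE); inside
    the subset, the adjustment uses m = subset size.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.ones_like(p)
    mask = p < p_cutoff
    if mask.any():
        out[mask] = bh_fdr(p[mask])
    return out


FDR_MODES = {"standard": bh_fdr, "conditional": conditional_bh_fdr}


@dataclass(frozen=True)
class Contrast:
    """A named two-group comparison defined by sample-sheet selectors."""

    name: str
    test: dict
    ref: dict
    fdr_mode: str = "standard"


def contrast_results(
    log2fc: np.ndarray,
    p: np.ndarray,
    gene_ids: Sequence[str],
    fdr_mode: str = "standard",
    alpha: float = 0.05,
    n_test: int | None = None,
    n_ref: int | None = None,
) -> pd.DataFrame:
    """Assemble a per-gene result frame from effect sizes and p-values."""
    if fdr_mode not in FDR_MODES:
        raise ValueError(f"fdr_mode must be one of {sorted(FDR_MODES)}")
    fdr = FDR_MODES[fdr_mode](p)
    de = fdr < alpha
    direction = np.where(~de, "none", np.where(log2fc > 0, "up", "down"))
    return pd.DataFrame(
        {
            "gene_id": list(gene_ids),
            "log2fc": log2fc,
            "fc_signed": signed_fold_change(log2fc, 0.0),
            "p_value": p,
            "fdr": fdr,
            "de_flag": de,
            "direction": direction,
            "n_test": n_test if n_test is not None else -1,
            "n_ref": n_ref if n_ref is not None else -1,
        }
    )


def compare_groups(
    norm_matrix: pd.DataFrame,
    samples: pd.DataFrame,
    test: dict,
    ref: dict,
    fdr_mode: str = "standard",
    alpha: float = 0.05,
    statistic: str = "welch",
) -> pd.DataFrame:
    """Per-gene two-group DE between two sample selections.

    ``test``/``ref`` are sample-sheet selectors, e.g.
    ``{"group": "TBI", "timepoint": "d7", "treatment": "vehicle"}`` vs
    ``{"group": "sham"}``. Values are log2-transformed normalized counts.
    """
    test_ids = select_samples(samples, **test)
    ref_ids = select_samples(samples, **ref)
    if len(test_ids) < 2 or len(ref_ids) < 2:
        raise ValueError(
            f"both groups need ≥2 samples (got {len(test_ids)} test, {len(ref_ids)} ref)"
        )
    x = np.log2(norm_matrix[test_ids].to_numpy(dtype=float))
    y = np.log2(norm_matrix[ref_ids].to_numpy(dtype=float))
    if statistic == "welch":
        t, p = _vectorized_welch(x, y)
    elif statistic == "student":
        t, p = stats.ttest_ind(x, y, axis=1, equal_var=True)
        p = np.nan_to_num(p, nan=1.0)
    elif statistic == "mann-whitney":
        res = stats.mannwhitneyu(x, y, axis=1, alternative="two-sided")
        p = res.pvalue
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    log2fc = x.mean(axis=1) - y.mean(axis=1)
    return contrast_results(
        log2fc,
        np.asarray(p, dtype=float),
        norm_matrix.index,
        fdr_mode=fdr_mode,
        alpha=alpha,
        n_test=len(test_ids),
        n_ref=len(ref_ids),
    )


def results_from_comparison_table(
    comparison: pd.DataFrame,
    contrast_id: str,
    fdr_mode: str = "standard",
    alpha: float = 0.05,
    use_precomputed_fdr: bool = False,
) -> pd.DataFrame:
    """Turn one contrast of an ingested comparison table into a result frame.

    This is the reproduction path for analyses whose fold changes and
    p-values were exported by external software: the downstream temporal,
    treatment and pathway modules consume the output exactly as if it came
    from :func:`compare_groups`.
    """
    sub = comparison[comparison["contrast_id"] == contrast_id]
    if sub.empty:
        raise ValueError(f"contrast {contrast_id!r} not present in comparison table")
    log2fc = log2fc_from_signed(sub["fc_signed"].to_numpy())
    p = sub["p_value"].to_numpy(dtype=float)
    if use_precomputed_fdr:
        if "fdr" not in sub.columns:
            raise ValueError("comparison table carries no precomputed fdr column")
        fdr = sub["fdr"].to_numpy(dtype=float)
        de = fdr < alpha
        res = pd.DataFrame(
            {
                "gene_id": sub["gene_id"].to_numpy(),
                "log2fc": log2fc,
                "fc_signed": sub["fc_signed"].to_numpy(dtype=float),
                "p_value": p,
                "fdr": fdr,
                "de_flag": de,
                "direction": np.where(~de, "none", np.where(log2fc > 0, "up", "down")),
                "n_test": -1,
                "n_ref": -1,
            }
        )
        return res
    return contrast_results(log2fc, p, sub["gene_id"], fdr_mode=fdr_mode, alpha=alpha)


def baseline_expression_ranking(
    norm_matrix: pd.DataFrame,
    samples: pd.DataFrame,
    gene_subset: Sequence[str] | None = None,
    annotations: pd.DataFrame | None = None,
    **selector,
) -> pd.DataFrame:
    """Rank genes by mean normalized count in a baseline sample selection.

    Default selection is the uninjured (sham) group. Ties are broken by
    gene id so the ordering is stable. Annotation columns (complement class
    and pathway) are carried through when an annotation table is given.
    """
    selector = selector or {"group": "sham"}
    ids = select_samples(samples, **selector)
    if not ids:
        raise ValueError(f"no samples match selector {selector!r}")
    genes = list(gene_subset) if gene_subset is not None else list(norm_matrix.index)
    if not genes:
        return pd.DataFrame(columns=["gene_id", "mean_count"])
    means = norm_matrix.loc[genes, ids].mean(axis=1)
    out = pd.DataFrame({"gene_id": genes, "mean_count": means.to_numpy()})
    out = out.sort_values(
        ["mean_count", "gene_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    if annotations is not None:
        out = out.merge(
            annotations[["gene_id", "complement_class", "complement_pathway"]],
            on="gene_id",
            how="left",
        )
    return out


def qpcr_relative_expression(ct_target, ct_reference):
    """Relative expression by the 2^−ΔCT method (ΔCT = target − reference)."""
    return 2.0 ** -(np.asarray(ct_target, dtype=float) - np.asarray(ct_reference, dtype=float))
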