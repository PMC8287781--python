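"""nSolver-style preprocessing of nCounter panel counts.

Three stages, mirroring the vendor pipeline:

1. **Background thresholding** — a per-sample floor θ_s estimated from the
   negative-control probes (default: mean + 2 sd); endogenous and
   housekeeping counts below θ_s are raised to θ_s, guaranteeing strictly
   positive values for downstream log transforms.
2. **Housekeeping selection** — candidate reference genes (code class
   ``Housekeeping``) are kept when their percent coefficient of variation
   across samples is strictly below a threshold (default 15%).
3. **Normalization factors** — each sample is scaled by
   f_s = reference_mean / g_s, where g_s is the geometric mean of the
   selected housekeeping genes in sample s and reference_mean is the
   arithmetic mean of the g_s across samples.

An optional positive-control (lane) normalization step is available but off
by default.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import CountTable


class NormalizationError(ValueError):
    pass


def geometric_mean(values) -> float:
    """exp(mean(log x)) of strictly positive values."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise NormalizationError("geometric mean of empty input")
    if (arr <= 0).any():
        raise NormalizationError("geometric mean requires strictly positive values")
    return float(np.exp(np.mean(np.log(arr))))


def percent_cv(values) -> float:
    """100 × sample standard deviation (ddof=1) / mean."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise NormalizationError("%CV needs at least 2 values")
    mean = arr.mean()
    if mean == 0:
        raise NormalizationError("%CV undefined for zero mean")
    return float(100.0 * arr.std(ddof=1) / mean)


@dataclass
class NormalizationModel:
    """Fitted preprocessing parameters for one run."""

    background_threshold: pd.Series  # θ_s per sample
    housekeeping_set: list[str]
    normalization_factor: pd.Series  # f_s per sample
    cv_table: pd.DataFrame  # per candidate: percent_cv, mean_count, selected
    reference_mean: float
    background_method: str = "mean2sd"
    positive_factor: pd.Series | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "background_method": self.background_method,
            "background_threshold": self.background_threshold.round(10).to_dict(),
            "housekeeping_set": list(self.housekeeping_set),
            "normalization_factor": self.normalization_factor.round(10).to_dict(),
            "reference_mean": self.reference_mean,
            "cv_table": self.cv_table.round(10).to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def background_threshold(
    table: CountTable, method: str = "mean2sd", fixed: float | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Estimate θ_s from negative controls and floor biological counts.

    ``method``: ``"mean2sd"`` (mean + 2 sd of negatives, the vendor default),
    ``"mean"``, ``"fixed"`` (use ``fixed``) or ``"off"``. The effective floor
    is max(θ_s, 1) so logarithms stay defined even for degenerate negatives.
    Only Endogenous and Housekeeping rows are thresholded; control rows pass
    through unchanged.
    """
    counts = table.counts.astype(float)
    samples = table.sample_ids
    if method == "off":
        theta = pd.Series(0.0, index=samples)
    elif method == "fixed":
        if fixed is None:
            raise NormalizationError("method 'fixed' requires a threshold value")
        theta = pd.Series(float(fixed), index=samples)
    elif method in ("mean", "mean2sd"):
        neg = counts.loc[table.genes_of_class("Negative")]
        if neg.shape[0] < 2:
            raise NormalizationError(
                "background thresholding needs ≥2 negative-control probes; "
                "pass method='off' to disable thresholding explicitly"
            )
        theta = neg.mean(axis=0)
        if method == "mean2sd":
            theta = theta + 2.0 * neg.std(axis=0, ddof=1)
    else:
        raise NormalizationError(f"unknown background method {method!r}")
    floor = theta.clip(lower=1.0)
    out = counts.copy()
    bio = table.code_class.isin(["Endogenous", "Housekeeping"]).to_numpy()
    out.loc[bio] = out.loc[bio].clip(lower=floor, axis=1)
    return out, theta


def select_housekeeping(
    thresholded: pd.DataFrame,
    code_class: pd.Series,
    cv_threshold: float = 15.0,
    sample_subset: list[str] | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Keep housekeeping candidates with %CV strictly below the threshold.

    %CV is computed on background-thresholded raw counts across all samples
    (or an explicit subset). Also reports the selected set's expression range
    (max/min of per-gene means) and warns when the set is small (<3 genes) or
    its dynamic range is under 10-fold — the selected genes should span a
    broad range of expression to normalize both low and high expressors.
    """
    candidates = code_class.index[code_class == "Housekeeping"]
    if len(candidates) == 0:
        raise NormalizationError("no Housekeeping-class candidates present")
    sub = thresholded.loc[candidates]
    if sample_subset is not None:
        sub = sub[sample_subset]
    cv = sub.apply(percent_cv, axis=1)
    means = sub.mean(axis=1)
    table = pd.DataFrame(
        {"percent_cv": cv, "mean_count": means, "selected": cv < cv_threshold}
    )
    table.index.name = "gene_id"
    selected = table.index[table["selected"]].tolist()
    if not selected:
        raise NormalizationError(
            f"no housekeeping candidate has %CV below {cv_threshold}; "
            "relax cv_threshold or inspect the run"
        )
    sel_means = means.loc[selected]
    spread = float(sel_means.max() / sel_means.min())
    if len(selected) < 3:
        warnings.warn(
            f"only {len(selected)} housekeeping gene(s) selected", stacklevel=2
        )
    if spread < 10.0:
        warnings.warn(
            f"selected housekeeping genes span only {spread:.1f}-fold in mean "
            "expression (≥10-fold expected)",
            stacklevel=2,
        )
    return selected, table


def normalization_factors(
    thresholded: pd.DataFrame, housekeeping_set: list[str]
) -> tuple[pd.Series, float]:
    """Per-sample scale factors f_s = reference_mean / g_s."""
    if not housekeeping_set:
        raise NormalizationError("empty housekeeping set")
    g = thresholded.loc[housekeeping_set].apply(geometric_mean, axis=0)
    reference_mean = float(g.mean())
    return reference_mean / g, reference_mean


def positive_control_factors(table: CountTable) -> pd.Series:
    """Lane normalization factors from positive-control geometric means."""
    pos = table.counts.loc[table.genes_of_class("Positive")].astype(float)
    if pos.shape[0] == 0:
        raise NormalizationError("no Positive-class controls present")
    g = pos.clip(lower=1.0).apply(geometric_mean, axis=0)
    return float(g.mean()) / g


def normalize_counts(
    table: CountTable,
    cv_threshold: float = 15.0,
    background: str = "mean2sd",
    background_fixed: float | None = None,
    positive_control: bool = False,
    sample_subset: list[str] | None = None,
) -> tuple[pd.DataFrame, NormalizationModel]:
    """Full preprocessing: threshold → select housekeeping → scale.

    Returns the normalized Endogenous + Housekeeping matrix (strictly
    positive floats) and the fitted :class:`NormalizationModel`.
    """
    table.require_all_classes()
    pos_f = None
    work = table
    if positive_control:
        pos_f = positive_control_factors(table)
        scaled = table.counts.astype(float).mul(pos_f, axis=1)
        work = CountTable(counts=scaled.round().astype(int), code_class=table.code_class)
    thresholded, theta = background_threshold(work, method=background, fixed=background_fixed)
    selected, cv_table = select_housekeeping(
        thresholded, table.code_class, cv_threshold=cv_threshold, sample_subset=sample_subset
    )
    factors, reference_mean = normalization_factors(thresholded, selected)
    bio = table.code_class.isin(["Endogenous", "Housekeeping"])
    normalized = thresholded.loc[bio.to_numpy()].mul(factors, axis=1)
    model = NormalizationModel(
        background_threshold=theta,
        housekeeping_set=selected,
        normalization_factor=factors,
        cv_table=cv_table,
        reference_mean=reference_mean,
        background_method=background,
        positive_factor=pos_f,
    )
    return normalized, model
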