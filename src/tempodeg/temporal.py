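"""Trajectory classification of differential expression across time points.

Given one DE contrast per post-injury time point (each against the shared
uninjured reference), every gene receives:

* its DE time-point sets by direction (``de_up``, ``de_down``),
* a canonical pattern label (``consistent_up``, ``up:d3+d7``,
  ``mixed:up@d3|down@d28``, ...), and
* a **peak-change set**: the DE time points at which the change from
  baseline is strongest, decided by pairwise injured-vs-injured contrasts.

Because all per-time-point contrasts share the same reference group, the
difference of two log2 fold changes equals the difference of the injured
group means — so "is the fold change at t_i significantly different from
t_j" is tested directly as a two-group comparison of the injured samples at
t_i and t_j on log2 normalized counts. The conditional FDR variant is used
for these injured-vs-injured families (higher intra-group variability after
injury). A DE time point is dropped from the peak set when another DE time
point significantly exceeds it in the gene's DE direction; genes with no
significant pairwise difference peak at all their DE time points.
"""

from __future__ import annotations

from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diffexpr import FDR_MODES, _vectorized_welch
from .io import TIMEPOINTS, select_samples

_TP_ORDER = {tp: i for i, tp in enumerate(TIMEPOINTS)}


def _tp_sorted(tps) -> list[str]:
    return sorted(tps, key=lambda t: (_TP_ORDER.get(t, len(_TP_ORDER)), t))


def _join(tps) -> str:
    return "+".join(_tp_sorted(tps))


def pattern_label(
    de_up: frozenset[str] | set[str],
    de_down: frozenset[str] | set[str],
    analyzed: Sequence[str],
) -> str:
    """Canonical, deterministic label for a gene's DE trajectory."""
    up, down = set(de_up), set(de_down)
    if up & down:
        raise ValueError("a gene cannot be up and down at the same time point")
    if not up and not down:
        return "none"
    if not down:
        return "consistent_up" if up == set(analyzed) else f"up:{_join(up)}"
    if not up:
        return "consistent_down" if down == set(analyzed) else f"down:{_join(down)}"
    ups = "|".join(f"up@{t}" for t in _tp_sorted(up))
    downs = "|".join(f"down@{t}" for t in _tp_sorted(down))
    return f"mixed:{ups}|{downs}"


def de_timepoint_sets(
    results: Mapping[str, pd.DataFrame],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene DE time-point sets and per-time-point up/down counts.

    ``results`` maps time point → ContrastResult frame (one row per gene,
    identical gene universe across time points).
    """
    if not results:
        raise ValueError("no contrast results supplied")
    timepoints = _tp_sorted(results.keys())
    universe = None
    for tp, res in results.items():
        genes = pd.Index(res["gene_id"])
        if universe is None:
            universe = genes
        elif not universe.equals(genes) and set(universe) != set(genes):
            raise ValueError(f"gene universe mismatch at time point {tp!r}")
    up_sets: dict[str, set[str]] = {g: set() for g in universe}
    down_sets: dict[str, set[str]] = {g: set() for g in universe}
    counts = []
    for tp in timepoints:
        res = results[tp]
        up = res.loc[res["direction"] == "up", "gene_id"]
        down = res.loc[res["direction"] == "down", "gene_id"]
        counts.append({"timepoint": tp, "n_up": len(up), "n_down": len(down)})
        for g in up:
            up_sets[g].add(tp)
        for g in down:
            down_sets[g].add(tp)
    profiles = pd.DataFrame(
        {
            "gene_id": list(universe),
            "de_up": [frozenset(up_sets[g]) for g in universe],
            "de_down": [frozenset(down_sets[g]) for g in universe],
        }
    )
    profiles["pattern_label"] = [
        pattern_label(u, d, timepoints)
        for u, d in zip(profiles["de_up"], profiles["de_down"])
    ]
    return profiles, pd.DataFrame(counts)


def peak_change_analysis(
    norm_matrix: pd.DataFrame,
    samples: pd.DataFrame,
    profiles: pd.DataFrame,
    timepoints: Sequence[str] = ("d3", "d7", "d28"),
    arm: dict | None = None,
    fdr_mode: str = "conditional",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Identify the time point(s) of peak change for each DE gene.

    Only genes with a single DE direction within ``timepoints`` participate;
    mixed-direction genes are excluded (their ``peak_basis`` is ``mixed``).
    For down-regulated genes "peak change" means the most negative log2 fold
    change. Genes DE at exactly one time point peak there with zero tests.
    """
    if fdr_mode not in FDR_MODES:
        raise ValueError(f"fdr_mode must be one of {sorted(FDR_MODES)}")
    arm = arm or {"group": "TBI", "treatment": "vehicle"}
    tps = _tp_sorted(timepoints)
    arm_ids = {tp: select_samples(samples, timepoint=tp, **arm) for tp in tps}

    restricted = profiles.copy()
    restricted["de_up_r"] = restricted["de_up"].map(lambda s: frozenset(s) & set(tps))
    restricted["de_down_r"] = restricted["de_down"].map(lambda s: frozenset(s) & set(tps))

    gene_dir: dict[str, int] = {}
    gene_de: dict[str, frozenset[str]] = {}
    basis: dict[str, str] = {}
    for _, row in restricted.iterrows():
        g, up, down = row["gene_id"], row["de_up_r"], row["de_down_r"]
        if up and down:
            basis[g] = "mixed"
            continue
        de = up or down
        if not de:
            continue
        gene_dir[g] = 1 if up else -1
        gene_de[g] = de

    # Pairwise injured-vs-injured contrasts; one conditional-FDR family per
    # unordered pair, restricted to the genes DE at both of its time points.
    losers: dict[str, set[str]] = {g: set() for g in gene_de}
    any_sig: set[str] = set()
    for ti, tj in combinations(tps, 2):
        fam = [g for g, de in gene_de.items() if ti in de and tj in de]
        if not fam:
            continue
        ids_i, ids_j = arm_ids[ti], arm_ids[tj]
        if len(ids_i) < 2 or len(ids_j) < 2:
            raise ValueError(
                f"need ≥2 injured samples at {ti} and {tj} for peak analysis"
            )
        xi = np.log2(norm_matrix.loc[fam, ids_i].to_numpy(dtype=float))
        xj = np.log2(norm_matrix.loc[fam, ids_j].to_numpy(dtype=float))
        _, p = _vectorized_welch(xi, xj)
        fdr = FDR_MODES[fdr_mode](p)
        delta = xi.mean(axis=1) - xj.mean(axis=1)  # mean_log2(ti) − mean_log2(tj)
        for g, q, d in zip(fam, fdr, delta):
            if q < alpha and d != 0:
                any_sig.add(g)
                stronger_is_i = (d > 0) == (gene_dir[g] > 0)
                losers[g].add(tj if stronger_is_i else ti)

    records = []
    for _, row in restricted.iterrows():
        g = row["gene_id"]
        if g in gene_de:
            de = gene_de[g]
            if len(de) == 1:
                peak, pb = de, "no_difference_all"
            elif g in any_sig:
                peak, pb = frozenset(de - losers[g]), "pairwise_significant"
            else:
                peak, pb = de, "no_difference_all"
        elif basis.get(g) == "mixed":
            peak, pb = frozenset(), "mixed"
        else:
            peak, pb = frozenset(), "not_de"
        records.append({"gene_id": g, "peak_set": peak, "peak_basis": pb})
    return pd.DataFrame(records)


def temporal_profiles(
    results: Mapping[str, pd.DataFrame],
    norm_matrix: pd.DataFrame | None = None,
    samples: pd.DataFrame | None = None,
    peak_timepoints: Sequence[str] = ("d3", "d7", "d28"),
    arm: dict | None = None,
    fdr_mode: str = "conditional",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """DE sets + pattern labels, with peak analysis when counts are given."""
    profiles, _ = de_timepoint_sets(results)
    if norm_matrix is not None and samples is not None:
        peaks = peak_change_analysis(
            norm_matrix,
            samples,
            profiles,
            timepoints=peak_timepoints,
            arm=arm,
            fdr_mode=fdr_mode,
            alpha=alpha,
        )
        profiles = profiles.merge(peaks, on="gene_id", how="left")
    return profiles


def peak_set_tally(profiles: pd.DataFrame, pattern: str = "consistent_up") -> pd.Series:
    """Count genes per peak set within one pattern label (e.g. the number of
    consistently upregulated genes peaking at each time-point combination)."""
    sub = profiles[profiles["pattern_label"] == pattern]
    return sub["peak_set"].map(_join).value_counts()
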