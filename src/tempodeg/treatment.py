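"""Categorization of an inhibitor's effect on each gene's DE trajectory.

For a gene with vehicle-arm DE time-point set V and treated-arm set C, the
pattern effect is decided by set algebra:

===========  =====================================
category     condition
===========  =====================================
unchanged    C = V (including both empty)
inhibited    V ≠ ∅ and C = ∅
induced      V = ∅ and C ≠ ∅
shortened    ∅ ≠ C ⊊ V
extended     ∅ ≠ V ⊊ C
shifted      C∖V ≠ ∅ and V∖C ≠ ∅
===========  =====================================

The six categories are mutually exclusive and exhaustive over all (V, C)
pairs. Level effects — did treatment change the expression *level* at a
time point among genes that stayed DE — are tested as treated-vs-vehicle
contrasts with the conditional FDR variant (injured-vs-injured comparison).
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .diffexpr import compare_groups
from .io import select_samples

PATTERN_EFFECTS = ("unchanged", "inhibited", "shortened", "extended", "induced", "shifted")


def pattern_effect_category(V: Iterable[str], C: Iterable[str]) -> str:
    """Categorical effect of treatment on the DE time-point set."""
    V, C = frozenset(V), frozenset(C)
    if C == V:
        return "unchanged"
    if V and not C:
        return "inhibited"
    if C and not V:
        return "induced"
    if C < V:
        return "shortened"
    if V < C:
        return "extended"
    return "shifted"


def level_effect_tests(
    norm_matrix: pd.DataFrame,
    samples: pd.DataFrame,
    timepoint: str,
    treated: dict | None = None,
    vehicle: dict | None = None,
    fdr_mode: str = "conditional",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Treated-vs-vehicle contrast at one time point with level-effect calls.

    ``level_effect`` is ``reduced`` when FDR < alpha and the treated mean is
    lower (log2), ``increased`` when higher, else ``none``.
    """
    treated = treated or {"group": "TBI", "treatment": "CR2-Crry"}
    vehicle = vehicle or {"group": "TBI", "treatment": "vehicle"}
    res = compare_groups(
        norm_matrix,
        samples,
        test={**treated, "timepoint": timepoint},
        ref={**vehicle, "timepoint": timepoint},
        fdr_mode=fdr_mode,
        alpha=alpha,
    )
    sig = res["fdr"] < alpha
    res["level_effect"] = np.where(
        ~sig, "none", np.where(res["log2fc"] < 0, "reduced", "increased")
    )
    res["timepoint"] = timepoint
    return res


def reduced_among_remaining_up(
    level_tests: pd.DataFrame,
    vehicle_results: pd.DataFrame,
    treated_results: pd.DataFrame,
    mode: str = "both-arms",
) -> pd.DataFrame:
    """Genes still differentially upregulated whose level treatment reduced.

    ``mode='both-arms'`` (default) requires the gene to be up versus the
    uninjured reference in *both* the vehicle and the treated arm at this
    time point; ``mode='vehicle-only'`` requires only the vehicle arm.
    """
    up_vehicle = set(vehicle_results.loc[vehicle_results["direction"] == "up", "gene_id"])
    if mode == "both-arms":
        up_treated = set(treated_results.loc[treated_results["direction"] == "up", "gene_id"])
        remaining = up_vehicle & up_treated
    elif mode == "vehicle-only":
        remaining = up_vehicle
    else:
        raise ValueError("mode must be 'both-arms' or 'vehicle-only'")
    sub = level_tests[
        level_tests["gene_id"].isin(remaining) & (level_tests["level_effect"] == "reduced")
    ]
    return sub.reset_index(drop=True)


def summarize_treatment_effects(
    vehicle_profiles: pd.DataFrame,
    treated_profiles: pd.DataFrame,
    level_tests: Mapping[str, pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """One TreatmentEffectRecord row per gene.

    Inputs are temporal profiles of each arm (same gene universe). DE sets
    merge both directions — the categories describe *when* a gene is DE, not
    which way. A gene is ``affected`` when its pattern changed or any level
    effect is non-none.
    """
    v = vehicle_profiles.set_index("gene_id")
    c = treated_profiles.set_index("gene_id")
    if set(v.index) != set(c.index):
        raise ValueError("vehicle and treated profiles cover different gene universes")
    c = c.reindex(v.index)
    records = pd.DataFrame(index=v.index)
    records["V"] = [u | d for u, d in zip(v["de_up"], v["de_down"])]
    records["C"] = [u | d for u, d in zip(c["de_up"], c["de_down"])]
    records["pattern_effect"] = [
        pattern_effect_category(vv, cc) for vv, cc in zip(records["V"], records["C"])
    ]
    any_level = pd.Series(False, index=v.index)
    if level_tests:
        for tp, lt in level_tests.items():
            eff = lt.set_index("gene_id")["level_effect"].reindex(v.index).fillna("none")
            records[f"level_effect_{tp}"] = eff
            records[f"remained_de_{tp}"] = [
                tp in vv and tp in cc for vv, cc in zip(records["V"], records["C"])
            ]
            any_level |= eff != "none"
    records["affected"] = (records["pattern_effect"] != "unchanged") | any_level
    return records.reset_index().rename(columns={"index": "gene_id"})


def arm_deg_counts(profiles_by_arm: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-arm, per-time-point up/down DEG tallies (Fig-4a-style)."""
    rows = []
    for arm, prof in profiles_by_arm.items():
        tps = sorted({t for s in prof["de_up"] for t in s} | {t for s in prof["de_down"] for t in s})
        for tp in tps:
            rows.append(
                {
                    "arm": arm,
                    "timepoint": tp,
                    "n_up": int(prof["de_up"].map(lambda s: tp in s).sum()),
                    "n_down": int(prof["de_down"].map(lambda s: tp in s).sum()),
                }
            )
    return pd.DataFrame(rows)


def pca_embedding(
    norm_matrix: pd.DataFrame, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on gene-centered log2 normalized counts.

    Samples are observations, genes are features; features are centered but
    not scaled to unit variance (panel counts share a scale after
    normalization). Component signs are fixed canonically: each loading
    vector is flipped so that its largest-magnitude loading is positive.
    Returns (coordinates frame indexed by sample, explained-variance
    fractions).
    """
    n_samples = norm_matrix.shape[1]
    if n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    if n_components > n_samples:
        raise ValueError("more components requested than samples available")
    X = np.log2(norm_matrix.to_numpy(dtype=float)).T  # samples × genes
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    for k in range(n_components):
        load = pca.components_[k]
        if load[np.argmax(np.abs(load))] < 0:
            coords[:, k] *= -1
            pca.components_[k] *= -1
    frame = pd.DataFrame(
        coords,
        index=norm_matrix.columns,
        columns=[f"PC{k + 1}" for k in range(n_components)],
    )
    frame.index.name = "sample_id"
    return frame, pca.explained_variance_ratio_.copy()
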