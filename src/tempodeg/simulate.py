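"""Synthetic nCounter panel data with known ground truth.

The generator emulates the study design every downstream module is built
for: a ~757-gene endogenous panel plus housekeeping, positive and negative
control probes, measured in a sham group and in injured (TBI) groups at
days 3/7/28 under vehicle or a complement inhibitor, n = 3 per group.

Counts are negative binomial with mean s_j · μ_g · 2^β and variance
μ + φμ² (mean/dispersion parameterization), where s_j is a per-sample
log-normal library scale factor, μ_g a log-normal baseline and β the
planted log2 effect for that gene, arm and time point. Negative controls
are Poisson(λ_bg); positive controls follow a geometric spike ladder. Of
the housekeeping candidates, 11 get low extra variance (so they pass the
%CV < 15% selection) and the rest inflated variance (so they are excluded).

Planted effects follow temporal **archetypes** (which time points a gene is
DE at in the vehicle arm, and where its change peaks) crossed with
treatment **modifiers** (how the inhibitor alters the trajectory or the
expression level). The default allocation mirrors the effect tallies of the
study the pipeline reimplements, so an end-to-end run on defaults produces
counts on the scale of the original analysis. All randomness flows through
one seeded generator; a fixed seed fixes every output bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .io import CountTable, validate_sample_sheet
from .temporal import pattern_label
from .treatment import pattern_effect_category

TIMEPOINTS = ("d3", "d7", "d28")

# archetype → (vehicle β pattern over d3/d7/d28 in units of (minor, full))
# encoded as weights on the full effect size; "minor" entries use the
# secondary effect so peak analysis has signal.
ARCHETYPES = (
    "null",
    "acute",  # DE at d3+d7
    "persistent",  # DE at all three, flat
    "acute_peak",  # DE at all three, stronger at d3+d7
    "chronic_peak",  # DE at d28 only
    "late_peak",  # DE at all three, stronger at d7+d28
    "d3_only",
    "consistent_down",  # −effect at all three
)
MODIFIERS = ("none", "inhibited", "shortened", "extended", "induced", "level_reduced")

# Marker-named genes planted into the benchmark so marker-level reporting is
# exercised end to end: (name, archetype, modifier).
_NAMED_GENES = (
    ("C3", "persistent", "level_reduced"),
    ("Fbln5", "persistent", "level_reduced"),
    ("H2-T23", "persistent", "level_reduced"),
    ("Serping1", "persistent", "level_reduced"),
    ("Srgn", "persistent", "level_reduced"),
    ("Gbp2", "persistent", "none"),
    ("Psmb8", "persistent", "none"),
    ("Emp1", "persistent", "level_reduced"),
    ("Ptx3", "persistent", "level_reduced"),
    ("Tm4sf1", "persistent", "level_reduced"),
    ("Tgm1", "persistent", "none"),
    ("Cd109", "persistent", "none"),
    ("S100a10", "persistent", "none"),
    ("Ptgs2", "persistent", "none"),
    ("Clec7a", "late_peak", "none"),
)


def default_allocation() -> dict[tuple[str, str], int]:
    """Gene counts per (archetype, modifier); remainder is (null, none)."""
    return {
        ("null", "induced"): 27,
        ("acute", "none"): 40,
        ("acute", "inhibited"): 40,
        ("acute", "level_reduced"): 27,
        # together with the accented consistent-up archetypes below this
        # makes 60 consistently upregulated genes untouched by treatment
        ("persistent", "none"): 30,
        ("persistent", "shortened"): 30,
        ("persistent", "level_reduced"): 60,
        ("acute_peak", "none"): 29,
        ("chronic_peak", "none"): 20,
        ("late_peak", "none"): 1,
        ("d3_only", "none"): 26,
        ("d3_only", "extended"): 34,
        ("consistent_down", "none"): 18,
    }


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic panel benchmark."""

    n_endogenous: int = 757
    n_housekeeping_candidates: int = 15
    n_housekeeping_stable: int = 11
    n_pos_controls: int = 6
    n_neg_controls: int = 8
    n_per_group: int = 3
    include_aging: bool = False
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 2.0
    dispersion: float = 0.05
    hk_dispersion_stable: float = 0.0015
    hk_dispersion_unstable: float = 0.15
    hk_log2_range: tuple[float, float] = (9.0, 13.0)
    sigma_lib: float = 0.08
    lambda_bg: float = 10.0
    pos_top_mean: float = 32768.0
    pos_ratio: float = 0.25
    effect_size: float = 3.0
    minor_effect: float = 1.5
    level_shift: float = -1.0
    allocation: Mapping[tuple[str, str], int] = field(default_factory=default_allocation)
    name_marker_genes: bool = True

    def validate(self) -> None:
        total = sum(self.allocation.values())
        if total > self.n_endogenous:
            raise ValueError(
                f"archetype allocation ({total}) exceeds n_endogenous ({self.n_endogenous})"
            )
        for (arch, mod), n in self.allocation.items():
            if arch not in ARCHETYPES:
                raise ValueError(f"unknown archetype {arch!r}")
            if mod not in MODIFIERS:
                raise ValueError(f"unknown modifier {mod!r}")
            if n < 0:
                raise ValueError("allocation counts must be non-negative")
            if mod == "induced" and arch != "null":
                raise ValueError("'induced' applies to the null archetype only")
            if mod == "shortened" and arch in ("null", "d3_only", "chronic_peak"):
                raise ValueError("'shortened' needs ≥2 vehicle DE time points")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.sigma_lib < 0:
            raise ValueError("sigma_lib must be non-negative")


def _vehicle_beta(arch: str, cfg: SimConfig) -> dict[str, float]:
    E, m = cfg.effect_size, cfg.minor_effect
    return {
        "null": {},
        "acute": {"d3": E, "d7": E},
        "persistent": {"d3": E, "d7": E, "d28": E},
        "acute_peak": {"d3": E, "d7": E, "d28": m},
        "chronic_peak": {"d28": E},
        "late_peak": {"d3": m, "d7": E, "d28": E},
        "d3_only": {"d3": E},
        "consistent_down": {"d3": -E, "d7": -E, "d28": -E},
    }[arch]


def _expected_peak(arch: str) -> frozenset[str]:
    return {
        "null": frozenset(),
        "acute": frozenset({"d3", "d7"}),
        "persistent": frozenset(TIMEPOINTS),
        "acute_peak": frozenset({"d3", "d7"}),
        "chronic_peak": frozenset({"d28"}),
        "late_peak": frozenset({"d7", "d28"}),
        "d3_only": frozenset({"d3"}),
        "consistent_down": frozenset(TIMEPOINTS),
    }[arch]


def _treated_beta(vehicle: dict[str, float], mod: str, cfg: SimConfig) -> dict[str, float]:
    E = cfg.effect_size
    if mod == "none":
        return dict(vehicle)
    if mod == "inhibited":
        return {}
    if mod == "shortened":  # drop the last DE time point
        tps = [t for t in TIMEPOINTS if t in vehicle]
        return {t: vehicle[t] for t in tps[:-1]}
    if mod == "extended":  # add the earliest non-DE time point
        extra = next(t for t in TIMEPOINTS if t not in vehicle)
        out = dict(vehicle)
        sign = np.sign(next(iter(vehicle.values()))) if vehicle else 1.0
        out[extra] = sign * E
        return out
    if mod == "induced":
        return {"d7": E}
    if mod == "level_reduced":
        return {t: b + cfg.level_shift for t, b in vehicle.items()}
    raise ValueError(f"unknown modifier {mod!r}")


@dataclass
class SimResult:
    count_table: CountTable
    samples: pd.DataFrame
    truth: pd.DataFrame
    hk_stable: list[str]
    annotations: pd.DataFrame


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB(mean, var = mean + phi·mean²); phi → 0 degenerates to Poisson."""
    mean = np.asarray(mean, dtype=float)
    if phi <= 0:
        return rng.poisson(mean)
    r = 1.0 / phi
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=mean.shape)


def _sample_sheet(cfg: SimConfig) -> pd.DataFrame:
    rows = []

    def add(prefix, group, treatment, timepoint, age):
        for k in range(cfg.n_per_group):
            rows.append(
                {
                    "sample_id": f"{prefix}_{k + 1}",
                    "group": group,
                    "treatment": treatment,
                    "timepoint": timepoint,
                    "age_class": age,
                }
            )

    add("sham", "sham", "none", "baseline", "12wk")
    for tp in TIMEPOINTS:
        add(f"veh_{tp}", "TBI", "vehicle", tp, "12wk")
    for tp in TIMEPOINTS:
        add(f"inh_{tp}", "TBI", "CR2-Crry", tp, "12wk")
    if cfg.include_aging:
        add("sham_y1", "sham", "none", "baseline", "1y")
        add("tbi_y1", "TBI", "none", "y1", "1y")
        add("sham_y2", "sham", "none", "baseline", "2y")
        add("tbi_y2", "TBI", "none", "y2", "2y")
    return validate_sample_sheet(pd.DataFrame(rows))


def simulate_panel(config: SimConfig | None = None, seed: int = 0) -> SimResult:
    """Draw one full synthetic dataset; deterministic under the seed."""
    cfg = config or SimConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    samples = _sample_sheet(cfg)
    sample_ids = samples["sample_id"].tolist()
    n_samp = len(sample_ids)

    # --- gene roster and planted truth ----------------------------------
    assignments: list[tuple[str, str]] = []
    for key in sorted(cfg.allocation, key=lambda k: (ARCHETYPES.index(k[0]), MODIFIERS.index(k[1]))):
        assignments.extend([key] * cfg.allocation[key])
    assignments.extend([("null", "none")] * (cfg.n_endogenous - len(assignments)))

    gene_ids = [f"G{i + 1:04d}" for i in range(cfg.n_endogenous)]
    if cfg.name_marker_genes:
        used: set[int] = set()
        for name, arch, mod in _NAMED_GENES:
            for i, key in enumerate(assignments):
                if i not in used and key == (arch, mod):
                    gene_ids[i] = name
                    used.add(i)
                    break

    truth_rows = []
    for gid, (arch, mod) in zip(gene_ids, assignments):
        vb = _vehicle_beta(arch, cfg)
        tb = _treated_beta(vb, mod, cfg)
        V = frozenset(vb)
        C = frozenset(tb)
        up = frozenset(t for t, b in vb.items() if b > 0)
        down = frozenset(t for t, b in vb.items() if b < 0)
        truth_rows.append(
            {
                "gene_id": gid,
                "archetype": arch,
                "modifier": mod,
                **{f"l2fc_{t}_vehicle": vb.get(t, 0.0) for t in TIMEPOINTS},
                **{f"l2fc_{t}_treated": tb.get(t, 0.0) for t in TIMEPOINTS},
                "expected_V": V,
                "expected_C": C,
                "expected_pattern": pattern_label(up, down, TIMEPOINTS),
                "expected_effect": pattern_effect_category(V, C),
                "expected_peak": _expected_peak(arch),
            }
        )
    truth = pd.DataFrame(truth_rows)

    # --- per-sample planted log2 effects --------------------------------
    beta = np.zeros((cfg.n_endogenous, n_samp))
    for j, (_, srow) in enumerate(samples.iterrows()):
        if srow["group"] != "TBI" or srow["timepoint"] not in TIMEPOINTS:
            continue
        col = "treated" if srow["treatment"] == "CR2-Crry" else "vehicle"
        beta[:, j] = truth[f"l2fc_{srow['timepoint']}_{col}"].to_numpy()

    # --- draw counts ----------------------------------------------------
    scale = np.exp(rng.normal(0.0, cfg.sigma_lib, size=n_samp)) if cfg.sigma_lib > 0 else np.ones(n_samp)
    base = 2.0 ** rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, size=cfg.n_endogenous)
    endo_mean = base[:, None] * 2.0**beta * scale[None, :]
    endo = _nb_draw(rng, endo_mean, cfg.dispersion)

    n_hk = cfg.n_housekeeping_candidates
    hk_ids = [f"Hk{i + 1:02d}" for i in range(n_hk)]
    # unstable candidates sit in the interior of the expression ladder so the
    # stable set spans the full (broad) range
    n_unstable = n_hk - cfg.n_housekeeping_stable
    unstable_idx = set(
        np.unique(np.linspace(1, n_hk - 2, n_unstable).round().astype(int))
    ) if n_unstable > 0 else set()
    hk_stable = [hk_ids[i] for i in range(n_hk) if i not in unstable_idx][
        : cfg.n_housekeeping_stable
    ]
    lo, hi = cfg.hk_log2_range
    hk_base = 2.0 ** np.linspace(lo, hi, n_hk)
    hk_mean = hk_base[:, None] * scale[None, :]
    hk = np.empty((n_hk, n_samp), dtype=np.int64)
    for i in range(n_hk):
        phi = cfg.hk_dispersion_stable if hk_ids[i] in hk_stable else cfg.hk_dispersion_unstable
        hk[i] = _nb_draw(rng, hk_mean[i], phi)

    pos_means = cfg.pos_top_mean * cfg.pos_ratio ** np.arange(cfg.n_pos_controls)
    pos = rng.poisson(pos_means[:, None] * scale[None, :], size=(cfg.n_pos_controls, n_samp))
    neg = rng.poisson(cfg.lambda_bg, size=(cfg.n_neg_controls, n_samp))

    all_ids = (
        gene_ids
        + hk_ids
        + [f"Pos{i + 1}" for i in range(cfg.n_pos_controls)]
        + [f"Neg{i + 1}" for i in range(cfg.n_neg_controls)]
    )
    classes = (
        ["Endogenous"] * cfg.n_endogenous
        + ["Housekeeping"] * n_hk
        + ["Positive"] * cfg.n_pos_controls
        + ["Negative"] * cfg.n_neg_controls
    )
    counts = pd.DataFrame(
        np.vstack([endo, hk, pos, neg]), index=pd.Index(all_ids, name="gene_id"), columns=sample_ids
    )
    table = CountTable(counts=counts, code_class=pd.Series(classes, index=counts.index))

    # --- pathway annotations for the synthetic panel --------------------
    from importlib import resources

    with resources.files("tempodeg.data").joinpath("neuroinflammation_pathways.txt").open() as fh:
        pathway_names = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    ann_rows = []
    for gid in gene_ids:
        k = int(rng.integers(1, 4))
        chosen = rng.choice(len(pathway_names), size=k, replace=False)
        ann_rows.append(
            {"gene_id": gid, "pathways": frozenset(pathway_names[c] for c in chosen)}
        )
    annotations = pd.DataFrame(ann_rows)
    annotations["marker_classes"] = [frozenset()] * len(annotations)
    annotations["complement_class"] = pd.NA
    annotations["complement_pathway"] = pd.NA

    return SimResult(
        count_table=table,
        samples=samples,
        truth=truth,
        hk_stable=hk_stable,
        annotations=annotations,
    )


def recovery_metrics(
    truth: pd.DataFrame,
    profiles: pd.DataFrame,
    treatment_records: pd.DataFrame | None = None,
    vehicle_results: Mapping[str, pd.DataFrame] | None = None,
) -> dict:
    """Recall/precision of planted labels, DE sensitivity and realized FDP.

    ``profiles`` are vehicle-arm temporal profiles; ``treatment_records``
    (optional) come from :func:`tempodeg.treatment.summarize_treatment_effects`;
    ``vehicle_results`` (optional) map time point → ContrastResult frame for
    gene-level DE sensitivity and false-discovery proportion.
    """
    t = truth.set_index("gene_id")
    p = profiles.set_index("gene_id")
    if set(t.index) != set(p.index):
        raise ValueError("truth and profiles cover different gene universes")
    p = p.reindex(t.index)

    out: dict = {"pattern": {}, "peak": {}, "effect": {}}
    observed_label = p["pattern_label"]
    for arch, sub in t.groupby("archetype"):
        if arch == "null":
            continue
        expected = sub["expected_pattern"]
        obs = observed_label.loc[sub.index]
        out["pattern"][arch] = float((obs == expected).mean())
        if "peak_set" in p.columns:
            obs_peak = p.loc[sub.index, "peak_set"]
            out["peak"][arch] = float(
                np.mean([o == e for o, e in zip(obs_peak, sub["expected_peak"])])
            )
    # overall recall among genes detected DE at ≥1 time point
    planted = t[t["archetype"] != "null"]
    detected = planted.index[observed_label.loc[planted.index] != "none"]
    if len(detected):
        out["pattern_overall"] = float(
            (observed_label.loc[detected] == t.loc[detected, "expected_pattern"]).mean()
        )
        if "peak_set" in p.columns:
            out["peak_overall"] = float(
                np.mean(
                    [
                        o == e
                        for o, e in zip(
                            p.loc[detected, "peak_set"], t.loc[detected, "expected_peak"]
                        )
                    ]
                )
            )
    # precision per observed pattern label
    label_truth = t["expected_pattern"]
    prec = {}
    for label, grp in p.groupby("pattern_label"):
        if label == "none":
            continue
        prec[label] = float((label_truth.loc[grp.index] == label).mean())
    out["pattern_precision"] = prec

    if treatment_records is not None:
        r = treatment_records.set_index("gene_id").reindex(t.index)
        for cat, sub in t.groupby("expected_effect"):
            obs = r.loc[sub.index, "pattern_effect"]
            out["effect"][cat] = float((obs == cat).mean())

    if vehicle_results is not None:
        tp_cols = {tp: f"l2fc_{tp}_vehicle" for tp in TIMEPOINTS}
        n_true = n_hit = n_calls = n_false = 0
        for tp, res in vehicle_results.items():
            if tp not in tp_cols:
                continue
            planted = t[tp_cols[tp]] != 0
            de = res.set_index("gene_id")["de_flag"].reindex(t.index).fillna(False)
            n_true += int(planted.sum())
            n_hit += int((planted & de).sum())
            n_calls += int(de.sum())
            n_false += int((~planted & de).sum())
        out["de_recall"] = n_hit / n_true if n_true else float("nan")
        out["fdp"] = n_false / n_calls if n_calls else 0.0
    return out
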