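"""End-to-end orchestration: counts → normalization → contrasts → trajectory
and treatment classification → pathway/marker summaries, with a
machine-readable run report.

The same analysis core serves three input modes:

* ``simulate`` — generate a synthetic benchmark with known truth;
* ``counts`` — raw panel counts + sample sheet from files;
* ``comparison_tables`` — precomputed per-contrast fold-change/p-value
  tables (the reproduction path for analyses whose statistics were exported
  by external software); peak and level analyses then require the
  corresponding injured-vs-injured tables instead of raw counts.

Reports are plain dicts (JSON-serializable) and identical for identical
config + seed; every written table carries a ``# run_id:`` header line.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
import pandas as pd
import yaml

from . import diffexpr, io, normalize, pathways, temporal, treatment
from .simulate import SimConfig, SimResult, recovery_metrics, simulate_panel

ANALYSIS_TIMEPOINTS = ("d3", "d7", "d28")


@dataclass
class AnalysisResult:
    """All intermediate and final tables of one standard analysis."""

    norm: pd.DataFrame
    model: normalize.NormalizationModel
    vehicle_results: dict[str, pd.DataFrame]
    treated_results: dict[str, pd.DataFrame]
    vehicle_profiles: pd.DataFrame
    treated_profiles: pd.DataFrame
    level_tests: dict[str, pd.DataFrame]
    records: pd.DataFrame
    arm_counts: pd.DataFrame
    marker_table: pd.DataFrame
    pca_coords: pd.DataFrame
    pca_evr: list[float]
    pathway_summary: pd.DataFrame | None = None


def analyze_counts(
    table: io.CountTable,
    samples: pd.DataFrame,
    alpha: float = 0.05,
    cv_threshold: float = 15.0,
    background: str = "mean2sd",
    sham_fdr_mode: str = "standard",
    timepoints=ANALYSIS_TIMEPOINTS,
    annotations: pd.DataFrame | None = None,
) -> AnalysisResult:
    """The standard two-arm time-course analysis on raw counts.

    Sham-vs-TBI contrasts use ``sham_fdr_mode`` (standard BH for the
    neuroinflammation panel); all injured-vs-injured comparisons (peak
    analysis, treated-vs-vehicle level tests) use the conditional variant.
    """
    norm, model = normalize.normalize_counts(
        table, cv_threshold=cv_threshold, background=background
    )
    endo = norm.loc[table.genes_of_class("Endogenous")]
    sham = {"group": "sham"}
    arms = {
        "vehicle": {"group": "TBI", "treatment": "vehicle"},
        "CR2-Crry": {"group": "TBI", "treatment": "CR2-Crry"},
    }
    results: dict[str, dict[str, pd.DataFrame]] = {}
    for arm, sel in arms.items():
        results[arm] = {
            tp: diffexpr.compare_groups(
                endo, samples, test={**sel, "timepoint": tp}, ref=sham,
                fdr_mode=sham_fdr_mode, alpha=alpha,
            )
            for tp in timepoints
        }
    vehicle_profiles = temporal.temporal_profiles(
        results["vehicle"], endo, samples, peak_timepoints=timepoints,
        arm=arms["vehicle"], alpha=alpha,
    )
    treated_profiles = temporal.temporal_profiles(
        results["CR2-Crry"], endo, samples, peak_timepoints=timepoints,
        arm=arms["CR2-Crry"], alpha=alpha,
    )
    level_tests = {
        tp: treatment.level_effect_tests(endo, samples, tp, alpha=alpha)
        for tp in timepoints
    }
    records = treatment.summarize_treatment_effects(
        vehicle_profiles, treated_profiles, level_tests
    )
    arm_counts = treatment.arm_deg_counts(
        {"vehicle": vehicle_profiles, "CR2-Crry": treated_profiles}
    )
    marker_table = pathways.marker_report(level_tests, endo.index)
    coords, evr = treatment.pca_embedding(endo)
    summary = (
        pathways.pathway_deg_summary(results["vehicle"], annotations)
        if annotations is not None
        else None
    )
    return AnalysisResult(
        norm=norm,
        model=model,
        vehicle_results=results["vehicle"],
        treated_results=results["CR2-Crry"],
        vehicle_profiles=vehicle_profiles,
        treated_profiles=treated_profiles,
        level_tests=level_tests,
        records=records,
        arm_counts=arm_counts,
        marker_table=marker_table,
        pca_coords=coords,
        pca_evr=list(map(float, evr)),
        pathway_summary=summary,
    )


def headline_counts(result: AnalysisResult, alpha: float = 0.05) -> dict:
    """The study-level tallies a full run reports.

    Counts of consistently up/down genes, treatment-effect categories,
    level-reduced genes among those remaining differentially upregulated at
    day 7, peak-set tallies among consistently upregulated genes, genes
    unaffected by treatment, and marker-class reductions.
    """
    vp = result.vehicle_profiles
    effect_tally = result.records["pattern_effect"].value_counts().to_dict()
    reduced_d7 = treatment.reduced_among_remaining_up(
        result.level_tests["d7"],
        result.vehicle_results["d7"],
        result.treated_results["d7"],
    )
    peaks = temporal.peak_set_tally(vp, "consistent_up")
    unaffected = result.records[~result.records["affected"]]
    consistent_up = set(vp.loc[vp["pattern_label"] == "consistent_up", "gene_id"])
    unaffected_consistent_up = [
        g for g in unaffected["gene_id"] if g in consistent_up
    ]
    markers = result.marker_table.set_index("marker_class")
    d7d28 = peaks.get("d7+d28", 0)
    return {
        "n_consistent_up": int((vp["pattern_label"] == "consistent_up").sum()),
        "n_consistent_down": int((vp["pattern_label"] == "consistent_down").sum()),
        "effect_categories": {k: int(v) for k, v in sorted(effect_tally.items())},
        "n_reduced_among_remaining_up_d7": int(len(reduced_d7)),
        "n_consistent_up_peak_two_acute": int(peaks.get("d3+d7", 0)),
        "n_consistent_up_peak_d7_d28": int(d7d28),
        "n_unaffected_consistent_up": len(unaffected_consistent_up),
        "deg_counts": {
            f"{row.arm}:{row.timepoint}": {"up": int(row.n_up), "down": int(row.n_down)}
            for row in result.arm_counts.itertuples()
        },
        "marker_reduced": {
            mc: {"reduced": int(markers.loc[mc, "n_reduced"]), "on_panel": int(markers.loc[mc, "n_on_panel"])}
            for mc in markers.index
        },
    }


# --------------------------------------------------------------------------
# Declarative run configuration


@dataclass
class RunConfig:
    mode: str = "simulate"  # simulate | counts | comparison_tables
    seed: int = 0
    alpha: float = 0.05
    cv_threshold: float = 15.0
    background: str = "mean2sd"
    sham_fdr_mode: str = "standard"
    out_dir: str = "tempodeg_out"
    counts_path: str | None = None
    samples_path: str | None = None
    annotations_path: str | None = None
    comparison_tables: dict = field(default_factory=dict)
    level_tables: dict = field(default_factory=dict)
    column_map: dict = field(default_factory=dict)
    sim: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def run_id(self) -> str:
        blob = repr(sorted(self.__dict__.items(), key=lambda kv: kv[0]))
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


def _results_from_tables(
    cfg: RunConfig,
) -> tuple[dict[str, dict[str, pd.DataFrame]], dict[str, pd.DataFrame]]:
    """Ingest precomputed comparison tables (one per arm × time point)."""
    spec = io.ComparisonTableSpec(**cfg.column_map) if cfg.column_map else io.ComparisonTableSpec()
    results: dict[str, dict[str, pd.DataFrame]] = {}
    for arm, per_tp in cfg.comparison_tables.items():
        fdr_mode = cfg.sham_fdr_mode
        results[arm] = {}
        for tp, path in per_tp.items():
            comp = io.read_comparison_table(path, spec=spec, contrast_id=f"{arm}:{tp}")
            results[arm][tp] = diffexpr.results_from_comparison_table(
                comp, f"{arm}:{tp}", fdr_mode=fdr_mode, alpha=cfg.alpha
            )
    level: dict[str, pd.DataFrame] = {}
    for tp, path in cfg.level_tables.items():
        comp = io.read_comparison_table(path, spec=spec, contrast_id=f"level:{tp}")
        res = diffexpr.results_from_comparison_table(
            comp, f"level:{tp}", fdr_mode="conditional", alpha=cfg.alpha
        )
        sig = res["fdr"] < cfg.alpha
        res["level_effect"] = [
            "none" if not s else ("reduced" if l < 0 else "increased")
            for s, l in zip(sig, res["log2fc"])
        ]
        res["timepoint"] = tp
        level[tp] = res
    return results, level


def run_full_analysis(cfg: RunConfig) -> dict:
    """Execute the configured pipeline, write tables, return the report."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rid = cfg.run_id()
    report: dict = {"run_id": rid, "mode": cfg.mode, "seed": cfg.seed, "stages": []}

    def stage(name):
        report["stages"].append(name)

    try:
        if cfg.mode == "simulate":
            stage("simulate")
            sim_kwargs = dict(cfg.sim)
            if "allocation" in sim_kwargs:
                # YAML configs use "archetype:modifier" string keys
                sim_kwargs["allocation"] = {
                    (tuple(k.split(":")) if isinstance(k, str) else k): v
                    for k, v in sim_kwargs["allocation"].items()
                }
            sim = simulate_panel(SimConfig(**sim_kwargs), seed=cfg.seed)
            io.write_count_table(sim.count_table, out / "counts.csv", run_id=rid)
            io.write_sample_sheet(sim.samples, out / "samples.csv", run_id=rid)
            io.write_table(sim.truth, out / "truth.csv", run_id=rid)
            table, samples, annotations = sim.count_table, sim.samples, sim.annotations
        elif cfg.mode == "counts":
            stage("read")
            if not cfg.counts_path or not Path(cfg.counts_path).exists():
                raise io.PanelIOError(f"counts file not found: {cfg.counts_path}")
            table = io.read_count_table(cfg.counts_path)
            samples = io.read_sample_sheet(cfg.samples_path)
            annotations = (
                io.read_gene_annotations(cfg.annotations_path)
                if cfg.annotations_path
                else None
            )
            sim = None
        elif cfg.mode == "comparison_tables":
            return _run_from_tables(cfg, out, rid, report)
        else:
            raise ValueError(f"unknown mode {cfg.mode!r}")

        stage("normalize")
        stage("contrasts")
        stage("temporal")
        stage("treatment")
        stage("pathways")
        result = analyze_counts(
            table,
            samples,
            alpha=cfg.alpha,
            cv_threshold=cfg.cv_threshold,
            background=cfg.background,
            sham_fdr_mode=cfg.sham_fdr_mode,
            annotations=annotations,
        )
        _write_outputs(result, out, rid)
        report["normalization"] = {
            "housekeeping_selected": result.model.housekeeping_set,
            "reference_mean": result.model.reference_mean,
        }
        report["headline"] = headline_counts(result, alpha=cfg.alpha)
        report["pca_explained_variance"] = result.pca_evr[:2]
        if cfg.mode == "simulate":
            stage("recovery")
            report["recovery"] = recovery_metrics(
                sim.truth,
                result.vehicle_profiles,
                result.records,
                result.vehicle_results,
            )
            report["recovery"]["housekeeping_exact"] = (
                sorted(result.model.housekeeping_set) == sorted(sim.hk_stable)
            )
    except Exception as exc:  # record the failing stage, then re-raise
        report["error"] = {"stage": report["stages"][-1] if report["stages"] else "config",
                          "message": str(exc)}
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True, default=str))
        raise
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True, default=str))
    return report


def _run_from_tables(cfg: RunConfig, out: Path, rid: str, report: dict) -> dict:
    report["stages"].append("ingest")
    results, level = _results_from_tables(cfg)
    report["stages"].append("temporal")
    vehicle_profiles, counts = temporal.de_timepoint_sets(results["vehicle"])
    report["stages"].append("treatment")
    treated_profiles, _ = temporal.de_timepoint_sets(results["CR2-Crry"])
    records = treatment.summarize_treatment_effects(
        vehicle_profiles, treated_profiles, level or None
    )
    io.write_table(vehicle_profiles, out / "vehicle_profiles.csv", run_id=rid)
    io.write_table(records, out / "treatment_records.csv", run_id=rid)
    effect_tally = records["pattern_effect"].value_counts().to_dict()
    report["headline"] = {
        "n_consistent_up": int((vehicle_profiles["pattern_label"] == "consistent_up").sum()),
        "n_consistent_down": int((vehicle_profiles["pattern_label"] == "consistent_down").sum()),
        "effect_categories": {k: int(v) for k, v in sorted(effect_tally.items())},
        "deg_counts": counts.to_dict(orient="records"),
    }
    if level:
        reduced = {}
        for tp in level:
            reduced[tp] = int(
                len(
                    treatment.reduced_among_remaining_up(
                        level[tp], results["vehicle"][tp], results["CR2-Crry"][tp]
                    )
                )
            )
        report["headline"]["n_reduced_among_remaining_up"] = reduced
        marker_table = pathways.marker_report(
            level, results["vehicle"][next(iter(level))]["gene_id"]
        )
        io.write_table(marker_table, out / "marker_report.csv", run_id=rid)
        report["headline"]["marker_reduced"] = {
            row.marker_class: int(row.n_reduced) for row in marker_table.itertuples()
        }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True, default=str))
    return report


def _write_outputs(result: AnalysisResult, out: Path, rid: str) -> None:
    norm = result.norm.copy()
    norm.insert(0, "gene_id", norm.index)
    io.write_table(norm, out / "normalized.csv", run_id=rid)
    result.model.to_json(out / "normalization_model.json")
    for tp, res in result.vehicle_results.items():
        io.write_table(res, out / f"de_vehicle_{tp}.csv", run_id=rid)
    for tp, res in result.treated_results.items():
        io.write_table(res, out / f"de_treated_{tp}.csv", run_id=rid)
    io.write_table(result.vehicle_profiles, out / "temporal_vehicle.csv", run_id=rid)
    io.write_table(result.treated_profiles, out / "temporal_treated.csv", run_id=rid)
    for tp, lt in result.level_tests.items():
        io.write_table(lt, out / f"level_{tp}.csv", run_id=rid)
    io.write_table(result.records, out / "treatment_records.csv", run_id=rid)
    io.write_table(result.arm_counts, out / "deg_counts.csv", run_id=rid)
    io.write_table(result.marker_table, out / "marker_report.csv", run_id=rid)
    coords = result.pca_coords.reset_index()
    io.write_table(coords, out / "pca.csv", run_id=rid)
    if result.pathway_summary is not None:
        io.write_table(result.pathway_summary, out / "pathway_summary.csv", run_id=rid)
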