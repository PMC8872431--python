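"""End-to-end orchestration of the misutilization analysis.

`run_pipeline` executes: ingest (or simulate) -> dedupe/collapse ->
descriptives -> three logistic fits + AUC comparison + pattern/tetrachoric
analyses -> decision curve + threshold -> per-visit labels + summary ->
disparity odds ratios -> facility profiling/flagging, writing a
reproducible report bundle (CSV/JSON artifacts, optional figures, and a
manifest with seed and config hash).
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .schema import CohortSchema, N_POSSIBLE_PATTERNS
from .synthetic import SyntheticConfig, generate_cohort, write_cohort
from .ingest import (
    CollapseRules, read_cohort, deduplicate_first_visit, collapse_categories,
    build_design, descriptive_stats,
)
from .model import (
    fit_logistic, auc_delong, compare_auc_delong, pattern_analysis,
    pattern_table, tetrachoric,
)
from .decision import (
    net_benefit_curve, calibrate_threshold, classify_visits, threshold_odds,
)
from .disparity import misuse_odds_ratios, odds_ratio_table, forest_data
from .profiling import (
    KINDS, facility_rates, add_expected_and_p, flag_facilities, bubble_data,
    volume_regression, extreme_tables,
)

SECTIONS = (
    "descriptive", "models", "auc", "patterns", "decision", "disparity", "facility",
)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and a remediation hint."""

    def __init__(self, stage: str, hint: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}  (hint: {hint})")
        self.stage = stage


@dataclass
class RunConfig:
    """Reproducible configuration of one end-to-end run."""

    input: str | None = None                 # visit-level CSV; None -> simulate
    synthetic: SyntheticConfig | None = None
    covariate_sets: tuple[str, ...] = ("a", "b", "c")
    threshold: float | str = "auto"          # "auto" = calibrate to prevalence
    alpha: float = 0.01
    outdir: str = "misutil_run"
    seed: int = 0
    figures: bool = True
    collapse: CollapseRules = field(default_factory=CollapseRules)
    disparity_characteristics: tuple[str, ...] = ("race",)

    def __post_init__(self) -> None:
        if isinstance(self.threshold, (int, float)) and not 0 < self.threshold < 1:
            raise ValueError("fixed threshold must be in (0,1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")

    def config_hash(self) -> str:
        d = asdict(self)
        if self.synthetic is not None:
            d["synthetic"] = self.synthetic.to_dict()
        def _default(o):
            if isinstance(o, (set, frozenset)):
                return sorted(o)
            return str(o)

        blob = json.dumps(d, sort_keys=True, default=_default).encode()
        return hashlib.sha256(blob).hexdigest()


def _stage(name: str, hint: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as e:  # noqa: BLE001 - stage wrapper
                raise PipelineError(name, hint, e) from e
        return wrapped
    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the report bundle; returns the in-memory
    bundle (tables, fitted models, summaries, manifest)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    schema = CohortSchema()
    bundle: dict = {}

    # ---- cohort ------------------------------------------------------
    @_stage("ingest", "check the input CSV header against the declared schema")
    def _load():
        if config.input is not None:
            return read_cohort(config.input, schema)
        synth = config.synthetic or SyntheticConfig(seed=config.seed)
        cohort, _ = generate_cohort(synth)
        write_cohort(cohort, synth, outdir / "cohort.csv")
        return cohort

    cohort = _load()
    cohort = deduplicate_first_visit(cohort)
    cohort, collapse_report = collapse_categories(cohort, config.collapse, schema)
    (outdir / "collapse_report.json").write_text(json.dumps(collapse_report, indent=2))

    desc = descriptive_stats(cohort, schema)
    desc.to_csv(outdir / "descriptive.csv", index=False)
    bundle["descriptive"] = desc

    # ---- models ------------------------------------------------------
    @_stage("fit", "inspect the collapse report for aliased or empty levels")
    def _fit():
        y = cohort[schema.outcome].to_numpy()
        fits, aucs = {}, {}
        for cs in config.covariate_sets:
            design = build_design(cohort, cs, schema)
            fit = fit_logistic(design, y)
            fit.to_json(outdir / f"model_{cs}.json")
            fits[cs] = fit
            aucs[cs] = auc_delong(fit.fitted_probabilities, y)
        return fits, aucs

    fits, aucs = _fit()
    y = cohort[schema.outcome].to_numpy()
    auc_report = {
        cs: {"auc": est.auc, "ci95": est.ci95, "variance": est.variance}
        for cs, est in aucs.items()
    }
    if {"a", "b"} <= set(fits):
        diff, ci, p = compare_auc_delong(
            fits["a"].fitted_probabilities, fits["b"].fitted_probabilities, y
        )
        auc_report["delong_a_vs_b"] = {"auc_diff": diff, "ci95": ci, "p": p}
    (outdir / "auc.json").write_text(json.dumps(auc_report, indent=2))
    bundle["models"], bundle["auc"] = fits, auc_report

    summaries, chi2, dof, chi_p = pattern_analysis(cohort, schema)
    ptable = pattern_table(summaries)
    ptable.to_csv(outdir / "patterns.csv", index=False)
    tets = tetrachoric(cohort, schema)
    pd.DataFrame([
        {"x": t.pair[0], "y": t.pair[1], "rho": t.rho, "defined": t.defined}
        for t in tets
    ]).to_csv(outdir / "tetrachoric.csv", index=False)
    bundle["patterns"] = {
        "table": ptable, "chi_square": chi2, "dof": dof, "p": chi_p,
        "observed": len(summaries), "possible": N_POSSIBLE_PATTERNS,
        "tetrachoric": tets,
    }
    probabilities = pd.DataFrame({"visit_id": cohort["visit_id"].to_numpy()})
    for cs, fit in fits.items():
        probabilities[f"p_{cs}"] = fit.fitted_probabilities
    probabilities.to_csv(outdir / "probabilities.csv", index=False)

    # ---- decision ----------------------------------------------------
    @_stage("decide", "the model adds no value on the grid; pass a fixed threshold")
    def _decide():
        p_hat = fits["a"].fitted_probabilities
        curve = net_benefit_curve(p_hat, y)
        curve.to_frame().to_csv(outdir / "decision_curve.csv", index=False)
        if config.threshold == "auto":
            t, cal_report = calibrate_threshold(p_hat, y, curve)
        else:
            t = float(config.threshold)
            cal_report = {"threshold": t, "fixed": True,
                          "cost_benefit_odds": threshold_odds(t)}
        labels, summary = classify_visits(p_hat, y, t)
        return curve, t, cal_report, labels, summary

    curve, t, cal_report, labels, summary = _decide()
    labeled = cohort.copy()
    labeled["utilization_label"] = labels
    labeled.to_csv(outdir / "visits_labeled.csv", index=False)
    (outdir / "summary.json").write_text(json.dumps(
        {"threshold": cal_report, "misutilization": summary.to_dict()}, indent=2
    ))
    bundle["decision"] = {"curve": curve, "threshold": t,
                          "calibration": cal_report, "summary": summary}

    # ---- disparity ---------------------------------------------------
    @_stage("disparity", "check that the characteristic and reference level exist")
    def _disparity():
        rows = []
        for char in config.disparity_characteristics:
            if char not in labeled.columns:
                continue
            ref = schema.reference_levels.get(char)
            if ref not in set(labeled[char]):
                ref = labeled[char].mode().iloc[0]
            rows.extend(misuse_odds_ratios(labels, labeled, char, ref))
        return rows

    or_rows = _disparity()
    or_table = odds_ratio_table(or_rows)
    or_table.to_csv(outdir / "odds_ratios.csv", index=False)
    bundle["disparity"] = {"rows": or_rows, "table": or_table}

    # ---- facility profiling ------------------------------------------
    @_stage("profile", "facility_id must be present on every visit")
    def _profile():
        profiles = add_expected_and_p(facility_rates(labels, labeled))
        flagged = flag_facilities(profiles, config.alpha)
        regs = {k: volume_regression(profiles, k) for k in ("over", "under")}
        return profiles, flagged, regs

    profiles, flagged, regs = _profile()
    profiles.to_csv(outdir / "facility_profiles.csv", index=False)
    for kind in KINDS:
        flagged[kind].to_csv(outdir / f"flagged_{kind}.csv", index=False)
    facility_summary = {
        "flagged_counts": {k: int(len(flagged[k])) for k in KINDS},
        "volume_regression": {
            k: {"slope": r.slope, "intercept": r.intercept, "p": r.p}
            for k, r in regs.items()
        },
    }
    (outdir / "facility_summary.json").write_text(json.dumps(facility_summary, indent=2))
    bundle["facility"] = {"profiles": profiles, "flagged": flagged,
                          "regressions": regs, "summary": facility_summary,
                          "extremes": extreme_tables(profiles)}

    # ---- figures -----------------------------------------------------
    if config.figures:
        render_figures(bundle, outdir, config.alpha)

    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "threshold": t,
        "sections": list(SECTIONS),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    bundle["manifest"] = manifest
    return bundle


def render_figures(bundle: dict, outdir: Path, alpha: float = 0.01) -> list[Path]:
    """Render the figure set from an in-memory bundle (headless)."""
    from . import plots  # deferred: matplotlib import is not free

    outdir = Path(outdir)
    written = []

    def save(fig, name):
        path = outdir / name
        fig.savefig(path, dpi=120)
        import matplotlib.pyplot as plt
        plt.close(fig)
        written.append(path)

    save(plots.decision_curve_plot(bundle["decision"]["curve"]), "fig_decision_curve.png")
    profiles = bundle["facility"]["profiles"]
    save(plots.facility_rate_histograms(profiles), "fig_facility_histograms.png")
    for kind in KINDS:
        save(plots.bubble_plot(bubble_data(profiles, kind, alpha), kind),
             f"fig_bubbles_{kind}.png")
    save(plots.volume_back_to_back(
        profiles, bundle["facility"]["flagged"]["mis"]["facility_id"]),
        "fig_volume_back_to_back.png")
    save(plots.under_over_bubble(profiles), "fig_under_over.png")
    if bundle["disparity"]["rows"]:
        save(plots.forest_plot(forest_data(bundle["disparity"]["rows"])),
             "fig_forest.png")
    return written
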