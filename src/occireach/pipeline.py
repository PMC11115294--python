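"""End-to-end orchestration with reproducible configuration.

``run_pipeline`` chains: simulate (or load) -> feature extraction ->
descriptives -> covariate-adjusted multivariate side comparison with a
normality gate -> logistic fits and ROC/Youden cutoffs for the significant
features -> DeLong AUC comparisons against the motor-time discriminator ->
unsupervised random-forest clustering per condition (side x phase).

Every stochastic stage derives its seed from the config seed, so a config
plus its inputs fully determines the run report.  The effective values of
all judgement-call parameters (segmentation epsilon, filter cutoff, angle
conventions, ROC direction) are logged and embedded in the report to keep
them auditable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, io, kinematics, simulate, stats
from .errors import OccireachError
from .kinematics import FEATURE_COLUMNS, ExtractionConfig
from .simulate import CohortSpec
from .trial import NON_PARALYZED, PARALYZED

log = logging.getLogger("occireach")

ALPHA = 0.05
CLUSTER_VARIABLES = ["motor_time", "shoulder_flex", "shoulder_abd", "elbow_flex"]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Fully serializable description of one pipeline run."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    input_paths: list[str] = field(default_factory=list)   # overrides cohort
    covariates_path: str | None = None
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    forest: clustering.ForestConfig = field(default_factory=clustering.ForestConfig)
    frame_stride: int = 10
    k_max: int = 8
    output_dir: str | None = None
    seed: int = 0

    def __post_init__(self):
        # a shared seed keeps cohort simulation and clustering in one stream
        self.cohort.seed = self.seed
        self.forest.seed = self.seed + 1

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            c = dict(d["cohort"])
            for key in ("paralyzed_params", "nonparalyzed_params"):
                if key in c and isinstance(c[key], dict):
                    p = dict(c[key])
                    for tn in ("motor_time", "return_motor_time",
                               "peak_shoulder_flex", "peak_shoulder_abd",
                               "peak_elbow_flex"):
                        if tn in p and isinstance(p[tn], dict):
                            p[tn] = simulate.TruncNormal(**p[tn])
                    c[key] = simulate.SidedMotionParams(**p)
            if c.get("geometry") is not None and isinstance(c["geometry"], dict):
                g = dict(c["geometry"])
                if isinstance(g.get("shoulder_offset_from_c7"), list):
                    g["shoulder_offset_from_c7"] = tuple(g["shoulder_offset_from_c7"])
                c["geometry"] = simulate.ArmGeometry(**g)
            d["cohort"] = CohortSpec(**c)
        if isinstance(d.get("extraction"), dict):
            d["extraction"] = ExtractionConfig(**d["extraction"])
        if isinstance(d.get("forest"), dict):
            d["forest"] = clustering.ForestConfig(**d["forest"])
        return cls(**d)

    def to_file(self, path) -> Path:
        path = Path(path)
        payload = self.to_dict()
        if path.suffix in (".yaml", ".yml"):
            import yaml
            path.write_text(yaml.safe_dump(payload, sort_keys=False))
        else:
            path.write_text(json.dumps(payload, indent=2))
        return path

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml
            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

@dataclass
class RunReport:
    config: dict
    warnings: list[str]
    descriptives: pd.DataFrame
    manova: dict                    # phase -> summary dict
    gated_tests: dict               # phase -> DataFrame
    logistic: pd.DataFrame
    roc: pd.DataFrame
    delong: pd.DataFrame
    clusters: dict                  # condition -> summary dict
    features: pd.DataFrame
    frame_rows: pd.DataFrame

    def to_json_dict(self) -> dict:
        def df(d: pd.DataFrame):
            return json.loads(d.to_json(orient="records", double_precision=10))

        return {
            "config": self.config,
            "warnings": self.warnings,
            "descriptives": df(self.descriptives),
            "manova": self.manova,
            "gated_tests": {k: df(v.reset_index()) for k, v in self.gated_tests.items()},
            "logistic": df(self.logistic),
            "roc": df(self.roc),
            "delong": df(self.delong),
            "clusters": self.clusters,
        }


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _load_or_simulate(config: PipelineConfig):
    if config.input_paths:
        cov = (io.read_covariates_csv(config.covariates_path)
               if config.covariates_path else None)
        trials = io.read_trial_files(config.input_paths, covariates=cov)
        log.info("loaded %d trials from %d files", len(trials),
                 len(config.input_paths))
    else:
        trials = simulate.generate_cohort(config.cohort)
        log.info("simulated %d trials (%d participants x 2 sides x %d trials)",
                 len(trials), config.cohort.n_participants,
                 config.cohort.trials_per_side)
    return trials


def _rank_independent_covariates(sub: pd.DataFrame,
                                 candidates: list[str]) -> list[str]:
    """Greedily keep covariates that add rank beyond the intercept.

    With few participants the participant-level covariates (sex, age, BMI,
    onset time) span fewer dimensions than their count and would make every
    downstream design singular.
    """
    present = [c for c in candidates if c in sub.columns]
    if not present:
        return []
    enc = stats._encode(sub, present)
    X = np.ones((len(sub), 1))
    keep = []
    for c in present:
        cand = np.column_stack([X, enc[c].to_numpy()])
        if np.linalg.matrix_rank(cand) == cand.shape[1]:
            X = cand
            keep.append(c)
    return keep


def discriminate(features: pd.DataFrame, alpha: float = ALPHA):
    """Statistical chain for one feature table (both phases).

    Returns (manova_by_phase, gated_by_phase, logistic_df, roc_df,
    delong_df, warnings).
    """
    warnings: list[str] = []
    manova_by_phase: dict[str, dict] = {}
    gated: dict[str, pd.DataFrame] = {}
    logi_rows, roc_rows, delong_rows = [], [], []

    for phase in (kinematics.OUTWARD, kinematics.RETURN):
        sub = features[features["phase"] == phase].reset_index(drop=True)
        covariates = _rank_independent_covariates(sub, stats.DEFAULT_COVARIATES)
        dropped = sorted(set(stats.DEFAULT_COVARIATES) - set(covariates))
        if dropped:
            warnings.append(
                f"{phase}: covariates dropped (constant or collinear with the"
                f" rest): {dropped}")
        try:
            res = stats.manova_rm(sub, FEATURE_COLUMNS, covariates=covariates)
            manova_by_phase[phase] = {
                "wilks_lambda": res.wilks_lambda, "F": res.F,
                "df1": res.df1, "df2": res.df2, "p": res.p,
                "univariate": json.loads(
                    res.univariate.reset_index().to_json(orient="records")),
            }
            significant = list(res.univariate.index[res.univariate["p"] < alpha])
        except OccireachError as exc:
            warnings.append(f"{phase}: multivariate comparison failed: {exc}")
            manova_by_phase[phase] = {"error": str(exc)}
            significant = list(FEATURE_COLUMNS)
        gated[phase] = stats.normality_gated_tests(sub, FEATURE_COLUMNS)

        y = (sub["side"] == PARALYZED).astype(int).to_numpy()
        cov_df = sub[covariates]
        motor_roc = stats.roc_analysis(sub["motor_time"], sub["side"])
        for dv in significant:
            fit = stats.logistic_fit(y, sub[[dv]], cov_df)
            logi_rows.append({
                "phase": phase, "feature": dv,
                "deviance": fit.deviance, "aic": fit.aic,
                "mcfadden_r2": fit.mcfadden_r2,
                "chi2": fit.chi2, "chi2_df": fit.chi2_df, "chi2_p": fit.chi2_p,
                "estimate": fit.coef(dv),
                "se": fit.standard_errors[fit.terms.index(dv)],
                "z": fit.z[fit.terms.index(dv)],
                "p": fit.p[fit.terms.index(dv)],
                "separation_flag": fit.separation_flag,
            })
            roc = (motor_roc if dv == "motor_time"
                   else stats.roc_analysis(sub[dv], sub["side"]))
            roc_rows.append({
                "phase": phase, "feature": dv,
                "cutoff": roc.cutoff,
                "sensitivity_pct": 100 * roc.cutoff_sensitivity,
                "specificity_pct": 100 * roc.cutoff_specificity,
                "youden_j": roc.cutoff_youden,
                "auc": roc.auc, "auc_se": roc.auc_se,
            })
            if dv != "motor_time":
                try:
                    auc_a, auc_b, var, z, p = stats.delong_auc_test(
                        sub["motor_time"], sub[dv], sub["side"])
                    delong_rows.append({
                        "phase": phase, "feature_a": "motor_time",
                        "feature_b": dv, "auc_a": auc_a, "auc_b": auc_b,
                        "z": z, "p": p,
                    })
                except OccireachError as exc:
                    warnings.append(f"{phase}/{dv}: DeLong comparison failed: {exc}")

    return (manova_by_phase, gated,
            pd.DataFrame(logi_rows), pd.DataFrame(roc_rows),
            pd.DataFrame(delong_rows), warnings)


def cluster_conditions(frame_rows: pd.DataFrame,
                       forest: clustering.ForestConfig,
                       k_max: int, seed: int) -> dict:
    """Pattern clustering for each side x phase condition."""
    out = {}
    for i, (side, phase) in enumerate(
            [(PARALYZED, kinematics.OUTWARD), (NON_PARALYZED, kinematics.OUTWARD),
             (PARALYZED, kinematics.RETURN), (NON_PARALYZED, kinematics.RETURN)]):
        sub = frame_rows[(frame_rows["side"] == side)
                         & (frame_rows["phase"] == phase)]
        X = sub[CLUSTER_VARIABLES].to_numpy(dtype=float)
        cfg = dataclasses.replace(forest, seed=forest.seed + i)
        sol = clustering.cluster_motion_patterns(
            X, CLUSTER_VARIABLES, forest_config=cfg,
            k_max=k_max, seed=seed + i)
        key = f"{phase}_{side}"
        out[key] = {
            "k": sol.k, "n": int(X.shape[0]),
            "r_squared": sol.r_squared,
            "aic": sol.aic_by_k[sol.k], "bic": sol.bic_by_k[sol.k],
            "wss_by_k": {str(k): v for k, v in sol.wss_by_k.items()},
            "aic_by_k": {str(k): v for k, v in sol.aic_by_k.items()},
            "bic_by_k": {str(k): v for k, v in sol.bic_by_k.items()},
            "low_confidence": sol.low_confidence,
            "profiles": json.loads(sol.profiles.to_json(orient="records")),
            "assignments": sol.assignments.tolist(),
        }
        log.info("clustering %s: k=%d (n=%d, R^2=%.2f)", key, sol.k,
                 X.shape[0], sol.r_squared)
    return out


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full analysis; deterministic under the config seed."""
    log.info("effective parameters: speed_eps=%.3g mm/s, window=%.2f s, "
             "filter=%g Hz order %d, ROC direction=higher-predicts-paralyzed, "
             "decomposition=abduction-atan2/flexion-asin",
             config.extraction.speed_eps_mm_s, config.extraction.window_s,
             config.extraction.filter_cutoff_hz, config.extraction.filter_order)
    warnings: list[str] = []
    trials = _load_or_simulate(config)
    n_participants = len({t.participant_id for t in trials})
    if n_participants < 5 or len(trials) < 30:
        warnings.append(
            f"small sample: {n_participants} participants / {len(trials)} trials;"
            " inferential results are unstable")

    features = kinematics.extract_cohort_features(trials, config.extraction)
    frame_rows = pd.concat(
        [kinematics.extract_frame_rows(t, config.extraction, config.frame_stride)
         for t in trials], ignore_index=True)

    desc = stats.descriptives(
        features.assign(group=features["phase"] + "/" + features["side"]),
        FEATURE_COLUMNS + kinematics.DISPLACEMENT_COLUMNS, factor="group")

    manova, gated, logistic, roc, delong, stage_warnings = discriminate(features)
    warnings += stage_warnings

    clusters = cluster_conditions(frame_rows, config.forest,
                                  config.k_max, config.seed + 100)

    report = RunReport(config=config.to_dict(), warnings=warnings,
                       descriptives=desc, manova=manova, gated_tests=gated,
                       logistic=logistic, roc=roc, delong=delong,
                       clusters=clusters, features=features,
                       frame_rows=frame_rows)
    if config.output_dir:
        _write_artifacts(report, config)
    return report


def _write_artifacts(report: RunReport, config: PipelineConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.features.to_csv(out / "features.csv", index=False)
    report.frame_rows.to_csv(out / "frame_rows.csv", index=False)
    report.descriptives.to_csv(out / "descriptives.csv", index=False)
    report.roc.to_csv(out / "roc_cutoffs.csv", index=False)
    for key, summary in report.clusters.items():
        curve = pd.DataFrame({
            "k": [int(k) for k in summary["wss_by_k"]],
            "wss": list(summary["wss_by_k"].values()),
            "aic": list(summary["aic_by_k"].values()),
            "bic": list(summary["bic_by_k"].values()),
        })
        curve.to_csv(out / f"cluster_curve_{key}.csv", index=False)
        phase, side = key.split("_", 1)
        rows = report.frame_rows[(report.frame_rows["side"] == side)
                                 & (report.frame_rows["phase"] == phase)]
        assigned = rows[["participant_id", "trial_id", "frame"]].copy()
        assigned["cluster"] = summary["assignments"]
        assigned.to_csv(out / f"cluster_assignments_{key}.csv", index=False)
    (out / "report.json").write_text(
        json.dumps(report.to_json_dict(), indent=2, default=float))
    log.info("artifacts written to %s", out)
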