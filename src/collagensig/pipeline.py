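"""End-to-end orchestration: simulate -> extract -> fit -> evaluate.

A single :class:`PipelineConfig` carries every knob of every stage; a run is
a pure function of (config, master seed).  The master seed spawns one child
seed per stage (simulation, split, LASSO CV, bootstrap) through
``numpy.random.SeedSequence`` so stages cannot couple through a shared
stream.  Every intermediate — feature tables, model JSONs, association
tables, performance reports, optional figures — is persisted under the run
directory together with a manifest.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clinical import (NomogramClassifier, INTEGRATED_MODEL_VARIABLES, split_cohort,
                       univariate_logistic)
from .evaluation import (bootstrap_ci, delong_test, evaluate_model, roc_auc,
                         youden_threshold)
from .features import (FEATURE_NAMES, FeatureConfig, aggregate_patient,
                       extract_feature_vector)
from .signature import CollagenSignature
from .simulate import CohortParams, FiberFieldParams, PatientRecord, simulate_cohort

CLINICAL_VARIABLES = ("location_upper", "size_gt1cm", "tci")


@dataclass(frozen=True)
class PipelineConfig:
    """All parameters of a full synthetic-cohort run."""

    seed: int = 0
    n_patients: int = 350
    rois_per_patient: int = 5
    image_size_px: int = 128
    pixel_size_um: float = 1000.0 / 512.0
    n_fibers: int | None = None          # None: scale with image area
    crosslink_rate: float = 0.5
    orientation_kappa: float = 2.0
    fiber_intensity_mean: float = 170.0
    background_noise_sd: float = 8.0
    beta_aggressiveness: float = 1.8
    split_ratio: float = 0.6
    folds: int = 5
    n_lambdas: int = 100
    bootstrap_B: int = 1000
    threshold_rule: str | float = "youden_on_train"
    n_gray: int = 32
    figures: bool = False

    def resolved_n_fibers(self) -> int:
        if self.n_fibers is not None:
            return self.n_fibers
        return max(6, round(60 * (self.image_size_px / 512) ** 2))

    def fiber_params(self) -> FiberFieldParams:
        return FiberFieldParams(
            n_fibers=self.resolved_n_fibers(),
            crosslink_rate=self.crosslink_rate,
            orientation_kappa=self.orientation_kappa,
            fiber_intensity_mean=self.fiber_intensity_mean,
            background_noise_sd=self.background_noise_sd,
            image_size_px=self.image_size_px,
            pixel_size_um=self.pixel_size_um,
        )

    def cohort_params(self) -> CohortParams:
        return CohortParams(
            n_patients=self.n_patients,
            rois_per_patient=self.rois_per_patient,
            beta_aggressiveness=self.beta_aggressiveness,
            base_fiber_params=self.fiber_params(),
        )

    def feature_config(self) -> FeatureConfig:
        return FeatureConfig(n_gray=self.n_gray)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)


def stage_seeds(master_seed: int) -> dict[str, int]:
    """Derive one independent integer seed per pipeline stage."""
    children = np.random.SeedSequence(master_seed).spawn(4)
    names = ("simulate", "split", "lasso", "bootstrap")
    return {name: int(c.generate_state(1)[0] % (2 ** 31))
            for name, c in zip(names, children)}


@dataclass
class PipelineResult:
    config: PipelineConfig
    seeds: dict[str, int]
    patient_table: pd.DataFrame          # covariates, label, cohort, signature
    roi_features: pd.DataFrame
    patient_features: pd.DataFrame
    signature_model: CollagenSignature
    integrated_model: NomogramClassifier
    clinical_model: NomogramClassifier
    univariate: pd.DataFrame
    multivariate: pd.DataFrame           # adjusted OR/CI/p per cohort
    performance: pd.DataFrame            # metric/value/CI per cohort
    reports: dict = field(default_factory=dict)
    out_dir: Path | None = None


def extract_cohort_features(records: list[PatientRecord],
                            fconfig: FeatureConfig
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-ROI and per-patient (ROI-mean) 142-feature tables."""
    roi_rows, pat_rows = [], []
    failed = 0
    for rec in records:
        vectors = []
        for j, img in enumerate(rec.images):
            try:
                fv = extract_feature_vector(img, fconfig)
            except Exception:  # pragma: no cover - defensive; counted, skipped
                failed += 1
                continue
            vectors.append(fv)
            roi_rows.append({"patient_id": rec.patient_id, "roi": j + 1,
                             **fv.to_dict()})
        agg = aggregate_patient(vectors, expected=len(rec.images))
        rec.features = agg.values
        pat_rows.append({"patient_id": rec.patient_id, **agg.to_dict()})
    if failed:
        warnings.warn(f"{failed} ROI(s) failed feature extraction and were "
                      "skipped", stacklevel=2)
    return pd.DataFrame(roi_rows), pd.DataFrame(pat_rows)


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None
                 ) -> PipelineResult:
    """Execute the full study protocol on one synthetic cohort."""
    seeds = stage_seeds(config.seed)
    records = simulate_cohort(config.cohort_params(), seeds["simulate"])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        roi_feat, pat_feat = extract_cohort_features(records,
                                                     config.feature_config())

    train_idx, test_idx = split_cohort(len(records), config.split_ratio,
                                       seeds["split"])
    cohort = np.array(["test"] * len(records), dtype=object)
    cohort[train_idx] = "train"
    for rec, c in zip(records, cohort):
        rec.cohort = str(c)

    X = pat_feat[list(FEATURE_NAMES)]
    y = np.array([rec.label for rec in records], dtype=float)
    is_train = cohort == "train"

    sig = CollagenSignature(folds=config.folds, seed=seeds["lasso"],
                            n_lambdas=config.n_lambdas)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sig.fit(X[is_train], y[is_train])
    signature = sig.decision_function(X)

    table = pd.DataFrame({
        "patient_id": [rec.patient_id for rec in records],
        "location_upper": [rec.covariates["location_upper"] for rec in records],
        "size_gt1cm": [rec.covariates["size_gt1cm"] for rec in records],
        "tci": [rec.covariates["tci"] for rec in records],
        "signature": signature,
        "label": y,
        "cohort": cohort,
        "aggressiveness": [rec.aggressiveness for rec in records],
        "true_probability": [rec.true_probability for rec in records],
    })
    train = table[table.cohort == "train"]
    test = table[table.cohort == "test"]

    # univariate screens, per cohort
    uni_rows = []
    for cname, part in (("train", train), ("test", test)):
        for var in INTEGRATED_MODEL_VARIABLES:
            try:
                r = univariate_logistic(part, var)
                uni_rows.append({"cohort": cname, **r.as_row()})
            except ValueError:
                uni_rows.append({"cohort": cname, "variable": var,
                                 "OR": np.nan, "CI_low": np.nan,
                                 "CI_high": np.nan, "p": np.nan,
                                 "coef": np.nan, "unstable": True})
    univariate = pd.DataFrame(uni_rows)

    # multivariate models: integrated (signature + clinical) fit on train,
    # and refit per cohort for the adjusted-OR association report
    integrated = NomogramClassifier(INTEGRATED_MODEL_VARIABLES).fit(
        train[list(INTEGRATED_MODEL_VARIABLES)], train.label)
    clinical = NomogramClassifier(CLINICAL_VARIABLES).fit(
        train[list(CLINICAL_VARIABLES)], train.label)
    multi_rows = []
    for cname, part in (("train", train), ("test", test)):
        m = NomogramClassifier(INTEGRATED_MODEL_VARIABLES).fit(
            part[list(INTEGRATED_MODEL_VARIABLES)], part.label)
        for a in m.associations_:
            multi_rows.append({"cohort": cname, **a.as_row()})
    multivariate = pd.DataFrame(multi_rows)

    p_int_train = integrated.predict_proba(train[list(INTEGRATED_MODEL_VARIABLES)])[:, 1]
    p_int_test = integrated.predict_proba(test[list(INTEGRATED_MODEL_VARIABLES)])[:, 1]
    p_cli_train = clinical.predict_proba(train[list(CLINICAL_VARIABLES)])[:, 1]
    p_cli_test = clinical.predict_proba(test[list(CLINICAL_VARIABLES)])[:, 1]

    if config.threshold_rule == "youden_on_train":
        threshold = youden_threshold(p_int_train, train.label)
    else:
        threshold = float(config.threshold_rule)

    B, bseed = config.bootstrap_B, seeds["bootstrap"]
    reports = {}
    perf_rows = []
    for cname, probs_int, probs_cli, part in (
            ("train", p_int_train, p_cli_train, train),
            ("test", p_int_test, p_cli_test, test)):
        yc = part.label.to_numpy()
        rep = evaluate_model(probs_int, yc, threshold, B=B, seed=bseed)
        sig_auc = roc_auc(part.signature, yc)
        sig_ci = bootstrap_ci(roc_auc, part.signature, yc, B=B, seed=bseed)
        cli_auc = roc_auc(probs_cli, yc)
        cli_ci = bootstrap_ci(roc_auc, probs_cli, yc, B=B, seed=bseed)
        dauc, dp = delong_test(probs_int, probs_cli, yc)
        rep.extras = {
            "signature_auc": sig_auc, "signature_auc_ci": sig_ci,
            "clinical_auc": cli_auc, "clinical_auc_ci": cli_ci,
            "delong_integrated_vs_clinical": {"delta_auc": dauc, "p": dp},
        }
        reports[cname] = rep
        for metric, value in rep.metrics.items():
            lo, hi = rep.metric_cis[metric]
            perf_rows.append({"cohort": cname, "metric": metric,
                              "value": value, "CI_low": lo, "CI_high": hi})
        perf_rows.append({"cohort": cname, "metric": "auc", "value": rep.auc,
                          "CI_low": rep.auc_ci[0], "CI_high": rep.auc_ci[1]})
    performance = pd.DataFrame(perf_rows)

    result = PipelineResult(
        config=config, seeds=seeds, patient_table=table,
        roi_features=roi_feat, patient_features=pat_feat,
        signature_model=sig, integrated_model=integrated,
        clinical_model=clinical, univariate=univariate,
        multivariate=multivariate, performance=performance, reports=reports)
    if out_dir is not None:
        result.out_dir = Path(out_dir)
        _persist(result)
    return result


def _persist(result: PipelineResult) -> None:
    out = result.out_dir
    out.mkdir(parents=True, exist_ok=True)
    result.roi_features.to_csv(out / "roi_features.csv", index=False)
    result.patient_features.to_csv(out / "patient_features.csv", index=False)
    from .features import feature_schema
    (out / "feature_schema.json").write_text(json.dumps(feature_schema(),
                                                        indent=1))
    result.patient_table.to_csv(out / "patients.csv", index=False)
    result.univariate.to_csv(out / "univariate.csv", index=False)
    result.multivariate.to_csv(out / "multivariate_associations.csv", index=False)
    result.performance.to_csv(out / "performance_metrics.csv", index=False)
    result.signature_model.save(out / "signature_model.json")
    for cname, rep in result.reports.items():
        rep.calibration.to_csv(out / f"calibration_{cname}.csv", index=False)
        rep.decision.to_csv(out / f"decision_curve_{cname}.csv", index=False)
    summary = {
        c: {
            "auc": rep.auc, "auc_ci": list(rep.auc_ci),
            "threshold": rep.threshold,
            "metrics": rep.metrics,
            "metric_cis": {k: list(v) for k, v in rep.metric_cis.items()},
            "confusion": rep.confusion,
            **{k: (v if not isinstance(v, tuple) else list(v))
               for k, v in rep.extras.items()},
        } for c, rep in result.reports.items()
    }
    (out / "evaluation.json").write_text(json.dumps(summary, indent=1))
    manifest = {
        "version": __version__,
        "config": result.config.to_dict(),
        "stage_seeds": result.seeds,
        "n_features": len(FEATURE_NAMES),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    if result.config.figures:
        _figures(result)


def _figures(result: PipelineResult) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from sklearn.metrics import roc_curve

    out = result.out_dir
    for cname, rep in result.reports.items():
        part = result.patient_table[result.patient_table.cohort == cname]
        model = result.integrated_model
        probs = model.predict_proba(part[list(model.variables)])[:, 1]

        fig, ax = plt.subplots(figsize=(4, 4))
        fpr, tpr, _ = roc_curve(part.label, probs)
        ax.plot(fpr, tpr, label=f"integrated (AUC {rep.auc:.3f})")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend(loc="lower right", fontsize=8)
        fig.tight_layout()
        fig.savefig(out / f"roc_{cname}.png", dpi=150)
        plt.close(fig)

        fig, ax = plt.subplots(figsize=(4, 4))
        ax.plot(rep.calibration.mean_predicted, rep.calibration.observed, "o-")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("predicted probability")
        ax.set_ylabel("observed frequency")
        fig.tight_layout()
        fig.savefig(out / f"calibration_{cname}.png", dpi=150)
        plt.close(fig)

        fig, ax = plt.subplots(figsize=(4, 4))
        dc = rep.decision
        ax.plot(dc.threshold, dc.net_benefit_model, label="model")
        ax.plot(dc.threshold, dc.net_benefit_all, label="treat all")
        ax.plot(dc.threshold, dc.net_benefit_none, label="treat none")
        ax.set_ylim(bottom=-0.05)
        ax.set_xlabel("threshold probability")
        ax.set_ylabel("net benefit")
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(out / f"dca_{cname}.png", dpi=150)
        plt.close(fig)
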