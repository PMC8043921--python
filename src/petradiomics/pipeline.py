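"""End-to-end orchestration: simulate → reduce → fit → validate → report.

A single master seed fans out to per-stage seeds through a fixed counter
scheme (``stage_seed = (master_seed + offset) mod 2^31`` with documented
offsets), so any stage can be re-run in isolation and the whole run is a
pure function of its :class:`RunConfig`.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

from . import __version__
from .markers import cluster_covariate_association
from .models import build_model_suite, lasso_select
from .reduction import cluster_patients, reduce_features
from .synthcohort import CohortSpec, generate_cohort
from .validate import bootstrap_validate

__all__ = ["RunConfig", "RunReport", "run_pipeline", "STAGE_OFFSETS"]

STAGE_OFFSETS = {"simulate": 1, "reduce": 2, "lasso": 3, "fit": 4, "validate": 5}


def stage_seed(master: int, stage: str) -> int:
    return int((master + STAGE_OFFSETS[stage]) % (2**31 - 1))


@dataclass
class RunConfig:
    """Serializable configuration of one pipeline run."""

    n_patients: int = 96
    prev_response: float = 0.22
    marker_prevalence: dict = field(default_factory=lambda: {"her2": 0.19, "cd44": 0.63})
    beta: dict = field(default_factory=lambda: {
        "her2": -1.5, "cd44": 1.2, "cT_T3-4a": -0.8, "feat_b0_00": 0.8, "feat_b1_00": -0.8,
    })
    n_blocks: int = 7
    n_features: int = 101
    rho_within: float = 0.8
    rho_between: float = 0.0
    cut_fraction: float = 0.6
    screen_threshold: float = 0.2
    lasso_folds: int = 5
    lasso_rule: str = "min"
    B: int = 1000
    refit_policy: str = "fixed"
    seed: int = 0

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def hash(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class RunReport:
    """Machine-readable run output: one performance row per model."""

    model_rows: dict
    cluster_summary: dict
    marker_associations: dict
    selected_features: list
    provenance: dict

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "model_rows": self.model_rows,
                "cluster_summary": self.cluster_summary,
                "marker_associations": self.marker_associations,
                "selected_features": self.selected_features,
                "provenance": self.provenance,
            },
            indent=2,
            sort_keys=True,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    def hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


def run_pipeline(config: RunConfig, log=print) -> RunReport:
    """Execute the full pipeline on a simulated cohort; returns the report.

    Stages: cohort simulation, feature-cluster reduction, L1 selection of
    radiomic model features, the 12-model suite, bootstrap optimism
    correction per model, and patient-cluster vs covariate association
    checks.  Any stage error aborts with the stage named.
    """
    def _stage(name):
        log(f"[pipeline] stage {name}")

    try:
        _stage("simulate")
        spec = CohortSpec(
            n_patients=config.n_patients,
            prev_response=config.prev_response,
            marker_prevalence=dict(config.marker_prevalence),
            beta=dict(config.beta),
            n_blocks=config.n_blocks,
            n_features=config.n_features,
            rho_within=config.rho_within,
            rho_between=config.rho_between,
            seed=stage_seed(config.seed, "simulate"),
        )
        cohort = generate_cohort(spec)
        data = cohort.features
        feat_cols = cohort.feature_columns
        log(f"[pipeline] cohort n={len(data)}, {len(feat_cols)} radiomic features, "
            f"prevalence {data['response'].mean():.3f}")
    except Exception as err:
        raise RuntimeError(f"stage 'simulate' failed: {err}") from err

    try:
        _stage("reduce")
        red = reduce_features(
            data[feat_cols], data["response"].to_numpy(),
            cut_fraction=config.cut_fraction, threshold=config.screen_threshold,
        )
        log(f"[pipeline] {red['assignment'].n_clusters} feature clusters, "
            f"{len(red['selected'])} screened representatives")
    except Exception as err:
        raise RuntimeError(f"stage 'reduce' failed: {err}") from err

    try:
        _stage("lasso")
        flags = []
        if len(red["selected"]) >= 2:
            sel = lasso_select(
                data, red["selected"], folds=config.lasso_folds,
                seed=stage_seed(config.seed, "lasso"), rule=config.lasso_rule,
            )
            radiomic = sel["selected"]
            if sel["empty"]:
                reps = red["representatives"]
                radiomic = [reps.sort_values(["p", "feature"]).iloc[0]["feature"]]
                flags.append("empty L1 selection: fell back to best representative")
        else:
            radiomic = list(red["selected"])
            flags.append("fewer than 2 screened representatives: L1 step skipped")
        if not radiomic:
            reps = red["representatives"]
            radiomic = [reps.sort_values(["p", "feature"]).iloc[0]["feature"]]
            flags.append("no representative passed the screen: best p used for M2")
        log(f"[pipeline] radiomic model features: {radiomic}")
    except Exception as err:
        raise RuntimeError(f"stage 'lasso' failed: {err}") from err

    try:
        _stage("fit")
        suite = build_model_suite(
            data,
            clinical_covariates=("histology_squamous", "cT_T3-4a"),
            radiomic_covariates=radiomic,
        )
    except Exception as err:
        raise RuntimeError(f"stage 'fit' failed: {err}") from err

    try:
        _stage("validate")
        rows = {}
        vseed = stage_seed(config.seed, "validate")
        for name, model in suite.items():
            markers_used = [c for c in ("her2", "cd44") if c in model.spec.covariates]
            rows_data = data.dropna(subset=markers_used) if markers_used else data
            report = bootstrap_validate(rows_data, model, B=config.B, seed=vseed,
                                        refit_policy=config.refit_policy)
            rows[name] = {
                "covariates": list(model.spec.covariates),
                "n": model.n,
                "aic": model.aic,
                "apparent": report.apparent,
                "optimism": report.optimism,
                "corrected": report.corrected,
                "failed_resamples": report.n_failed,
            }
        log(f"[pipeline] validated {len(rows)} models at B={config.B}")
    except Exception as err:
        raise RuntimeError(f"stage 'validate' failed: {err}") from err

    try:
        _stage("associations")
        _, passign = cluster_patients(data[feat_cols], cut_fraction=config.cut_fraction)
        pclusters = passign.assignment.to_numpy()
        assoc = {}
        for cov in ("histology_squamous", "cT_T3-4a", "cN_N2-3", "her2", "cd44"):
            vals = data[cov].dropna()
            try:
                res = cluster_covariate_association(pclusters[vals.index], vals)
                assoc[cov] = {"p": res.p_value, "method": res.method}
            except ValueError as err:
                assoc[cov] = {"p": None, "method": f"skipped: {err}"}
    except Exception as err:
        raise RuntimeError(f"stage 'associations' failed: {err}") from err

    provenance = {
        "config": asdict(config),
        "config_hash": config.hash(),
        "package_version": __version__,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in STAGE_OFFSETS},
        "flags": flags,
        "truth_intercept": cohort.truth["intercept"],
    }
    return RunReport(
        model_rows=rows,
        cluster_summary={
            "n_feature_clusters": red["assignment"].n_clusters,
            "n_patient_clusters": passign.n_clusters,
            "representatives": red["representatives"].reset_index().to_dict("records"),
        },
        marker_associations=assoc,
        selected_features=list(radiomic),
        provenance=provenance,
    )
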