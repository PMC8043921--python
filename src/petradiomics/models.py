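"""Logistic model building: univariable screening, LASSO selection, and the
12-model suite.

The suite follows a fixed design: a clinical reference model (M1: histology
+ clinical T-stage), a radiomic reference model (M2: the LASSO-selected
radiomic features), their union (M3), and each reference model augmented
with HER2 (M4-M6), CD44 (M7-M9), or both markers (M10-M12).  Marker models
are fitted on marker-complete cases only.

All final models are ordinary (unpenalized) maximum-likelihood logistic
fits; the L1 penalty is used solely to select the radiomic feature set,
with the penalty weight tuned by stratified cross-validated deviance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "FittedModel",
    "ModelSpec",
    "fit_logistic",
    "lrt_pvalue",
    "univariable_screen",
    "lasso_select",
    "build_model_suite",
    "encode_clinical",
    "MODEL_NAMES",
]

MODEL_NAMES = tuple(f"M{i}" for i in range(1, 13))

#: absolute log-odds coefficient beyond which we call the fit separated
SEPARATION_COEF = 15.0


@dataclass
class ModelSpec:
    name: str
    covariates: tuple[str, ...]
    outcome: str = "response"


@dataclass
class FittedModel:
    """An unpenalized logistic fit with its likelihood bookkeeping.

    ``params``/``bse`` are indexed by ``["intercept", *covariates]``;
    ``aic = 2k - 2*llf`` with k the number of estimated parameters.
    """

    spec: ModelSpec
    params: pd.Series
    bse: pd.Series
    llf: float
    llnull: float
    n: int
    converged: bool
    separation: bool
    flags: list[str] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.params)

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.llf

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        """Predicted event probabilities, strictly inside (0, 1)."""
        eta = np.full(len(data), self.params["intercept"], dtype=float)
        for name in self.spec.covariates:
            eta += self.params[name] * data[name].to_numpy(dtype=float)
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        return np.clip(p, 1e-15, 1 - 1e-15)


class OneClassError(ValueError):
    """The outcome has a single class; the model is not identifiable."""


def _design(data: pd.DataFrame, covariates) -> np.ndarray:
    X = np.column_stack(
        [np.ones(len(data))] + [data[c].to_numpy(dtype=float) for c in covariates]
    )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns by incremental rank check
        bad = []
        cols = [X[:, :1]]
        for idx, c in enumerate(covariates):
            trial = np.column_stack(cols + [X[:, idx + 1]])
            if np.linalg.matrix_rank(trial) == trial.shape[1]:
                cols.append(X[:, idx + 1 : idx + 2])
            else:
                bad.append(c)
        raise ValueError(f"design matrix is rank deficient; collinear terms: {bad}")
    return X


def fit_logistic(data: pd.DataFrame, covariates, outcome: str = "response", name: str = "model") -> FittedModel:
    """Maximum-likelihood logistic regression (IRLS via statsmodels).

    Raises on a one-class outcome or a rank-deficient design; quasi-complete
    separation is detected by diverging coefficients and flagged, not
    silently accepted.
    """
    covariates = tuple(covariates)
    y = data[outcome].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise OneClassError(f"outcome {outcome!r} has a single class")
    if len(data) <= len(covariates) + 1:
        raise ValueError(f"n={len(data)} too small for {len(covariates)} covariates")
    X = _design(data, covariates)
    with warnings.catch_warnings(), np.errstate(all="ignore"):
        # IRLS on separated data emits perfect-prediction warnings; we detect
        # separation explicitly below and flag it instead.  bse/llf are lazy
        # statsmodels properties, so force them inside the guard.
        warnings.simplefilter("ignore")
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
        idx = ["intercept", *covariates]
        params = pd.Series(res.params, index=idx)
        bse = pd.Series(res.bse, index=idx)
        llf = float(res.llf)
    converged = bool(getattr(res, "converged", True))
    separation = bool(np.any(np.abs(res.params) > SEPARATION_COEF)) or not converged
    flags = ["possible separation: coefficients diverged"] if separation else []
    p0 = y.mean()
    llnull = float(np.sum(y * np.log(p0) + (1 - y) * np.log1p(-p0)))
    return FittedModel(
        spec=ModelSpec(name, covariates, outcome),
        params=params,
        bse=bse,
        llf=llf,
        llnull=llnull,
        n=len(y),
        converged=converged,
        separation=separation,
        flags=flags,
    )


def lrt_pvalue(model: FittedModel, df: int | None = None) -> float:
    """Likelihood-ratio p-value against the intercept-only model."""
    if df is None:
        df = model.k - 1
    g2 = max(0.0, 2.0 * (model.llf - model.llnull))
    return float(stats.chi2.sf(g2, df))


def univariable_screen(
    data: pd.DataFrame, features, outcome: str = "response", threshold: float = 0.2
) -> pd.DataFrame:
    """Per-feature univariable logistic LRT; keep = (p < threshold).

    Returns a DataFrame indexed by feature with columns ``p``, ``keep``,
    ``separation``.  Perfect-separation fits still yield a guarded LRT p
    (the deviance is finite after coefficient clipping) and are flagged.
    """
    rows = {}
    for feat in features:
        m = fit_logistic(data, [feat], outcome=outcome, name=f"uni:{feat}")
        rows[feat] = {"p": lrt_pvalue(m, df=1), "separation": m.separation}
    out = pd.DataFrame(rows).T
    out["keep"] = out["p"] < threshold
    return out


def lasso_select(
    data: pd.DataFrame,
    features,
    outcome: str = "response",
    lambda_grid: np.ndarray | None = None,
    folds: int = 5,
    seed: int = 0,
    rule: str = "min",
) -> dict:
    """Select radiomic features by L1-penalized logistic regression.

    Candidate features are standardized internally; the penalty weight is
    chosen on a log-spaced grid by stratified ``folds``-fold cross-validated
    binomial deviance (``rule="min"``; ``rule="1se"`` takes the sparsest
    model within one standard error of the minimum).  The selection is the
    nonzero-coefficient set at the chosen penalty; an empty set is legal and
    flagged, the caller decides the fallback.
    """
    features = list(features)
    if len(features) < 2:
        raise ValueError("need at least 2 candidate features for selection")
    y = data[outcome].to_numpy(dtype=float)
    X = data[features].to_numpy(dtype=float)
    mu, sd = X.mean(0), X.std(0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    if lambda_grid is None:
        lambda_grid = np.geomspace(1e-3, 10.0, 40)

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(Xs, y))
    dev = np.zeros((len(lambda_grid), folds))
    for li, lam in enumerate(lambda_grid):
        C = 1.0 / (lam * len(y))
        for fi, (tr, te) in enumerate(splits):
            clf = LogisticRegression(l1_ratio=1.0, C=C, solver="liblinear", max_iter=1000)
            clf.fit(Xs[tr], y[tr])
            p = np.clip(clf.predict_proba(Xs[te])[:, 1], 1e-12, 1 - 1e-12)
            dev[li, fi] = -2.0 * np.mean(y[te] * np.log(p) + (1 - y[te]) * np.log1p(-p))
    mean_dev = dev.mean(axis=1)
    se_dev = dev.std(axis=1, ddof=1) / np.sqrt(folds)
    best = int(np.argmin(mean_dev))
    if rule == "1se":
        cutoff = mean_dev[best] + se_dev[best]
        ok = np.nonzero(mean_dev <= cutoff)[0]
        best = int(ok[np.argmax(lambda_grid[ok])])  # sparsest admissible
    elif rule != "min":
        raise ValueError(f"unknown rule {rule!r}")
    lam = float(lambda_grid[best])
    clf = LogisticRegression(l1_ratio=1.0, C=1.0 / (lam * len(y)), solver="liblinear", max_iter=1000)
    clf.fit(Xs, y)
    nonzero = np.abs(clf.coef_.ravel()) > 1e-10
    selected = [f for f, nz in zip(features, nonzero) if nz]
    return {
        "selected": selected,
        "lambda": lam,
        "lambda_grid": np.asarray(lambda_grid),
        "cv_deviance": mean_dev,
        "empty": len(selected) == 0,
    }


def encode_clinical(df: pd.DataFrame) -> pd.DataFrame:
    """Dichotomized clinical covariates and binary markers from a validated table.

    Indicator coding mirrors the published strata: histology squamous vs
    adenocarcinoma, cT T3-4a vs T1-2, cN N2-3 vs N0-1.  Marker columns map
    positive → 1, negative → 0, missing → NaN (complete-case handling is the
    caller's responsibility).
    """
    out = pd.DataFrame(index=df.index)
    out["histology_squamous"] = (df["histology"] == "squamous").astype(int)
    out["cT_T3-4a"] = (df["cT"] == "T3-4a").astype(int)
    out["cN_N2-3"] = (df["cN"] == "N2-3").astype(int)
    for marker in ("her2", "cd44", "hif1a_nucleus", "hif1a_cytosol", "ptch1", "shh"):
        if marker in df.columns:
            out[marker] = df[marker].map({"positive": 1.0, "negative": 0.0}).astype(float)
    if "response" in df.columns:
        out["response"] = df["response"].astype(int)
    return out


def build_model_suite(
    data: pd.DataFrame,
    clinical_covariates=("histology_squamous", "cT_T3-4a"),
    radiomic_covariates=(),
    her2_col: str = "her2",
    cd44_col: str = "cd44",
    outcome: str = "response",
) -> dict[str, FittedModel]:
    """Fit the 12-model suite; returns name → :class:`FittedModel`.

    ``radiomic_covariates`` is the LASSO-selected feature set.  Models that
    involve a marker are fitted on the rows where that marker is non-missing
    (NaN marks missing).
    """
    clin = tuple(clinical_covariates)
    rad = tuple(radiomic_covariates)
    specs = {
        "M1": clin,
        "M2": rad,
        "M3": clin + rad,
        "M4": clin + (her2_col,),
        "M5": rad + (her2_col,),
        "M6": clin + rad + (her2_col,),
        "M7": clin + (cd44_col,),
        "M8": rad + (cd44_col,),
        "M9": clin + rad + (cd44_col,),
        "M10": clin + (her2_col, cd44_col),
        "M11": rad + (her2_col, cd44_col),
        "M12": clin + rad + (her2_col, cd44_col),
    }
    suite = {}
    for name, covs in specs.items():
        markers_used = [c for c in (her2_col, cd44_col) if c in covs]
        rows = data
        if markers_used:
            rows = data.dropna(subset=markers_used)
        suite[name] = fit_logistic(rows, covs, outcome=outcome, name=name)
    return suite
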