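"""Model performance measures and bootstrap optimism correction.

The report mirrors the standard internal-validation panel for a clinical
logistic model: overall performance (Nagelkerke R², Brier score),
discrimination (AUC with tie-corrected Mann-Whitney counting, and the
discrimination slope — mean predicted risk in events minus non-events), and
calibration (calibration-in-the-large intercept with the slope fixed at 1,
and the logistic recalibration slope of the outcome on the linear
predictor).

Optimism correction is Harrell's bootstrap: each resample refits the model
(by a caller-chosen policy), is scored on itself (boot-apparent) and on the
original sample (boot-test); optimism is the mean gap and
``corrected = apparent - optimism``.  Resampling is stratified on the
outcome to reduce degenerate one-class resamples; failed refits are dropped
and counted, and more than 20% failures is a hard error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import logit
from scipy.stats import rankdata

from .models import FittedModel, fit_logistic

__all__ = [
    "MEASURES",
    "PerformanceReport",
    "nagelkerke_r2",
    "brier",
    "auc",
    "discrimination_slope",
    "calibration_coefficients",
    "performance_measures",
    "bootstrap_validate",
    "calibration_curve",
]

MEASURES = ("nagelkerke_r2", "brier", "auc", "discrimination_slope",
            "calibration_intercept", "calibration_slope")


def nagelkerke_r2(llnull: float, llf: float, n: int) -> float:
    """Nagelkerke R²: Cox-Snell R² rescaled by its attainable maximum."""
    if llf < llnull - 1e-8:
        raise AssertionError("fitted log-likelihood below the null: not a nested MLE")
    cox_snell = 1.0 - np.exp((2.0 / n) * (llnull - llf))
    max_cs = 1.0 - np.exp((2.0 / n) * llnull)
    return float(cox_snell / max_cs) if max_cs > 0 else 0.0


def brier(p: np.ndarray, y: np.ndarray) -> float:
    """Mean squared error of the predicted probabilities."""
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(np.mean((p - y) ** 2))


def auc(p: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney AUC; tied predictions count 1/2."""
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=int)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: a single outcome class")
    r = rankdata(p)
    u = r[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def discrimination_slope(p: np.ndarray, y: np.ndarray) -> float:
    """Mean predicted risk among events minus among non-events."""
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=int)
    if y.min() == y.max():
        raise ValueError("discrimination slope undefined: a single outcome class")
    return float(p[y == 1].mean() - p[y == 0].mean())


def calibration_coefficients(p: np.ndarray, y: np.ndarray, clip: float = 1e-8) -> tuple[float, float]:
    """Calibration intercept and slope of outcomes on logit predictions.

    Slope b from the recalibration fit ``y ~ a + b*logit(p)``; the intercept
    is calibration-in-the-large: ``a`` refitted with b fixed at 1 (offset
    logistic model).  Probabilities are clipped to [clip, 1-clip].
    """
    p = np.clip(np.asarray(p, dtype=float), clip, 1 - clip)
    y = np.asarray(y, dtype=float)
    lp = logit(p)
    if np.ptp(lp) == 0:
        raise ValueError("calibration slope undefined: constant predictions")
    with warnings.catch_warnings(), np.errstate(all="ignore"):
        warnings.simplefilter("ignore")
        slope_fit = sm.GLM(y, np.column_stack([np.ones_like(lp), lp]),
                           family=sm.families.Binomial()).fit()
        intercept_fit = sm.GLM(y, np.ones((len(y), 1)), family=sm.families.Binomial(),
                               offset=lp).fit()
        a, b = float(intercept_fit.params[0]), float(slope_fit.params[1])
    return a, b


def performance_measures(p: np.ndarray, y: np.ndarray) -> dict[str, float]:
    """All six measures from predictions and outcomes on one dataset."""
    p = np.clip(np.asarray(p, dtype=float), 1e-15, 1 - 1e-15)
    y = np.asarray(y, dtype=float)
    n = len(y)
    ll = float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))
    p0 = y.mean()
    ll0 = float(np.sum(y * np.log(p0) + (1 - y) * np.log1p(-p0)))
    out = {
        "nagelkerke_r2": nagelkerke_r2(ll0, max(ll, ll0), n),
        "brier": brier(p, y),
        "auc": auc(p, y),
        "discrimination_slope": discrimination_slope(p, y),
    }
    try:
        a, b = calibration_coefficients(p, y)
    except ValueError:
        a, b = np.nan, np.nan
    # a separated recalibration fit diverges; its coefficients carry no
    # information, so report them as undefined rather than astronomically
    if not np.isfinite(a) or abs(a) > 50:
        a = np.nan
    if not np.isfinite(b) or abs(b) > 50:
        b = np.nan
    out["calibration_intercept"] = a
    out["calibration_slope"] = b
    return out


@dataclass
class PerformanceReport:
    """Apparent, optimism and corrected values for each measure."""

    apparent: dict[str, float]
    optimism: dict[str, float]
    corrected: dict[str, float]
    aic: float
    B: int
    seed: int
    n_failed: int = 0
    flags: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"apparent": self.apparent, "optimism": self.optimism, "corrected": self.corrected}
        )


def _default_refit(boot: pd.DataFrame, model: FittedModel):
    """Fixed-covariate policy: refit the coefficients of the given model."""
    refit = fit_logistic(boot, model.spec.covariates, outcome=model.spec.outcome,
                         name=model.spec.name)
    return refit.predict


def bootstrap_validate(
    data: pd.DataFrame,
    model: FittedModel,
    B: int = 20000,
    seed: int = 0,
    refit_policy="fixed",
    max_failure_rate: float = 0.2,
) -> PerformanceReport:
    """Optimism-corrected performance of ``model`` by Harrell's bootstrap.

    ``refit_policy`` is ``"fixed"`` (refit the coefficients of the model's
    fixed covariate set on each resample) or a callable
    ``f(boot_data) -> predict_fn`` re-running any amount of the selection
    pipeline inside the resample.  Deterministic for a given seed and B.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    y = data[model.spec.outcome].to_numpy(dtype=int)
    apparent = performance_measures(model.predict(data), y)
    rng = np.random.default_rng(seed)
    idx_pos = np.flatnonzero(y == 1)
    idx_neg = np.flatnonzero(y == 0)

    sums = {m: 0.0 for m in MEASURES}
    counts = {m: 0 for m in MEASURES}
    done = 0
    failed = 0
    for _ in range(B):
        boot_idx = np.concatenate(
            [
                rng.choice(idx_pos, size=len(idx_pos), replace=True),
                rng.choice(idx_neg, size=len(idx_neg), replace=True),
            ]
        )
        boot = data.iloc[boot_idx]
        try:
            if refit_policy == "fixed":
                predict = _default_refit(boot, model)
            else:
                predict = refit_policy(boot)
            m_boot = performance_measures(predict(boot), y[boot_idx])
            m_test = performance_measures(predict(data), y)
        except Exception:
            failed += 1
            continue
        # per-measure aggregation: a resample where one measure is undefined
        # (e.g. a separated recalibration fit) still informs the others
        for m in MEASURES:
            diff = m_boot[m] - m_test[m]
            if np.isfinite(diff):
                sums[m] += diff
                counts[m] += 1
        done += 1
    if failed > max_failure_rate * B or done == 0:
        raise RuntimeError(
            f"bootstrap refit failed on {failed}/{B} resamples "
            f"(> {max_failure_rate:.0%}); model too unstable for internal validation"
        )
    optimism = {m: sums[m] / counts[m] if counts[m] else np.nan for m in MEASURES}
    corrected = {m: apparent[m] - optimism[m] for m in MEASURES}
    flags = [f"{failed} failed resamples dropped"] if failed else []
    for m in MEASURES:
        if counts[m] < done:
            flags.append(f"{m}: undefined on {done - counts[m]}/{done} resamples")
    return PerformanceReport(
        apparent=apparent,
        optimism=optimism,
        corrected=corrected,
        aic=model.aic,
        B=B,
        seed=seed,
        n_failed=failed,
        flags=flags,
    )


def calibration_curve(p: np.ndarray, y: np.ndarray, n_bins: int = 10) -> pd.DataFrame:
    """Grouped observed-vs-predicted calibration points plus a smoothed curve.

    Returns a table with one row per non-empty quantile bin (columns
    ``p_mean``, ``obs_rate``, ``n``) and, merged on ``p_grid``, a lowess
    smoothed observed-rate curve; the ideal line is the diagonal.
    """
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    edges = np.unique(np.quantile(p, np.linspace(0, 1, n_bins + 1)))
    if len(edges) < 2:  # constant predictions: a single all-inclusive bin
        edges = np.array([edges[0], edges[0] + 1e-12])
    which = np.clip(np.searchsorted(edges, p, side="right") - 1, 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        sel = which == b
        if sel.any():
            rows.append({"bin": b, "p_mean": p[sel].mean(), "obs_rate": y[sel].mean(),
                         "n": int(sel.sum())})
    binned = pd.DataFrame(rows)
    with np.errstate(all="ignore"):  # lowess on degenerate x emits divide warnings
        smooth = sm.nonparametric.lowess(y, p, frac=2.0 / 3.0, return_sorted=True)
    curve = pd.DataFrame({"p_grid": smooth[:, 0], "smoothed_obs": smooth[:, 1]})
    binned.attrs["smoothed"] = curve
    return binned
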