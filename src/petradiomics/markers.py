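"""Biomarker dichotomization and univariable 2×2 statistics.

HER2 immunohistochemistry follows the standard guideline rule: score 0 is
negative, 3+ positive, and the ambiguous 1+/2+ scores are resolved by
fluorescence in situ hybridization (FISH); without a FISH result the status
is missing.  CD44, cytosolic HIF1α and PTCH1 arrive as 15-point
immuno-reactivity scores dichotomized upstream (the cut-point is a config
field, consumed as given); nuclear HIF1α and SHH are present/absent calls.

Diagnostic metrics carry exact Clopper-Pearson binomial confidence
intervals.  Fisher's exact test uses the two-sided point-probability
convention (sum of all tables at fixed margins whose probability does not
exceed the observed table's, with a small relative tolerance), the
convention of mainstream statistical software.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyTable2x2",
    "DiagnosticMetrics",
    "dichotomize_her2",
    "diagnostic_metrics",
    "fisher_exact",
    "cluster_covariate_association",
]


@dataclass
class ContingencyTable2x2:
    """Counts laid out as rows = exposure levels, columns = outcome levels.

    ::

                     col_levels[0]   col_levels[1]
      row_levels[0]        a               b
      row_levels[1]        c               d
    """

    a: int
    b: int
    c: int
    d: int
    row_levels: tuple[str, str] = ("positive", "negative")
    col_levels: tuple[str, str] = ("event", "non-event")
    name: str = ""

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if int(v) != v or v < 0:
                raise ValueError(f"counts must be nonnegative integers, got {v}")
        if self.total == 0:
            raise ValueError("contingency table is empty")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def to_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)

    def row_sums(self) -> tuple[int, int]:
        return (self.a + self.b, self.c + self.d)

    def col_sums(self) -> tuple[int, int]:
        return (self.a + self.c, self.b + self.d)


@dataclass
class _Rate:
    """A proportion with its exact binomial confidence interval."""

    value: float | None
    numer: int
    denom: int
    ci: tuple[float, float] | None
    defined: bool = True


@dataclass
class DiagnosticMetrics:
    sensitivity: _Rate
    specificity: _Rate
    ppv: _Rate
    npv: _Rate
    flags: list[str] = field(default_factory=list)


def _exact_rate(k: int, n: int, alpha: float = 0.05) -> _Rate:
    if n == 0:
        return _Rate(None, k, n, None, defined=False)
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return _Rate(k / n, k, n, (lo, hi))


def dichotomize_her2(ihc_score: str, fish: str = "unavailable") -> str:
    """Dichotomize a HER2 immunohistochemistry score.

    ``ihc_score`` in {"0", "1+", "2+", "3+"}; ``fish`` in
    {"amplified", "not_amplified", "unavailable"}.  Score 0 → negative,
    3+ → positive; 1+/2+ are decided by FISH and become ``missing`` when no
    FISH result exists.
    """
    score = str(ihc_score)
    valid_fish = ("amplified", "not_amplified", "unavailable")
    if fish not in valid_fish:
        raise ValueError(f"invalid FISH result {fish!r}; expected one of {valid_fish}")
    if score == "0":
        return "negative"
    if score == "3+":
        return "positive"
    if score in ("1+", "2+"):
        if fish == "amplified":
            return "positive"
        if fish == "not_amplified":
            return "negative"
        return "missing"
    raise ValueError(f"invalid HER2 IHC score {ihc_score!r}; expected 0/1+/2+/3+")


def diagnostic_metrics(table: ContingencyTable2x2) -> DiagnosticMetrics:
    """Sensitivity/specificity/PPV/NPV of row-positivity for column-events.

    Layout per :class:`ContingencyTable2x2`: ``a`` = test-positive with
    event (true positive), ``b`` = test-positive without event, ``c`` =
    test-negative with event, ``d`` = test-negative without event.  Empty
    margins leave the affected metric undefined (flagged, not zeroed).
    """
    t = table
    flags = []
    out = {}
    for metric, (k, n) in {
        "sensitivity": (t.a, t.a + t.c),
        "specificity": (t.d, t.b + t.d),
        "ppv": (t.a, t.a + t.b),
        "npv": (t.d, t.c + t.d),
    }.items():
        rate = _exact_rate(k, n)
        if not rate.defined:
            flags.append(f"{metric} undefined: empty margin")
        out[metric] = rate
    return DiagnosticMetrics(flags=flags, **out)


def fisher_exact(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p-value (point-probability method).

    Delegates to the standard hypergeometric implementation; equivalence to
    a full enumeration over all tables with the observed margins is part of
    the test suite's oracle checks.
    """
    return float(stats.fisher_exact(table.to_array(), alternative="two-sided")[1])


@dataclass
class AssociationResult:
    p_value: float
    statistic: float | None
    method: str
    flags: list[str] = field(default_factory=list)


def cluster_covariate_association(
    patient_clusters,
    covariate,
    rng: np.random.Generator | None = None,
    n_permutations: int = 20000,
) -> AssociationResult:
    """Test association between patient-cluster labels and a categorical covariate.

    Pearson χ² on the clusters × covariate contingency table; when more than
    20% of expected cells fall below 5 the χ² approximation is unreliable and
    the test switches to an exact alternative (Fisher for 2×2, otherwise a
    seeded permutation test of the χ² statistic), flagged in the result.
    """
    clusters = pd.Categorical(patient_clusters)
    cov = pd.Categorical(covariate)
    if len(clusters) != len(cov):
        raise ValueError("cluster labels and covariate must align")
    if len(clusters.categories) < 2:
        raise ValueError("need at least 2 patient clusters")
    if len(cov.categories) < 2:
        raise ValueError("covariate is degenerate (single level)")
    table = pd.crosstab(clusters, cov).to_numpy()
    chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
    if (expected < 5).mean() <= 0.2:
        return AssociationResult(float(p), float(chi2), "chi2")
    if table.shape == (2, 2):
        p = float(stats.fisher_exact(table)[1])
        return AssociationResult(p, None, "fisher_exact", ["sparse table: exact test used"])
    if rng is None:
        rng = np.random.default_rng(0)
    # margins are fixed under permutation, so E is constant and the statistic
    # reduces to sum(O^2/E) - n
    r, c = table.shape
    ccodes = np.asarray(clusters.codes)
    vcodes = np.asarray(cov.codes).copy()
    n = len(ccodes)
    inv_e = 1.0 / expected.ravel()
    count = 0
    for _ in range(n_permutations):
        rng.shuffle(vcodes)
        obs = np.bincount(ccodes * c + vcodes, minlength=r * c)
        stat = float((obs * obs * inv_e).sum()) - n
        if stat >= chi2 - 1e-12:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return AssociationResult(float(p), float(chi2), "permutation_chi2",
                             ["sparse table: permutation test used"])
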