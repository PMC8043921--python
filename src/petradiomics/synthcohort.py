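"""Synthetic inputs for the response-prediction pipeline.

The study this package models used a private cohort, so every pipeline input
is generated here under explicit, seeded specifications:

* PET-like **phantoms** — an ellipsoidal lesion with a smoothed Gaussian
  random field (GRF) as texture.  A GRF gives controllable spatial
  autocorrelation, which is exactly what the Moran's I / Geary's C features
  and the texture families quantify, without pretending to model anatomy or
  scanner physics.
* **Block-correlated feature tables** — multivariate-normal feature blocks
  with a target within-block Spearman correlation, emulating the redundancy
  structure that hierarchical feature clustering is meant to collapse.
* **Cohorts** — clinical covariates, binary tumor markers and a binary
  response drawn from a known logistic model, with the generating
  coefficients stored for parameter-recovery tests.
* **Printed-count fixtures** — the 2×2 contingency tables and deterministic
  per-patient clinical tables whose margins match the published cohort
  (n=96 with 21 complete responders; marker sub-cohort n=43 with 9).

Defaults follow the published cohort's marginals: response prevalence 0.22,
HER2 positivity 0.19, CD44 positivity 0.63.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, label
from scipy.optimize import brentq
from scipy.special import expit

from .markers import ContingencyTable2x2
from .petio import PETVolume, ROIMask, validate_clinical

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "SyntheticCohort",
    "generate_phantom",
    "generate_block_features",
    "generate_cohort",
    "published_fixtures",
    "fixture_clinical_group1",
    "fixture_clinical_group2",
]


# --------------------------------------------------------------------------
# phantoms
# --------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Specification of an ellipsoidal PET phantom.

    ``texture_corr_mm`` is the Gaussian smoothing length of the random
    texture field (mm); ``texture_amplitude`` its standard deviation in SUV.
    ``noise_sd`` adds white voxel noise (SUV).  The ellipsoid is centred on
    the grid and must fit fully inside it.
    """

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    ellipsoid_radii: tuple[float, float, float] = (18.0, 14.0, 12.0)
    base_suv: float = 6.0
    texture_corr_mm: float = 6.0
    texture_amplitude: float = 1.5
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.ellipsoid_radii):
            raise ValueError(f"ellipsoid radii must be positive, got {self.ellipsoid_radii}")
        if self.base_suv <= 0:
            raise ValueError(f"base_suv must be positive, got {self.base_suv}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        extent = [n * s for n, s in zip(self.grid_shape, self.spacing)]
        # centre-placed ellipsoid needs a one-voxel margin on each side
        for r, e, s, n in zip(self.ellipsoid_radii, extent, self.spacing, self.grid_shape):
            if 2 * r > e - 2 * s:
                raise ValueError(
                    f"ellipsoid (radius {r} mm) exceeds grid extent {e} mm "
                    f"({n} voxels at {s} mm); enlarge the grid or shrink the lesion"
                )


def generate_phantom(spec: PhantomSpec) -> tuple[PETVolume, ROIMask]:
    """Generate an ellipsoidal PET phantom and its mask.

    In-mask SUV = ``base_suv`` + GRF texture + white noise, clipped at 0
    (SUV is nonnegative); background is 0.  The mask depends only on the
    geometry, never on the seed, and is a single connected component.
    Identical specs (including seed) give bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(n) for n in spec.grid_shape)
    sp = np.asarray(spec.spacing, dtype=float)
    centre = (np.asarray(shape) - 1) / 2.0 * sp
    axes = [np.arange(n) * s for n, s in zip(shape, sp)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    rr = np.asarray(spec.ellipsoid_radii, dtype=float)
    inside = (
        ((xx - centre[0]) / rr[0]) ** 2
        + ((yy - centre[1]) / rr[1]) ** 2
        + ((zz - centre[2]) / rr[2]) ** 2
    ) <= 1.0
    if not inside.any():
        raise ValueError("ellipsoid digitizes to zero voxels on this grid")

    values = np.zeros(shape, dtype=float)
    texture = np.zeros(shape, dtype=float)
    if spec.texture_amplitude > 0:
        white = rng.standard_normal(shape)
        sigma_vox = np.asarray([spec.texture_corr_mm / s for s in sp])
        grf = gaussian_filter(white, sigma=sigma_vox) if np.any(sigma_vox > 0) else white
        sd = grf.std()
        if sd > 0:
            texture = grf / sd * spec.texture_amplitude
    noise = rng.standard_normal(shape) * spec.noise_sd if spec.noise_sd > 0 else 0.0
    values[inside] = spec.base_suv + texture[inside] + (
        noise[inside] if np.ndim(noise) else 0.0
    )
    np.clip(values, 0.0, None, out=values)

    n_comp = label(inside)[1]
    assert n_comp == 1, "ellipsoid mask must be one connected component"
    vol = PETVolume(values, tuple(sp))
    mask = ROIMask(inside, tuple(sp), provenance=f"synthetic ellipsoid seed={spec.seed}")
    return vol, mask


# --------------------------------------------------------------------------
# feature tables and cohorts
# --------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Specification of a synthetic patient cohort.

    ``beta`` maps covariate names (clinical indicator, feature or marker
    columns) to true log-odds coefficients.  If it contains an
    ``"intercept"`` entry that value is used as-is; otherwise the intercept
    is tuned so the mean event probability equals ``prev_response``.

    ``rho_within`` is the target within-block *Spearman* correlation of the
    radiomic feature blocks (converted internally to the Pearson correlation
    of the generating Gaussian).
    """

    n_patients: int = 96
    prev_response: float = 0.22
    marker_prevalence: dict[str, float] = field(
        default_factory=lambda: {"her2": 0.19, "cd44": 0.63}
    )
    beta: dict[str, float] = field(default_factory=dict)
    n_blocks: int = 7
    block_sizes: tuple[int, ...] | None = None
    rho_within: float = 0.8
    rho_between: float = 0.0
    n_features: int = 101
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if not 0.0 <= self.prev_response <= 1.0:
            raise ValueError("prev_response must be a probability")
        for m, p in self.marker_prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"marker prevalence for {m!r} must be in [0,1]")
        if abs(self.rho_within) > 1 or abs(self.rho_between) > 1:
            raise ValueError("correlations must lie in [-1, 1]")
        if self.block_sizes is None:
            base = self.n_features // self.n_blocks
            sizes = [base] * self.n_blocks
            for i in range(self.n_features - base * self.n_blocks):
                sizes[i] += 1
            self.block_sizes = tuple(sizes)
        if sum(self.block_sizes) != self.n_features:
            raise ValueError(
                f"block sizes {self.block_sizes} sum to {sum(self.block_sizes)}, "
                f"expected n_features={self.n_features}"
            )


@dataclass
class SyntheticCohort:
    """Bundle of generated features, labels and the generating truth."""

    features: pd.DataFrame
    labels: np.ndarray
    truth: dict
    images: list[tuple[PETVolume, ROIMask]] | None = None

    @property
    def feature_columns(self) -> list[str]:
        return [c for c in self.features.columns if c.startswith("feat_")]


def _spearman_to_pearson(rho_s: float) -> float:
    # bivariate-normal identity rho_s = (6/pi) asin(rho_p / 2)
    return float(2.0 * np.sin(np.pi * rho_s / 6.0))


def _block_covariance(spec: CohortSpec) -> np.ndarray:
    p = spec.n_features
    rw = _spearman_to_pearson(spec.rho_within)
    rb = _spearman_to_pearson(spec.rho_between)
    cov = np.full((p, p), rb)
    start = 0
    for b, size in enumerate(spec.block_sizes):
        blk = slice(start, start + size)
        cov[blk, blk] = rw
        # within-block PSD condition for an equicorrelated block
        if size > 1 and (rw < -1.0 / (size - 1) or rw > 1.0):
            raise ValueError(
                f"block {b} (size {size}) has non-positive-semidefinite "
                f"within-block correlation {spec.rho_within}"
            )
        start += size
    np.fill_diagonal(cov, 1.0)
    eigmin = np.linalg.eigvalsh(cov).min()
    if eigmin < -1e-10:
        raise ValueError(
            f"block correlation matrix is not positive semidefinite "
            f"(min eigenvalue {eigmin:.3g}); check between-block rho {spec.rho_between}"
        )
    return cov


def generate_block_features(spec: CohortSpec, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw an n_patients × n_features table with block-correlated columns.

    Columns are named ``feat_b{block}_{index}`` so block membership is
    recoverable in clustering-recovery experiments.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    cov = _block_covariance(spec)
    # eigendecomposition square root: tolerant of the rho=1 boundary
    w, v = np.linalg.eigh(cov)
    w = np.clip(w, 0.0, None)
    root = v * np.sqrt(w)
    z = rng.standard_normal((spec.n_patients, spec.n_features))
    x = z @ root.T
    names = []
    for b, size in enumerate(spec.block_sizes):
        names += [f"feat_b{b}_{j:02d}" for j in range(size)]
    return pd.DataFrame(x, columns=names)


CLINICAL_INDICATORS = {
    "histology_squamous": 8 / 96,
    "cT_T3-4a": 85 / 96,
    "cN_N2-3": 28 / 96,
}


def generate_cohort(spec: CohortSpec, with_images: bool = False) -> SyntheticCohort:
    """Generate a full synthetic cohort from a known logistic model.

    Covariates: three binary clinical indicators with the published cohort's
    marginal frequencies, binary markers at ``marker_prevalence``, and the
    block-correlated radiomic feature table.  Labels are Bernoulli(expit(Xβ)).
    Markers and features are generated independently by default, mirroring
    the observed lack of association between imaging phenotype clusters and
    marker status.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    df = generate_block_features(spec, rng)
    for name, prev in CLINICAL_INDICATORS.items():
        df[name] = (rng.random(n) < prev).astype(int)
    for marker, prev in spec.marker_prevalence.items():
        df[marker] = (rng.random(n) < prev).astype(int)

    unknown = [k for k in spec.beta if k != "intercept" and k not in df.columns]
    if unknown:
        raise ValueError(f"beta names covariates absent from the cohort: {unknown}")
    eta = np.zeros(n)
    for name, b in spec.beta.items():
        if name != "intercept":
            eta += b * df[name].to_numpy(dtype=float)

    if "intercept" in spec.beta:
        intercept = float(spec.beta["intercept"])
    else:
        target = float(np.clip(spec.prev_response, 1e-6, 1 - 1e-6))

        def gap(c: float) -> float:
            return float(expit(c + eta).mean() - target)

        intercept = brentq(gap, -40.0, 40.0)
    p = expit(intercept + eta)
    labels = (rng.random(n) < p).astype(int)
    df["response"] = labels

    truth = {"beta": dict(spec.beta), "intercept": intercept, "prob": p}
    images = None
    if with_images:
        images = []
        for i in range(n):
            pspec = PhantomSpec(
                grid_shape=(24, 24, 24),
                ellipsoid_radii=(9.0, 8.0, 7.0),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            images.append(generate_phantom(pspec))
    return SyntheticCohort(features=df, labels=labels, truth=truth, images=images)


# --------------------------------------------------------------------------
# printed-count fixtures
# --------------------------------------------------------------------------

def published_fixtures() -> dict:
    """Published 2×2 contingency tables and response counts, bit-exact.

    Keys
    ----
    ``her2_response_g1``
        HER2 status × response in the full cohort (n=94 after excluding the
        two patients with indeterminate HER2).
    ``cd44_response_g2``
        CD44 status × response in the marker sub-cohort (n=43).
    ``her2_tstage_g1`` / ``cd44_tstage_g2``
        Marker status × clinical T-stage.
    ``response_counts_g1`` / ``response_counts_g2``
        (complete, incomplete) responder counts.
    """
    return {
        "her2_response_g1": ContingencyTable2x2(
            a=1, b=17, c=19, d=57,
            row_levels=("positive", "negative"),
            col_levels=("pCR", "non-pCR"),
            name="HER2 x response (full cohort)",
        ),
        "cd44_response_g2": ContingencyTable2x2(
            a=8, b=19, c=1, d=15,
            row_levels=("positive", "negative"),
            col_levels=("pCR", "non-pCR"),
            name="CD44 x response (marker sub-cohort)",
        ),
        "her2_tstage_g1": ContingencyTable2x2(
            a=0, b=18, c=11, d=65,
            row_levels=("positive", "negative"),
            col_levels=("T1-2", "T3-4a"),
            name="HER2 x clinical T-stage",
        ),
        "cd44_tstage_g2": ContingencyTable2x2(
            a=1, b=15, c=5, d=22,
            row_levels=("negative", "positive"),
            col_levels=("T1-2", "T3-4a"),
            name="CD44 x clinical T-stage",
        ),
        "response_counts_g1": (21, 75),
        "response_counts_g2": (9, 34),
    }


def _rows(n: int, **assignments) -> pd.DataFrame:
    """Build n rows; each kwarg maps column -> list of (count, level) runs."""
    out = {}
    for col, runs in assignments.items():
        vals = []
        for count, level in runs:
            vals += [level] * count
        assert len(vals) == n, f"{col}: {len(vals)} != {n}"
        out[col] = vals
    return pd.DataFrame(out)


def fixture_clinical_group1() -> pd.DataFrame:
    """Deterministic synthetic 96-patient clinical table.

    Synthetic reconstruction: every printed pairwise margin involving the
    response (histology, T/N stage, chemotherapy cycles, Mandard grade, HER2)
    and the HER2 × T-stage joint (no HER2-positive T1-2 tumors) is matched
    exactly; joint cells that were never printed are filled by a fixed
    feasible assignment.  Markers only measured in the sub-cohort are
    ``missing`` here.
    """
    pcr = _rows(
        21,
        histology=[(5, "squamous"), (16, "adenocarcinoma")],
        cT=[(5, "T1-2"), (1, "T1-2"), (15, "T3-4a")],
        cN=[(19, "N0-1"), (2, "N2-3")],
        chemo_cycles=[(4, 4), (17, 5)],
        mandard=[(21, 1)],
        her2=[(6, "negative"), (1, "positive"), (1, "missing"), (13, "negative")],
    )
    non = _rows(
        75,
        histology=[(3, "squamous"), (72, "adenocarcinoma")],
        cT=[(5, "T1-2"), (70, "T3-4a")],
        cN=[(49, "N0-1"), (26, "N2-3")],
        chemo_cycles=[(14, 4), (61, 5)],
        mandard=[(24, 2), (33, 3), (16, 4), (2, 5)],
        her2=[(5, "negative"), (17, "positive"), (1, "missing"), (52, "negative")],
    )
    df = pd.concat([pcr, non], ignore_index=True)
    df.insert(0, "id", [f"G1-{i + 1:03d}" for i in range(96)])
    for col in ("cd44", "hif1a_nucleus", "hif1a_cytosol", "ptch1", "shh"):
        df[col] = "missing"
    return validate_clinical(df)


def fixture_clinical_group2() -> pd.DataFrame:
    """Deterministic synthetic 43-patient marker sub-cohort table.

    Matches the printed margins: 9/34 responders, CD44 1/8 (pCR) and 15/19
    (non-pCR) negative/positive, CD44 × T-stage {(−,T1-2)=1, (−,T3-4a)=15,
    (+,T1-2)=5, (+,T3-4a)=22}, HER2 8 positive all in non-responders with one
    indeterminate responder, exactly 6 patients HER2+/CD44+ (all
    non-responders), and the printed HIF1α/PTCH1/SHH distributions.
    """
    pcr = _rows(
        9,
        cd44=[(1, "negative"), (8, "positive")],
        cT=[(1, "T3-4a"), (3, "T1-2"), (5, "T3-4a")],
        her2=[(1, "missing"), (8, "negative")],
        histology=[(8, "adenocarcinoma"), (1, "squamous")],
        cN=[(8, "N0-1"), (1, "N2-3")],
        chemo_cycles=[(2, 4), (7, 5)],
        mandard=[(9, 1)],
        hif1a_nucleus=[(1, "positive"), (8, "negative")],
        hif1a_cytosol=[(2, "negative"), (7, "positive")],
        ptch1=[(2, "negative"), (7, "positive")],
        shh=[(9, "positive")],
    )
    non = _rows(
        34,
        cd44=[(15, "negative"), (19, "positive")],
        cT=[(1, "T1-2"), (14, "T3-4a"), (2, "T1-2"), (17, "T3-4a")],
        her2=[(1, "negative"), (2, "positive"), (12, "negative"),
              (2, "negative"), (6, "positive"), (11, "negative")],
        histology=[(34, "adenocarcinoma")],
        cN=[(22, "N0-1"), (12, "N2-3")],
        chemo_cycles=[(8, 4), (26, 5)],
        mandard=[(12, 2), (17, 3), (4, 4), (1, 5)],
        hif1a_nucleus=[(3, "positive"), (31, "negative")],
        hif1a_cytosol=[(13, "negative"), (21, "positive")],
        ptch1=[(4, "negative"), (30, "positive")],
        shh=[(3, "negative"), (31, "positive")],
    )
    df = pd.concat([pcr, non], ignore_index=True)
    df.insert(0, "id", [f"G2-{i + 1:03d}" for i in range(43)])
    return validate_clinical(df)
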