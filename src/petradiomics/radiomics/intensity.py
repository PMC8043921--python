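"""Intensity-statistical and local-intensity features.

The statistical family holds 16 conventional first-order statistics of the
in-mask SUV distribution plus the two spatial-autocorrelation statistics,
Moran's I and Geary's C, computed over voxel positions in mm with
inverse-Euclidean-distance weights:

    I = (N / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2
    C = ((N - 1) / (2 S0)) * sum_ij w_ij (x_i - x_j)^2 / sum_i z_i^2

with z_i = x_i - mean(x), w_ij = 1 / d_ij (i != j), S0 = sum_ij w_ij.  Both
are exact for ROIs up to ``max_exact`` voxels; larger ROIs are reduced by
deterministic intensity-stratified subsampling (flagged), keeping the cost
bounded at O(max_exact^2).

The local-intensity family is SUVpeak: the sphere used has a volume of
1 cm^3 (radius 6.204 mm) and is averaged over all image voxels whose centre
falls inside it (in-grid, mask membership not required).  ``peak_global`` is
the maximum sphere-mean over in-mask centres; ``peak_local`` is the
sphere-mean centred at the hottest in-mask voxel (the larger sphere-mean on
ties).
"""

from __future__ import annotations

import numpy as np

from ..petio import PETVolume, ROIMask

__all__ = [
    "STAT_FEATURES",
    "LOCAL_FEATURES",
    "intensity_statistics",
    "morans_i_gearys_c",
    "suv_peak",
]

STAT_FEATURES = (
    "mean",
    "median",
    "minimum",
    "maximum",
    "p10",
    "p90",
    "iqr",
    "range",
    "variance",
    "skewness",
    "kurtosis",
    "mad",
    "rmad",
    "energy",
    "rms",
    "cov",
    "moran_i",
    "gearys_c",
)

LOCAL_FEATURES = ("peak_local", "peak_global")

#: 1 cm^3 sphere radius, mm
PEAK_RADIUS_MM = (3.0 * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)


def _stratified_subsample(x: np.ndarray, coords: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic subsample of k voxels stratified over the intensity order."""
    order = np.argsort(x, kind="stable")
    pick = order[np.linspace(0, len(x) - 1, k).round().astype(int)]
    pick = np.unique(pick)
    return x[pick], coords[pick]


def morans_i_gearys_c(
    x: np.ndarray,
    coords_mm: np.ndarray,
    max_exact: int = 20000,
) -> tuple[float, float, list[str]]:
    """Moran's I and Geary's C with inverse-distance weights (see module doc)."""
    flags: list[str] = []
    x = np.asarray(x, dtype=float)
    coords = np.asarray(coords_mm, dtype=float)
    n = len(x)
    if n < 2:
        return np.nan, np.nan, ["fewer than 2 voxels: autocorrelation undefined"]
    if x.var() == 0:
        return np.nan, np.nan, ["zero in-mask variance: autocorrelation undefined"]
    if n > max_exact:
        x, coords = _stratified_subsample(x, coords, max_exact)
        n = len(x)
        flags.append(f"autocorrelation subsampled to {n} voxels (deterministic, stratified)")

    z = x - x.mean()
    sz2 = float(np.sum(z * z))
    s0 = 0.0
    num_i = 0.0
    num_c = 0.0
    chunk = max(1, int(2**22 // max(n, 1)))  # ~32 MB of doubles per block
    for start in range(0, n, chunk):
        sl = slice(start, min(start + chunk, n))
        d = np.sqrt(((coords[sl, None, :] - coords[None, :, :]) ** 2).sum(-1))
        with np.errstate(divide="ignore"):
            w = 1.0 / d
        rows = np.arange(sl.start, sl.stop)
        w[rows - sl.start, rows] = 0.0
        s0 += float(w.sum())
        num_i += float(z[sl] @ (w @ z))
        diff2 = (x[sl, None] - x[None, :]) ** 2
        num_c += float((w * diff2).sum())
    moran = (n / s0) * num_i / sz2
    geary = ((n - 1) / (2.0 * s0)) * num_c / sz2
    return float(moran), float(geary), flags


def intensity_statistics(
    vol: PETVolume, mask: ROIMask, max_exact_autocorr: int = 20000
) -> tuple[dict, dict]:
    """The 18 statistical features; returns (values, flags)."""
    mask.check_grid(vol)
    x = vol.values[mask.values]
    values: dict[str, float] = {}
    flags: dict[str, str] = {}

    p10, q1, med, q3, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    mean = float(x.mean())
    values["mean"] = mean
    values["median"] = float(med)
    values["minimum"] = float(x.min())
    values["maximum"] = float(x.max())
    values["p10"] = float(p10)
    values["p90"] = float(p90)
    values["iqr"] = float(q3 - q1)
    values["range"] = float(x.max() - x.min())
    var = float(x.var())  # population variance
    values["variance"] = var
    sd = np.sqrt(var)
    if sd > 0:
        zc = (x - mean) / sd
        values["skewness"] = float(np.mean(zc**3))
        values["kurtosis"] = float(np.mean(zc**4) - 3.0)  # excess
        values["cov"] = sd / mean if mean != 0 else np.nan
        if mean == 0:
            flags["cov"] = "zero mean"
    else:
        values["skewness"] = np.nan
        values["kurtosis"] = np.nan
        values["cov"] = 0.0 if mean != 0 else np.nan
        flags["skewness"] = flags["kurtosis"] = "zero variance"
    values["mad"] = float(np.mean(np.abs(x - mean)))
    inner = x[(x >= p10) & (x <= p90)]
    values["rmad"] = float(np.mean(np.abs(inner - inner.mean()))) if inner.size else np.nan
    values["energy"] = float(np.sum(x**2))
    values["rms"] = float(np.sqrt(np.mean(x**2)))

    coords = np.argwhere(mask.values) * np.asarray(mask.spacing)
    moran, geary, ac_flags = morans_i_gearys_c(x, coords, max_exact=max_exact_autocorr)
    values["moran_i"] = moran
    values["gearys_c"] = geary
    for f in ac_flags:
        flags["moran_i"] = flags["gearys_c"] = f
    return values, flags


def _sphere_offsets(spacing, radius_mm: float) -> np.ndarray:
    sp = np.asarray(spacing, dtype=float)
    r_vox = np.ceil(radius_mm / sp).astype(int)
    grids = np.meshgrid(*[np.arange(-r, r + 1) for r in r_vox], indexing="ij")
    off = np.stack([g.ravel() for g in grids], axis=1)
    d = np.linalg.norm(off * sp, axis=1)
    return off[d <= radius_mm + 1e-9]


def suv_peak(vol: PETVolume, mask: ROIMask, radius_mm: float = PEAK_RADIUS_MM) -> tuple[dict, dict]:
    """The two local-intensity features; returns (values, flags)."""
    mask.check_grid(vol)
    offsets = _sphere_offsets(vol.spacing, radius_mm)
    shape = np.asarray(vol.shape)
    centres = np.argwhere(mask.values)
    sums = np.zeros(len(centres))
    counts = np.zeros(len(centres), dtype=int)
    for off in offsets:
        pos = centres + off
        ok = np.all((pos >= 0) & (pos < shape), axis=1)
        if not ok.any():
            continue
        p = pos[ok]
        sums[ok] += vol.values[p[:, 0], p[:, 1], p[:, 2]]
        counts[ok] += 1
    means = sums / counts
    peak_global = float(means.max())
    suv = vol.values[centres[:, 0], centres[:, 1], centres[:, 2]]
    hottest = suv == suv.max()
    peak_local = float(means[hottest].max())  # larger sphere-mean on ties
    return {"peak_local": peak_local, "peak_global": peak_global}, {}
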