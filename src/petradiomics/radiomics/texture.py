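"""Texture-matrix feature families: GLCM, GLRLM, GLSZM, NGTDM.

All families operate on a :class:`~petradiomics.radiomics.discretize.DiscretizedROI`
(gray levels 1..Ng, 0 outside the mask).  Directional families (GLCM, GLRLM)
use the 13 unique 3D directions at Chebyshev distance 1 and by default
average the per-direction feature values; a merged-matrix variant (features
computed once on the direction-summed matrix) is available.  GLSZM zones and
NGTDM neighbourhoods use 26-connectivity.

Where a feature's defining sum is empty (e.g. inverse variance with a single
gray level: no i != j mass) the value is 0 when the formula forces it and
NaN + flag when it is genuinely undefined (e.g. GLCM correlation of a
constant region).  The NGTDM coarseness denominator carries an epsilon guard
(1e-12); hitting the guard is flagged as a capped value.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .discretize import DiscretizedROI

__all__ = [
    "DIRECTIONS_13",
    "GLCM_FEATURES",
    "GLRLM_FEATURES",
    "GLSZM_FEATURES",
    "NGTDM_FEATURES",
    "glcm_matrix",
    "glcm_features",
    "glrlm_matrix",
    "glrlm_features",
    "glszm_matrix",
    "glszm_features",
    "ngtdm_table",
    "ngtdm_features",
]

#: the 13 unique 3D directions (one per +/- pair) at distance 1
DIRECTIONS_13 = (
    (0, 0, 1), (0, 1, -1), (0, 1, 0), (0, 1, 1),
    (1, -1, -1), (1, -1, 0), (1, -1, 1), (1, 0, -1),
    (1, 0, 0), (1, 0, 1), (1, 1, -1), (1, 1, 0), (1, 1, 1),
)

NGTDM_EPS = 1e-12


def _offset_views(arr: np.ndarray, d: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Aligned views a, b with b displaced by d relative to a."""
    sl_a, sl_b = [], []
    for n, step in zip(arr.shape, d):
        if step == 0:
            sl_a.append(slice(None))
            sl_b.append(slice(None))
        elif step > 0:
            sl_a.append(slice(0, n - step))
            sl_b.append(slice(step, n))
        else:
            sl_a.append(slice(-step, n))
            sl_b.append(slice(0, n + step))
    return arr[tuple(sl_a)], arr[tuple(sl_b)]


# --------------------------------------------------------------------------
# GLCM
# --------------------------------------------------------------------------

GLCM_FEATURES = (
    "joint_maximum",
    "joint_average",
    "joint_variance",
    "joint_entropy",
    "difference_average",
    "difference_variance",
    "difference_entropy",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "angular_second_moment",
    "contrast",
    "dissimilarity",
    "inverse_difference",
    "inverse_difference_norm",
    "inverse_difference_moment",
    "inverse_difference_moment_norm",
    "inverse_variance",
    "correlation",
    "autocorrelation",
    "cluster_tendency",
    "cluster_shade",
    "cluster_prominence",
    "information_correlation_1",
    "information_correlation_2",
)


def glcm_matrix(d: DiscretizedROI, direction: tuple[int, int, int]) -> np.ndarray:
    """Symmetric co-occurrence count matrix for one direction at distance 1."""
    ng = d.ng
    a, b = _offset_views(d.levels, direction)
    valid = (a > 0) & (b > 0)
    i, j = a[valid] - 1, b[valid] - 1
    counts = np.bincount(i * ng + j, minlength=ng * ng).reshape(ng, ng).astype(float)
    return counts + counts.T


def _glcm_features_from_p(p: np.ndarray) -> dict[str, float]:
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)  # symmetric: px == py
    mu = float((ii * p).sum())
    sig2 = float(((ii - mu) ** 2 * p).sum())

    out: dict[str, float] = {}
    out["joint_maximum"] = float(p.max())
    out["joint_average"] = mu
    out["joint_variance"] = sig2
    nz = p[p > 0]
    out["joint_entropy"] = float(-(nz * np.log2(nz)).sum())

    k_abs = np.abs(ii - jj)
    pdm = np.bincount(k_abs.ravel(), weights=p.ravel(), minlength=ng)
    kk = np.arange(ng)
    da = float((kk * pdm).sum())
    out["difference_average"] = da
    out["difference_variance"] = float(((kk - da) ** 2 * pdm).sum())
    nzd = pdm[pdm > 0]
    out["difference_entropy"] = float(-(nzd * np.log2(nzd)).sum())

    psum = np.bincount((ii + jj).ravel(), weights=p.ravel(), minlength=2 * ng + 1)
    ks = np.arange(2 * ng + 1)
    sa = float((ks * psum).sum())
    out["sum_average"] = sa
    out["sum_variance"] = float(((ks - sa) ** 2 * psum).sum())
    nzs = psum[psum > 0]
    out["sum_entropy"] = float(-(nzs * np.log2(nzs)).sum())

    out["angular_second_moment"] = float((p**2).sum())
    out["contrast"] = float((k_abs**2 * p).sum())
    out["dissimilarity"] = float((k_abs * p).sum())
    out["inverse_difference"] = float((p / (1.0 + k_abs)).sum())
    out["inverse_difference_norm"] = float((p / (1.0 + k_abs / ng)).sum())
    out["inverse_difference_moment"] = float((p / (1.0 + k_abs**2)).sum())
    out["inverse_difference_moment_norm"] = float((p / (1.0 + (k_abs / ng) ** 2)).sum())
    off = ii != jj
    with np.errstate(divide="ignore", invalid="ignore"):
        out["inverse_variance"] = float((p[off] / (ii - jj)[off] ** 2).sum()) if off.any() else 0.0

    if sig2 > 0:
        out["correlation"] = float(((ii * jj * p).sum() - mu * mu) / sig2)
    else:
        out["correlation"] = np.nan
    out["autocorrelation"] = float((ii * jj * p).sum())
    dev = ii + jj - 2.0 * mu
    out["cluster_tendency"] = float((dev**2 * p).sum())
    out["cluster_shade"] = float((dev**3 * p).sum())
    out["cluster_prominence"] = float((dev**4 * p).sum())

    hxy = out["joint_entropy"]
    pxpy = np.outer(px, px)
    nzm = (p > 0) & (pxpy > 0)
    hxy1 = float(-(p[nzm] * np.log2(pxpy[nzm])).sum())
    nzo = pxpy > 0
    hxy2 = float(-(pxpy[nzo] * np.log2(pxpy[nzo])).sum())
    nzx = px[px > 0]
    hx = float(-(nzx * np.log2(nzx)).sum())
    out["information_correlation_1"] = (hxy - hxy1) / hx if hx > 0 else np.nan
    out["information_correlation_2"] = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
    return out


def glcm_features(d: DiscretizedROI, aggregation: str = "average") -> tuple[dict, dict]:
    """The 25 co-occurrence features; returns (values, flags)."""
    flags: dict[str, str] = {}
    mats = [glcm_matrix(d, direction) for direction in DIRECTIONS_13]
    if aggregation == "merge":
        merged = np.sum(mats, axis=0)
        tot = merged.sum()
        if tot == 0:
            return {k: np.nan for k in GLCM_FEATURES}, {"_glcm": "no voxel pairs in any direction"}
        values = _glcm_features_from_p(merged / tot)
    elif aggregation == "average":
        per_dir = []
        for mat in mats:
            tot = mat.sum()
            if tot > 0:
                per_dir.append(_glcm_features_from_p(mat / tot))
        if not per_dir:
            return {k: np.nan for k in GLCM_FEATURES}, {"_glcm": "no voxel pairs in any direction"}
        values = {k: float(np.mean([f[k] for f in per_dir])) for k in GLCM_FEATURES}
    else:
        raise ValueError(f"unknown GLCM aggregation {aggregation!r}")
    if d.ng == 1:
        flags["correlation"] = "single gray level: undefined"
        flags["information_correlation_1"] = "single gray level: undefined"
    return values, flags


# --------------------------------------------------------------------------
# GLRLM
# --------------------------------------------------------------------------

GLRLM_FEATURES = (
    "sre", "lre", "lgre", "hgre",
    "srlge", "srhge", "lrlge", "lrhge",
    "glnu", "glnu_norm", "rlnu", "rlnu_norm",
    "run_pct", "gl_var", "rl_var", "run_entropy",
)


def glrlm_matrix(d: DiscretizedROI, direction: tuple[int, int, int]) -> np.ndarray:
    """Run-length count matrix r[i-1, j-1] (level i, run length j) for one direction."""
    lv = d.levels
    shape = lv.shape
    # run starts: in-mask voxels whose predecessor along -direction is absent or differs
    start = lv > 0
    a, b = _offset_views(lv, tuple(-s for s in direction))
    # a is the slice with a valid predecessor b; mark continuations
    cont = (a > 0) & (a == b)
    sl = tuple(
        slice(0, n - s) if s > 0 else slice(-s, n) if s < 0 else slice(None)
        for n, s in zip(shape, tuple(-s for s in direction))
    )
    start[sl] &= ~cont

    counts = np.zeros((d.ng, max(shape) * 2), dtype=float)
    dvec = np.asarray(direction)
    for pos in np.argwhere(start):
        level = lv[tuple(pos)]
        length = 1
        nxt = pos + dvec
        while (
            np.all(nxt >= 0)
            and np.all(nxt < shape)
            and lv[tuple(nxt)] == level
        ):
            length += 1
            nxt = nxt + dvec
        counts[level - 1, length - 1] += 1
    # trim trailing empty run lengths
    used = np.nonzero(counts.sum(axis=0))[0]
    jmax = used[-1] + 1 if used.size else 1
    return counts[:, :jmax]


def _rl_features(r: np.ndarray, n_voxels: int) -> dict[str, float]:
    ns = r.sum()
    i = np.arange(1, r.shape[0] + 1, dtype=float)
    j = np.arange(1, r.shape[1] + 1, dtype=float)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    out: dict[str, float] = {}
    if ns == 0:
        return {k: np.nan for k in GLRLM_FEATURES}
    out["sre"] = float((r / jj**2).sum() / ns)
    out["lre"] = float((r * jj**2).sum() / ns)
    out["lgre"] = float((r / ii**2).sum() / ns)
    out["hgre"] = float((r * ii**2).sum() / ns)
    out["srlge"] = float((r / (ii**2 * jj**2)).sum() / ns)
    out["srhge"] = float((r * ii**2 / jj**2).sum() / ns)
    out["lrlge"] = float((r * jj**2 / ii**2).sum() / ns)
    out["lrhge"] = float((r * ii**2 * jj**2).sum() / ns)
    out["glnu"] = float((r.sum(axis=1) ** 2).sum() / ns)
    out["glnu_norm"] = float((r.sum(axis=1) ** 2).sum() / ns**2)
    out["rlnu"] = float((r.sum(axis=0) ** 2).sum() / ns)
    out["rlnu_norm"] = float((r.sum(axis=0) ** 2).sum() / ns**2)
    out["run_pct"] = float(ns / n_voxels)
    p = r / ns
    mu_i = float((ii * p).sum())
    mu_j = float((jj * p).sum())
    out["gl_var"] = float(((ii - mu_i) ** 2 * p).sum())
    out["rl_var"] = float(((jj - mu_j) ** 2 * p).sum())
    nz = p[p > 0]
    out["run_entropy"] = float(-(nz * np.log2(nz)).sum())
    return out


def glrlm_features(d: DiscretizedROI, aggregation: str = "average") -> tuple[dict, dict]:
    """The 16 run-length features; returns (values, flags)."""
    n_vox = int(d.mask.sum())
    mats = [glrlm_matrix(d, direction) for direction in DIRECTIONS_13]
    if aggregation == "merge":
        jmax = max(m.shape[1] for m in mats)
        merged = np.zeros((d.ng, jmax))
        for m in mats:
            merged[:, : m.shape[1]] += m
        # merged run counts are summed over directions, as is the voxel budget
        values = _rl_features(merged, n_vox * len(DIRECTIONS_13))
    elif aggregation == "average":
        feats = [_rl_features(m, n_vox) for m in mats]
        values = {k: float(np.mean([f[k] for f in feats])) for k in GLRLM_FEATURES}
    else:
        raise ValueError(f"unknown GLRLM aggregation {aggregation!r}")
    return values, {}


# --------------------------------------------------------------------------
# GLSZM
# --------------------------------------------------------------------------

GLSZM_FEATURES = (
    "sze", "lze", "lgze", "hgze",
    "szlge", "szhge", "lzlge", "lzhge",
    "glnu", "glnu_norm", "zsnu", "zsnu_norm",
    "zone_pct", "gl_var", "zs_var", "zone_entropy",
)

_CONN26 = np.ones((3, 3, 3), dtype=int)


def glszm_matrix(d: DiscretizedROI) -> np.ndarray:
    """Zone count matrix s[i-1, j-1] (level i, zone size j); 26-connected zones."""
    sizes_per_level: list[list[int]] = []
    max_size = 1
    for level in range(1, d.ng + 1):
        lab, nz = ndimage.label(d.levels == level, structure=_CONN26)
        if nz:
            sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, nz + 1))
            sizes = sizes.astype(int).tolist()
            max_size = max(max_size, max(sizes))
        else:
            sizes = []
        sizes_per_level.append(sizes)
    s = np.zeros((d.ng, max_size), dtype=float)
    for i, sizes in enumerate(sizes_per_level):
        for size in sizes:
            s[i, size - 1] += 1
    return s


def glszm_features(d: DiscretizedROI) -> tuple[dict, dict]:
    """The 16 size-zone features (single matrix, rotation invariant)."""
    s = glszm_matrix(d)
    n_vox = int(d.mask.sum())
    rl = _rl_features(s, n_vox)  # identical functional forms, zone semantics
    rename = dict(zip(GLRLM_FEATURES, GLSZM_FEATURES))
    return {rename[k]: v for k, v in rl.items()}, {}


# --------------------------------------------------------------------------
# NGTDM
# --------------------------------------------------------------------------

NGTDM_FEATURES = ("coarseness", "contrast", "busyness", "complexity", "strength")


def ngtdm_table(d: DiscretizedROI) -> tuple[np.ndarray, np.ndarray]:
    """Per-level (n_i, s_i): occurrence counts and summed absolute differences
    from the 26-neighbourhood in-mask mean.  Voxels with no in-mask neighbour
    are excluded."""
    lv = d.levels
    m = d.mask
    nb_sum = np.zeros(lv.shape)
    nb_cnt = np.zeros(lv.shape)
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dx == dy == dz == 0:
                    continue
                a_sum, b_lv = _offset_views(nb_sum, (dz, dy, dx))
                a_cnt, _ = _offset_views(nb_cnt, (dz, dy, dx))
                lv_a, lv_b = _offset_views(lv, (dz, dy, dx))
                valid = lv_b > 0
                a_sum[valid] += lv_b[valid]
                a_cnt[valid] += 1
    ok = m & (nb_cnt > 0)
    n = np.zeros(d.ng)
    s = np.zeros(d.ng)
    levels = lv[ok]
    diffs = np.abs(levels - nb_sum[ok] / nb_cnt[ok])
    np.add.at(n, levels - 1, 1)
    np.add.at(s, levels - 1, diffs)
    return n, s


def ngtdm_features(d: DiscretizedROI) -> tuple[dict, dict]:
    """The 5 neighbourhood gray-tone-difference features; returns (values, flags)."""
    n, s = ngtdm_table(d)
    flags: dict[str, str] = {}
    ntot = n.sum()
    values: dict[str, float] = {k: np.nan for k in NGTDM_FEATURES}
    if ntot == 0:
        return values, {"_ngtdm": "no voxel has an in-mask neighbour"}
    p = n / ntot
    present = p > 0
    i = np.arange(1, d.ng + 1, dtype=float)
    np_levels = int(present.sum())

    denom = float((p * s).sum())
    values["coarseness"] = 1.0 / (NGTDM_EPS + denom)
    if denom == 0.0:
        flags["coarseness"] = "uniform region: coarseness capped at 1/eps"

    if np_levels > 1:
        pi, pj = np.meshgrid(p[present], p[present], indexing="ij")
        iv, jv = np.meshgrid(i[present], i[present], indexing="ij")
        values["contrast"] = float(
            (pi * pj * (iv - jv) ** 2).sum()
            / (np_levels * (np_levels - 1))
            * s.sum()
            / ntot
        )
        dens = float(np.abs(iv * pi - jv * pj)[iv != jv].sum())
        num = float((p * s).sum())
        values["busyness"] = num / dens if dens > 0 else np.nan
        if dens == 0:
            flags["busyness"] = "degenerate level distribution"
        si = s[present]
        sii, sjj = np.meshgrid(si, si, indexing="ij")
        values["complexity"] = float(
            (np.abs(iv - jv) * (pi * sii + pj * sjj) / (pi + pj)).sum() / ntot
        )
        values["strength"] = float(
            ((pi + pj) * (iv - jv) ** 2).sum() / (NGTDM_EPS + s.sum())
        )
    else:
        values["contrast"] = 0.0
        values["busyness"] = 0.0
        values["complexity"] = 0.0
        values["strength"] = 0.0
        flags["contrast"] = "single gray level"
    return values, flags
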