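"""Independent naive reference implementations used as test oracles.

Everything here is written as plain Python loops directly from the feature
definitions, deliberately sharing no code with the package implementation.
Intended only for tiny inputs (<= a few hundred voxels).
"""

from __future__ import annotations

import math

import numpy as np

DIRS_13 = [
    (0, 0, 1), (0, 1, -1), (0, 1, 0), (0, 1, 1),
    (1, -1, -1), (1, -1, 0), (1, -1, 1), (1, 0, -1),
    (1, 0, 0), (1, 0, 1), (1, 1, -1), (1, 1, 0), (1, 1, 1),
]


def _inb(pos, shape):
    return all(0 <= p < s for p, s in zip(pos, shape))


# ---------------------------------------------------------------- GLCM ----

def glcm_counts_naive(levels: np.ndarray, ng: int, direction) -> np.ndarray:
    c = np.zeros((ng, ng))
    shape = levels.shape
    for pos in np.argwhere(levels > 0):
        for sign in (1, -1):
            nb = tuple(pos[k] + sign * direction[k] for k in range(3))
            if _inb(nb, shape) and levels[nb] > 0:
                c[levels[tuple(pos)] - 1, levels[nb] - 1] += 1
    return c


def glcm_features_naive(p: np.ndarray) -> dict:
    ng = p.shape[0]
    out = {}
    px = [sum(p[i][j] for j in range(ng)) for i in range(ng)]
    mu = sum((i + 1) * p[i][j] for i in range(ng) for j in range(ng))
    sig2 = sum((i + 1 - mu) ** 2 * p[i][j] for i in range(ng) for j in range(ng))
    out["joint_maximum"] = max(p[i][j] for i in range(ng) for j in range(ng))
    out["joint_average"] = mu
    out["joint_variance"] = sig2
    out["joint_entropy"] = -sum(
        p[i][j] * math.log2(p[i][j]) for i in range(ng) for j in range(ng) if p[i][j] > 0
    )
    pdm = [0.0] * ng
    psum = [0.0] * (2 * ng + 1)
    for i in range(ng):
        for j in range(ng):
            pdm[abs(i - j)] += p[i][j]
            psum[i + j + 2] += p[i][j]
    da = sum(k * pdm[k] for k in range(ng))
    out["difference_average"] = da
    out["difference_variance"] = sum((k - da) ** 2 * pdm[k] for k in range(ng))
    out["difference_entropy"] = -sum(v * math.log2(v) for v in pdm if v > 0)
    sa = sum(k * psum[k] for k in range(2 * ng + 1))
    out["sum_average"] = sa
    out["sum_variance"] = sum((k - sa) ** 2 * psum[k] for k in range(2 * ng + 1))
    out["sum_entropy"] = -sum(v * math.log2(v) for v in psum if v > 0)
    out["angular_second_moment"] = sum(p[i][j] ** 2 for i in range(ng) for j in range(ng))
    out["contrast"] = sum((i - j) ** 2 * p[i][j] for i in range(ng) for j in range(ng))
    out["dissimilarity"] = sum(abs(i - j) * p[i][j] for i in range(ng) for j in range(ng))
    out["inverse_difference"] = sum(
        p[i][j] / (1 + abs(i - j)) for i in range(ng) for j in range(ng)
    )
    out["inverse_difference_norm"] = sum(
        p[i][j] / (1 + abs(i - j) / ng) for i in range(ng) for j in range(ng)
    )
    out["inverse_difference_moment"] = sum(
        p[i][j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng)
    )
    out["inverse_difference_moment_norm"] = sum(
        p[i][j] / (1 + ((i - j) / ng) ** 2) for i in range(ng) for j in range(ng)
    )
    out["inverse_variance"] = sum(
        p[i][j] / (i - j) ** 2 for i in range(ng) for j in range(ng) if i != j
    )
    corr_num = sum((i + 1) * (j + 1) * p[i][j] for i in range(ng) for j in range(ng)) - mu * mu
    out["correlation"] = corr_num / sig2 if sig2 > 0 else float("nan")
    out["autocorrelation"] = sum(
        (i + 1) * (j + 1) * p[i][j] for i in range(ng) for j in range(ng)
    )
    for power, name in ((2, "cluster_tendency"), (3, "cluster_shade"), (4, "cluster_prominence")):
        out[name] = sum(
            (i + 1 + j + 1 - 2 * mu) ** power * p[i][j] for i in range(ng) for j in range(ng)
        )
    hxy = out["joint_entropy"]
    hxy1 = -sum(
        p[i][j] * math.log2(px[i] * px[j])
        for i in range(ng) for j in range(ng)
        if p[i][j] > 0 and px[i] * px[j] > 0
    )
    hxy2 = -sum(
        px[i] * px[j] * math.log2(px[i] * px[j])
        for i in range(ng) for j in range(ng)
        if px[i] * px[j] > 0
    )
    hx = -sum(v * math.log2(v) for v in px if v > 0)
    out["information_correlation_1"] = (hxy - hxy1) / hx if hx > 0 else float("nan")
    out["information_correlation_2"] = math.sqrt(max(0.0, 1.0 - math.exp(-2 * (hxy2 - hxy))))
    return out


def glcm_averaged_naive(levels: np.ndarray, ng: int) -> dict:
    feats = []
    for d in DIRS_13:
        c = glcm_counts_naive(levels, ng, d)
        if c.sum() > 0:
            feats.append(glcm_features_naive(c / c.sum()))
    return {k: float(np.mean([f[k] for f in feats])) for k in feats[0]}


# --------------------------------------------------------------- GLRLM ----

def glrlm_counts_naive(levels: np.ndarray, ng: int, direction) -> dict:
    """{(level, run length): count} by walking every maximal line."""
    shape = levels.shape
    runs: dict[tuple[int, int], int] = {}
    starts = []
    for pos in np.ndindex(shape):
        prev = tuple(pos[k] - direction[k] for k in range(3))
        if not _inb(prev, shape):
            starts.append(pos)
    for start in starts:
        line = []
        pos = start
        while _inb(pos, shape):
            line.append(levels[pos])
            pos = tuple(pos[k] + direction[k] for k in range(3))
        i = 0
        while i < len(line):
            if line[i] == 0:
                i += 1
                continue
            j = i
            while j < len(line) and line[j] == line[i]:
                j += 1
            key = (int(line[i]), j - i)
            runs[key] = runs.get(key, 0) + 1
            i = j
    return runs


def rl_features_naive(runs: dict, n_voxels: int) -> dict:
    ns = sum(runs.values())
    out = {}
    out["sre"] = sum(c / j**2 for (_, j), c in runs.items()) / ns
    out["lre"] = sum(c * j**2 for (_, j), c in runs.items()) / ns
    out["lgre"] = sum(c / i**2 for (i, _), c in runs.items()) / ns
    out["hgre"] = sum(c * i**2 for (i, _), c in runs.items()) / ns
    out["srlge"] = sum(c / (i**2 * j**2) for (i, j), c in runs.items()) / ns
    out["srhge"] = sum(c * i**2 / j**2 for (i, j), c in runs.items()) / ns
    out["lrlge"] = sum(c * j**2 / i**2 for (i, j), c in runs.items()) / ns
    out["lrhge"] = sum(c * i**2 * j**2 for (i, j), c in runs.items()) / ns
    by_i: dict[int, float] = {}
    by_j: dict[int, float] = {}
    for (i, j), c in runs.items():
        by_i[i] = by_i.get(i, 0) + c
        by_j[j] = by_j.get(j, 0) + c
    out["glnu"] = sum(v**2 for v in by_i.values()) / ns
    out["glnu_norm"] = sum(v**2 for v in by_i.values()) / ns**2
    out["rlnu"] = sum(v**2 for v in by_j.values()) / ns
    out["rlnu_norm"] = sum(v**2 for v in by_j.values()) / ns**2
    out["run_pct"] = ns / n_voxels
    mu_i = sum(i * c / ns for (i, _), c in runs.items())
    mu_j = sum(j * c / ns for (_, j), c in runs.items())
    out["gl_var"] = sum((i - mu_i) ** 2 * c / ns for (i, _), c in runs.items())
    out["rl_var"] = sum((j - mu_j) ** 2 * c / ns for (_, j), c in runs.items())
    out["run_entropy"] = -sum(
        (c / ns) * math.log2(c / ns) for c in runs.values()
    )
    return out


def glrlm_averaged_naive(levels: np.ndarray, ng: int) -> dict:
    n_vox = int((levels > 0).sum())
    feats = [rl_features_naive(glrlm_counts_naive(levels, ng, d), n_vox) for d in DIRS_13]
    return {k: float(np.mean([f[k] for f in feats])) for k in feats[0]}


# --------------------------------------------------------------- GLSZM ----

def glszm_zones_naive(levels: np.ndarray) -> dict:
    """{(level, zone size): count} by BFS flood fill, 26-connected."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    zones: dict[tuple[int, int], int] = {}
    nbrs = [
        (a, b, c)
        for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)
        if (a, b, c) != (0, 0, 0)
    ]
    for pos in np.ndindex(shape):
        if levels[pos] == 0 or seen[pos]:
            continue
        level = levels[pos]
        stack = [pos]
        seen[pos] = True
        size = 0
        while stack:
            cur = stack.pop()
            size += 1
            for d in nbrs:
                nb = tuple(cur[k] + d[k] for k in range(3))
                if _inb(nb, shape) and not seen[nb] and levels[nb] == level:
                    seen[nb] = True
                    stack.append(nb)
        key = (int(level), size)
        zones[key] = zones.get(key, 0) + 1
    return zones


SZ_RENAME = {
    "sre": "sze", "lre": "lze", "lgre": "lgze", "hgre": "hgze",
    "srlge": "szlge", "srhge": "szhge", "lrlge": "lzlge", "lrhge": "lzhge",
    "glnu": "glnu", "glnu_norm": "glnu_norm", "rlnu": "zsnu", "rlnu_norm": "zsnu_norm",
    "run_pct": "zone_pct", "gl_var": "gl_var", "rl_var": "zs_var", "run_entropy": "zone_entropy",
}


def glszm_features_naive(levels: np.ndarray) -> dict:
    zones = glszm_zones_naive(levels)
    n_vox = int((levels > 0).sum())
    base = rl_features_naive(zones, n_vox)
    return {SZ_RENAME[k]: v for k, v in base.items()}


# --------------------------------------------------------------- NGTDM ----

def ngtdm_features_naive(levels: np.ndarray, ng: int, eps: float = 1e-12) -> dict:
    shape = levels.shape
    nbrs = [
        (a, b, c)
        for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)
        if (a, b, c) != (0, 0, 0)
    ]
    n = [0.0] * (ng + 1)
    s = [0.0] * (ng + 1)
    for pos in np.argwhere(levels > 0):
        vals = []
        for d in nbrs:
            nb = tuple(pos[k] + d[k] for k in range(3))
            if _inb(nb, shape) and levels[nb] > 0:
                vals.append(levels[nb])
        if not vals:
            continue
        lev = int(levels[tuple(pos)])
        n[lev] += 1
        s[lev] += abs(lev - sum(vals) / len(vals))
    ntot = sum(n)
    p = [v / ntot for v in n]
    present = [i for i in range(1, ng + 1) if p[i] > 0]
    npl = len(present)
    out = {}
    out["coarseness"] = 1.0 / (eps + sum(p[i] * s[i] for i in present))
    if npl > 1:
        out["contrast"] = (
            sum(p[i] * p[j] * (i - j) ** 2 for i in present for j in present)
            / (npl * (npl - 1))
            * sum(s[i] for i in present) / ntot
        )
        dens = sum(abs(i * p[i] - j * p[j]) for i in present for j in present if i != j)
        out["busyness"] = sum(p[i] * s[i] for i in present) / dens if dens > 0 else float("nan")
        out["complexity"] = sum(
            abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / (p[i] + p[j])
            for i in present for j in present
        ) / ntot
        out["strength"] = sum(
            (p[i] + p[j]) * (i - j) ** 2 for i in present for j in present
        ) / (eps + sum(s[i] for i in present))
    else:
        out.update({"contrast": 0.0, "busyness": 0.0, "complexity": 0.0, "strength": 0.0})
    return out


# --------------------------------------- spatial autocorrelation, peak ----

def moran_geary_naive(x, coords) -> tuple[float, float]:
    n = len(x)
    mean = sum(x) / n
    z = [v - mean for v in x]
    sz2 = sum(v * v for v in z)
    s0 = num_i = num_c = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = math.dist(coords[i], coords[j])
            w = 1.0 / d
            s0 += w
            num_i += w * z[i] * z[j]
            num_c += w * (x[i] - x[j]) ** 2
    return (n / s0) * num_i / sz2, ((n - 1) / (2 * s0)) * num_c / sz2


def suv_peak_naive(values: np.ndarray, mask: np.ndarray, spacing, radius_mm: float) -> float:
    shape = values.shape
    sp = spacing
    best = -math.inf
    for c in np.argwhere(mask):
        total = 0.0
        count = 0
        for pos in np.ndindex(shape):
            d = math.sqrt(sum(((pos[k] - c[k]) * sp[k]) ** 2 for k in range(3)))
            if d <= radius_mm + 1e-9:
                total += values[pos]
                count += 1
        best = max(best, total / count)
    return best


# --------------------------------------------------- other statistics ----

def fisher_two_sided_naive(a: int, b: int, c: int, d: int) -> float:
    """Full hypergeometric enumeration, point-probability two-sided rule."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def pmf(k: int) -> float:
        return (
            math.comb(r1, k) * math.comb(r2, c1 - k) / math.comb(n, c1)
        )

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = pmf(a)
    return sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= p_obs * (1 + 1e-7))


def auc_pairs_naive(p, y) -> float:
    pos = [pi for pi, yi in zip(p, y) if yi == 1]
    neg = [pi for pi, yi in zip(p, y) if yi == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else 0.5 if a == b else 0.0
    return total / (len(pos) * len(neg))


def spearman_naive(x, y) -> float:
    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j < len(order) and v[order[j]] == v[order[i]]:
                j += 1
            avg = (i + j + 1) / 2.0
            for k in range(i, j):
                r[order[k]] = avg
            i = j
        return r

    rx, ry = ranks(list(x)), ranks(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den
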