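"""Per-family radiomic feature formulas.

Each ``*_features`` function returns a plain ``dict`` of named, finite
feature values for one family.  Degenerate inputs (constant VOIs, zero
denominators) return the documented fallback value with a warning instead of
raising, so constant phantoms pass through the whole registry.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

from ..pet_io import SUVImage, VOIMask
from .texture import DiscretizedImage, TextureMatrix

__all__ = [
    "morphology_features",
    "intensity_features",
    "histogram_features",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "ngtdm_features",
]

PEAK_SPHERE_MM3 = 1000.0  # 1 cm^3 sphere used for SUVpeak
_EPS = np.finfo(float).tiny


def _safe_div(num: float, den: float, fallback: float = 0.0, what: str = "") -> float:
    if abs(den) < _EPS:
        if what:
            warnings.warn(f"{what}: zero denominator, returning {fallback}", stacklevel=3)
        return fallback
    return num / den


# ---------------------------------------------------------------------------
# morphology
# ---------------------------------------------------------------------------


def _surface_area(mask: np.ndarray, spacing) -> float:
    """Total exposed voxel-face area in mm^2 (face-counting estimator)."""
    area = 0.0
    face = [spacing[1] * spacing[2], spacing[0] * spacing[2], spacing[0] * spacing[1]]
    for ax in range(3):
        m = np.moveaxis(mask, ax, 0)
        n_faces = int(m[0].sum()) + int(m[-1].sum()) + int((m[1:] != m[:-1]).sum())
        area += n_faces * face[ax]
    return area


def _ellipsoid_area(a: float, b: float, c: float) -> float:
    p = 1.6075  # Thomsen's approximation
    return 4.0 * np.pi * (((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3.0) ** (1.0 / p)


def morphology_features(mask: VOIMask, spacing=None) -> dict[str, float]:
    """Geometric descriptors of the VOI (volumes in mm^3, areas in mm^2).

    Accepts a :class:`VOIMask` or a raw boolean grid plus ``spacing``.
    """
    if isinstance(mask, VOIMask):
        grid, spacing = mask.values, mask.spacing
    else:
        grid = np.asarray(mask, dtype=bool)
        if spacing is None:
            raise ValueError("spacing is required with a raw mask grid")
    n = int(grid.sum())
    if n == 0:
        raise ValueError("empty mask")
    voxvol = float(np.prod(spacing))
    volume = n * voxvol
    area = _surface_area(grid, spacing)

    coords = np.argwhere(grid) * np.asarray(spacing)  # mm voxel centers
    # surface voxels suffice for the maximum diameter; convex hull prunes further
    eroded = ndimage.binary_erosion(grid)
    surf = np.argwhere(grid & ~eroded) * np.asarray(spacing)
    pts = surf if len(surf) else coords
    if len(pts) > 3:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass
    max_diam = float(pdist(pts).max()) if len(pts) > 1 else 0.0

    if n > 1:
        lam = np.sort(np.linalg.eigvalsh(np.cov(coords.T)))[::-1]
        lam = np.clip(lam, 0.0, None)
    else:
        lam = np.zeros(3)
    major, minor, least = (4.0 * np.sqrt(l) for l in lam)
    elongation = np.sqrt(_safe_div(lam[1], lam[0], 1.0))
    flatness = np.sqrt(_safe_div(lam[2], lam[0], 1.0))

    idx = np.argwhere(grid)
    bbox_mm = [
        (int(idx[:, ax].max()) - int(idx[:, ax].min()) + 1) * spacing[ax] for ax in range(3)
    ]
    bbox_vol = float(np.prod(bbox_mm))
    bbox_area = 2.0 * (
        bbox_mm[0] * bbox_mm[1] + bbox_mm[0] * bbox_mm[2] + bbox_mm[1] * bbox_mm[2]
    )

    a, b, c = major / 2.0, minor / 2.0, least / 2.0
    aee_vol = 4.0 / 3.0 * np.pi * a * b * c
    aee_area = _ellipsoid_area(a, b, c) if min(a, b, c) > 0 else 0.0

    r_equiv = (3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0)
    return {
        "morph_volume": volume,
        "morph_surface_area": area,
        "morph_surface_to_volume_ratio": area / volume,
        "morph_sphericity": (36.0 * np.pi * volume**2) ** (1.0 / 3.0) / area,
        "morph_compactness1": volume / (np.sqrt(np.pi) * area**1.5),
        "morph_compactness2": 36.0 * np.pi * volume**2 / area**3,
        "morph_spherical_disproportion": area / (4.0 * np.pi * r_equiv**2),
        "morph_asphericity": (area**3 / (36.0 * np.pi * volume**2)) ** (1.0 / 3.0) - 1.0,
        "morph_max_diameter_3d": max_diam,
        "morph_major_axis_length": major,
        "morph_minor_axis_length": minor,
        "morph_least_axis_length": least,
        "morph_elongation": float(elongation),
        "morph_flatness": float(flatness),
        "morph_volume_density_aabb": volume / bbox_vol,
        "morph_area_density_aabb": area / bbox_area,
        "morph_volume_density_aee": _safe_div(volume, aee_vol, 0.0),
        "morph_area_density_aee": _safe_div(area, aee_area, 0.0),
    }


# ---------------------------------------------------------------------------
# intensity (statistics + local peaks + TLG + intensity-volume histogram)
# ---------------------------------------------------------------------------


def _sphere_kernel(spacing, volume_mm3: float = PEAK_SPHERE_MM3) -> np.ndarray:
    r = (3.0 * volume_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    half = [int(np.ceil(r / s)) for s in spacing]
    ax = [np.arange(-h, h + 1) * s for h, s in zip(half, spacing)]
    zz, yy, xx = np.meshgrid(*ax, indexing="ij")
    return (zz**2 + yy**2 + xx**2) <= r**2


def _peaks(image: SUVImage, mask: VOIMask) -> tuple[float, float]:
    """(local peak, global peak): sphere means at the hottest voxel and maximized."""
    vals = image.values
    m = mask.values
    voi_volume = mask.voxel_count * image.voxel_volume
    mean = float(vals[m].mean())
    if voi_volume < PEAK_SPHERE_MM3:
        warnings.warn(
            "VOI smaller than the 1 cm^3 peak sphere; SUVpeak falls back to SUVmean",
            stacklevel=3,
        )
        return mean, mean
    kernel = _sphere_kernel(image.spacing).astype(np.float64)
    sphere_mean = ndimage.convolve(vals, kernel / kernel.sum(), mode="nearest")
    vmax = vals[m].max()
    hottest = m & (vals == vmax)
    local = float(sphere_mean[hottest].max())
    global_ = float(sphere_mean[m].max())
    return local, global_


def _ivh(vals: np.ndarray) -> dict[str, float]:
    lo, hi = float(vals.min()), float(vals.max())
    rng = hi - lo

    def v_at(x: float) -> float:
        # fraction of VOI volume at or above x% of the intensity range
        thr = lo + x / 100.0 * rng
        return float(np.mean(vals >= thr))

    def i_at(x: float) -> float:
        # intensity such that x% of the volume is at or above it
        return float(np.quantile(vals, 1.0 - x / 100.0, method="higher"))

    out = {}
    for x in (10, 25, 75, 90):
        out[f"ivh_v{x}"] = v_at(x)
        out[f"ivh_i{x}"] = i_at(x)
    out["ivh_v10_minus_v90"] = out["ivh_v10"] - out["ivh_v90"]
    out["ivh_v25_minus_v75"] = out["ivh_v25"] - out["ivh_v75"]
    out["ivh_i10_minus_i90"] = out["ivh_i10"] - out["ivh_i90"]
    out["ivh_i25_minus_i75"] = out["ivh_i25"] - out["ivh_i75"]
    return out


def intensity_features(image: SUVImage, mask: VOIMask) -> dict[str, float]:
    """First-order SUV statistics, intensity peaks, TLG and IVH features."""
    mask.check_paired(image)
    if mask.voxel_count == 0:
        raise ValueError("empty VOI")
    x = image.values[mask.values].astype(np.float64)
    n = x.size
    mean = float(x.mean())
    var = float(x.var())  # population variance
    sd = np.sqrt(var)
    med = float(np.median(x))
    q = {p: float(np.percentile(x, p)) for p in (5, 10, 25, 75, 90, 95)}
    iqr = q[75] - q[25]
    in_deciles = x[(x >= q[10]) & (x <= q[90])]
    skew = _safe_div(float(np.mean((x - mean) ** 3)), var**1.5, 0.0)
    kurt = _safe_div(float(np.mean((x - mean) ** 4)), var**2, 0.0) - 3.0

    local_peak, global_peak = _peaks(image, mask)
    volume = mask.voxel_count * image.voxel_volume

    out = {
        "stat_mean": mean,
        "stat_variance": var,
        "stat_skewness": skew,
        "stat_kurtosis": kurt,
        "stat_median": med,
        "stat_min": float(x.min()),
        "stat_p5": q[5],
        "stat_p10": q[10],
        "stat_p25": q[25],
        "stat_p75": q[75],
        "stat_p90": q[90],
        "stat_p95": q[95],
        "stat_max": float(x.max()),
        "stat_iqr": iqr,
        "stat_range": float(x.max() - x.min()),
        "stat_mad": float(np.mean(np.abs(x - mean))),
        "stat_rmad": float(np.mean(np.abs(in_deciles - in_deciles.mean())))
        if in_deciles.size
        else 0.0,
        "stat_medad": float(np.mean(np.abs(x - med))),
        "stat_cov": _safe_div(sd, mean, 0.0),
        "stat_qcod": _safe_div(q[75] - q[25], q[75] + q[25], 0.0),
        "stat_energy": float(np.sum(x**2)),
        "stat_rms": float(np.sqrt(np.mean(x**2))),
        "intensity_peak_local": local_peak,
        "intensity_peak_global": global_peak,
        "tlg": mean * volume,
    }
    out.update(_ivh(x))
    return out


# ---------------------------------------------------------------------------
# intensity histogram (on discretized levels)
# ---------------------------------------------------------------------------


def histogram_features(disc: DiscretizedImage, mask: VOIMask) -> dict[str, float]:
    """Discrete intensity-histogram features on gray levels 1..n_levels."""
    g = disc.levels_in(mask.values).astype(np.float64)
    if g.size == 0:
        raise ValueError("empty VOI")
    G = disc.n_levels
    counts = np.bincount(g.astype(int), minlength=G + 1)[1:].astype(np.float64)
    p = counts / counts.sum()
    levels = np.arange(1, G + 1, dtype=np.float64)
    mean = float((p * levels).sum())
    var = float((p * (levels - mean) ** 2).sum())
    med = float(np.median(g))
    qv = {pr: float(np.percentile(g, pr)) for pr in (10, 25, 75, 90)}
    in_dec = g[(g >= qv[10]) & (g <= qv[90])]
    grad = np.gradient(counts) if G > 1 else np.zeros(1)
    nz = p > 0
    return {
        "ih_mean": mean,
        "ih_variance": var,
        "ih_skewness": _safe_div(float((p * (levels - mean) ** 3).sum()), var**1.5, 0.0),
        "ih_kurtosis": _safe_div(float((p * (levels - mean) ** 4).sum()), var**2, 0.0) - 3.0,
        "ih_median": med,
        "ih_min": float(g.min()),
        "ih_p10": qv[10],
        "ih_p25": qv[25],
        "ih_p75": qv[75],
        "ih_p90": qv[90],
        "ih_max": float(g.max()),
        "ih_mode": float(np.argmax(counts) + 1),
        "ih_iqr": qv[75] - qv[25],
        "ih_range": float(g.max() - g.min()),
        "ih_mad": float(np.mean(np.abs(g - mean))),
        "ih_rmad": float(np.mean(np.abs(in_dec - in_dec.mean()))) if in_dec.size else 0.0,
        "ih_medad": float(np.mean(np.abs(g - med))),
        "ih_cov": _safe_div(np.sqrt(var), mean, 0.0),
        "ih_qcod": _safe_div(qv[75] - qv[25], qv[75] + qv[25], 0.0),
        "ih_entropy": float(-(p[nz] * np.log2(p[nz])).sum()),
        "ih_uniformity": float((p**2).sum()),
        "ih_max_gradient": float(grad.max()),
        "ih_max_gradient_level": float(np.argmax(grad) + 1),
        "ih_min_gradient": float(grad.min()),
        "ih_min_gradient_level": float(np.argmin(grad) + 1),
    }


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------


def glcm_features(tm: TextureMatrix) -> dict[str, float]:
    """26 features of the merged, normalized co-occurrence matrix."""
    if tm.kind != "GLCM":
        raise ValueError(f"expected a GLCM, got {tm.kind}")
    P = tm.matrix
    G = P.shape[0]
    i = np.arange(1, G + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    mu_x = float((px * i).sum())
    sd_x = np.sqrt(float((px * (i - mu_x) ** 2).sum()))
    mu = float((P * ii).sum())  # symmetric: mu_x == mu_y == mu

    # diagonal (difference) and cross-diagonal (sum) probabilities
    k_diff = np.arange(G, dtype=np.float64)
    p_diff = np.array([P[np.abs(ii - jj) == k].sum() for k in range(G)])
    k_sum = np.arange(2, 2 * G + 1, dtype=np.float64)
    p_sum = np.array([P[(ii + jj) == k].sum() for k in range(2, 2 * G + 1)])

    nz = P > 0
    ent = float(-(P[nz] * np.log2(P[nz])).sum())
    da = float((p_diff * k_diff).sum())
    sa = float((p_sum * k_sum).sum())
    nzd, nzs = p_diff > 0, p_sum > 0

    pxpy = np.outer(px, px)
    nzj = pxpy > 0
    hxy1 = float(-(P[nzj] * np.log2(pxpy[nzj])).sum())
    hxy2 = float(-(pxpy[nzj] * np.log2(pxpy[nzj])).sum())
    hx = float(-(px[px > 0] * np.log2(px[px > 0])).sum())

    # maximal correlation coefficient: second-largest eigenvalue of Q
    present = px > 0
    if present.sum() > 1:
        Psub = P[np.ix_(present, present)]
        pxs = px[present]
        # Q(i,j) = sum_k P(i,k) P(j,k) / (px(i) px(k))
        Q = (Psub / pxs[:, None]) @ (Psub / pxs[None, :]).T
        ev = np.sort(np.abs(np.linalg.eigvals(Q)))
        mcc = float(np.sqrt(np.clip(ev[-2], 0.0, 1.0))) if ev.size > 1 else 1.0
    else:
        mcc = 1.0

    off = np.abs(ii - jj) > 0
    inv_var = float((P[off] / (ii[off] - jj[off]) ** 2).sum())

    corr = _safe_div(float((P * (ii - mu_x) * (jj - mu_x)).sum()), sd_x**2, 1.0)
    ic2_arg = 1.0 - np.exp(-2.0 * max(hxy2 - ent, 0.0))
    return {
        "glcm_joint_max": float(P.max()),
        "glcm_joint_average": mu,
        "glcm_joint_variance": float((P * (ii - mu) ** 2).sum()),
        "glcm_joint_entropy": ent,
        "glcm_diff_average": da,
        "glcm_diff_variance": float((p_diff * (k_diff - da) ** 2).sum()),
        "glcm_diff_entropy": float(-(p_diff[nzd] * np.log2(p_diff[nzd])).sum()),
        "glcm_sum_average": sa,
        "glcm_sum_variance": float((p_sum * (k_sum - sa) ** 2).sum()),
        "glcm_sum_entropy": float(-(p_sum[nzs] * np.log2(p_sum[nzs])).sum()),
        "glcm_asm": float((P**2).sum()),
        "glcm_contrast": float((P * (ii - jj) ** 2).sum()),
        "glcm_dissimilarity": float((P * np.abs(ii - jj)).sum()),
        "glcm_inverse_difference": float((P / (1.0 + np.abs(ii - jj))).sum()),
        "glcm_inverse_difference_norm": float((P / (1.0 + np.abs(ii - jj) / G)).sum()),
        "glcm_inverse_difference_moment": float((P / (1.0 + (ii - jj) ** 2)).sum()),
        "glcm_inverse_difference_moment_norm": float(
            (P / (1.0 + (ii - jj) ** 2 / G**2)).sum()
        ),
        "glcm_inverse_variance": inv_var,
        "glcm_correlation": corr,
        "glcm_autocorrelation": float((P * ii * jj).sum()),
        "glcm_cluster_tendency": float((P * (ii + jj - 2 * mu_x) ** 2).sum()),
        "glcm_cluster_shade": float((P * (ii + jj - 2 * mu_x) ** 3).sum()),
        "glcm_cluster_prominence": float((P * (ii + jj - 2 * mu_x) ** 4).sum()),
        "glcm_info_corr1": _safe_div(ent - hxy1, hx, 0.0),
        "glcm_info_corr2": float(np.sqrt(np.clip(ic2_arg, 0.0, 1.0))),
        "glcm_mcc": mcc,
    }


# ---------------------------------------------------------------------------
# GLRLM / GLSZM (shared formula core)
# ---------------------------------------------------------------------------


def _rl_family(counts: np.ndarray, n_potential: float, prefix: str, axis_name: str):
    N = counts.sum()
    if N == 0:
        raise ValueError("empty run/zone matrix")
    p = counts / N
    G, L = counts.shape
    i = np.arange(1, G + 1, dtype=np.float64)
    j = np.arange(1, L + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    ri = counts.sum(axis=1)  # per gray level
    rj = counts.sum(axis=0)  # per length/size
    mu_i = float((p * ii).sum())
    mu_j = float((p * jj).sum())
    nz = p > 0
    return {
        f"{prefix}_short_{axis_name}_emphasis": float((counts / jj**2).sum() / N),
        f"{prefix}_long_{axis_name}_emphasis": float((counts * jj**2).sum() / N),
        f"{prefix}_low_gl_emphasis": float((counts / ii**2).sum() / N),
        f"{prefix}_high_gl_emphasis": float((counts * ii**2).sum() / N),
        f"{prefix}_short_{axis_name}_low_gl_emphasis": float(
            (counts / (ii**2 * jj**2)).sum() / N
        ),
        f"{prefix}_short_{axis_name}_high_gl_emphasis": float(
            (counts * ii**2 / jj**2).sum() / N
        ),
        f"{prefix}_long_{axis_name}_low_gl_emphasis": float(
            (counts * jj**2 / ii**2).sum() / N
        ),
        f"{prefix}_long_{axis_name}_high_gl_emphasis": float(
            (counts * ii**2 * jj**2).sum() / N
        ),
        f"{prefix}_gl_nonuniformity": float((ri**2).sum() / N),
        f"{prefix}_gl_nonuniformity_norm": float((ri**2).sum() / N**2),
        f"{prefix}_{axis_name}_nonuniformity": float((rj**2).sum() / N),
        f"{prefix}_{axis_name}_nonuniformity_norm": float((rj**2).sum() / N**2),
        f"{prefix}_{axis_name}_percentage": float(N / n_potential),
        f"{prefix}_gl_variance": float((p * (ii - mu_i) ** 2).sum()),
        f"{prefix}_{axis_name}_variance": float((p * (jj - mu_j) ** 2).sum()),
        f"{prefix}_{axis_name}_entropy": float(-(p[nz] * np.log2(p[nz])).sum()),
    }


def glrlm_features(tm: TextureMatrix, n_voxels: int) -> dict[str, float]:
    """16 run-length features; run percentage uses 13 x n_voxels potential runs."""
    if tm.kind != "GLRLM":
        raise ValueError(f"expected a GLRLM, got {tm.kind}")
    return _rl_family(tm.matrix, 13.0 * n_voxels, "glrlm", "run")


def glszm_features(tm: TextureMatrix, n_voxels: int) -> dict[str, float]:
    """16 size-zone features; zone percentage normalizes by the voxel count."""
    if tm.kind != "GLSZM":
        raise ValueError(f"expected a GLSZM, got {tm.kind}")
    return _rl_family(tm.matrix, float(n_voxels), "glszm", "zone")


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------


def ngtdm_features(tm: TextureMatrix) -> dict[str, float]:
    """Coarseness, contrast, busyness, complexity and strength.

    Zero denominators (constant VOIs) yield 0 with a warning rather than an
    error, so flat phantoms survive full extraction.
    """
    if tm.kind != "NGTDM":
        raise ValueError(f"expected an NGTDM, got {tm.kind}")
    n_i = tm.matrix[:, 0]
    s_i = tm.matrix[:, 1]
    N = n_i.sum()
    if N == 0:
        raise ValueError("NGTDM has no valid voxels")
    p = n_i / N
    G = len(p)
    i = np.arange(1, G + 1, dtype=np.float64)
    present = p > 0
    Ngp = int(present.sum())

    coarse_den = float((p * s_i).sum())
    coarseness = _safe_div(1.0, coarse_den, 0.0, "ngtdm_coarseness")

    if Ngp > 1:
        pi, pj = np.meshgrid(p, p, indexing="ij")
        iii, jjj = np.meshgrid(i, i, indexing="ij")
        both = (pi > 0) & (pj > 0)
        contrast = (
            float((pi * pj * (iii - jjj) ** 2)[both].sum())
            / (Ngp * (Ngp - 1))
            * float(s_i.sum())
            / N
        )
        busy_den = float(np.abs(i[present, None] * p[present, None] - i[None, present] * p[None, present]).sum())
        busyness = _safe_div(coarse_den, busy_den, 0.0, "ngtdm_busyness")
        with np.errstate(invalid="ignore"):
            comp_num = (
                np.abs(iii - jjj)
                * (pi * s_i[:, None] + pj * s_i[None, :])
                / np.where(pi + pj > 0, pi + pj, 1.0)
            )
        complexity = float(comp_num[both].sum()) / N
        strength_num = float(((pi + pj) * (iii - jjj) ** 2)[both].sum())
        strength = _safe_div(strength_num, float(s_i.sum()), 0.0, "ngtdm_strength")
    else:
        contrast = busyness = complexity = strength = 0.0

    return {
        "ngtdm_coarseness": coarseness,
        "ngtdm_contrast": contrast,
        "ngtdm_busyness": busyness,
        "ngtdm_complexity": complexity,
        "ngtdm_strength": strength,
    }
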