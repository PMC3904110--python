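"""Group-level inference: voxelwise GLM with a sex-moderation term, Monte
Carlo cluster-extent correction, cluster extraction, ROI averaging, and
simple-slopes probing.

The design is y = b0 + b1 * GRP + b2 * sex + b3 * GRP x sex with GRP
mean-centered and sex coded female = 0 / male = 1, so b1 is the female
slope and b1 + b3 the male slope (the focal/moderator convention of
moderated-regression probing). Cluster-extent family-wise correction
follows the smooth-null-field Monte Carlo recipe: simulate white noise,
smooth to the applied FWHM, standardize within the mask, threshold at the
cluster-forming voxel p, and take the alpha quantile of the maximum cluster
extent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .fcd import adjacency_structure
from .grid import BrainGrid
from .rsfc import SeedROI

TERMS = ("intercept", "grp", "sex", "grp_x_sex")


def build_design(grp: np.ndarray, sex: np.ndarray | pd.Series) -> pd.DataFrame:
    """Design matrix [1, centered GRP, male indicator, product]; rank-checked."""
    grp = np.asarray(grp, dtype=float)
    sex = np.asarray(sex)
    if len(grp) != len(sex):
        raise ValueError("grp and sex must align")
    n = len(grp)
    if n <= 4:
        raise ValueError("need more than 4 subjects")
    male = np.where(sex == "male", 1.0, 0.0)
    g = grp - grp.mean()
    x = np.column_stack([np.ones(n), g, male, g * male])
    if np.linalg.matrix_rank(x) < 4:
        raise ValueError(
            "design matrix is rank deficient (single-sex sample or constant GRP?)")
    return pd.DataFrame(x, columns=list(TERMS))


@dataclass
class StatMaps:
    """Voxelwise t-maps per term plus the interaction F-map."""

    t: dict[str, np.ndarray]       # term -> volume
    f_interaction: np.ndarray
    beta: dict[str, np.ndarray]
    df_resid: int
    mask: np.ndarray

    def t_map(self, term: str) -> np.ndarray:
        return self.t[term]


def voxelwise_glm(maps: np.ndarray | list[np.ndarray], design: pd.DataFrame,
                  mask: np.ndarray) -> StatMaps:
    """OLS at every in-mask voxel.

    ``maps``: per-subject volumes, shape (n, *dims) or a list of volumes.
    Returns per-term t-maps and the single-degree F-map (t^2) for the
    interaction term.
    """
    y = np.stack(maps) if isinstance(maps, list) else np.asarray(maps, dtype=float)
    x = design.to_numpy(dtype=float)
    n, k = x.shape
    if y.shape[0] != n:
        raise ValueError("one volume per design row required")
    if n <= k:
        raise ValueError(f"need more than {k} subjects for {k} coefficients")
    data = y[:, mask]  # (n, n_voxels)
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ data  # (k, n_voxels)
    resid = data - x @ beta
    df = n - k
    sigma2 = (resid ** 2).sum(axis=0) / df
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    tvals = np.nan_to_num(tvals, nan=0.0)

    def to_vol(v):
        vol = np.zeros(mask.shape)
        vol[mask] = v
        return vol

    t_maps = {term: to_vol(tvals[j]) for j, term in enumerate(TERMS)}
    betas = {term: to_vol(beta[j]) for j, term in enumerate(TERMS)}
    with np.errstate(over="ignore"):  # exact-fit voxels carry infinite t
        f_int = to_vol(tvals[TERMS.index("grp_x_sex")] ** 2)
    return StatMaps(t=t_maps, f_interaction=f_int, beta=betas,
                    df_resid=df, mask=mask)


@dataclass
class MCThreshold:
    """Monte Carlo cluster-extent threshold and the settings that produced it."""

    min_extent_voxels: int
    min_extent_mm3: float
    voxel_p: float
    fwe_alpha: float
    fwhm_mm: float
    n_iter: int
    adjacency: int
    mask_voxels: int
    max_extent_distribution: np.ndarray = field(repr=False, default=None)  # type: ignore


def mc_cluster_threshold(mask: np.ndarray, grid: BrainGrid, fwhm: float = 8.0,
                         voxel_p: float = 0.001, fwe_alpha: float = 0.05,
                         n_iter: int = 1000, adjacency: int = 26,
                         seed: int = 0) -> MCThreshold:
    """Minimum cluster extent controlling family-wise error at ``fwe_alpha``.

    Each iteration smooths a white-noise field to the applied FWHM,
    re-standardizes it within the mask, applies the two-sided voxelwise
    threshold, and records the maximum suprathreshold cluster extent. The
    returned extent is the smallest k with P(max extent >= k) < alpha.
    """
    if not 0 < voxel_p < 1:
        raise ValueError("voxel_p must be in (0, 1)")
    if n_iter < 100:
        raise ValueError("need at least 100 iterations")
    if not mask.any():
        raise ValueError("mask is empty")
    struct = adjacency_structure(adjacency)
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / grid.voxel_size if fwhm > 0 else 0.0
    zthr = stats.norm.isf(voxel_p / 2.0)  # two-sided
    rng = np.random.default_rng(seed)
    max_extent = np.zeros(n_iter, dtype=np.int64)
    supra = np.zeros(mask.shape, dtype=bool)
    for it in range(n_iter):
        fieldv = rng.standard_normal(mask.shape)
        if sigma > 0:
            fieldv = ndimage.gaussian_filter(fieldv, sigma=sigma)
        vals = fieldv[mask]
        vals = (vals - vals.mean()) / vals.std()
        supra[:] = False
        supra[mask] = np.abs(vals) > zthr
        labels, n_lab = ndimage.label(supra, structure=struct)
        if n_lab:
            max_extent[it] = np.bincount(labels.ravel())[1:].max()
    # smallest k with exceedance probability < alpha
    k = 1
    while (max_extent >= k).sum() / n_iter >= fwe_alpha:
        k += 1
    return MCThreshold(
        min_extent_voxels=int(k),
        min_extent_mm3=float(k * grid.voxel_volume_mm3),
        voxel_p=voxel_p, fwe_alpha=fwe_alpha, fwhm_mm=fwhm, n_iter=n_iter,
        adjacency=adjacency, mask_voxels=int(mask.sum()),
        max_extent_distribution=max_extent,
    )


def extract_clusters(stat_map: np.ndarray, mask: np.ndarray, grid: BrainGrid,
                     df: int, voxel_p: float = 0.001,
                     min_extent_mm3: float = 513.0, adjacency: int = 26,
                     stat: str = "t") -> pd.DataFrame:
    """Suprathreshold clusters above the extent threshold.

    ``stat='t'`` thresholds |t| at the two-sided voxel-p quantile;
    ``stat='F'`` thresholds a single-degree F at its upper quantile. A
    min extent that is not a multiple of the voxel volume is rounded up.
    Returns a table with size (voxels, mm3), peak statistic and peak MNI
    coordinates (via the grid affine).
    """
    if stat == "t":
        thr = stats.t.isf(voxel_p / 2.0, df)
        exceed = np.abs(stat_map) > thr
        peak_stat = np.abs(stat_map)
    elif stat == "F":
        thr = stats.f.isf(voxel_p, 1, df)
        exceed = stat_map > thr
        peak_stat = stat_map
    else:
        raise ValueError("stat must be 't' or 'F'")
    vox_vol = grid.voxel_volume_mm3
    min_vox = int(np.ceil(min_extent_mm3 / vox_vol - 1e-9))
    exceed = exceed & mask
    labels, n_lab = ndimage.label(exceed, structure=adjacency_structure(adjacency))
    rows = []
    for lab in range(1, n_lab + 1):
        sel = labels == lab
        size = int(sel.sum())
        if size < min_vox:
            continue
        idx = np.argwhere(sel)
        vals = peak_stat[sel]
        peak = idx[np.argmax(vals)]
        world = grid.voxel_to_world(peak)[0]
        rows.append({
            "cluster_id": len(rows) + 1,
            "size_voxels": size,
            "size_mm3": size * vox_vol,
            "peak_x": world[0], "peak_y": world[1], "peak_z": world[2],
            "peak_stat": float(stat_map[tuple(peak)]),
        })
    rows.sort(key=lambda r: -r["size_voxels"])
    for i, r in enumerate(rows):
        r["cluster_id"] = i + 1
    return pd.DataFrame(
        rows, columns=["cluster_id", "size_voxels", "size_mm3",
                       "peak_x", "peak_y", "peak_z", "peak_stat"])


def roi_average(maps: np.ndarray | list[np.ndarray], roi: SeedROI,
                mask: np.ndarray) -> np.ndarray:
    """Unweighted in-ROI mean per subject volume."""
    y = np.stack(maps) if isinstance(maps, list) else np.asarray(maps, dtype=float)
    if not mask[tuple(roi.voxels.T)].all():
        raise ValueError(f"ROI {roi.name!r} is not fully inside the mask")
    return y[(slice(None),) + tuple(roi.voxels.T)].mean(axis=1)


@dataclass
class SimpleSlopes:
    """Conditional slope of a measure on GRP at each sex, from the joint
    moderated regression. With female = 0 / male = 1 coding,
    slope_male - slope_female equals the interaction coefficient."""

    slope_male: float
    se_male: float
    t_male: float
    p_male: float
    slope_female: float
    se_female: float
    t_female: float
    p_female: float
    interaction_coef: float
    interaction_se: float
    interaction_t: float
    interaction_p: float
    df_resid: int

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"group": "male", "slope": self.slope_male, "se": self.se_male,
             "t": self.t_male, "p": self.p_male},
            {"group": "female", "slope": self.slope_female, "se": self.se_female,
             "t": self.t_female, "p": self.p_female},
            {"group": "interaction", "slope": self.interaction_coef,
             "se": self.interaction_se, "t": self.interaction_t,
             "p": self.interaction_p},
        ])


def probe_interaction(values: np.ndarray, grp: np.ndarray,
                      sex: np.ndarray | pd.Series) -> SimpleSlopes:
    """Simple-slopes probe of the GRP x sex interaction on an ROI measure.

    Fits the joint model and reads conditional slopes and their standard
    errors from the coefficient covariance: slope_f = b_grp,
    slope_m = b_grp + b_int, Var(slope_m) = V_gg + V_ii + 2 V_gi.
    """
    values = np.asarray(values, dtype=float)
    sex = np.asarray(sex)
    for label in ("male", "female"):
        if (sex == label).sum() < 3:
            raise ValueError(f"need at least 3 {label} subjects")
    x = build_design(grp, sex).to_numpy()
    n, k = x.shape
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ values
    resid = values - x @ beta
    df = n - k
    sigma2 = float(resid @ resid) / df
    cov = sigma2 * xtx_inv
    ig, ii = TERMS.index("grp"), TERMS.index("grp_x_sex")
    slope_f, se_f = beta[ig], np.sqrt(cov[ig, ig])
    slope_m = beta[ig] + beta[ii]
    se_m = np.sqrt(cov[ig, ig] + cov[ii, ii] + 2.0 * cov[ig, ii])
    b_int, se_int = beta[ii], np.sqrt(cov[ii, ii])

    def tp(b, se):
        t = b / se
        return float(t), float(2.0 * stats.t.sf(abs(t), df))

    t_m, p_m = tp(slope_m, se_m)
    t_f, p_f = tp(slope_f, se_f)
    t_i, p_i = tp(b_int, se_int)
    return SimpleSlopes(
        slope_male=float(slope_m), se_male=float(se_m), t_male=t_m, p_male=p_m,
        slope_female=float(slope_f), se_female=float(se_f), t_female=t_f,
        p_female=p_f,
        interaction_coef=float(b_int), interaction_se=float(se_int),
        interaction_t=t_i, interaction_p=p_i, df_resid=df,
    )
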