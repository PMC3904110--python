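"""Seed-based resting-state functional connectivity (RSFC) with Fisher z.

The seed's mean time series is correlated with every in-mask voxel and the
correlations are variance-stabilized with Fisher's r-to-z (atanh), clipping
|r| at 1 - 1e-7 so machine-precision unit correlations stay finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .grid import BOLDSeries

_CLIP = 1.0 - 1e-7


@dataclass
class SeedROI:
    """A named voxel set used as a connectivity seed."""

    name: str
    voxels: np.ndarray  # (k, 3) indices

    def __post_init__(self):
        self.voxels = np.atleast_2d(np.asarray(self.voxels, dtype=int))
        if self.voxels.shape[1] != 3 or len(self.voxels) == 0:
            raise ValueError("SeedROI needs a non-empty (k, 3) voxel array")


@dataclass
class RSFCMap:
    """Fisher-z connectivity volume for one subject x seed."""

    z: np.ndarray
    mask: np.ndarray
    seed_name: str
    n_clipped: int
    n_zero_variance: int


def extract_seed_series(bold: BOLDSeries, roi: SeedROI) -> np.ndarray:
    """Unweighted mean time series over the ROI's voxels."""
    if not bold.mask[tuple(roi.voxels.T)].all():
        raise ValueError(f"seed ROI {roi.name!r} is not fully inside the mask")
    return bold.data[tuple(roi.voxels.T)].mean(axis=0)


def compute_rsfc_zmap(bold: BOLDSeries, seed_series: np.ndarray,
                      seed_name: str = "seed") -> RSFCMap:
    """Pearson r of every in-mask voxel with the seed series, Fisher
    transformed. Zero-variance voxels get z = 0 and are counted; an
    all-constant seed series raises."""
    seed = np.asarray(seed_series, dtype=float)
    if seed.ndim != 1 or len(seed) != bold.n_volumes:
        raise ValueError("seed series length must match the BOLD series")
    if len(seed) < 3:
        raise ValueError("need at least 3 time points")
    seed = seed - seed.mean()
    seed_norm = np.linalg.norm(seed)
    if seed_norm == 0:
        raise ValueError("seed series is constant; correlation undefined")
    ts = bold.masked_series().astype(float)
    ts = ts - ts.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(ts, axis=1)
    zero = norm == 0
    norm[zero] = 1.0
    r = ts @ seed / (norm * seed_norm)
    r[zero] = 0.0
    clipped = np.abs(r) > _CLIP
    z = np.arctanh(np.clip(r, -_CLIP, _CLIP))
    vol = np.zeros(bold.grid.dims)
    vol[bold.mask] = z
    return RSFCMap(z=vol, mask=bold.mask, seed_name=seed_name,
                   n_clipped=int(clipped.sum()), n_zero_variance=int(zero.sum()))


def connectivity_mask(zmaps: list[RSFCMap], voxel_p: float = 0.001) -> np.ndarray:
    """Group mask of voxels reliably connected to the seed: one-sample t-test
    of the z-maps against zero, thresholded at an uncorrected voxel p
    (two-sided). Used to constrain seed-level group statistics; the threshold
    is explicit configuration, not a fixed constant."""
    if not zmaps:
        raise ValueError("need at least one z-map")
    mask = zmaps[0].mask
    data = np.stack([m.z[mask] for m in zmaps])
    n = len(data)
    if n < 3:
        raise ValueError("need at least 3 subjects for a one-sample t-test")
    mean = data.mean(axis=0)
    se = data.std(axis=0, ddof=1) / np.sqrt(n)
    se[se == 0] = np.inf
    t = mean / se
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    out = np.zeros(mask.shape, dtype=bool)
    out[mask] = p < voxel_p
    return out
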