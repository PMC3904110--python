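"""Functional connectivity density (FCD) mapping.

A voxel pair is functionally connected when the Pearson correlation of their
time series exceeds a threshold (default r > 0.6, strict). Three per-voxel
counts are produced:

* global FCD — connections to all other in-mask voxels;
* short-range FCD — the size of the spatially contiguous cluster grown from
  the voxel: a candidate joins when it is adjacent (26-neighbourhood by
  default) to a voxel already linked to the seed by a continuous path of
  connected voxels and its own correlation with the seed exceeds the
  threshold, iterated until no new neighbour can be added;
* long-range FCD — global minus short-range, exact at the raw stage.

Raw count maps are then Gaussian-smoothed (8 mm FWHM default) and divided by
their in-mask mean (global-mean normalization), in that order.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .grid import BOLDSeries, BrainGrid

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def adjacency_structure(adjacency: int) -> np.ndarray:
    """3x3x3 connectivity structure for 6-, 18- or 26-neighbourhoods."""
    try:
        return _STRUCTURES[adjacency]
    except KeyError:
        raise ValueError(f"adjacency must be one of 6, 18, 26; got {adjacency}")


@dataclass
class FCDMaps:
    """Per-subject global / short-range / long-range density volumes."""

    global_: np.ndarray
    short: np.ndarray
    long: np.ndarray
    mask: np.ndarray
    stage: str  # 'raw' | 'smoothed' | 'normalized'
    r_threshold: float
    adjacency: int
    n_zero_variance: int = 0

    def validate_raw(self) -> None:
        if self.stage != "raw":
            raise ValueError("raw-stage invariants only apply to stage='raw'")
        for name, m in (("global", self.global_), ("short", self.short),
                        ("long", self.long)):
            vals = m[self.mask]
            if np.any(vals < 0) or np.any(vals != np.round(vals)):
                raise ValueError(f"raw {name} FCD must be non-negative integers")
        if np.any(self.long[self.mask] !=
                  self.global_[self.mask] - self.short[self.mask]):
            raise ValueError("long FCD must equal global - short exactly")


def _standardized_series(bold: BOLDSeries):
    """In-mask series standardized so r = rows @ rows.T; zero-variance rows
    are zeroed (no connections) and counted."""
    ts = bold.masked_series().astype(float)
    n, t = ts.shape
    if n < 2:
        raise ValueError("need at least 2 in-mask voxels")
    if t < 3:
        raise ValueError("need series length >= 3")
    ts = ts - ts.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(ts, axis=1)
    zero = norm == 0
    norm[zero] = 1.0
    ts /= norm[:, None]
    ts[zero] = 0.0
    return ts, zero


def compute_global_fcd(bold: BOLDSeries, r_min: float = 0.6,
                       chunk: int = 1024) -> np.ndarray:
    """Global FCD: per in-mask voxel, the number of other in-mask voxels with
    Pearson r strictly above ``r_min``. Zero-variance voxels contribute no
    edges and score 0."""
    ts, zero = _standardized_series(bold)
    n = len(ts)
    counts = np.zeros(n, dtype=np.int64)
    for start in range(0, n, chunk):
        block = ts[start:start + chunk] @ ts.T
        hits = (block > r_min).sum(axis=1)
        # remove the self-correlation (r=1) of non-degenerate voxels
        self_r = np.einsum("ij,ij->i", ts[start:start + chunk],
                           ts[start:start + chunk])
        hits -= (self_r > r_min).astype(np.int64)
        counts[start:start + chunk] = hits
    counts[zero] = 0
    vol = np.zeros(bold.grid.dims, dtype=np.int64)
    vol[bold.mask] = counts
    return vol


def compute_short_range_fcd(bold: BOLDSeries, r_min: float = 0.6,
                            adjacency: int = 26, chunk: int = 1024) -> np.ndarray:
    """Short-range FCD by the growing rule (see module docstring).

    For each seed voxel the suprathreshold set is formed, the spatial
    connected component (under the chosen neighbourhood) of the seed within
    that set plus the seed itself is found, and its size minus the seed is
    the count. Equivalent to iterative neighbour growth until closure.
    """
    struct = adjacency_structure(adjacency)
    ts, zero = _standardized_series(bold)
    mask = bold.mask
    coords = np.argwhere(mask)
    n = len(ts)
    short = np.zeros(n, dtype=np.int64)
    connected = np.zeros(mask.shape, dtype=bool)
    for start in range(0, n, chunk):
        block = ts[start:start + chunk] @ ts.T  # correlations with all voxels
        for local, i in enumerate(range(start, min(start + chunk, n))):
            if zero[i]:
                continue
            supra = block[local] > r_min
            supra[i] = False
            if not supra.any():
                continue
            connected[:] = False
            connected[tuple(coords[supra].T)] = True
            connected[tuple(coords[i])] = True
            # crop to the bounding box of the candidate set for speed
            hit = np.argwhere(connected)
            lo = hit.min(axis=0)
            hi = hit.max(axis=0) + 1
            sub = connected[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
            lab, _ = ndimage.label(sub, structure=struct)
            seed_lab = lab[tuple(coords[i] - lo)]
            short[i] = int((lab == seed_lab).sum()) - 1
    vol = np.zeros(bold.grid.dims, dtype=np.int64)
    vol[mask] = short
    return vol


def compute_long_range_fcd(global_map: np.ndarray, short_map: np.ndarray,
                           mask: np.ndarray) -> np.ndarray:
    """Long-range FCD = global - short, elementwise; negative values signal a
    growth-rule bug and raise."""
    long_map = global_map.astype(np.int64) - short_map.astype(np.int64)
    if np.any(long_map[mask] < 0):
        raise ValueError(
            "long-range FCD came out negative: short exceeds global somewhere, "
            "which violates the growth rule")
    return long_map


def compute_fcd_maps(bold: BOLDSeries, r_min: float = 0.6,
                     adjacency: int = 26) -> FCDMaps:
    """Raw global/short/long FCD maps for one subject."""
    _, zero = _standardized_series(bold)
    g = compute_global_fcd(bold, r_min)
    s = compute_short_range_fcd(bold, r_min, adjacency)
    lng = compute_long_range_fcd(g, s, bold.mask)
    maps = FCDMaps(global_=g, short=s, long=lng, mask=bold.mask, stage="raw",
                   r_threshold=r_min, adjacency=adjacency,
                   n_zero_variance=int(zero.sum()))
    maps.validate_raw()
    return maps


def smooth_volume(volume: np.ndarray, grid: BrainGrid, fwhm: float = 8.0,
                  mask: np.ndarray | None = None) -> np.ndarray:
    """3D Gaussian smoothing with sigma = FWHM / (2 sqrt(2 ln 2)) per axis.

    Smoothing runs on the full volume (values leak across the mask edge, as
    volumetric smoothers do) and the result is re-masked if a mask is given.
    ``fwhm=0`` is the identity.
    """
    if fwhm < 0:
        raise ValueError("fwhm must be >= 0")
    out = np.asarray(volume, dtype=float)
    if fwhm > 0:
        sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / grid.voxel_size
        out = ndimage.gaussian_filter(out, sigma=sigma, mode="reflect")
    else:
        out = out.copy()
    if mask is not None:
        out = np.where(mask, out, 0.0)
    return out


def normalize_by_global_mean(volume: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Divide by the in-mask mean; the output's in-mask mean is exactly 1."""
    vals = np.asarray(volume, dtype=float)[mask]
    mean = vals.mean()
    if mean <= 0:
        raise ValueError(f"in-mask mean must be positive, got {mean}")
    return np.where(mask, np.asarray(volume, dtype=float) / mean, 0.0)


def smooth_and_normalize(maps: FCDMaps, grid: BrainGrid, fwhm: float = 8.0) -> FCDMaps:
    """Standardization stage: smooth each raw map, then divide by its global
    (in-mask) mean — smoothing precedes normalization."""
    if maps.stage != "raw":
        raise ValueError("expected raw-stage maps")
    out = {}
    for name, m in (("global_", maps.global_), ("short", maps.short),
                    ("long", maps.long)):
        sm = smooth_volume(m, grid, fwhm, mask=maps.mask)
        out[name] = normalize_by_global_mean(sm, maps.mask)
    return replace(maps, stage="normalized", **out)
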