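"""Arithmetic preprocessing of BOLD series: discard, band-pass, nuisance
regression, and motion quality control.

Registration-type steps (slice timing, realignment estimation, spatial
normalization) are out of scope: synthetic data are generated directly on
the common grid. The pipeline order is discard -> band-pass -> confound
regression; confound columns are band-passed with the same filter before
regression so the projection cannot reintroduce stop-band energy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .grid import BOLDSeries


def discard_initial_volumes(bold: BOLDSeries, k: int = 10) -> BOLDSeries:
    """Drop the first ``k`` volumes (magnetization equilibration)."""
    if k < 0:
        raise ValueError("k must be >= 0")
    if k >= bold.n_volumes:
        raise ValueError(
            f"cannot discard {k} volumes from a series of {bold.n_volumes}")
    return bold.copy_with(bold.data[..., k:].copy())


def _bandpass_matrix(ts: np.ndarray, tr: float, f_lo: float, f_hi: float,
                     method: str, order: int) -> np.ndarray:
    """Zero-phase band-pass of (n_series, t) rows; removes the mean."""
    nyq = 0.5 / tr
    if not 0.0 <= f_lo < f_hi:
        raise ValueError(f"need 0 <= f_lo < f_hi, got ({f_lo}, {f_hi})")
    if f_hi >= nyq:
        raise ValueError(f"f_hi={f_hi} Hz must be below Nyquist ({nyq} Hz)")
    ts = ts - ts.mean(axis=-1, keepdims=True)
    if method == "butterworth":
        if f_lo > 0:
            b, a = signal.butter(order, [f_lo, f_hi], btype="bandpass",
                                 fs=1.0 / tr)
        else:
            b, a = signal.butter(order, f_hi, btype="lowpass", fs=1.0 / tr)
        # Gustafsson forward-backward filtering: minimizes the edge
        # transients that dominate short series with a low f_lo cutoff
        out = signal.filtfilt(b, a, ts, axis=-1, method="gust")
    elif method == "fft":
        n = ts.shape[-1]
        freqs = np.fft.rfftfreq(n, d=tr)
        keep = (freqs >= f_lo) & (freqs <= f_hi)
        spec = np.fft.rfft(ts, axis=-1)
        spec[..., ~keep] = 0.0
        out = np.fft.irfft(spec, n=n, axis=-1)
    else:
        raise ValueError(f"unknown filter method {method!r}")
    return out - out.mean(axis=-1, keepdims=True)


def bandpass_filter(bold: BOLDSeries, f_lo: float = 0.01, f_hi: float = 0.1,
                    method: str = "butterworth", order: int = 4) -> BOLDSeries:
    """Zero-phase temporal band-pass (default 0.01-0.1 Hz).

    ``method='butterworth'`` applies a 4th-order Butterworth forward and
    backward (zero phase, squared magnitude response); ``method='fft'`` is an
    ideal brick-wall alternative. The per-voxel mean is removed inside the
    filter, so a constant series maps to zero.
    """
    flat = bold.data.reshape(-1, bold.n_volumes)
    out = _bandpass_matrix(flat, bold.tr, f_lo, f_hi, method, order)
    return bold.copy_with(np.ascontiguousarray(out.reshape(bold.data.shape)))


def regress_confounds(bold: BOLDSeries, confounds: np.ndarray | pd.DataFrame) -> BOLDSeries:
    """Project out nuisance columns (plus an intercept) from every voxel.

    Residuals are orthogonal to the confounds and the intercept. Raises on
    rank-deficient designs (collinear confounds).
    """
    conf = np.asarray(confounds, dtype=float)
    if conf.ndim == 1:
        conf = conf[:, None]
    t = bold.n_volumes
    if conf.shape[0] != t:
        raise ValueError(
            f"confounds have {conf.shape[0]} rows for a series of {t} volumes")
    design = np.column_stack([np.ones(t), conf])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("confound matrix is rank deficient after adding intercept")
    flat = bold.data.reshape(-1, t).T  # (t, n_voxels)
    beta, *_ = np.linalg.lstsq(design, flat, rcond=None)
    resid = flat - design @ beta
    return bold.copy_with(np.ascontiguousarray(resid.T.reshape(bold.data.shape)))


@dataclass
class QCResult:
    """Motion QC decision with the first offending measurement, if any."""

    decision: str  # 'keep' | 'exclude'
    offending_kind: str | None = None  # 'translation' | 'rotation'
    offending_axis: str | None = None  # 'x' | 'y' | 'z'
    offending_volume: int | None = None
    offending_value: float | None = None

    @property
    def keep(self) -> bool:
        return self.decision == "keep"


def motion_qc(trace: pd.DataFrame | np.ndarray, trans_limit: float = 2.0,
              rot_limit: float = 2.0) -> QCResult:
    """Exclude if any |translation| > ``trans_limit`` mm or |rotation| >
    ``rot_limit`` degrees on any cardinal axis (strict inequalities).

    ``trace`` has six columns: translations x/y/z (mm) then rotations x/y/z
    (degrees), one row per volume, as motion correctors emit relative to the
    reference volume.
    """
    arr = np.asarray(trace, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 6:
        raise ValueError("motion trace must be (n_volumes, 6)")
    if arr.shape[0] == 0:
        raise ValueError("motion trace is empty")
    if not np.isfinite(arr).all():
        raise ValueError("motion trace contains non-finite values")
    limits = [trans_limit] * 3 + [rot_limit] * 3
    kinds = ["translation"] * 3 + ["rotation"] * 3
    axes = ["x", "y", "z"] * 2
    worst = None  # (excess, col, vol)
    for col in range(6):
        vol = int(np.argmax(np.abs(arr[:, col])))
        val = arr[vol, col]
        excess = abs(val) - limits[col]
        if excess > 0 and (worst is None or excess > worst[0]):
            worst = (excess, col, vol)
    if worst is None:
        return QCResult(decision="keep")
    _, col, vol = worst
    return QCResult(
        decision="exclude",
        offending_kind=kinds[col],
        offending_axis=axes[col],
        offending_volume=vol,
        offending_value=float(arr[vol, col]),
    )


def preprocess_subject(
    bold: BOLDSeries,
    motion: pd.DataFrame | np.ndarray | None = None,
    k_discard: int = 10,
    f_lo: float = 0.01,
    f_hi: float = 0.1,
    filter_method: str = "butterworth",
) -> BOLDSeries:
    """discard -> band-pass -> (band-passed) motion regression, in order."""
    out = discard_initial_volumes(bold, k_discard)
    out = bandpass_filter(out, f_lo, f_hi, method=filter_method)
    if motion is not None:
        conf = np.asarray(motion, dtype=float)
        if conf.shape[0] == bold.n_volumes:  # trace covers pre-discard volumes
            conf = conf[k_discard:]
        conf = _bandpass_matrix(conf.T, out.tr, f_lo, f_hi,
                                filter_method, 4).T
        # filtered confounds can be numerically collinear for tiny traces;
        # regress_confounds validates rank
        out = regress_confounds(out, conf)
    return out
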