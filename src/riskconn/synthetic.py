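"""Synthetic cohorts with the statistical structure the analysis assumes.

Four generators, one per input the pipeline consumes:

* :func:`generate_roster` — a recruitment roster with staged exclusion flags
  (missing behavioural data, raw-image errors, bad raw images, excess motion)
  and a sex split for the retained subjects.
* :func:`generate_questionnaire_scores` — a 15-variable trait table drawn
  from a linear factor model whose first latent factor (risk seeking) can be
  mean-shifted for males.
* :func:`generate_motion_traces` — 6-parameter motion traces, clean or with
  a planted above-threshold spike for subjects flagged ``excess_motion``.
* :func:`generate_bold_dataset` — band-limited 4D BOLD series in which voxels
  of a region share a latent signal and the latent signals of region pairs
  correlate with a baseline plus a sex-specific slope on the subject's risk
  score (coupling expressed in Fisher-z units, see :class:`NetworkSpec`).

All generators take one master seed; per-subject randomness is drawn from
deterministically spawned child streams, so identical seeds reproduce
bit-identical outputs regardless of subject order of consumption.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import BOLDSeries, BrainGrid

# fixed column order of the questionnaire table
QUESTIONNAIRE_VARS = [
    "RPS",
    "SSS_TAS", "SSS_ES", "SSS_DIS", "SSS_BS",
    "EPQ_E", "EPQ_N", "EPQ_P", "EPQ_L",
    "TPQ_NS", "TPQ_HA", "TPQ_RD",
    "BIS_ATT", "BIS_MOT", "BIS_NP",
]

EXCLUSION_STAGES = ["missing_behavior", "raw_error", "bad_raw", "excess_motion"]

# Published rotated-loading pattern of the 15 trait scales on the four
# components (risk seeking, impulsivity, lack of control, reward dependence).
# Cells below the display threshold are zero here; the whole matrix is scaled
# so the four components explain 55.8% of total variance, the level reported
# for the original cohort, which the visible cells alone do not reach.
_PATTERN = {
    "RPS":     (0.487, 0.0, 0.0, 0.0),
    "SSS_TAS": (0.486, 0.0, 0.0, 0.0),
    "SSS_ES":  (0.599, 0.0, 0.0, 0.0),
    "SSS_DIS": (0.531, 0.0, 0.0, 0.0),
    "SSS_BS":  (0.0, 0.0, 0.670, 0.0),
    "EPQ_E":   (0.662, 0.0, 0.0, 0.543),
    "EPQ_N":   (-0.578, 0.0, 0.546, 0.0),
    "EPQ_P":   (0.0, 0.0, 0.699, -0.320),
    "EPQ_L":   (0.0, 0.0, -0.596, 0.0),
    "TPQ_NS":  (0.354, 0.657, 0.0, 0.0),
    "TPQ_HA":  (-0.774, 0.0, 0.0, 0.0),
    "TPQ_RD":  (0.0, 0.0, 0.0, 0.824),
    "BIS_ATT": (0.0, 0.525, 0.421, 0.0),
    "BIS_MOT": (0.0, 0.814, 0.0, 0.0),
    "BIS_NP":  (0.0, 0.652, 0.0, -0.319),
}
_TARGET_VARIANCE_FRACTION = 0.558  # 21.8 + 18.0 + 8.7 + 7.3 %


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# roster


@dataclass
class Roster:
    """Recruited subjects with exclusion flags and (for retained) sex."""

    table: pd.DataFrame  # subject_id, sex, flag ('' if retained)

    def __post_init__(self):
        ids = self.table["subject_id"]
        if ids.duplicated().any():
            raise ValueError("subject_ids must be unique")

    @property
    def retained(self) -> pd.DataFrame:
        return self.table[self.table["flag"] == ""].reset_index(drop=True)

    @property
    def n_retained(self) -> int:
        return int((self.table["flag"] == "").sum())

    def flagged(self, flag: str) -> pd.DataFrame:
        return self.table[self.table["flag"] == flag]


def generate_roster(
    n_recruited: int,
    per_stage_exclusions: dict[str, int] | None = None,
    sex_split: tuple[int, int] | None = None,
    seed: int = 0,
) -> Roster:
    """Build a roster of ``n_recruited`` subjects with staged exclusions.

    Exclusion flags are assigned to disjoint subject sets in the stated stage
    order (behavioural -> raw error -> bad raw -> excess motion), mirroring a
    sequential QC cascade. ``sex_split`` = (n_male, n_female) applies to the
    retained subjects; it must sum to the retained count.
    """
    excl = dict.fromkeys(EXCLUSION_STAGES, 0)
    if per_stage_exclusions:
        unknown = set(per_stage_exclusions) - set(EXCLUSION_STAGES)
        if unknown:
            raise ValueError(f"unknown exclusion stages: {sorted(unknown)}")
        excl.update(per_stage_exclusions)
    if any(v < 0 for v in excl.values()):
        raise ValueError("exclusion counts must be non-negative")
    n_excluded = sum(excl.values())
    if n_excluded > n_recruited:
        raise ValueError(
            f"total exclusions ({n_excluded}) exceed n_recruited ({n_recruited})")
    n_retained = n_recruited - n_excluded
    if sex_split is None:
        n_male = n_retained // 2
        sex_split = (n_male, n_retained - n_male)
    if sum(sex_split) != n_retained:
        raise ValueError(
            f"sex_split {sex_split} must sum to retained count {n_retained}")

    rng = np.random.default_rng(seed)
    order = rng.permutation(n_recruited)
    flags = np.array([""] * n_recruited, dtype=object)
    pos = 0
    for stage in EXCLUSION_STAGES:
        k = excl[stage]
        flags[order[pos:pos + k]] = stage
        pos += k
    sex = np.array([""] * n_recruited, dtype=object)
    retained_idx = order[pos:]
    sexes = np.array(["male"] * sex_split[0] + ["female"] * sex_split[1], dtype=object)
    sex[retained_idx] = rng.permutation(sexes)
    # excluded-at-earlier-stages subjects still get a sex for realism
    sex[order[:pos]] = rng.choice(["male", "female"], size=pos)
    table = pd.DataFrame({
        "subject_id": [f"sub-{i + 1:04d}" for i in range(n_recruited)],
        "sex": sex,
        "flag": flags,
    })
    return Roster(table=table)


# ---------------------------------------------------------------------------
# questionnaire factor model


@dataclass
class FactorModel:
    """Linear latent-factor model for the 15 trait variables.

    scores = loadings @ latent + sqrt(uniqueness) * noise, with latent factors
    standard normal and factor 1 mean-shifted by ``sex_shift`` (SD units) for
    males. Communalities + uniqueness sum to 1, so generated variables have
    unit variance and the implied covariance is the correlation matrix
    ``loadings @ loadings.T + diag(uniqueness)``.
    """

    loadings: np.ndarray  # (15, k)
    uniqueness: np.ndarray  # (15,)
    sex_shift: float = 0.8
    variables: list[str] = field(default_factory=lambda: list(QUESTIONNAIRE_VARS))

    def __post_init__(self):
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.uniqueness = np.asarray(self.uniqueness, dtype=float)
        if self.loadings.ndim != 2 or self.loadings.shape[0] != len(self.variables):
            raise ValueError("loadings must be (n_variables, k)")
        if np.any(np.abs(self.loadings) > 1.0):
            raise ValueError("|loadings| must be <= 1")
        if np.any(self.uniqueness <= 0):
            raise ValueError("uniqueness must be strictly positive")
        comm = (self.loadings ** 2).sum(axis=1)
        if np.any(np.abs(comm + self.uniqueness - 1.0) > 1e-9):
            raise ValueError("communality + uniqueness must equal 1 per variable")

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[1]

    def implied_correlation(self) -> np.ndarray:
        return self.loadings @ self.loadings.T + np.diag(self.uniqueness)


def default_factor_model(sex_shift: float = 0.8) -> FactorModel:
    """The published four-component pattern, variance-matched (see module doc)."""
    lam = np.array([_PATTERN[v] for v in QUESTIONNAIRE_VARS], dtype=float)
    lam *= np.sqrt(_TARGET_VARIANCE_FRACTION * len(QUESTIONNAIRE_VARS) / (lam ** 2).sum())
    uniq = 1.0 - (lam ** 2).sum(axis=1)
    return FactorModel(loadings=lam, uniqueness=uniq, sex_shift=sex_shift)


def generate_questionnaire_scores(
    roster: Roster,
    model: FactorModel | None = None,
    seed: int = 0,
    include_excluded: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the questionnaire table (and the latent factors, for validation).

    Returns ``(table, latent)``: the table has subject_id, sex and the 15
    variables in :data:`QUESTIONNAIRE_VARS` order; ``latent`` holds the
    planted factor scores (columns ``factor_1 .. factor_k``) row-aligned with
    the table. By default only retained (unflagged) subjects are scored.
    """
    model = model or default_factor_model()
    subjects = roster.table if include_excluded else roster.retained
    if len(subjects) == 0:
        raise ValueError("roster has no subjects to score")
    n = len(subjects)
    rng = np.random.default_rng(seed)
    latent = rng.standard_normal((n, model.n_factors))
    male = (subjects["sex"] == "male").to_numpy()
    latent[:, 0] += model.sex_shift * male
    noise = rng.standard_normal((n, len(model.variables)))
    scores = latent @ model.loadings.T + noise * np.sqrt(model.uniqueness)
    table = pd.DataFrame(scores, columns=model.variables)
    table.insert(0, "sex", subjects["sex"].to_numpy())
    table.insert(0, "subject_id", subjects["subject_id"].to_numpy())
    latent_df = pd.DataFrame(
        latent, columns=[f"factor_{j + 1}" for j in range(model.n_factors)])
    latent_df.insert(0, "subject_id", subjects["subject_id"].to_numpy())
    return table, latent_df


# ---------------------------------------------------------------------------
# motion traces

MOTION_COLUMNS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]


def generate_motion_traces(
    roster: Roster,
    n_volumes: int = 180,
    clean_sd: float = 0.1,
    spike_amplitude: float = 2.5,
    trans_limit: float = 2.0,
    rot_limit: float = 2.0,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Per-subject 6-parameter motion traces (mm translations, deg rotations).

    Subjects flagged ``excess_motion`` receive one spike of ``spike_amplitude``
    on a random axis/volume; everyone else is kept strictly inside both QC
    bounds by clipping the clean jitter.
    """
    if n_volumes < 1:
        raise ValueError("n_volumes must be >= 1")
    if spike_amplitude <= max(trans_limit, rot_limit):
        raise ValueError(
            f"spike amplitude {spike_amplitude} does not exceed the QC bounds "
            f"({trans_limit} mm / {rot_limit} deg); flagged subjects would pass QC")
    table = roster.table
    rngs = _child_rngs(seed, len(table))
    out: dict[str, pd.DataFrame] = {}
    clip = 0.9 * min(trans_limit, rot_limit)
    for (_, row), rng in zip(table.iterrows(), rngs):
        trace = np.clip(rng.standard_normal((n_volumes, 6)) * clean_sd, -clip, clip)
        if row["flag"] == "excess_motion":
            axis = int(rng.integers(0, 6))
            vol = int(rng.integers(0, n_volumes))
            trace[vol, axis] = spike_amplitude * (1 if rng.random() < 0.5 else -1)
        out[row["subject_id"]] = pd.DataFrame(trace, columns=MOTION_COLUMNS)
    return out


# ---------------------------------------------------------------------------
# BOLD


@dataclass
class NetworkSpec:
    """Planted network structure for BOLD generation.

    ``rois`` maps names to (k, 3) voxel index arrays. For an ROI pair (a, b),
    the latent-signal correlation of a subject with risk score ``g`` and the
    given sex is ``tanh(atanh(baseline_corr[a,b]) + coupling[a,b][sex] * g)``:
    couplings are Fisher-z slopes per risk-score SD, which keeps every implied
    correlation inside (-1, 1) at any ``g``. Each ROI voxel observes its ROI's
    latent signal plus white noise of SD ``noise_sd``; in-mask voxels outside
    every ROI get an independent band-limited signal plus the same noise.
    """

    rois: dict[str, np.ndarray]
    baseline_corr: dict[tuple[str, str], float] = field(default_factory=dict)
    coupling: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    noise_sd: float = 0.5

    def __post_init__(self):
        self.rois = {k: np.atleast_2d(np.asarray(v, dtype=int)) for k, v in self.rois.items()}
        for name, vox in self.rois.items():
            if vox.shape[1] != 3 or len(vox) == 0:
                raise ValueError(f"ROI {name!r} must be a non-empty (k, 3) index array")
        for key, r in self.baseline_corr.items():
            if not -1.0 < r < 1.0:
                raise ValueError(f"baseline correlation for edge {key} outside (-1, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def roi_names(self) -> list[str]:
        return list(self.rois)

    def _edge(self, a: str, b: str):
        if (a, b) in self.baseline_corr:
            return (a, b)
        if (b, a) in self.baseline_corr:
            return (b, a)
        return None

    def latent_correlation(self, grp: float, sex: str) -> np.ndarray:
        """Implied latent correlation matrix for one subject."""
        names = self.roi_names
        k = len(names)
        c = np.eye(k)
        si = 0 if sex == "male" else 1
        for i in range(k):
            for j in range(i + 1, k):
                edge = self._edge(names[i], names[j])
                if edge is None:
                    continue
                z = np.arctanh(self.baseline_corr[edge])
                slope = self.coupling.get(edge, (0.0, 0.0))[si]
                c[i, j] = c[j, i] = np.tanh(z + slope * grp)
        return c


def two_roi_spec(
    grid: BrainGrid,
    roi_size: int = 3,
    baseline_corr: float = 0.71,
    male_slope: float = -0.2,
    female_slope: float = 0.0,
    noise_sd: float = 0.5,
) -> NetworkSpec:
    """Two cubic ROIs in opposite corners of the grid, one coupled edge.

    The default edge sits just above the connectivity threshold used by the
    density mapping (r = 0.6) at risk score 0, so a negative male slope
    detaches the regions for high-risk males — the planted moderation effect.
    """
    s = roi_size
    nx, ny, nz = grid.dims
    if min(grid.dims) < 2 * s + 2:
        raise ValueError("grid too small for two separated ROIs of this size")
    a = np.array([(i, j, k) for i in range(1, 1 + s)
                  for j in range(1, 1 + s) for k in range(1, 1 + s)])
    b = np.array([(i, j, k) for i in range(nx - 1 - s, nx - 1)
                  for j in range(ny - 1 - s, ny - 1) for k in range(nz - 1 - s, nz - 1)])
    return NetworkSpec(
        rois={"roi_a": a, "roi_b": b},
        baseline_corr={("roi_a", "roi_b"): baseline_corr},
        coupling={("roi_a", "roi_b"): (male_slope, female_slope)},
        noise_sd=noise_sd,
    )


def band_limited_noise(rng: np.random.Generator, n_series: int, n_volumes: int,
                       tr: float, f_lo: float = 0.01, f_hi: float = 0.1) -> np.ndarray:
    """Unit-variance series with spectrum confined to [f_lo, f_hi] Hz.

    White noise is hard band-limited in the frequency domain, then each
    series is standardized, making the planted spectrum unambiguous.
    """
    white = rng.standard_normal((n_series, n_volumes))
    freqs = np.fft.rfftfreq(n_volumes, d=tr)
    keep = (freqs >= f_lo) & (freqs <= f_hi)
    if not keep.any():
        raise ValueError("band contains no resolvable frequency")
    spec = np.fft.rfft(white, axis=1)
    spec[:, ~keep] = 0.0
    out = np.fft.irfft(spec, n=n_volumes, axis=1)
    out -= out.mean(axis=1, keepdims=True)
    sd = out.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    return out / sd[:, None]


def generate_bold_dataset(
    roster: Roster,
    grid: BrainGrid,
    spec: NetworkSpec,
    grp: pd.Series | np.ndarray,
    mask: np.ndarray | None = None,
    n_volumes: int = 180,
    tr: float = 2.0,
    f_lo: float = 0.01,
    f_hi: float = 0.1,
    seed: int = 0,
) -> dict[str, BOLDSeries]:
    """Generate one 4D BOLD series per retained subject.

    ``grp`` is the per-subject risk score aligned with ``roster.retained``.
    Within-ROI voxels share their ROI's latent series (short-range density is
    planted); ROI-pair latent correlations follow the spec's baseline +
    sex-specific Fisher-z coupling x score (long-range density and seed-based
    connectivity couplings are planted).
    """
    subjects = roster.retained
    grp = np.asarray(grp, dtype=float)
    if len(grp) != len(subjects):
        raise ValueError("grp must align with retained roster subjects")
    if mask is None:
        mask = np.ones(grid.dims, dtype=bool)
    for name, vox in spec.rois.items():
        if not mask[tuple(vox.T)].all():
            raise ValueError(f"ROI {name!r} is not fully inside the mask")
    names = spec.roi_names
    roi_flat = {n: np.ravel_multi_index(tuple(spec.rois[n].T), grid.dims) for n in names}
    mask_flat = np.flatnonzero(mask.ravel())
    in_roi = np.zeros(int(np.prod(grid.dims)), dtype=bool)
    for n in names:
        in_roi[roi_flat[n]] = True
    bg_flat = mask_flat[~in_roi[mask_flat]]

    rngs = _child_rngs(seed, len(subjects))
    out: dict[str, BOLDSeries] = {}
    for idx, ((_, row), rng) in enumerate(zip(subjects.iterrows(), rngs)):
        c = spec.latent_correlation(grp[idx], row["sex"])
        try:
            chol = np.linalg.cholesky(c)
        except np.linalg.LinAlgError as err:
            raise ValueError(
                f"implied latent correlation matrix for subject "
                f"{row['subject_id']} (score {grp[idx]:.3f}) is not positive "
                f"definite; offending edges: "
                f"{[(a, b) for (a, b) in spec.baseline_corr]}") from err
        raw = band_limited_noise(rng, len(names), n_volumes, tr, f_lo, f_hi)
        latents = chol @ raw
        vol = np.zeros((int(np.prod(grid.dims)), n_volumes))
        if len(bg_flat):
            vol[bg_flat] = band_limited_noise(rng, len(bg_flat), n_volumes, tr, f_lo, f_hi)
        for j, n in enumerate(names):
            vol[roi_flat[n]] = latents[j]
        if spec.noise_sd > 0:
            vol[mask_flat] += spec.noise_sd * rng.standard_normal(
                (len(mask_flat), n_volumes))
        data = vol.reshape(grid.dims + (n_volumes,))
        data[~mask] = 0.0
        out[row["subject_id"]] = BOLDSeries(data=data, tr=tr, grid=grid, mask=mask)
    return out
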