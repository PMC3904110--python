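"""Composite general-risk-propensity (GRP) score from 15 trait variables.

The score is the regression-method score of the varimax-rotated principal
component that carries the risk-seeking loading pattern. PCA is run on the
correlation matrix (the variables mix scales), components with unrotated
eigenvalue > 1 are retained, and varimax with Kaiser row normalization is
applied to the retained loadings. Sampling adequacy (KMO) and Bartlett's
sphericity test are provided as the standard pre-checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import QUESTIONNAIRE_VARS

#: default signed markers of the risk-seeking component: sign convention such
#: that a high score means risk taking (harm avoidance loads negatively).
DEFAULT_MARKERS: dict[str, int] = {
    "RPS": 1, "SSS_TAS": 1, "SSS_ES": 1, "SSS_DIS": 1,
    "EPQ_E": 1, "TPQ_NS": 1, "TPQ_HA": -1,
}


def _numeric_matrix(table: pd.DataFrame, variables: list[str] | None = None):
    variables = variables or [v for v in QUESTIONNAIRE_VARS if v in table.columns]
    missing = [v for v in variables if v not in table.columns]
    if missing:
        raise ValueError(f"table lacks variables: {missing}")
    x = table[variables].to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("missing values in questionnaire table")
    return x, variables


def _correlation(x: np.ndarray) -> np.ndarray:
    if x.shape[0] <= x.shape[1]:
        raise ValueError(
            f"need more subjects ({x.shape[0]}) than variables ({x.shape[1]})")
    return np.corrcoef(x, rowvar=False)


def sampling_adequacy(table: pd.DataFrame, variables: list[str] | None = None) -> float:
    """Kaiser-Meyer-Olkin measure of sampling adequacy, in [0, 1].

    KMO = sum r_ij^2 / (sum r_ij^2 + sum q_ij^2) over i != j, where q are the
    anti-image partial correlations obtained from the inverse correlation
    matrix.
    """
    x, _ = _numeric_matrix(table, variables)
    r = _correlation(x)
    sign, logdet = np.linalg.slogdet(r)
    if sign <= 0 or logdet < np.log(1e-12):
        raise ValueError("correlation matrix is singular; KMO undefined")
    rinv = np.linalg.inv(r)
    d = np.sqrt(np.diag(rinv))
    partial = -rinv / np.outer(d, d)
    off = ~np.eye(len(r), dtype=bool)
    ssr = (r[off] ** 2).sum()
    ssq = (partial[off] ** 2).sum()
    return float(ssr / (ssr + ssq))


def bartlett_test(table: pd.DataFrame, variables: list[str] | None = None):
    """Bartlett's test of sphericity: H0 is an identity correlation matrix.

    Returns (chi2, df, p) with chi2 = -(n - 1 - (2p + 5) / 6) * ln det R and
    df = p (p - 1) / 2.
    """
    x, variables = _numeric_matrix(table, variables)
    n, p = x.shape
    r = _correlation(x)
    sign, logdet = np.linalg.slogdet(r)
    if sign <= 0:
        raise ValueError("correlation matrix has non-positive determinant")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    pval = float(stats.chi2.sf(chi2, df))
    return float(chi2), int(df), pval


def varimax_rotation(loadings: np.ndarray, kaiser_normalize: bool = True,
                     tol: float = 1e-8, max_iter: int = 500):
    """Varimax rotation of a loading matrix; returns (rotated, rotation).

    Maximizes the variance of squared loadings per component (orthogonal
    rotation), by the standard SVD fixed-point iteration. With Kaiser
    normalization rows are scaled to unit communality during the rotation.
    """
    a = np.asarray(loadings, dtype=float)
    p, k = a.shape
    if k == 1:
        return a.copy(), np.eye(1)
    h = np.sqrt((a ** 2).sum(axis=1))
    if kaiser_normalize:
        if np.any(h == 0):
            raise ValueError("zero-communality row; cannot Kaiser-normalize")
        a = a / h[:, None]
    # classic pairwise (Jacobi-style) sweeps: rotate every component pair by
    # its closed-form optimal planar angle until a whole sweep moves nothing;
    # each planar rotation increases the criterion, so this cannot cycle
    rot = np.eye(k)
    b = a.copy()
    for _ in range(max_iter):
        max_phi = 0.0
        for i in range(k - 1):
            for j in range(i + 1, k):
                u, v = b[:, i], b[:, j]
                u2 = u ** 2 - v ** 2
                uv = 2.0 * u * v
                num = 2.0 * (p * (u2 * uv).sum() - u2.sum() * uv.sum())
                den = (p * (u2 ** 2 - uv ** 2).sum()
                       - (u2.sum() ** 2 - uv.sum() ** 2))
                phi = 0.25 * np.arctan2(num, den)
                if abs(phi) < tol:
                    continue
                max_phi = max(max_phi, abs(phi))
                c, s = np.cos(phi), np.sin(phi)
                g = np.array([[c, -s], [s, c]])
                b[:, [i, j]] = b[:, [i, j]] @ g
                rot[:, [i, j]] = rot[:, [i, j]] @ g
        if max_phi < tol:
            break
    out = b
    if kaiser_normalize:
        out = out * h[:, None]
    return out, rot


@dataclass
class PCAResult:
    """Correlation-matrix PCA with varimax rotation of retained components."""

    variables: list[str]
    eigenvalues: np.ndarray           # all p, descending
    retained_k: int
    loadings_unrotated: np.ndarray    # (p, k)
    loadings: np.ndarray              # (p, k) rotated, ordered by variance
    rotation: np.ndarray              # (k, k) orthogonal
    variance_explained_pct: np.ndarray  # per rotated component
    score_coefficients: np.ndarray    # (p, k) regression-method weights
    column_means: np.ndarray
    column_sds: np.ndarray

    def loadings_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.loadings, index=self.variables,
            columns=[f"component_{j + 1}" for j in range(self.retained_k)])


def fit_pca_varimax(table: pd.DataFrame, retain_rule: float = 1.0,
                    variables: list[str] | None = None,
                    kaiser_normalize: bool = True, tol: float = 1e-8,
                    max_iter: int = 500) -> PCAResult:
    """PCA on the correlation matrix; retain eigenvalues > ``retain_rule``
    (strict, applied to unrotated eigenvalues); varimax-rotate the retained
    loadings and report variance explained per rotated component.
    """
    x, variables = _numeric_matrix(table, variables)
    n, p = x.shape
    r = _correlation(x)
    w, v = np.linalg.eigh(r)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    # strict rule with a numerical guard: eigenvalues that equal the cutoff
    # to machine precision (identity correlation) must not be retained
    k = int((w > retain_rule + 1e-10).sum())
    if k == 0:
        raise ValueError(
            f"no component has eigenvalue > {retain_rule}; nothing to retain")
    load = v[:, :k] * np.sqrt(w[:k])
    rot_load, rot = varimax_rotation(load, kaiser_normalize, tol, max_iter)
    # order rotated components by variance explained, orient each so its
    # largest-magnitude loading is positive (sign is arbitrary)
    ve = (rot_load ** 2).sum(axis=0)
    order2 = np.argsort(ve)[::-1]
    rot_load = rot_load[:, order2]
    rot = rot[:, order2]
    signs = np.sign(rot_load[np.abs(rot_load).argmax(axis=0), np.arange(k)])
    signs[signs == 0] = 1.0
    rot_load *= signs
    rot *= signs
    ve = (rot_load ** 2).sum(axis=0) / p * 100.0
    # regression-method scoring weights: R^-1 Lambda_rot
    coef = np.linalg.solve(r, rot_load)
    return PCAResult(
        variables=variables,
        eigenvalues=w,
        retained_k=k,
        loadings_unrotated=load,
        loadings=rot_load,
        rotation=rot,
        variance_explained_pct=ve,
        score_coefficients=coef,
        column_means=x.mean(axis=0),
        column_sds=x.std(axis=0, ddof=1),
    )


def score_components(table: pd.DataFrame, pca: PCAResult) -> np.ndarray:
    """Regression-method component scores, (n, k): Z @ R^-1 Lambda_rot.

    The table must carry the same variables the PCA was fit on; columns are
    standardized with the fit-time means/SDs, so each score column has mean
    zero on the fitting sample.
    """
    x, _ = _numeric_matrix(table, pca.variables)
    z = (x - pca.column_means) / pca.column_sds
    return z @ pca.score_coefficients


def select_grp_component(pca: PCAResult,
                         markers: dict[str, int] | None = None) -> tuple[int, int]:
    """Pick the rotated component carrying the signed risk-marker pattern.

    Returns (index, sign): the component maximizing |sum of signed marker
    loadings| and the sign that makes the sum positive (high score = risk
    taking). A tie within 1e-6 raises, prompting a manual choice.
    """
    markers = markers or DEFAULT_MARKERS
    idx = [pca.variables.index(m) for m in markers]
    signs = np.array([markers[m] for m in markers], dtype=float)
    sums = (pca.loadings[idx] * signs[:, None]).sum(axis=0)
    mags = np.abs(sums)
    best = int(np.argmax(mags))
    others = np.delete(mags, best)
    if others.size and mags[best] - others.max() < 1e-6:
        raise ValueError(
            "marker-loading sums tie across components; select manually")
    return best, (1 if sums[best] > 0 else -1)


@dataclass
class GRPScores:
    """Per-subject risk-propensity score (SD units, mean 0 on the fit sample)."""

    subject_id: pd.Series
    score: np.ndarray
    component_index: int
    sign: int

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"subject_id": self.subject_id, "grp": self.score})


def extract_grp(table: pd.DataFrame, pca: PCAResult | None = None,
                markers: dict[str, int] | None = None) -> tuple[GRPScores, PCAResult]:
    """Fit (if needed), score, and orient the GRP component in one call."""
    if pca is None:
        pca = fit_pca_varimax(table)
    scores = score_components(table, pca)
    idx, sign = select_grp_component(pca, markers)
    return GRPScores(
        subject_id=table["subject_id"] if "subject_id" in table else
        pd.Series(np.arange(len(table))),
        score=sign * scores[:, idx],
        component_index=idx,
        sign=sign,
    ), pca


@dataclass
class SexComparison:
    male_mean: float
    male_sd: float
    male_n: int
    female_mean: float
    female_sd: float
    female_n: int
    t: float
    df: float
    p: float


def compare_sexes(scores: np.ndarray, sex: pd.Series | np.ndarray,
                  equal_var: bool = False) -> SexComparison:
    """Two-sided independent-samples t-test of male vs female scores.

    Welch by default; ``equal_var=True`` gives the pooled-variance test.
    """
    scores = np.asarray(scores, dtype=float)
    sex = np.asarray(sex)
    male = scores[sex == "male"]
    female = scores[sex == "female"]
    if len(male) < 2 or len(female) < 2:
        raise ValueError("both sexes need at least two subjects")
    res = stats.ttest_ind(male, female, equal_var=equal_var)
    return SexComparison(
        male_mean=float(male.mean()), male_sd=float(male.std(ddof=1)),
        male_n=len(male),
        female_mean=float(female.mean()), female_sd=float(female.std(ddof=1)),
        female_n=len(female),
        t=float(res.statistic), df=float(res.df), p=float(res.pvalue),
    )
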