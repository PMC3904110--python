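"""Trait-score construction: KMO against an explicit partial-correlation
oracle, Bartlett closed forms, varimax against a pairwise-rotation oracle,
regression scoring identities, marker-based component selection, and the
sex comparison against the textbook Welch formula."""

import numpy as np
import pandas as pd
import pytest

from riskconn import grp, synthetic


def _table(data, cols=None):
    cols = cols or [f"v{i}" for i in range(data.shape[1])]
    return pd.DataFrame(np.asarray(data, dtype=float), columns=cols)


class TestKMO:
    def test_matches_partial_correlation_oracle_three_vars(self, rng):
        x = rng.standard_normal((500, 3)) @ np.array(
            [[1.0, 0.5, 0.2], [0.0, 1.0, 0.4], [0.0, 0.0, 1.0]])
        table = _table(x)
        r = np.corrcoef(x, rowvar=False)
        # oracle: first-order partials r_ij.k by the textbook formula
        def partial(i, j, k):
            return (r[i, j] - r[i, k] * r[j, k]) / np.sqrt(
                (1 - r[i, k] ** 2) * (1 - r[j, k] ** 2))
        q = [partial(0, 1, 2), partial(0, 2, 1), partial(1, 2, 0)]
        ssr = 2 * sum(r[i, j] ** 2 for i, j in [(0, 1), (0, 2), (1, 2)])
        ssq = 2 * sum(v ** 2 for v in q)
        expected = ssr / (ssr + ssq)
        assert grp.sampling_adequacy(table, ["v0", "v1", "v2"]) == \
            pytest.approx(expected, abs=1e-10)

    def test_equicorrelated_closed_form(self):
        # p=4, all pairwise r=0.5: the partial correlation of any pair given
        # the other two variables is rho / (1 + (p-2) rho) = 0.25 exactly, so
        # KMO = 0.5^2 / (0.5^2 + 0.25^2) = 0.8. Data with that exact sample
        # correlation are built from orthonormal columns via the matrix root.
        p, rho = 4, 0.5
        r = np.full((p, p), rho)
        np.fill_diagonal(r, 1.0)
        w, v = np.linalg.eigh(r)
        root = v @ np.diag(np.sqrt(w)) @ v.T
        rng = np.random.default_rng(0)
        x = rng.standard_normal((40, p))
        x -= x.mean(0)
        q, _ = np.linalg.qr(x)
        table = _table(q @ root)
        partial = rho / (1 + (p - 2) * rho)
        expected = rho ** 2 / (rho ** 2 + partial ** 2)
        assert grp.sampling_adequacy(table, list(table.columns)) == \
            pytest.approx(expected, abs=1e-8)

    def test_duplicated_variable_is_singular(self, rng):
        x = rng.standard_normal((100, 2))
        table = _table(np.column_stack([x, x[:, 0]]))
        with pytest.raises(ValueError):
            grp.sampling_adequacy(table, list(table.columns))


class TestBartlett:
    def test_identity_correlation_gives_zero_chi2(self):
        n, p = 60, 4
        rng = np.random.default_rng(1)
        x = rng.standard_normal((n, p))
        x -= x.mean(0)
        q, _ = np.linalg.qr(x)  # exactly orthogonal columns -> R = I
        chi2, df, pval = grp.bartlett_test(_table(q), [f"v{i}" for i in range(p)])
        assert chi2 == pytest.approx(0.0, abs=1e-8)
        assert pval == pytest.approx(1.0, abs=1e-8)

    def test_df_for_fifteen_variables(self, cohort_table):
        table, _ = cohort_table
        _, df, _ = grp.bartlett_test(table)
        assert df == 105  # 15 * 14 / 2

    def test_strong_structure_rejects(self, cohort_table):
        table, _ = cohort_table
        chi2, _, p = grp.bartlett_test(table)
        assert chi2 > 500 and p < 1e-10


class TestVarimax:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_angle_grid_search_oracle(self, seed):
        # for two components the rotation is a single angle: a dense grid
        # search plus local refinement is a fully independent oracle
        rng = np.random.default_rng(seed)
        a = rng.standard_normal((6, 2))

        def criterion(m):
            s = m ** 2
            return (s.var(axis=0)).sum()

        def rotated(a, phi):
            c, s = np.cos(phi), np.sin(phi)
            return a @ np.array([[c, -s], [s, c]])

        grid = np.linspace(0, np.pi / 2, 20001)
        best = max((criterion(rotated(a, phi)) for phi in grid))
        ours, rot = grp.varimax_rotation(a, kaiser_normalize=False)
        assert criterion(ours) == pytest.approx(best, abs=1e-6)
        # rotation matrix is orthonormal and reproduces the output
        np.testing.assert_allclose(rot.T @ rot, np.eye(2), atol=1e-10)
        np.testing.assert_allclose(a @ rot, ours, atol=1e-10)

    def test_symmetric_two_block_case_reaches_optimum(self):
        # a near-45-degree configuration on which naive fixed-point varimax
        # iterations are known to stall between two rotations
        a = np.array([[0.396, -0.811], [0.389, -0.813], [0.380, -0.820],
                      [0.816, 0.389], [0.819, 0.384], [0.819, 0.387]])

        def criterion(m):
            s = m ** 2
            return (s.var(axis=0)).sum()

        grid = np.linspace(0, np.pi / 2, 20001)

        def rotated(phi):
            c, s = np.cos(phi), np.sin(phi)
            return a @ np.array([[c, -s], [s, c]])

        best = max(criterion(rotated(phi)) for phi in grid)
        ours, _ = grp.varimax_rotation(a, kaiser_normalize=False)
        assert criterion(ours) == pytest.approx(best, abs=1e-6)

    def test_communalities_invariant(self, rng):
        a = rng.standard_normal((10, 3))
        out, _ = grp.varimax_rotation(a)
        np.testing.assert_allclose((a ** 2).sum(1), (out ** 2).sum(1), atol=1e-8)


class TestFitPCA:
    def test_identity_correlation_retains_nothing(self):
        n, p = 60, 5
        rng = np.random.default_rng(2)
        x = rng.standard_normal((n, p))
        x -= x.mean(0)
        q, _ = np.linalg.qr(x)
        with pytest.raises(ValueError):
            grp.fit_pca_varimax(_table(q), variables=[f"v{i}" for i in range(p)])

    def test_recovers_planted_two_block_structure(self):
        lam = np.zeros((6, 2))
        lam[:3, 0] = 0.85
        lam[3:, 1] = 0.85
        rng = np.random.default_rng(3)
        latent = rng.standard_normal((3000, 2))
        x = latent @ lam.T + rng.standard_normal((3000, 6)) * np.sqrt(
            1 - (lam ** 2).sum(1))
        pca = grp.fit_pca_varimax(_table(x), variables=[f"v{i}" for i in range(6)])
        assert pca.retained_k == 2
        load = np.abs(pca.loadings)
        for var in range(6):
            block = 0 if var < 3 else 1
            on = load[var].max()
            off = load[var].min()
            assert on > 0.7 and off < 0.2

    def test_eigenvalues_sum_to_p(self, cohort_table):
        table, _ = cohort_table
        pca = grp.fit_pca_varimax(table)
        assert pca.eigenvalues.sum() == pytest.approx(15.0, abs=1e-6)

    def test_rotation_preserves_retained_variance(self, cohort_table):
        table, _ = cohort_table
        pca = grp.fit_pca_varimax(table)
        unrot = (pca.loadings_unrotated ** 2).sum()
        rot = (pca.loadings ** 2).sum()
        assert rot == pytest.approx(unrot, abs=1e-8)
        np.testing.assert_allclose(
            (pca.loadings_unrotated ** 2).sum(1), (pca.loadings ** 2).sum(1),
            atol=1e-8)


class TestScores:
    def test_scores_zero_at_column_means(self, cohort_table):
        table, _ = cohort_table
        pca = grp.fit_pca_varimax(table)
        centered = table.copy()
        centered[pca.variables] = pca.column_means
        s = grp.score_components(centered, pca)
        assert np.abs(s).max() < 1e-10

    def test_single_component_score_is_first_pc(self):
        # one dominant factor -> k=1; regression score must equal the PC score
        lam = np.full((6, 1), 0.9)
        rng = np.random.default_rng(4)
        latent = rng.standard_normal((2000, 1))
        x = latent @ lam.T + rng.standard_normal((2000, 6)) * np.sqrt(1 - 0.81)
        table = _table(x)
        pca = grp.fit_pca_varimax(table, variables=list(table.columns))
        assert pca.retained_k == 1
        s = grp.score_components(table, pca)[:, 0]
        z = (x - x.mean(0)) / x.std(0, ddof=1)
        pc = z @ pca.loadings_unrotated[:, 0]
        assert abs(np.corrcoef(s, pc)[0, 1]) == pytest.approx(1.0, abs=1e-10)

    def test_scores_invariant_to_affine_rescaling(self, cohort_table):
        table, _ = cohort_table
        scores_a, _ = grp.extract_grp(table)
        rescaled = table.copy()
        for j, v in enumerate(synthetic.QUESTIONNAIRE_VARS):
            rescaled[v] = table[v] * (j + 2.0) + 10.0 * j
        scores_b, _ = grp.extract_grp(rescaled)
        np.testing.assert_allclose(scores_a.score, scores_b.score, atol=1e-8)

    def test_score_mean_zero(self, cohort_table):
        table, _ = cohort_table
        pca = grp.fit_pca_varimax(table)
        s = grp.score_components(table, pca)
        assert np.abs(s.mean(0)).max() < 1e-10


class TestSelectComponent:
    def _pca_with_loadings(self, loadings):
        p, k = loadings.shape
        return grp.PCAResult(
            variables=list(synthetic.QUESTIONNAIRE_VARS),
            eigenvalues=np.ones(p), retained_k=k,
            loadings_unrotated=loadings, loadings=loadings,
            rotation=np.eye(k),
            variance_explained_pct=(loadings ** 2).sum(0) / p * 100,
            score_coefficients=loadings,
            column_means=np.zeros(p), column_sds=np.ones(p))

    def _published_pattern(self):
        m = synthetic.default_factor_model()
        return m.loadings

    def test_published_pattern_selects_first_component(self):
        pca = self._pca_with_loadings(self._published_pattern())
        idx, sign = grp.select_grp_component(pca)
        assert (idx, sign) == (0, 1)

    def test_negated_component_flips_sign(self):
        lam = self._published_pattern().copy()
        lam[:, 0] *= -1
        idx, sign = grp.select_grp_component(self._pca_with_loadings(lam))
        assert (idx, sign) == (0, -1)

    def test_agrees_with_enumeration_oracle(self, cohort_table):
        table, _ = cohort_table
        pca = grp.fit_pca_varimax(table)
        idx, sign = grp.select_grp_component(pca)
        sums = []
        for j in range(pca.retained_k):
            s = sum(w * pca.loadings[pca.variables.index(v), j]
                    for v, w in grp.DEFAULT_MARKERS.items())
            sums.append(s)
        assert idx == int(np.argmax(np.abs(sums)))
        assert sign == (1 if sums[idx] > 0 else -1)

    def test_tie_raises(self):
        lam = np.zeros((15, 2))
        lam[0, 0] = lam[0, 1] = 0.5  # identical marker sums
        with pytest.raises(ValueError, match="tie"):
            grp.select_grp_component(self._pca_with_loadings(lam))


class TestCompareSexes:
    def test_identical_groups_null(self):
        scores = np.r_[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        sex = np.array(["male"] * 3 + ["female"] * 3)
        res = grp.compare_sexes(scores, sex)
        assert res.t == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0, abs=1e-12)

    def test_matches_welch_formula(self):
        m = np.array([1.1, 2.3, 0.7])
        f = np.array([0.2, -0.4, 0.9])
        sex = np.array(["male"] * 3 + ["female"] * 3)
        res = grp.compare_sexes(np.r_[m, f], sex)
        se = np.sqrt(m.var(ddof=1) / 3 + f.var(ddof=1) / 3)
        assert res.t == pytest.approx((m.mean() - f.mean()) / se, abs=1e-10)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            grp.compare_sexes(np.arange(4.0), np.array(["male"] * 4))
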