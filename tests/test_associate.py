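import numpy as np
import pandas as pd
import pytest
from scipy import stats

from circaging import associate, synthetic
from circaging.associate import (
    bonferroni_threshold,
    count_dysregulated,
    fit_phenotype_association,
    mouse_lifespan_association,
    normalize_qpcr,
    senescence_compare,
)
from circaging.data import load_senescence_reference


def qpcr_long(ct_matrix, n_technical=1):
    """ct_matrix: dict assay -> dict sample -> ct."""
    rows = []
    for assay, samples in ct_matrix.items():
        for sample, ct in samples.items():
            for tech in range(1, n_technical + 1):
                rows.append(
                    {
                        "assay_id": assay,
                        "sample_id": sample,
                        "technical_replicate": tech,
                        "ct": ct,
                    }
                )
    return pd.DataFrame(rows)


class TestNormalizeQpcr:
    def test_flat_matrix_all_ones(self):
        matrix = qpcr_long(
            {"a1": {"s1": 25.0, "s2": 25.0}, "a2": {"s1": 25.0, "s2": 25.0}}
        )
        out = normalize_qpcr(matrix)
        assert np.allclose(out.expression.values, 1.0)

    def test_2x2_hand_oracle(self):
        # spreadsheet-style evaluation of the four steps on a 2x2 matrix
        # with a1/s1 lowered by one cycle
        ct = {"a1": {"s1": 24.0, "s2": 25.0}, "a2": {"s1": 25.0, "s2": 25.0}}
        out = normalize_qpcr(qpcr_long(ct)).expression

        # step 2: per-sample mean: s1 = 24.5, s2 = 25
        dct = {
            ("a1", "s1"): 24.0 - 24.5,
            ("a2", "s1"): 25.0 - 24.5,
            ("a1", "s2"): 0.0,
            ("a2", "s2"): 0.0,
        }
        # step 3: expression; step 4: per-assay geometric mean scaling
        e = {k: 2.0 ** (-v) for k, v in dct.items()}
        for assay in ("a1", "a2"):
            gm = np.sqrt(e[(assay, "s1")] * e[(assay, "s2")])
            for sample in ("s1", "s2"):
                expected = e[(assay, sample)] / gm
                assert out.loc[assay, sample] == pytest.approx(expected, abs=1e-12)

    def test_technical_replicates_median(self):
        rows = qpcr_long({"a1": {"s1": 24.0, "s2": 25.0}, "a2": {"s1": 25.0, "s2": 25.0}})
        # add an outlier technical replicate that the median ignores
        extra = pd.DataFrame(
            [
                {"assay_id": "a1", "sample_id": "s1", "technical_replicate": 2, "ct": 24.0},
                {"assay_id": "a1", "sample_id": "s1", "technical_replicate": 3, "ct": 40.0},
            ]
        )
        base = normalize_qpcr(rows).expression
        out = normalize_qpcr(pd.concat([rows, extra], ignore_index=True)).expression
        pd.testing.assert_frame_equal(base, out)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        ct = {
            f"a{i}": {f"s{j}": float(rng.uniform(20, 30)) for j in range(4)}
            for i in range(3)
        }
        matrix = qpcr_long(ct)
        shuffled = matrix.sample(frac=1.0, random_state=0).reset_index(drop=True)
        out1 = normalize_qpcr(matrix).expression
        out2 = normalize_qpcr(shuffled).expression
        pd.testing.assert_frame_equal(out1, out2.loc[out1.index, out1.columns])

    def test_per_assay_geometric_mean_is_one(self):
        rng = np.random.default_rng(2)
        ct = {
            f"a{i}": {f"s{j}": float(rng.uniform(18, 32)) for j in range(5)}
            for i in range(4)
        }
        out = normalize_qpcr(qpcr_long(ct)).expression
        gm = np.exp(np.log(out).mean(axis=1))
        assert np.allclose(gm, 1.0, atol=1e-10)

    def test_all_missing_sample_dropped_with_warning(self):
        matrix = qpcr_long(
            {"a1": {"s1": 24.0, "s2": 25.0, "s3": np.nan}, "a2": {"s1": 25.0, "s2": 25.0, "s3": np.nan}}
        )
        with pytest.warns(UserWarning, match="s3"):
            out = normalize_qpcr(matrix)
        assert out.dropped_samples == ["s3"]
        assert "s3" not in out.expression.columns

    def test_sparse_assay_flagged(self):
        matrix = qpcr_long(
            {
                "a1": {"s1": 24.0, "s2": 25.0, "s3": 26.0},
                "a2": {"s1": 25.0, "s2": 25.0, "s3": 25.0},
                "sparse": {"s1": 25.0, "s2": np.nan, "s3": np.nan},
            }
        )
        out = normalize_qpcr(matrix)
        assert out.flagged_assays == ["sparse"]

    def test_out_of_range_ct_rejected(self):
        matrix = qpcr_long({"a1": {"s1": 60.0, "s2": 25.0}, "a2": {"s1": 25.0, "s2": 25.0}})
        with pytest.raises(ValueError, match="Ct"):
            normalize_qpcr(matrix)


class TestFitAssociation:
    @staticmethod
    def _covariates(n, rng):
        return pd.DataFrame(
            {
                "cov1": rng.normal(size=n),
                "cov2": rng.uniform(size=n),
            }
        )

    def test_noise_free_recovery_exact(self):
        rng = np.random.default_rng(0)
        n = 60
        cov = self._covariates(n, rng)
        expr = pd.Series(rng.normal(size=n))
        outcome = 0.5 * expr + 0.3 * cov["cov1"] - 0.2 * cov["cov2"] + 1.0
        res = fit_phenotype_association(
            expr, outcome, cov, outcome_name="grip_cross_sectional"
        )
        assert res.orientation == "outcome_dependent"
        assert res.beta == pytest.approx(0.5, abs=1e-10)
        assert res.p < 1e-12

    def test_expression_dependent_orientation(self):
        rng = np.random.default_rng(1)
        n = 50
        cov = self._covariates(n, rng)
        outcome = pd.Series(rng.normal(size=n))
        expr = 1.0 - 0.065 * outcome
        res = fit_phenotype_association(expr, outcome, cov, outcome_name="PLS")
        assert res.orientation == "expression_dependent"
        assert res.beta == pytest.approx(-0.065, abs=1e-10)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(7)
        n = 40
        cov = self._covariates(n, rng)
        expr = pd.Series(rng.normal(size=n))
        outcome = pd.Series(0.4 * expr + rng.normal(scale=0.7, size=n))
        res = fit_phenotype_association(
            expr, outcome, cov, outcome_name="grip_cross_sectional"
        )
        X = np.column_stack([np.ones(n), expr, cov["cov1"], cov["cov2"]])
        y = outcome.to_numpy()
        beta_hat = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta_hat
        sigma2 = resid @ resid / (n - X.shape[1])
        cov_beta = sigma2 * np.linalg.inv(X.T @ X)
        assert res.beta == pytest.approx(beta_hat[1], abs=1e-8)
        assert res.se == pytest.approx(np.sqrt(cov_beta[1, 1]), abs=1e-8)
        # CI bracket and t-based p
        t = beta_hat[1] / np.sqrt(cov_beta[1, 1])
        p = 2 * stats.t.sf(abs(t), n - X.shape[1])
        assert res.p == pytest.approx(p, abs=1e-10)
        assert res.ci_low <= res.beta <= res.ci_high

    def test_listwise_deletion(self):
        rng = np.random.default_rng(3)
        n = 50
        cov = self._covariates(n, rng)
        expr = pd.Series(rng.normal(size=n))
        outcome = pd.Series(rng.normal(size=n))
        outcome.iloc[0] = np.nan
        cov.loc[1, "cov1"] = np.nan
        res = fit_phenotype_association(expr, outcome, cov, outcome_name="PLS")
        assert res.n_used == n - 2

    def test_rank_deficient_named(self):
        rng = np.random.default_rng(4)
        n = 30
        cov = self._covariates(n, rng)
        cov["dup"] = cov["cov1"] * 2.0
        expr = pd.Series(rng.normal(size=n))
        outcome = pd.Series(rng.normal(size=n))
        with pytest.raises(ValueError, match="rank deficient"):
            fit_phenotype_association(expr, outcome, cov, outcome_name="PLS")

    def test_too_few_cases_rejected(self):
        rng = np.random.default_rng(5)
        cov = self._covariates(4, rng)
        with pytest.raises(ValueError, match="complete cases"):
            fit_phenotype_association(
                pd.Series(rng.normal(size=4)),
                pd.Series(rng.normal(size=4)),
                cov,
                outcome_name="PLS",
            )

    def test_significant_adjusted_uses_unrounded_threshold(self):
        rng = np.random.default_rng(6)
        n = 200
        cov = self._covariates(n, rng)
        outcome = pd.Series(rng.normal(size=n))
        expr = 1.0 + 0.5 * outcome + pd.Series(rng.normal(scale=0.5, size=n))
        res = fit_phenotype_association(
            expr, outcome, cov, outcome_name="PLS", alpha=0.05, n_tests=15
        )
        assert res.significant_adjusted == (res.p < 0.05 / 15)


class TestBonferroni:
    def test_fifteen_tests(self):
        assert bonferroni_threshold(0.05, 15, 3) == pytest.approx(0.003)

    def test_four_tests_rounds_half_up(self):
        # 0.0125 rounds half-up to 0.013, not banker's 0.012
        assert bonferroni_threshold(0.05, 4, 3) == pytest.approx(0.013)

    def test_single_test(self):
        assert bonferroni_threshold(0.05, 1, 3) == pytest.approx(0.05)

    def test_unrounded_default(self):
        assert bonferroni_threshold(0.05, 4) == pytest.approx(0.0125)

    def test_invalid_n_tests(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


class TestSenescence:
    @staticmethod
    def _matrix(early, late, n_assays=3, target="c0"):
        """Per-biological-replicate Ct vectors for the target assay;
        other assays constant at 25."""
        rows = []
        for assay_i in range(n_assays):
            assay = f"c{assay_i}"
            for passage, values in (("early", early), ("late", late)):
                for bio, val in enumerate(values, start=1):
                    ct = val if assay == target else 25.0
                    rows.append(
                        {
                            "assay_id": assay,
                            "cell_type": "fibroblasts",
                            "passage": passage,
                            "biological_replicate": bio,
                            "technical_replicate": 1,
                            "ct": ct,
                        }
                    )
        return pd.DataFrame(rows)

    def test_identical_groups_p_one(self):
        matrix = self._matrix([25.0, 25.0, 25.0], [25.0, 25.0, 25.0])
        results = {r.circ_id: r for r in senescence_compare(matrix, "fibroblasts")}
        assert results["c0"].p == pytest.approx(1.0)
        assert results["c0"].expressed

    def test_anova_equals_pooled_t_test(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            a = rng.normal(size=4)
            b = rng.normal(loc=rng.normal(), size=5)
            _, p_anova = associate._two_group_anova([a, b])
            p_t = stats.ttest_ind(a, b, equal_var=True).pvalue
            assert p_anova == pytest.approx(p_t, rel=1e-10)

    def test_missing_group_not_expressed(self):
        matrix = self._matrix([25.0, 25.0, 25.0], [np.nan, np.nan, np.nan])
        results = {r.circ_id: r for r in senescence_compare(matrix, "fibroblasts")}
        assert not results["c0"].expressed
        assert np.isnan(results["c0"].p)

    def test_median_iqr_ordering(self):
        rng = np.random.default_rng(9)
        matrix = self._matrix(
            list(rng.uniform(24, 26, 3)), list(rng.uniform(23, 25, 3))
        )
        for r in senescence_compare(matrix, "fibroblasts"):
            if r.expressed:
                assert r.iqr_early[0] <= r.median_early <= r.iqr_early[1]
                assert r.iqr_late[0] <= r.median_late <= r.iqr_late[1]

    def test_planted_shift_detected(self):
        assays = [f"c{i}" for i in range(5)]
        shifts = {(a, "fibroblasts"): 0.0 for a in assays}
        shifts[("c0", "fibroblasts")] = -1.0
        hits = 0
        for seed in range(100):
            matrix, _ = synthetic.simulate_senescence_qpcr(shifts, seed=seed)
            results = {r.circ_id: r for r in senescence_compare(matrix, "fibroblasts")}
            hits += results["c0"].p < 0.05
        assert hits > 90


class TestCountDysregulated:
    def test_reference_table(self):
        ref = load_senescence_reference()
        n_dys, n_expr, pct = count_dysregulated(ref, alpha=0.05)
        assert (n_dys, n_expr, pct) == (7, 12, 58)

    def test_all_p_one(self):
        frame = pd.DataFrame(
            {
                "circ_id": ["a", "b"],
                "cell_type": ["x", "x"],
                "p": [1.0, 1.0],
                "expressed": [True, True],
            }
        )
        assert count_dysregulated(frame)[0] == 0

    def test_distinct_count_semantics(self):
        frame = pd.DataFrame(
            {
                "circ_id": ["a", "a", "b"],
                "cell_type": ["x", "y", "x"],
                "p": [0.01, 0.02, 0.9],
                "expressed": [True, True, True],
            }
        )
        n_dys, n_expr, pct = count_dysregulated(frame)
        assert (n_dys, n_expr) == (1, 2)
        assert pct == 50

    def test_order_and_duplicate_invariance(self):
        ref = load_senescence_reference()
        shuffled = ref.sample(frac=1.0, random_state=0)
        doubled = pd.concat([ref, ref], ignore_index=True)
        assert count_dysregulated(shuffled) == count_dysregulated(ref)
        assert count_dysregulated(doubled) == count_dysregulated(ref)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            count_dysregulated(pd.DataFrame())


class TestMouse:
    @staticmethod
    def _slopes(young_spleen=0.01):
        slopes = {}
        for circ in ("circA", "circB"):
            slopes[(circ, "spleen", "young")] = young_spleen if circ == "circA" else 0.0
            slopes[(circ, "spleen", "old")] = 0.0
        slopes[("circA", "muscle", "young")] = 0.0
        slopes[("circA", "muscle", "old")] = 0.0
        return slopes

    def test_nd_propagation(self):
        panel, _ = synthetic.simulate_mouse_panel(planted_slopes=self._slopes(), seed=0)
        results = {r.circ_id: r for r in mouse_lifespan_association(panel, "muscle")}
        assert results["circB"].detected is False
        assert np.isnan(results["circB"].beta)
        assert results["circA"].detected is True

    def test_too_few_strains_rejected(self):
        panel, _ = synthetic.simulate_mouse_panel(
            strain_lifespans={"s1": 20.0, "s2": 30.0},
            planted_slopes=self._slopes(),
            seed=0,
        )
        with pytest.raises(ValueError, match="strains"):
            mouse_lifespan_association(panel, "spleen")

    def test_unknown_stratum_rejected(self):
        panel, _ = synthetic.simulate_mouse_panel(planted_slopes=self._slopes(), seed=0)
        with pytest.raises(ValueError, match="stratum"):
            mouse_lifespan_association(panel, "spleen", stratum="middle")

    def test_significance_flag(self):
        panel, _ = synthetic.simulate_mouse_panel(planted_slopes=self._slopes(), seed=1)
        for r in mouse_lifespan_association(panel, "spleen", n_tests=4):
            if r.detected:
                assert r.significant_adjusted == (r.p < 0.05 / 4)
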