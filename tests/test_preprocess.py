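import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from genopred import preprocess, synthio
from genopred.exceptions import (
    EmptyPanelError,
    InvalidParameterError,
    RankDeficientDesignError,
)
from genopred.preprocess import QCThresholds, hwe_pvalue

from conftest import make_matrix


class TestHwePvalue:
    def test_perfect_hwe(self):
        assert hwe_pvalue(25, 50, 25) == pytest.approx(1.0)

    def test_monomorphic_convention(self):
        assert hwe_pvalue(100, 0, 0) == 1.0
        assert hwe_pvalue(0, 0, 77) == 1.0

    def test_derived_chi_square_example(self):
        # counts (30,40,30): expected (25,50,25), chi2 = 1 + 2 + 1 = 4
        expected_p = stats.chi2.sf(4.0, df=1)  # ~0.0455
        assert hwe_pvalue(30, 40, 30) == pytest.approx(expected_p, rel=1e-12)
        assert hwe_pvalue(30, 40, 30) == pytest.approx(0.04550026, abs=1e-8)

    def test_extreme_departure(self):
        # (50, 0, 50): chi2 = 100 on expected (25,50,25)
        p = hwe_pvalue(50, 0, 50)
        assert p == pytest.approx(stats.chi2.sf(100.0, 1), rel=1e-9)
        assert p < 1e-5

    def test_negative_counts(self):
        with pytest.raises(InvalidParameterError):
            hwe_pvalue(-1, 2, 3)
        with pytest.raises(InvalidParameterError):
            hwe_pvalue(0, 0, 0)

    @given(
        st.integers(min_value=0, max_value=500),
        st.integers(min_value=0, max_value=500),
        st.integers(min_value=0, max_value=500),
    )
    @settings(max_examples=200, deadline=None)
    def test_pvalue_in_unit_interval(self, a, b, c):
        if a + b + c == 0:
            return
        p = hwe_pvalue(a, b, c)
        assert 0.0 <= p <= 1.0


class TestFilterMarkers:
    def test_perfect_marker_kept(self):
        vals = np.concatenate([np.ones(25), np.zeros(50), -np.ones(25)])[:, None]
        g = make_matrix(vals)
        kept, report = preprocess.filter_markers(g)
        assert kept.n_markers == 1
        row = report.iloc[0]
        assert row["call_rate"] == 1.0 and row["maf"] == 0.5 and row["hwe_p"] == 1.0

    def test_hwe_failure_removed(self):
        bad = np.concatenate([np.ones(50), -np.ones(50)])
        good = np.concatenate([np.ones(25), np.zeros(50), -np.ones(25)])
        g = make_matrix(np.column_stack([bad, good]))
        kept, report = preprocess.filter_markers(g)
        assert kept.marker_ids.tolist() == ["m1"]
        assert report.loc[0, "fail_reason"] == "hwe"
        assert report.loc[0, "hwe_p"] < 1e-5

    def test_maf_boundary_strict(self):
        # MAF exactly 0.05 -> removed under strict "higher than"
        col = np.concatenate([-np.ones(1), np.zeros(8), np.ones(91)])  # maf = 10/200 = 0.05
        good = np.concatenate([np.ones(25), np.zeros(50), -np.ones(25)])
        g = make_matrix(np.column_stack([col, good]))
        kept, report = preprocess.filter_markers(g)
        assert report.loc[0, "maf"] == pytest.approx(0.05)
        assert not report.loc[0, "keep"]
        assert report.loc[0, "fail_reason"] == "maf"

    def test_call_rate_strict(self):
        col = np.concatenate([np.full(5, np.nan), np.ones(47), np.zeros(40), -np.ones(8)])
        g = make_matrix(col[:, None])
        report = preprocess.marker_qc_table(g, QCThresholds())
        assert report.loc[0, "call_rate"] == pytest.approx(0.95)
        assert not report.loc[0, "keep"]  # 0.95 is not > 0.95

    def test_all_removed_raises(self):
        g = make_matrix(np.ones((10, 2)))  # monomorphic, maf=0
        with pytest.raises(EmptyPanelError):
            preprocess.filter_markers(g)

    def test_report_covers_all_markers(self):
        g = synthio.simulate_genotypes(100, 50, maf_range=(0.02, 0.5), missing_rate=0.02, seed=5)
        kept, report = preprocess.filter_markers(g)
        assert len(report) == 50
        assert report["keep"].sum() == kept.n_markers
        assert report["keep"].sum() + (~report["keep"]).sum() == 50


class TestFilterSamples:
    def test_boundary_strict(self):
        vals = np.zeros((3, 100))
        vals[0, :11] = np.nan  # 0.11 > 0.10 -> removed
        vals[1, :10] = np.nan  # 0.10 not > 0.10 -> kept
        g = make_matrix(vals)
        out = preprocess.filter_samples(g)
        assert out.individual_ids.tolist() == ["i1", "i2"]

    def test_identity_on_complete(self):
        g = make_matrix(np.zeros((4, 10)))
        out = preprocess.filter_samples(g)
        np.testing.assert_array_equal(out.values, g.values)

    def test_all_removed(self):
        vals = np.full((3, 10), np.nan)
        vals[:, 0] = 1
        with pytest.raises(EmptyPanelError):
            preprocess.filter_samples(make_matrix(vals))


class TestImputeMissing:
    def test_mean_imputation(self):
        g = make_matrix(np.array([[1.0], [-1.0], [np.nan]]))
        out = preprocess.impute_missing(g)
        assert out.values[2, 0] == pytest.approx(0.0)
        assert out.fractional

    def test_constant_marker(self):
        g = make_matrix(np.array([[1.0], [1.0], [1.0], [np.nan]]))
        out = preprocess.impute_missing(g)
        assert out.values[3, 0] == pytest.approx(1.0)

    def test_complete_unchanged(self):
        g = make_matrix(np.array([[1.0, 0.0], [-1.0, 1.0]]))
        out = preprocess.impute_missing(g)
        np.testing.assert_array_equal(out.values, g.values)

    def test_fully_missing_marker_raises(self):
        g = make_matrix(np.array([[np.nan, 1.0], [np.nan, 0.0]]))
        with pytest.raises(InvalidParameterError, match="filter_markers"):
            preprocess.impute_missing(g)

    def test_non_missing_untouched(self):
        g = synthio.simulate_genotypes(50, 30, missing_rate=0.2, seed=9)
        out = preprocess.impute_missing(g)
        obs = ~np.isnan(g.values)
        np.testing.assert_array_equal(out.values[obs], g.values[obs])


class TestPipelineProperties:
    def test_rerun_is_noop(self):
        g = synthio.simulate_genotypes(200, 100, maf_range=(0.02, 0.5), missing_rate=0.05, seed=3)
        once, _ = preprocess.run_qc(g)
        twice_markers, _ = preprocess.filter_markers(once)
        twice = preprocess.impute_missing(preprocess.filter_samples(twice_markers))
        np.testing.assert_array_equal(once.values, twice.values)


class TestAdjustPhenotype:
    def test_constant_response(self):
        rng = np.random.default_rng(0)
        pheno = pd.DataFrame(
            {
                "id": [f"i{k}" for k in range(12)],
                "y": [5.0] * 12,
                "sex": ["M", "F"] * 6,
                "birth_year": [2008, 2008, 2009, 2009] * 3,
                "fatten_days": rng.normal(size=12),
                "init_weight": rng.normal(size=12),
            }
        )
        adj = preprocess.adjust_phenotype(pheno)
        np.testing.assert_allclose(adj.y_star, 0.0, atol=1e-10)

    def test_exact_group_means(self):
        pheno = pd.DataFrame(
            {
                "id": list("abcd"),
                "y": [10.0, 10.0, 12.0, 12.0],
                "sex": ["A", "A", "B", "B"],
            }
        )
        adj = preprocess.adjust_phenotype(pheno, factors=["sex"], covariates=[])
        np.testing.assert_allclose(adj.y_star, 0.0, atol=1e-10)
        assert adj.coefficients["sex_B"] == pytest.approx(2.0)

    def test_recovers_genetic_plus_noise(self, polygenic_study):
        # y* must equal the projection of (g + e) onto the design's orthogonal
        # complement: subtracting the known Xbeta and residualizing on the same
        # design reproduces it exactly
        adj = preprocess.adjust_phenotype(polygenic_study.phenotypes)
        target = polygenic_study.true_breeding_values + polygenic_study.noise
        X, _ = preprocess._design_matrix(
            polygenic_study.phenotypes, ["sex", "birth_year"], ["fatten_days", "init_weight"]
        )
        oracle = target - X @ np.linalg.lstsq(X, target, rcond=None)[0]
        np.testing.assert_allclose(adj.y_star, oracle, atol=1e-8)
        assert np.corrcoef(adj.y_star, target - target.mean())[0, 1] > 0.97

    def test_zero_mean_and_orthogonality(self, polygenic_study):
        adj = preprocess.adjust_phenotype(polygenic_study.phenotypes)
        assert abs(adj.y_star.mean()) < 1e-8
        pheno = polygenic_study.phenotypes
        X, _ = preprocess._design_matrix(
            pheno, ["sex", "birth_year"], ["fatten_days", "init_weight"]
        )
        Xs = X / np.linalg.norm(X, axis=0, keepdims=True)
        assert np.abs(Xs.T @ adj.y_star).max() < 1e-8

    def test_rank_deficient_names_columns(self):
        pheno = pd.DataFrame(
            {
                "id": list("abcd"),
                "y": [1.0, 2.0, 3.0, 4.0],
                "sex": ["M", "M", "F", "F"],
                "dup": [1.0, 1.0, 0.0, 0.0],  # collinear with sex dummy
            }
        )
        with pytest.raises(RankDeficientDesignError) as err:
            preprocess.adjust_phenotype(pheno, factors=["sex"], covariates=["dup"])
        assert err.value.columns

    def test_missing_column(self):
        pheno = pd.DataFrame({"id": ["a"], "y": [1.0]})
        with pytest.raises(InvalidParameterError, match="lacks columns"):
            preprocess.adjust_phenotype(pheno)


def test_thresholds_domain():
    with pytest.raises(InvalidParameterError):
        QCThresholds(min_maf=1.5)
    with pytest.raises(InvalidParameterError):
        QCThresholds(max_sample_missing=-0.1)
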