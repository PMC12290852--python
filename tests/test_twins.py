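"""ACE twin model: likelihood, fitting, Falconer check, generator."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal, pearsonr

from neurofei.twins import (
    ACEModel,
    TwinSample,
    ace_loglikelihood,
    falconer_h2,
    simulate_twins,
)


def brute_force_loglike(a, c, e, sample, beta):
    """Independent oracle: per-pair bivariate normal densities, summed."""
    a2, c2, e2 = a * a, c * c, e * e
    v = a2 + c2 + e2
    x1 = np.column_stack(
        [np.ones(sample.n_pairs)]
        + ([sample.age1] if sample.age1 is not None else [])
        + ([sample.sex1] if sample.sex1 is not None else [])
    )
    x2 = np.column_stack(
        [np.ones(sample.n_pairs)]
        + ([sample.age2] if sample.age2 is not None else [])
        + ([sample.sex2] if sample.sex2 is not None else [])
    )
    total = 0.0
    for i in range(sample.n_pairs):
        r_a = 1.0 if sample.mz[i] else 0.5
        cov = np.array([[v, r_a * a2 + c2], [r_a * a2 + c2, v]])
        mean = np.array([x1[i] @ beta, x2[i] @ beta])
        total += multivariate_normal.logpdf(
            [sample.y1[i], sample.y2[i]], mean=mean, cov=cov
        )
    return total


class TestLikelihood:
    def test_matches_brute_force_oracle(self):
        sample = simulate_twins(
            0.5, 0.2, 0.3, n_mz=10, n_dz=10,
            covariate_effects={"age": 0.05, "sex": -0.3}, seed=0,
        )
        beta = np.array([0.1, 0.04, -0.2])
        got = ace_loglikelihood(0.7, 0.45, 0.55, sample, beta)
        want = brute_force_loglike(0.7, 0.45, 0.55, sample, beta)
        assert got == pytest.approx(want, abs=1e-10)

    def test_no_a_no_c_means_zero_cross_twin_covariance(self):
        # with a = c = 0 the implied pair covariance is diagonal, so the
        # likelihood equals the product of univariate normals
        sample = simulate_twins(0.0, 0.0, 1.0, 15, 15, seed=1)
        beta = np.zeros(3)
        got = ace_loglikelihood(0.0, 0.0, 1.0, sample, beta)
        from scipy.stats import norm

        want = norm.logpdf(sample.y1).sum() + norm.logpdf(sample.y2).sum()
        assert got == pytest.approx(want, abs=1e-10)

    def test_singular_covariance_gives_minus_inf(self):
        sample = simulate_twins(0.4, 0.2, 0.4, 5, 5, seed=2)
        assert ace_loglikelihood(0.0, 0.0, 0.0, sample) == -np.inf

    def test_c_zero_implies_mz_covariance_twice_dz(self):
        a2, e2 = 0.6, 0.4
        cov_mz = 1.0 * a2
        cov_dz = 0.5 * a2
        assert cov_mz == pytest.approx(2 * cov_dz)


class TestSimulateTwins:
    def test_pure_genetic_mz_pairs_identical(self):
        s = simulate_twins(1.0, 0.0, 0.0, n_mz=50, n_dz=0, seed=3)
        np.testing.assert_allclose(s.y1, s.y2, atol=1e-12)

    def test_pure_unique_environment_uncorrelated(self):
        s = simulate_twins(0.0, 0.0, 1.0, n_mz=5000, n_dz=5000, seed=4)
        r_mz = pearsonr(s.y1[s.mz], s.y2[s.mz]).statistic
        r_dz = pearsonr(s.y1[~s.mz], s.y2[~s.mz]).statistic
        assert abs(r_mz) < 0.05 and abs(r_dz) < 0.05

    def test_empirical_correlations_match_path_model(self):
        a2, c2, e2 = 0.5, 0.2, 0.3
        s = simulate_twins(a2, c2, e2, n_mz=10_000, n_dz=10_000, seed=5)
        r_mz = pearsonr(s.y1[s.mz], s.y2[s.mz]).statistic
        r_dz = pearsonr(s.y1[~s.mz], s.y2[~s.mz]).statistic
        assert r_mz == pytest.approx(a2 + c2, abs=0.02)
        assert r_dz == pytest.approx(0.5 * a2 + c2, abs=0.02)

    def test_incomplete_pairs_are_dropped(self):
        y1 = np.array([1.0, np.nan, 3.0])
        y2 = np.array([1.5, 2.0, np.nan])
        s = TwinSample(y1=y1, y2=y2, mz=np.array([True, False, True]))
        assert s.n_pairs == 1


class TestFalconer:
    def test_printed_twin_correlations_give_expected_estimate(self):
        # construct samples with target correlations via the path model
        rng = np.random.default_rng(6)
        n = 120_000
        z = rng.standard_normal((4, n))
        r_mz, r_dz = 0.68, 0.32
        y1_mz = z[0]
        y2_mz = r_mz * z[0] + np.sqrt(1 - r_mz**2) * z[1]
        y1_dz = z[2]
        y2_dz = r_dz * z[2] + np.sqrt(1 - r_dz**2) * z[3]
        s = TwinSample(
            y1=np.concatenate([y1_mz, y1_dz]),
            y2=np.concatenate([y2_mz, y2_dz]),
            mz=np.repeat([True, False], n),
        )
        assert falconer_h2(s) == pytest.approx(2 * (0.68 - 0.32), abs=0.02)

    def test_equal_correlations_give_zero(self):
        s = simulate_twins(0.0, 0.5, 0.5, 2000, 2000, seed=7)
        assert falconer_h2(s) == pytest.approx(0.0, abs=0.06)

    def test_simulated_components_recovered(self):
        s = simulate_twins(0.4, 0.2, 0.4, 20_000, 20_000, seed=8)
        assert falconer_h2(s) == pytest.approx(0.4, abs=0.03)


@pytest.fixture(scope="module")
def recovery_fit():
    sample = simulate_twins(
        0.6, 0.1, 0.3, n_mz=500, n_dz=500,
        covariate_effects={"age": 0.02, "sex": 0.1}, seed=9,
    )
    return sample, ACEModel(sample).fit()


class TestACEFit:
    def test_heritability_recovered_within_tolerance(self, recovery_fit):
        _, res = recovery_fit
        assert res.heritability_full == pytest.approx(0.6 / 1.0, abs=0.08)

    def test_proportions_sum_to_one(self, recovery_fit):
        _, res = recovery_fit
        assert sum(res.proportions.values()) == pytest.approx(1.0, abs=1e-12)
        assert 0.0 <= res.heritability <= 1.0
        assert res.e2 > 0

    def test_total_variance_near_generating_value(self, recovery_fit):
        _, res = recovery_fit
        assert res.total_variance == pytest.approx(1.0, rel=0.15)

    def test_a_drop_lrt_significant_when_a_large(self, recovery_fit):
        _, res = recovery_fit
        assert res.lrt_a_p < 0.001

    def test_summary_mentions_components(self, recovery_fit):
        _, res = recovery_fit
        text = res.summary()
        for token in ("A (a^2)", "C (c^2)", "E (e^2)", "heritability"):
            assert token in text

    def test_scale_equivariance(self):
        sample = simulate_twins(0.5, 0.2, 0.3, 300, 300, seed=10)
        res1 = ACEModel(sample).fit()
        scaled = TwinSample(
            y1=10 * sample.y1, y2=10 * sample.y2, mz=sample.mz,
            age1=sample.age1, age2=sample.age2,
            sex1=sample.sex1, sex2=sample.sex2,
        )
        res2 = ACEModel(scaled).fit()
        assert res2.heritability == pytest.approx(res1.heritability, abs=0.02)
        assert res2.total_variance == pytest.approx(100 * res1.total_variance, rel=0.02)

    def test_no_genetic_signal_detected_as_such(self):
        sample = simulate_twins(0.0, 0.5, 0.5, 400, 400, seed=11)
        res = ACEModel(sample).fit()
        assert res.proportions["a2"] < 0.12
        assert res.lrt_a_p > 0.01

    def test_small_sample_warns(self):
        sample = simulate_twins(0.4, 0.2, 0.4, 10, 10, seed=12)
        with pytest.warns(UserWarning, match="pairs per zygosity"):
            ACEModel(sample)

    def test_from_dataframe_round_trip(self):
        import pandas as pd

        sample = simulate_twins(0.5, 0.1, 0.4, 60, 60, seed=13)
        rows = []
        for i in range(sample.n_pairs):
            for twin, (y, age, sex) in enumerate(
                [(sample.y1[i], sample.age1[i], sample.sex1[i]),
                 (sample.y2[i], sample.age2[i], sample.sex2[i])],
                start=1,
            ):
                rows.append(
                    dict(pair_id=i, zygosity="MZ" if sample.mz[i] else "DZ",
                         twin=twin, age=age, sex=sex, phenotype=y)
                )
        df = pd.DataFrame(rows)
        model = ACEModel.from_dataframe(df)
        assert model.sample.n_pairs == sample.n_pairs
        assert model.sample.n_mz == sample.n_mz
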