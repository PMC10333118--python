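"""Placebo permutation inference, bootstrap group test, ANOSIM balance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from tigersynth.inference import (
    anosim,
    balance_report,
    bootstrap_group_test,
    minimum_donors_for_alpha,
    mspe_ratio,
    placebo_distribution,
    rank_p_value,
)
from tigersynth.simulate import SimConfig, simulate_study
from tigersynth.synth import SynthConfig, SyntheticFit


def stub_fit(mspe_pre: float, mspe_post: float, pre_var: float = 1.0) -> SyntheticFit:
    from tigersynth.synth import SyntheticWeights

    years = np.arange(2001, 2007)
    return SyntheticFit(
        treated_id="X", donor_ids=["A", "B"], intervention_year=2004,
        years=years, observed=np.zeros(6), counterfactual=np.zeros(6),
        weights=SyntheticWeights(np.array([1.0]), np.array([0.5, 0.5])),
        predictor_names=["p"], mspe_pre=mspe_pre, mspe_post=mspe_post,
        pre_variance=pre_var,
    )


class TestMspeRatio:
    def test_identity(self):
        assert mspe_ratio(stub_fit(4.0, 4.0)) == pytest.approx(1.0)

    def test_degenerate_denominator_uses_documented_floor(self):
        ratio = mspe_ratio(stub_fit(0.0, 2.0, pre_var=1.0))
        assert ratio == pytest.approx(2.0 / 1e-8)

    def test_hand_computed_series(self):
        # pre gaps (1, 2, 3): mspe_pre = 14/3; post gaps (3, 4, 5): 50/3
        obs = np.array([1, 2, 3, 7, 8, 9], float)
        cf = np.array([2, 4, 6, 10, 12, 14], float)
        fit = stub_fit(0, 0)
        fit.observed, fit.counterfactual = obs, cf
        fit.mspe_pre = float(np.mean((obs[:3] - cf[:3]) ** 2))
        fit.mspe_post = float(np.mean((obs[3:] - cf[3:]) ** 2))
        assert mspe_ratio(fit) == pytest.approx((50 / 3) / (14 / 3))


class TestRankPValue:
    def test_largest_ratio_hits_floor(self):
        placebos = np.arange(20, dtype=float)
        assert rank_p_value(100.0, placebos) == pytest.approx(1 / 21)

    def test_smallest_ratio_gives_one(self):
        placebos = np.arange(1, 21, dtype=float)
        assert rank_p_value(0.5, placebos) == pytest.approx(1.0)

    def test_ties_take_worst_rank(self):
        placebos = np.array([5.0, 5.0, 1.0])
        # treated ties both 5s: rank = 3 of 4
        assert rank_p_value(5.0, placebos) == pytest.approx(3 / 4)


class TestMinimumDonors:
    def test_conventional_alpha_needs_more_than_twenty(self):
        assert minimum_donors_for_alpha(0.05) == 20

    def test_half_alpha(self):
        assert minimum_donors_for_alpha(0.5) == 2

    @given(st.floats(min_value=0.003, max_value=0.9))
    def test_matches_brute_force(self, alpha):
        n = minimum_donors_for_alpha(alpha)
        assert 1 / (n + 1) < alpha
        assert n == 1 or 1 / n >= alpha


@pytest.fixture(scope="module")
def null_ensemble():
    study, _ = simulate_study(SimConfig(n_groups=1, donors_per_group=21,
                                        treated_per_group=1, effect_rho=0.0,
                                        seed=17))
    rid = study.treated_ids[0]
    return placebo_distribution(study, rid, config=SynthConfig(outer_maxiter=80))


class TestPlaceboDistribution:
    def test_counts_and_floor(self, null_ensemble):
        ens = null_ensemble
        assert ens.n_placebos == 21
        assert ens.p_floor == pytest.approx(1 / 22)
        assert 1 / 22 <= ens.p_value <= 1.0
        assert not ens.cannot_reach_alpha
        # p equals the descending rank of the treated ratio
        ratios = np.array([r for u, r in ens.unit_ratios.items()
                           if u != ens.treated_id])
        assert ens.p_value == pytest.approx(rank_p_value(ens.treated_ratio, ratios))

    def test_donor_order_does_not_change_p(self):
        study, _ = simulate_study(SimConfig(n_groups=1, donors_per_group=21,
                                            treated_per_group=1, seed=23))
        rid = study.treated_ids[0]
        donors = study.group_donors(rid)
        cfg = SynthConfig(outer_maxiter=40)
        p1 = placebo_distribution(study, rid, donor_ids=donors, config=cfg).p_value
        p2 = placebo_distribution(study, rid, donor_ids=donors[::-1], config=cfg).p_value
        assert p1 == p2

    def test_small_pool_flags_cannot_reach_alpha(self, toy_study):
        cfg = SynthConfig(allow_small_donor_pool=True, outer_maxiter=20)
        with pytest.warns(UserWarning, match="cannot reach"):
            ens = placebo_distribution(toy_study, "R00", config=cfg)
        assert ens.cannot_reach_alpha
        assert ens.n_placebos == 4


class TestBootstrapGroupTest:
    def test_identical_groups_not_rejected(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        p = bootstrap_group_test(a, a.copy(), iterations=999, seed=0)
        assert p >= 0.9

    def test_extreme_separation(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.0, 1.0, 15)
        b = rng.normal(10.0, 1.0, 15)  # ten pooled SDs apart
        p = bootstrap_group_test(a, b, iterations=9999, seed=2)
        assert p <= 0.001

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=10), rng.normal(size=12)
        assert bootstrap_group_test(a, b, seed=7) == bootstrap_group_test(a, b, seed=7)

    def test_type_i_error_calibration(self):
        rng = np.random.default_rng(99)
        hits = 0
        n_rep = 500
        for i in range(n_rep):
            a = rng.normal(size=15)
            b = rng.normal(size=15)
            if bootstrap_group_test(a, b, iterations=499, seed=i) <= 0.05:
                hits += 1
        rate = hits / n_rep
        # binomial 99% envelope around 0.05 at n=500
        assert 0.025 <= rate <= 0.08


class TestAnosim:
    def test_homogeneous_data_near_zero(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 4))
        labels = np.array(["a"] * 15 + ["b"] * 15)
        R, p = anosim(X, labels, permutations=499, seed=0)
        assert abs(R) < 0.2
        assert p > 0.05

    def test_separated_clusters(self):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(0, 1, (12, 3)), rng.normal(10, 1, (12, 3))])
        labels = np.array(["a"] * 12 + ["b"] * 12)
        R, p = anosim(X, labels, permutations=999, seed=0)
        assert R > 0.99
        assert p == pytest.approx(1 / 1000)

    def test_matches_scikit_bio(self):
        """Dual-route check of the ANOSIM statistic against an
        independent implementation."""
        from scipy.spatial.distance import pdist, squareform
        from skbio import DistanceMatrix
        from skbio.stats import distance as skbio_stats

        rng = np.random.default_rng(6)
        X = np.vstack([rng.normal(0, 1, (10, 3)), rng.normal(1.5, 1, (10, 3))])
        labels = ["a"] * 10 + ["b"] * 10
        R, _ = anosim(X, np.array(labels), permutations=99, seed=0)
        dm = DistanceMatrix(squareform(pdist(X)), ids=[str(i) for i in range(20)])
        ref = skbio_stats.anosim(dm, grouping=labels, permutations=99)
        assert R == pytest.approx(ref["test statistic"], abs=1e-12)


class TestBalanceReport:
    def test_duplicated_covariate_flagged(self):
        study_cov = pd.DataFrame({
            "reserve_id": [f"R{i}" for i in range(10)],
        })
        rng = np.random.default_rng(7)
        from tigersynth.panel import NUMERIC_COVARIATES
        for c in NUMERIC_COVARIATES:
            study_cov[c] = rng.normal(10, 2, 10)
        study_cov["road_length"] = study_cov["pop_density"]  # perfect collinearity
        study_cov["group"] = "G"
        rep = balance_report(study_cov, [f"R{i}" for i in range(5)],
                             [f"R{i}" for i in range(5, 10)],
                             permutations=99, seed=0)
        assert ("pop_density", "road_length", 1.0) in [
            (a, b, round(r, 6)) for a, b, r in rep.flagged_pairs
        ]
        assert np.allclose(np.diag(rep.pearson_matrix.to_numpy()), 1.0)
        arr = rep.pearson_matrix.to_numpy()
        assert np.allclose(arr, arr.T)
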