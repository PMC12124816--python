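import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from twinmap.benefit import (
    kl_permutation_test,
    km_estimate,
    logrank_test,
    estimate_pdf,
    select_treatment_neighbors,
    survival_at,
    symmetric_kl,
)
from twinmap.exceptions import (
    ConfigError,
    DegenerateSampleError,
    EmptyInputError,
    InsufficientArmError,
)


# -------------------------------------------------------- neighbor picking

class TestTreatmentNeighbors:
    def _coords(self, n, seed=0):
        return np.random.default_rng(seed).normal(size=(n, 3))

    def test_fifteen_per_arm(self):
        coords = self._coords(40)
        chemo = np.array([True] * 20 + [False] * 20)
        hood = select_treatment_neighbors(np.zeros(3), coords, chemo, k=15)
        assert len(hood.chemo_indices) == 15
        assert len(hood.nochemo_indices) == 15
        assert not set(hood.chemo_indices) & set(hood.nochemo_indices)

    def test_matches_bruteforce_sorted_distances(self):
        coords = self._coords(10, seed=3)
        chemo = np.array([True] * 5 + [False] * 5)
        q = np.array([0.1, -0.2, 0.3])
        hood = select_treatment_neighbors(q, coords, chemo, k=3)
        # exhaustive oracle per arm
        for arm_idx, mask in ((hood.chemo_indices, chemo), (hood.nochemo_indices, ~chemo)):
            cand = [(np.linalg.norm(coords[i] - q), i) for i in np.flatnonzero(mask)]
            expected = [i for _, i in sorted(cand)[:3]]
            assert list(arm_idx) == expected

    def test_insufficient_arm_error_names_arm(self):
        coords = self._coords(25)
        chemo = np.array([True] * 10 + [False] * 15)
        with pytest.raises(InsufficientArmError, match="chemotherapy"):
            select_treatment_neighbors(np.zeros(3), coords, chemo, k=15)
        try:
            select_treatment_neighbors(np.zeros(3), coords, chemo, k=15)
        except InsufficientArmError as e:
            assert e.arm == "chemotherapy" and e.available == 10


# -------------------------------------------------------- Kaplan-Meier

class TestKaplanMeier:
    def test_hand_product_limit_all_deaths(self):
        curve = km_estimate([6.0, 12.0, 18.0], [True, True, True])
        assert survival_at(curve, 6) == pytest.approx(2 / 3)
        assert survival_at(curve, 12) == pytest.approx(1 / 3)
        assert survival_at(curve, 18) == pytest.approx(0.0)
        assert survival_at(curve, 0) == 1.0

    def test_hand_product_limit_with_censoring(self):
        # death at 5 (risk 4) -> 3/4; censor at 8; death at 10 (risk 2) -> 3/8
        curve = km_estimate([5, 8, 10, 12], [True, False, True, False])
        assert survival_at(curve, 5) == pytest.approx(0.75)
        assert survival_at(curve, 10) == pytest.approx(0.375)

    def test_no_events_flat_at_one(self):
        curve = km_estimate([3, 9, 27], [False, False, False])
        assert (curve.survival_probabilities == 1.0).all()

    @given(
        times=st.lists(st.floats(0.5, 100), min_size=1, max_size=20),
    )
    @settings(deadline=None, max_examples=40)
    def test_uncensored_curve_equals_empirical_survivor_fraction(self, times):
        t = np.round(np.asarray(times), 2)
        curve = km_estimate(t, np.ones_like(t, dtype=bool))
        for u in t:
            assert survival_at(curve, u) == pytest.approx((t > u).mean(), abs=1e-9)

    def test_order_invariance(self):
        t = np.array([4.0, 1.0, 9.0, 2.0, 9.0])
        e = np.array([True, False, True, True, False])
        perm = [2, 0, 4, 1, 3]
        a = km_estimate(t, e)
        b = km_estimate(t[perm], e[perm])
        np.testing.assert_allclose(a.survival_probabilities, b.survival_probabilities)

    def test_monotone_from_one(self):
        curve = km_estimate([1, 2, 3, 4], [True, False, True, True])
        s = curve.survival_probabilities
        assert s[0] == 1.0
        assert (np.diff(s) <= 1e-12).all()

    def test_empty_input_rejected(self):
        with pytest.raises(EmptyInputError):
            km_estimate([], [])


# -------------------------------------------------------- log-rank

def _logrank_oracle(ta, ea, tb, eb):
    """Hand observed-minus-expected computation of the log-rank chi-square."""
    ta, tb = np.asarray(ta, float), np.asarray(tb, float)
    ea, eb = np.asarray(ea, bool), np.asarray(eb, bool)
    times = np.unique(np.concatenate([ta[ea], tb[eb]]))
    O_E = 0.0
    V = 0.0
    for t in times:
        na = (ta >= t).sum()
        nb = (tb >= t).sum()
        da = ((ta == t) & ea).sum()
        db = ((tb == t) & eb).sum()
        n, d = na + nb, da + db
        if n < 2:
            continue
        O_E += da - d * na / n
        V += d * (na / n) * (nb / n) * (n - d) / (n - 1)
    return O_E**2 / V


class TestLogRank:
    def test_identical_groups_statistic_zero_p_one(self):
        t = [3.0, 6.0, 9.0]
        e = [True, False, True]
        stat, p = logrank_test(t, e, t, e)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_observed_minus_expected(self):
        ta, ea = [1, 3, 5, 7, 20, 22], [1, 1, 1, 1, 0, 1]
        tb, eb = [2, 10, 14, 18, 25, 30], [1, 0, 1, 1, 1, 0]
        stat, _ = logrank_test(ta, ea, tb, eb)
        assert stat == pytest.approx(_logrank_oracle(ta, ea, tb, eb), rel=1e-6)

    def test_label_swap_invariance(self):
        ta, ea = [1.0, 4.0, 6.0], [True, True, False]
        tb, eb = [2.0, 3.0, 8.0], [False, True, True]
        s1, p1 = logrank_test(ta, ea, tb, eb)
        s2, p2 = logrank_test(tb, eb, ta, ea)
        assert s1 == pytest.approx(s2)
        assert p1 == pytest.approx(p2)

    def test_empty_group_rejected(self):
        with pytest.raises(EmptyInputError):
            logrank_test([], [], [1.0], [True])


# -------------------------------------------------------- density / KL

class TestDensity:
    def test_floor_applies_everywhere(self):
        pts = np.random.default_rng(0).normal(size=(30, 3))
        pdf = estimate_pdf(pts)
        far = np.full((4, 3), 1e4)
        assert (pdf(far) >= 1e-12).all()

    def test_integrates_to_one_on_grid(self):
        pts = np.random.default_rng(1).normal(size=(200, 3))
        pdf = estimate_pdf(pts)
        g = np.linspace(-6, 6, 41)
        xx, yy, zz = np.meshgrid(g, g, g, indexing="ij")
        vals = pdf(np.c_[xx.ravel(), yy.ravel(), zz.ravel()])
        integral = vals.sum() * (g[1] - g[0]) ** 3
        assert integral == pytest.approx(1.0, abs=0.05)

    def test_density_higher_at_centroid_than_far_away(self):
        pts = np.random.default_rng(2).normal(0, 0.5, size=(50, 3))
        pdf = estimate_pdf(pts)
        center = pts.mean(axis=0, keepdims=True)
        assert pdf(center)[0] > pdf(center + 10.0)[0]

    def test_degenerate_sample_rejected(self):
        with pytest.raises(DegenerateSampleError):
            estimate_pdf(np.zeros((1, 3)))
        with pytest.raises(DegenerateSampleError):
            estimate_pdf(np.zeros((10, 3)))  # singular covariance


class TestSymmetricKL:
    def test_identical_samples_give_zero(self):
        P = np.random.default_rng(0).normal(size=(20, 3))
        assert symmetric_kl(P, P) == 0.0

    def test_exact_symmetry(self):
        rng = np.random.default_rng(1)
        A, B = rng.normal(size=(15, 3)), rng.normal(size=(18, 3))
        assert symmetric_kl(A, B) == symmetric_kl(B, A)

    def test_nonnegative_on_random_pairs(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            A = rng.normal(rng.uniform(-2, 2), 1.0, size=(15, 3))
            B = rng.normal(rng.uniform(-2, 2), 1.0, size=(15, 3))
            assert symmetric_kl(A, B) >= -1e-9

    def test_offset_gaussian_closed_form(self):
        # symmetric KL between N(0,I) and N(delta*e1,I) in 3D is delta^2
        ests = []
        for s in range(3):
            rng = np.random.default_rng(500 + s)
            P = rng.normal(size=(2000, 3))
            Q = rng.normal(size=(2000, 3))
            Q[:, 0] += 1.0
            ests.append(symmetric_kl(P, Q))
        assert np.mean(ests) == pytest.approx(1.0, abs=0.3)

    def test_increases_with_separation(self):
        rng = np.random.default_rng(3)
        P = rng.normal(size=(100, 3))
        kls = [symmetric_kl(P, rng.normal(size=(100, 3)) + d) for d in (0.0, 2.0, 5.0)]
        assert kls[0] < kls[1] < kls[2]


class TestKLPermutation:
    def test_null_pair_usually_comparable(self):
        rng = np.random.default_rng(4)
        res = kl_permutation_test(
            rng.normal(size=(15, 3)), rng.normal(size=(15, 3)),
            n_permutations=200, seed=0,
        )
        assert res.p_value > 0.05
        assert res.comparable

    def test_separated_blobs_highly_significant(self):
        rng = np.random.default_rng(5)
        res = kl_permutation_test(
            rng.normal(size=(15, 3)), rng.normal(size=(15, 3)) + 8.0,
            n_permutations=200, seed=0,
        )
        assert res.p_value <= 0.01
        assert not res.comparable

    def test_p_value_bookkeeping(self):
        rng = np.random.default_rng(6)
        res = kl_permutation_test(
            rng.normal(size=(10, 3)), rng.normal(size=(10, 3)),
            n_permutations=50, seed=1,
        )
        assert len(res.permuted_kls) == 50
        assert 0.0 <= res.p_value <= 1.0
        assert res.p_value == (res.permuted_kls >= res.observed_kl).mean()

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(7)
        A, B = rng.normal(size=(12, 3)), rng.normal(size=(12, 3))
        r1 = kl_permutation_test(A, B, n_permutations=50, seed=5)
        r2 = kl_permutation_test(A, B, n_permutations=50, seed=5)
        assert r1.p_value == r2.p_value
        np.testing.assert_array_equal(r1.permuted_kls, r2.permuted_kls)

    def test_plus_one_mode_never_zero(self):
        rng = np.random.default_rng(8)
        res = kl_permutation_test(
            rng.normal(size=(15, 3)), rng.normal(size=(15, 3)) + 8.0,
            n_permutations=50, seed=0, plus_one=True,
        )
        assert res.p_value == pytest.approx(1 / 51)

    def test_invalid_permutation_count(self):
        with pytest.raises(ConfigError):
            kl_permutation_test(np.zeros((5, 3)), np.zeros((5, 3)), n_permutations=0)


# -------------------------------------------------------- full report

@pytest.fixture(scope="module")
def mixed_cohort_models():
    """Two stratified cohorts at a 50% treatment rate: one with a
    protective chemotherapy effect (hazard ratio 0.4) confined to the
    poor-prognosis archetype, one with no effect anywhere."""
    from twinmap.cohort import to_predictor_vectors
    from twinmap.pipeline import run_stratification
    from twinmap.simulate import GeneratorConfig, generate_cohort

    out = {}
    for name, hr in (("effect", [1.0, 1.0, 1.0, 0.4, 1.0, 1.0]),
                     ("null", 1.0)):
        cohort = generate_cohort(GeneratorConfig(
            n=1000, seed=7, chemo_rate=0.5, chemo_hazard_ratio=hr))
        res = run_stratification(cohort, seed=7)
        poor = cohort[cohort["true_cluster"] == 3].iloc[2]
        dev = res.scorer.transform(
            to_predictor_vectors(poor.to_frame().T))[0]
        out[name] = (res, dev)
    return out


class TestBenefitReport:
    def test_protective_effect_visible_and_arms_comparable(self, mixed_cohort_models):
        from twinmap.benefit import assemble_benefit_report

        res, dev = mixed_cohort_models["effect"]
        rep = assemble_benefit_report(dev, res.manifold, res.model_records,
                                      k=15, n_permutations=300, seed=1)
        assert survival_at(rep.km_chemo, 60) > survival_at(rep.km_nochemo, 60)
        assert rep.kl_result.comparable
        assert "NOT comparable" not in rep.verdict

    def test_null_effect_gives_nonsignificant_logrank(self, mixed_cohort_models):
        from twinmap.benefit import assemble_benefit_report

        res, dev = mixed_cohort_models["null"]
        rep = assemble_benefit_report(dev, res.manifold, res.model_records,
                                      k=15, n_permutations=300, seed=1)
        assert rep.logrank_p > 0.05

    def test_sparse_treatment_arms_trigger_heterogeneity_warning(self):
        """At a realistic 12% treatment rate the 15 nearest treated
        patients are far more dispersed than the 15 nearest untreated,
        and the verdict must carry the heterogeneity warning."""
        from twinmap.benefit import HETEROGENEITY_WARNING, assemble_benefit_report
        from twinmap.cohort import to_predictor_vectors
        from twinmap.pipeline import run_synthetic_stratification

        res = run_synthetic_stratification(n=800, seed=7)
        query = res.model_records.iloc[0]
        dev = res.scorer.transform(to_predictor_vectors(query.to_frame().T))[0]
        rep = assemble_benefit_report(dev, res.manifold, res.model_records,
                                      k=15, n_permutations=200, seed=1)
        if not rep.kl_result.comparable:
            assert HETEROGENEITY_WARNING in rep.verdict
        else:  # well-mixed neighborhoods carry no warning
            assert HETEROGENEITY_WARNING not in rep.verdict
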