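import itertools

import numpy as np
import pytest

from fourquad.data import AnalysisConfig, DifferencePairs
from fourquad.errors import EstimationError, NumericalError, UndefinedRateError
from fourquad.mvn import (
    AgreementPattern,
    MVNParams,
    enumerate_numerator_rectangles,
    estimate_mvn_params,
    proposed_rate,
    rectangle_probability,
)


def random_params(rng, T=2, mean_scale=1.5):
    """A random, well-conditioned 2T-dimensional model."""
    d = 2 * T
    A = rng.normal(size=(d, d)) / np.sqrt(d)
    cov = A @ A.T + 0.5 * np.eye(d)
    return MVNParams(mean=mean_scale * rng.normal(size=d), covariance=cov)


class TestEstimateParams:
    def test_two_subject_hand_arithmetic(self):
        diffs = DifferencePairs(x=[[1, 1], [3, 3]], y=[[1, 1], [3, 3]])
        params = estimate_mvn_params(diffs)
        np.testing.assert_allclose(params.mean, [2, 2, 2, 2])
        np.testing.assert_allclose(params.covariance, np.full((4, 4), 2.0))

    def test_single_subject_rejected(self):
        with pytest.raises(EstimationError):
            estimate_mvn_params(DifferencePairs(x=[[1, 1]], y=[[0, 0]]))

    def test_recovers_known_model_within_five_standard_errors(self, rng):
        mean = np.array([1.5, -0.5, 1.0, 0.0])
        cov = np.array(
            [
                [1.0, 1 / 3, 1 / 3, 1 / 3],
                [1 / 3, 1.0, 1 / 3, 1 / 3],
                [1 / 3, 1 / 3, 1.0, 1 / 3],
                [1 / 3, 1 / 3, 1 / 3, 1.0],
            ]
        )
        n = 1000
        z = rng.multivariate_normal(mean, cov, size=n)
        params = estimate_mvn_params(DifferencePairs(x=z[:, :2], y=z[:, 2:]))
        se_mean = np.sqrt(np.diag(cov) / n)
        assert np.all(np.abs(params.mean - mean) < 5 * se_mean)
        # covariance entries: SE ~ sqrt((s_ii s_jj + s_ij^2)/n)
        se_cov = np.sqrt(
            (np.outer(np.diag(cov), np.diag(cov)) + cov**2) / n
        )
        assert np.all(np.abs(params.covariance - cov) < 5 * se_cov)

    def test_identical_subjects_yield_zero_covariance(self):
        diffs = DifferencePairs(x=[[1, 1]] * 3, y=[[2, 2]] * 3)
        params = estimate_mvn_params(diffs)
        np.testing.assert_allclose(params.covariance, 0.0)
        # downstream the zero matrix is regularized with a warning
        with pytest.warns(RuntimeWarning, match="near-singular"):
            res = proposed_rate(params, AnalysisConfig(a=0.5, T=2, m=2))
        assert res.rate == pytest.approx(1.0, abs=1e-6)


class TestRectangleProbability:
    def test_orthant_identity(self):
        rho = 1 / 3
        params = MVNParams(np.zeros(2), [[1, rho], [rho, 1]])
        p, err = rectangle_probability(params, [0, 0], [np.inf, np.inf])
        assert p == pytest.approx(0.25 + np.arcsin(rho) / (2 * np.pi), abs=1e-5)
        assert err >= 0

    def test_normalization(self, rng):
        params = random_params(rng)
        p, _ = rectangle_probability(params, [-np.inf] * 4, [np.inf] * 4)
        assert p == pytest.approx(1.0, abs=1e-10)


class TestEnumerator:
    def test_t2_double_agreement_has_16_rectangles(self):
        rects = enumerate_numerator_rectangles(
            AgreementPattern((True, True)), a=0.5, T=2
        )
        assert len(rects) == 16
        assert sum(r.weight for r in rects) == 0  # 8 positive, 8 negative

    def test_t1_base_case(self):
        rects = enumerate_numerator_rectangles(AgreementPattern((True,)), a=1.0, T=1)
        got = {
            (tuple(r.lower), tuple(r.upper), r.weight) for r in rects
        }
        inf = np.inf
        want = {
            ((0, 0), (inf, inf), 1),        # quadrant A
            ((-inf, -inf), (0, 0), 1),      # quadrant B
            ((0, 0), (1, 1), -1),           # EzA
            ((-1, -1), (0, 0), -1),         # EzB
        }
        assert got == want

    def test_matches_hand_coded_t2_expansion(self):
        """The general enumerator reproduces, term by term, the printed T=2
        expansion: both coordinates of a time drawn from the same element of
        F = {[0,inf], [-inf,0]} (quadrants) or E = {[0,a], [-a,0]} (exclusion
        cells), with + for FF/EE combinations and - for mixed ones."""
        a = 0.7
        inf = np.inf
        F = [(0, inf), (-inf, 0)]
        E = [(0, a), (-a, 0)]
        want = set()
        for fam1, fam2 in itertools.product((F, E), repeat=2):
            weight = 1 if fam1 is fam2 else -1
            for v1, v2 in itertools.product(fam1, fam2):
                # agreement at both times: X_t and Y_t share the interval
                lower = (v1[0], v2[0], v1[0], v2[0])
                upper = (v1[1], v2[1], v1[1], v2[1])
                want.add((lower, upper, weight))
        rects = enumerate_numerator_rectangles(AgreementPattern((True, True)), a, 2)
        got = {(tuple(r.lower), tuple(r.upper), r.weight) for r in rects}
        assert got == want

    def test_zero_zone_collapses_to_measure_zero_cells(self):
        rects = enumerate_numerator_rectangles(AgreementPattern((True, True)), 0.0, 2)
        degenerate = [r for r in rects if np.any(r.lower == r.upper)]
        assert len(degenerate) == 12  # all terms touching an exclusion cell
        pure = [r for r in rects if not np.any(r.lower == r.upper)]
        assert len(pure) == 4  # 2^T pure-quadrant rectangles


class TestProposedRate:
    @pytest.mark.parametrize(
        "m, a, want", [(2, 0.0, 0.25), (1, 0.0, 0.75), (2, 0.5, 0.25), (1, 1.0, 0.75)]
    )
    def test_standard_normal_symmetry(self, m, a, want):
        """Zero mean + identity covariance: agreement is a fair coin per
        time point, and the square exclusion zone removes equal mass from
        all four quadrants."""
        params = MVNParams(np.zeros(4), np.eye(4))
        res = proposed_rate(params, AnalysisConfig(a=a, T=2, m=m))
        assert res.rate == pytest.approx(want, abs=1e-5)

    @pytest.mark.parametrize("T", [1, 2, 3])
    def test_partition_of_unity(self, T, rng):
        """Sum over t=0..T of P[H_t and NEz] equals 1 - P[union Ez]."""
        params = random_params(rng, T=T)
        a = 0.5
        res_m1 = proposed_rate(params, AnalysisConfig(a=a, T=T, m=1))
        # P[H_0 cap NEz]: all time points disagreeing
        from fourquad.integrate import mvn_rectangle_probabilities

        rects = enumerate_numerator_rectangles(
            AgreementPattern((False,) * T), a, T
        )
        probs, _ = mvn_rectangle_probabilities(
            params.mean,
            params.covariance,
            np.array([r.lower for r in rects]),
            np.array([r.upper for r in rects]),
        )
        h0 = float(sum(r.weight * p for r, p in zip(rects, probs)))
        assert res_m1.numerator + h0 == pytest.approx(res_m1.denominator, abs=1e-5)

    def test_monotone_in_m(self, rng):
        fast = dict(n_base=256, max_base=512, n_shifts=8)
        for _ in range(5):
            params = random_params(rng, T=3)
            cfgs = [AnalysisConfig(a=0.5, T=3, m=m) for m in (1, 2, 3)]
            rates = [
                proposed_rate(params, c, tol=1e-4, qmc_options=fast).rate
                for c in cfgs
            ]
            assert rates[0] >= rates[1] - 1e-3 >= rates[2] - 2e-3

    def test_method_swap_symmetry(self, rng):
        params = random_params(rng)
        cfg = AnalysisConfig(a=0.5, T=2, m=2)
        direct = proposed_rate(params, cfg).rate
        swapped = proposed_rate(params.swap_methods(), cfg).rate
        assert swapped == pytest.approx(direct, abs=1e-5)

    def test_scale_invariance(self, rng):
        params = random_params(rng)
        c = 3.7
        scaled = MVNParams(c * params.mean, c**2 * params.covariance)
        r1 = proposed_rate(params, AnalysisConfig(a=0.5, T=2, m=2)).rate
        r2 = proposed_rate(scaled, AnalysisConfig(a=0.5 * c, T=2, m=2)).rate
        assert r2 == pytest.approx(r1, abs=1e-5)

    def test_concentrated_in_zone_is_undefined(self):
        params = MVNParams(np.zeros(4), 1e-8 * np.eye(4))
        with pytest.raises(UndefinedRateError):
            proposed_rate(params, AnalysisConfig(a=0.5, T=2, m=2))

    def test_t_cap_enforced(self):
        params = MVNParams(np.zeros(14), np.eye(14))
        with pytest.raises(NumericalError):
            proposed_rate(params, AnalysisConfig(a=0.5, T=7, m=7))

    def test_t_mismatch_rejected(self):
        params = MVNParams(np.zeros(4), np.eye(4))
        with pytest.raises(ValueError):
            proposed_rate(params, AnalysisConfig(a=0.5, T=3, m=1))

    def test_agrees_with_monte_carlo_oracle(self, rng):
        from fourquad.oracle import mc_proposed_rate

        rho = 1 / 3
        within = np.array([[1.0, rho], [rho, 1.0]])
        cross = np.full((2, 2), rho)
        params = MVNParams(
            np.array([1.5, 1.5, 1.5, 1.5]),
            np.block([[within, cross], [cross, within]]),
        )
        cfg = AnalysisConfig(a=0.5, T=2, m=2)
        analytic = proposed_rate(params, cfg)
        mc = mc_proposed_rate(params, cfg, n_draws=1_000_000, seed=7)
        assert abs(analytic.rate - mc.estimate) < 3 * mc.std_error + 1e-5
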