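"""Unit and property tests for the one-sided Cauchy-prior Bayes factor."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from seqbf import bayes
from seqbf.bayes import BFConfig, bf01, bf10, robustness_sweep, summarize
from seqbf._nct import log_nct_pdf

# Published per-lab and overall summaries with their printed Bayes factors;
# the 2-decimal rounding of mean/sd bounds agreement at roughly the percent
# level (the worst row, Russia, reconstructs to within 1.9%).
PRINTED_ROWS = [
    ("overall", 2004, 29.97, 3.92, 0.23),
    ("Germany", 1413, 30.00, 3.88, 0.20),
    ("Italy", 235, 30.12, 4.10, 0.31),
    ("Russia", 154, 29.49, 3.83, 1.93),
    ("France", 103, 29.52, 4.27, 1.19),
    ("Sweden", 99, 30.20, 3.80, 0.40),
]


def t_of(n, mean, sd, mu0=30.0):
    return (mean - mu0) / (sd / math.sqrt(n))


class TestStableNoncentralT:
    def test_matches_scipy_in_its_safe_region(self, rng):
        """Where scipy's boost backend works, the two densities agree."""
        checked = 0
        for _ in range(400):
            t = rng.uniform(-8, 8)
            df = float(rng.integers(1, 2400))
            nc = rng.uniform(-12, 12)
            try:
                ref = stats.nct.logpdf(t, df, nc)
            except (OverflowError, RuntimeWarning):
                continue
            if not np.isfinite(ref):
                continue
            assert float(log_nct_pdf(t, df, nc)) == pytest.approx(ref, abs=1e-5)
            checked += 1
        assert checked > 100

    def test_central_case_reduces_to_student_t(self):
        t = np.linspace(-30, 30, 101)
        for df in (1.0, 5.0, 59.0, 2003.0):
            np.testing.assert_allclose(
                log_nct_pdf(t, df, 0.0), stats.t.logpdf(t, df), atol=1e-7
            )

    def test_extreme_noncentrality_stays_finite(self):
        """Parameter combinations that break library implementations."""
        vals = log_nct_pdf(
            np.array([-0.34, 5.0, -300.0]), 2327.0, np.array([-500.0, 800.0, -90.0])
        )
        assert np.all(np.isfinite(vals))


class TestSummarize:
    def test_reconstructs_printed_overall_t(self, overall):
        assert t_of(overall.n, overall.mean, overall.sd) == pytest.approx(
            -0.3426, abs=5e-4
        )

    def test_symmetric_sample_gives_zero_t(self):
        assert summarize([28, 30, 32], 30.0).t == 0.0

    def test_degenerate_samples(self):
        assert math.isnan(summarize([30, 30], 30.0).t)
        assert summarize([29, 29], 30.0).t == -math.inf
        assert summarize([31, 31], 30.0).t == math.inf

    def test_rejects_tiny_samples(self):
        with pytest.raises(ValueError):
            summarize([30], 30.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.integers(min_value=0, max_value=60), min_size=2, max_size=40)
    )
    def test_t_consistent_with_moments(self, counts):
        s = summarize(counts, 30.0)
        assert s.n == len(counts)
        assert s.df == s.n - 1
        if s.sd > 0:
            assert s.t == pytest.approx((s.mean - 30.0) / (s.sd / math.sqrt(s.n)))


class TestPrintedBayesFactors:
    @pytest.mark.parametrize("label,n,mean,sd,printed", PRINTED_ROWS)
    def test_reproduces_printed_value(self, label, n, mean, sd, printed):
        value = bf10(t_of(n, mean, sd), n, prior_scale=0.1, direction="less")
        assert value == pytest.approx(printed, rel=0.02)

    def test_reciprocal_matches_printed_bf01(self, overall):
        value = bf01(t_of(overall.n, overall.mean, overall.sd), overall.n)
        assert value == pytest.approx(4.38, rel=0.02)


def brute_force_bf10(t, n, r, direction="less"):
    """Independent oracle: dense 2-D trapezoid integration of the marginal
    density written from first principles,

        m(t) = int d(delta) pi(delta) int dw  w phi(w t - delta sqrt(n)) h(w)

    with h the density of sqrt(chi2_df / df).  Uses only elementary
    formulas; shares no code with the production quadrature path."""
    from scipy import special

    df = n - 1
    sqrt_n = math.sqrt(n)
    # w-grid: sqrt(chi2/df) has mean ~1 and sd ~ 1/sqrt(2 df)
    sw = 1.0 / math.sqrt(2.0 * df)
    w = np.linspace(max(1e-9, 1.0 - 20.0 * sw), 1.0 + 24.0 * sw, 6001)
    log_h = (
        math.log(2.0)
        + 0.5 * df * math.log(df / 2.0)
        - special.gammaln(df / 2.0)
        + (df - 1.0) * np.log(w)
        - 0.5 * df * w * w
    )
    # delta grid spans the likelihood's support on the allowed side(s)
    if direction == "less":
        lo, hi = (min(t, 0.0) - 18.0) / sqrt_n, 0.0
    elif direction == "greater":
        lo, hi = 0.0, (max(t, 0.0) + 18.0) / sqrt_n
    else:
        lo, hi = (min(t, 0.0) - 18.0) / sqrt_n, (max(t, 0.0) + 18.0) / sqrt_n
    # the step must resolve both the likelihood width (1/sqrt(n)) and the
    # prior peak width (r)
    step = min(r, 1.0 / sqrt_n) / 150.0
    delta = np.linspace(lo, hi, min(120_001, max(4001, int((hi - lo) / step))))

    def marginal(nc):
        """density of t at noncentralities nc via trapezoid over w."""
        out = np.empty(nc.size)
        for start in range(0, nc.size, 500):
            block = nc[start : start + 500, None]
            z = w[None, :] * t - block
            integrand = np.exp(np.log(w)[None, :] + log_h[None, :] - 0.5 * z * z)
            out[start : start + 500] = np.trapezoid(integrand, w, axis=1)
        return out / math.sqrt(2.0 * math.pi)

    prior = (r / math.pi) / (delta * delta + r * r)
    if direction != "two_sided":
        prior = 2.0 * prior
    m1 = np.trapezoid(marginal(delta * sqrt_n) * prior, delta)
    m0 = marginal(np.zeros(1))[0]
    return m1 / m0


class TestQuadratureAgainstBruteForce:
    @pytest.mark.parametrize("t", [-3.0, -1.652, 1.5])
    @pytest.mark.parametrize("n", [10, 154, 2004])
    @pytest.mark.parametrize("r", [0.05, 0.1, 0.707])
    def test_relative_1e5_agreement(self, t, n, r):
        assert bf10(t, n, prior_scale=r) == pytest.approx(
            brute_force_bf10(t, n, r), rel=1e-5
        )

    def test_two_sided_against_brute_force(self):
        assert bf10(-1.2, 200, prior_scale=0.3, direction="two_sided") == pytest.approx(
            brute_force_bf10(-1.2, 200, 0.3, "two_sided"), rel=1e-5
        )


class TestBayesFactorProperties:
    grid = [(-2.5, 50, 0.1), (-0.34, 2004, 0.1), (0.8, 120, 0.707), (1.9, 17, 1.0)]

    @pytest.mark.parametrize("t,n,r", grid)
    def test_one_sided_halves_sum_to_two_sided(self, t, n, r):
        less = bf10(t, n, prior_scale=r, direction="less")
        greater = bf10(t, n, prior_scale=r, direction="greater")
        two = bf10(t, n, prior_scale=r, direction="two_sided")
        assert less + greater == pytest.approx(2.0 * two, rel=1e-6)

    @pytest.mark.parametrize("n,r", [(100, 0.1), (1413, 0.1), (35, 1.0)])
    def test_directions_coincide_at_t_zero(self, n, r):
        values = {
            d: bf10(0.0, n, prior_scale=r, direction=d)
            for d in ("less", "greater", "two_sided")
        }
        assert values["less"] == pytest.approx(values["greater"], rel=1e-8)
        assert values["less"] == pytest.approx(values["two_sided"], rel=1e-8)

    def test_monotone_decreasing_in_t_for_less(self):
        ts = np.linspace(-4, 4, 17)
        vals = [bf10(t, 154, prior_scale=0.1, direction="less") for t in ts]
        assert np.all(np.diff(vals) < 0)

    def test_prior_collapse_returns_equipoise(self):
        """As r -> 0 the alternative collapses onto the null: BF -> 1."""
        for t, n in [(-2.0, 50), (1.3, 500)]:
            assert bf10(t, n, prior_scale=1e-8) == pytest.approx(1.0, abs=1e-4)

    def test_continuity_in_prior_scale(self):
        a = bf10(-1.652, 154, prior_scale=0.1)
        b = bf10(-1.652, 154, prior_scale=0.1 + 1e-6)
        assert abs(a - b) < 1e-4

    def test_invalid_parameters_raise(self):
        with pytest.raises(ValueError):
            bf10(1.0, 100, prior_scale=-0.1)
        with pytest.raises(ValueError):
            bf10(1.0, 1)
        with pytest.raises(ValueError):
            bf10(1.0, 100, direction="sideways")
        with pytest.raises(ValueError):
            BFConfig(min_n=1)


class TestDegenerateSamples:
    def test_non_finite_t_scores_equipoise(self):
        """Zero-variance prefixes are uninformative for a standardized
        effect: BF = 1 regardless of direction or sample size."""
        for n in (2, 5, 100):
            assert bf10(-math.inf, n) == 1.0
            assert bf10(math.inf, n) == 1.0

    def test_finite_bf_grows_slowly_toward_the_degenerate_regime(self):
        """The exact BF diverges only logarithmically at df = 1: huge |t|
        still yields a single-digit Bayes factor."""
        a = bf10(-600.0, 2)
        b = bf10(-60000.0, 2)
        assert 1.0 < a < b < 10.0

    def test_nan_t_maps_to_equipoise(self):
        assert bf10(math.nan, 10) == 1.0


class TestRobustnessSweep:
    def test_single_scale_reproduces_main_analysis(self, overall):
        counts = [29, 31] * 30  # any data; compare the two call paths
        sweep = robustness_sweep(counts, (0.1,))
        s = summarize(counts, 30.0)
        assert sweep[0.1] == pytest.approx(bf10(s.t, s.n, prior_scale=0.1))

    def test_wide_priors_strengthen_null_evidence(self, overall):
        """On the overall summary, wider priors push BF01 to ~30 and beyond."""
        t = t_of(overall.n, overall.mean, overall.sd)
        values = {r: bf10(t, overall.n, prior_scale=r) for r in (0.707, 1.0, 1.414)}
        assert 1.0 / values[0.707] == pytest.approx(29.5, rel=0.02)
        assert 1.0 / values[1.0] > 30
        assert 1.0 / values[1.414] > 30

    def test_empty_or_invalid_grid_raises(self):
        with pytest.raises(ValueError):
            robustness_sweep([29, 31, 30], ())
        with pytest.raises(ValueError):
            robustness_sweep([29, 31, 30], (0.1, -1.0))
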