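import math

import numpy as np
import pytest

from multiskew import (
    ReproductiveSample,
    SkewEstimate,
    SkewUndefinedError,
    compute_B,
    compute_I,
    compute_Q,
    compute_gini,
    compute_m,
    compute_mcheck,
    compute_mmp,
    compute_morisita,
    compute_waples,
    mcheck_forms,
    null_expectation_mcheck,
)
from multiskew.indices import ENUMERATION_CAP

from conftest import random_samples


class TestMcheck:
    def test_perfectly_proportional_shares_give_zero(self):
        assert compute_mcheck(ReproductiveSample([2, 2, 2, 2])) == 0.0
        # proportional to unequal exposure also gives zero
        s = ReproductiveSample([1, 2, 3], [1.0, 2.0, 3.0])
        assert compute_mcheck(s) == pytest.approx(0.0, abs=1e-15)

    def test_full_monopoly_equal_exposure(self, monopolist):
        # (N/R^2) sum (r - rbar)^2 = (4/16)*12 = 3
        assert compute_mcheck(monopolist) == pytest.approx(3.0)

    def test_unequal_exposure_hand_value(self):
        # shares r-hat = (1/2, 1/2), t-hat = (1/4, 3/4)
        s = ReproductiveSample([1, 1], [1.0, 3.0])
        assert compute_mcheck(s) == pytest.approx(0.25)

    def test_no_reproduction_is_an_error(self):
        with pytest.raises(SkewUndefinedError, match="no reproduction"):
            compute_mcheck(ReproductiveSample([0, 0, 0]))

    def test_all_forms_agree_on_random_samples(self, rng):
        for s in random_samples(rng, 300):
            forms = mcheck_forms(s)
            vals = np.array(list(forms.values()))
            np.testing.assert_allclose(vals, vals[0], rtol=1e-10,
                                       atol=1e-12)
            assert vals[0] >= 0


class TestNullExpectation:
    def test_exhaustive_enumeration_two_cells(self):
        # outcomes (2,0),(1,1),(0,2) with pmf (1/4,1/2,1/4), M-check (1,0,1)
        val = null_expectation_mcheck(2, 2, [0.5, 0.5], method="enumerate")
        assert val == pytest.approx(0.5, abs=1e-14)

    def test_analytic_reduces_to_nm1_over_r_under_equal_shares(self):
        val = null_expectation_mcheck(4, 100, np.full(4, 0.25))
        assert val == pytest.approx(3 / 100, abs=1e-15)

    def test_analytic_matches_enumeration_small_grid(self, rng):
        """Closed form (N/R)(1 - sum t^2) against exact enumeration."""
        for n in range(2, 5):
            for r in range(1, 9):
                shares = rng.dirichlet(np.ones(n) * 3)
                exact = null_expectation_mcheck(n, r, shares,
                                                method="enumerate")
                analytic = null_expectation_mcheck(n, r, shares)
                assert analytic == pytest.approx(exact, abs=1e-12)

    def test_monte_carlo_converges_to_analytic(self):
        shares = np.array([0.5, 0.3, 0.2])
        analytic = null_expectation_mcheck(3, 5, shares)
        n_draws = 200_000
        mc = null_expectation_mcheck(3, 5, shares, method="monte_carlo",
                                     n_draws=n_draws, seed=7)
        # SE of the MC mean, conservatively from a pilot draw set
        rng = np.random.default_rng(8)
        pilot = rng.multinomial(5, shares, size=20_000)
        dev = pilot - 5 * shares
        vals = 3 / 25 * np.einsum("ij,ij->i", dev, dev)
        se = vals.std() / math.sqrt(n_draws)
        assert abs(mc - analytic) < 4 * se

    def test_enumeration_cap_is_enforced(self):
        n, r = 20, 100
        assert math.comb(r + n - 1, n - 1) > ENUMERATION_CAP
        with pytest.raises(ValueError, match="analytic"):
            null_expectation_mcheck(n, r, np.full(n, 1 / n),
                                    method="enumerate")

    @pytest.mark.parametrize(
        "kwargs, message",
        [
            (dict(n=2, total_rs=0, exposure_shares=[0.5, 0.5]), "total_rs"),
            (dict(n=2, total_rs=2, exposure_shares=[0.7, 0.7]), "sum to 1"),
            (dict(n=2, total_rs=2, exposure_shares=[0.5, 0.5],
                  method="bogus"), "unknown method"),
        ],
    )
    def test_validation(self, kwargs, message):
        with pytest.raises(ValueError, match=message):
            null_expectation_mcheck(**kwargs)


class TestM:
    def test_monopoly_value_and_metadata(self, monopolist):
        est = compute_m(monopolist)
        assert isinstance(est, SkewEstimate)
        assert est.value == pytest.approx(3.0 - 0.75)
        assert est.null_expectation == pytest.approx(0.75)
        assert est.n == 4 and est.total_rs == 4
        assert est.index_name == "M"

    def test_hyper_equal_sample_is_negative(self):
        est = compute_m(ReproductiveSample([1, 1, 1, 1]))
        assert est.value == pytest.approx(-0.75)

    def test_monte_carlo_method_close_to_analytic(self, monopolist):
        a = compute_m(monopolist).value
        mc = compute_m(monopolist, method="monte_carlo", n_draws=100_000,
                       seed=3).value
        assert mc == pytest.approx(a, abs=0.02)


class TestComparatorIndices:
    def test_opportunity_for_selection(self, monopolist):
        assert compute_I(monopolist) == pytest.approx(3.0)
        assert compute_I(monopolist) == pytest.approx(
            compute_mcheck(monopolist))
        assert compute_I(ReproductiveSample([3, 3, 3])) == 0.0

    def test_I_on_rates_equalised_by_exposure(self):
        s = ReproductiveSample([2, 1], [2.0, 1.0])
        assert compute_I(s, on_rate=True) == pytest.approx(0.0)

    def test_I_zero_mean_error(self):
        with pytest.raises(SkewUndefinedError):
            compute_I(ReproductiveSample([0, 0]))

    def test_nonacs_B(self, monopolist):
        assert compute_B(monopolist) == pytest.approx(0.75 - 3 / 16)

    def test_nonacs_B_nhat_variant(self):
        # N-hat = 1/max(t-hat) differs from N under unequal exposure
        s = ReproductiveSample([2, 1, 1], [1.0, 1.0, 2.0])
        default = compute_B(s)
        nhat = compute_B(s, nonacs_n=True)
        assert default != pytest.approx(nhat)
        # equal exposure: both agree
        e = ReproductiveSample([2, 1, 1])
        assert compute_B(e) == pytest.approx(compute_B(e, nonacs_n=True))

    def test_ruzzante_Q(self, monopolist):
        assert compute_Q(monopolist) == pytest.approx(2 / 3)

    def test_Q_forward_relation_roundtrip(self, rng):
        for s in random_samples(rng, 50, equal_exposure=True):
            if s.total_rs <= 1:
                continue
            q = compute_Q(s)
            n, r = s.n, s.total_rs
            assert n / r * ((r - 1) * q + 1) == pytest.approx(
                compute_mcheck(s), rel=1e-12)

    def test_Q_guards(self):
        with pytest.raises(SkewUndefinedError, match="R > 1"):
            compute_Q(ReproductiveSample([1, 0]))
        with pytest.raises(ValueError, match="equal exposure"):
            compute_Q(ReproductiveSample([1, 1], [1.0, 2.0]))

    def test_morisita(self, monopolist):
        # classic form N*sum r(r-1) / (R(R-1)); even counts underdisperse
        assert compute_morisita(monopolist) == pytest.approx(4.0)
        assert compute_morisita(ReproductiveSample([1, 1, 1, 1])) == 0.0
        assert compute_morisita(ReproductiveSample([2, 2])) == pytest.approx(
            2 * (2 + 2) / (4 * 3))

    def test_morisita_relation_to_m(self, rng):
        """M = ((R-1)/R)(I_sigma - 1) is exact under equal exposure."""
        for s in random_samples(rng, 100, equal_exposure=True):
            if s.total_rs <= 1:
                continue
            lhs = compute_m(s).value
            rhs = (s.total_rs - 1) / s.total_rs * (compute_morisita(s) - 1)
            assert lhs == pytest.approx(rhs, rel=1e-10, abs=1e-12)

    def test_waples_equals_m_under_equal_exposure(self, rng, monopolist):
        assert compute_waples(monopolist) == pytest.approx(2.25)
        assert compute_waples(
            ReproductiveSample([1, 1, 1, 1])) == pytest.approx(-0.75)
        for s in random_samples(rng, 100, equal_exposure=True):
            assert compute_waples(s) == pytest.approx(
                compute_m(s).value, rel=1e-10, abs=1e-12)

    def test_gini(self, monopolist):
        assert compute_gini(ReproductiveSample([0, 2])) == pytest.approx(0.5)
        assert compute_gini(monopolist) == pytest.approx(0.75)
        assert compute_gini(ReproductiveSample([3, 3, 3])) == 0.0

    def test_gini_bounds(self, rng):
        for s in random_samples(rng, 50, equal_exposure=True):
            assert 0.0 <= compute_gini(s) < 1.0

    def test_mmp(self, monopolist):
        assert compute_mmp(monopolist) == 1.0
        assert compute_mmp(ReproductiveSample([1, 1, 1, 1])) == 0.25
        assert compute_mmp(ReproductiveSample([3, 1])) == 0.75


class TestEqualExposureIdentities:
    """Closed-form equalities tying M to I and M-check to I."""

    def test_identities_on_random_samples(self, rng):
        for s in random_samples(rng, 200, equal_exposure=True):
            n, r = s.n, s.total_rs
            i_val = compute_I(s)
            assert compute_mcheck(s) == pytest.approx(i_val, rel=1e-10,
                                                      abs=1e-12)
            assert compute_m(s).value == pytest.approx(
                i_val - (n - 1) / r, rel=1e-10, abs=1e-12)
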