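"""Term-by-term checks of the model right-hand sides and their invariants."""

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings
from hypothesis import strategies as st

from nichefate import (ParamsLV2, ParamsModelA, ParamsModelB, StateVector,
                       feedback_terms, get_model, rhs_lv2, rhs_model_a,
                       rhs_model_b)
from nichefate.models import (DomainError, params_from_csv, params_to_csv)

rates = st.floats(0.0, 1.0, allow_nan=False)
pops = st.floats(0.0, 2.0, allow_nan=False)


# ---------------------------------------------------------------------------
# two-species Lotka–Volterra
# ---------------------------------------------------------------------------

class TestLV2:
    def test_zero_state_is_fixed_point(self):
        dx, dy = rhs_lv2((0.0, 0.0), ParamsLV2(0.7, 0.2, 0.5))
        assert dx == 0.0 and dy == 0.0

    def test_equal_rates_equal_states_symmetric(self):
        dx, dy = rhs_lv2((0.3, 0.3), ParamsLV2(0.4, 0.4, 0.2))
        assert dx == dy

    def test_hand_evaluated_point(self):
        # X(α − γ(X+Y)) with X=0.5, Y=0.2, α=0.3, β=0.1, γ=0.4:
        # crowding γ(X+Y) = 0.28, so dX = 0.5·0.02, dY = 0.2·(−0.18)
        dx, dy = rhs_lv2((0.5, 0.2), ParamsLV2(0.3, 0.1, 0.4))
        assert dx == pytest.approx(0.01)
        assert dy == pytest.approx(-0.036)

    def test_negative_population_rejected(self):
        with pytest.raises(DomainError):
            rhs_lv2((-0.1, 0.2), ParamsLV2(0.3, 0.1, 0.4))

    @given(alpha=rates, beta=rates, gamma=rates, x=pops, y=pops)
    @hyp_settings(max_examples=50, deadline=None)
    def test_log_ratio_drift_is_rate_difference(self, alpha, beta, gamma, x, y):
        """d/dt log(X/Y) = α − β: the larger growth rate always gains."""
        dx, dy = rhs_lv2((x, y), ParamsLV2(alpha, beta, gamma))
        if x > 1e-6 and y > 1e-6:
            assert dx / x - dy / y == pytest.approx(alpha - beta, abs=1e-9)


# ---------------------------------------------------------------------------
# model A
# ---------------------------------------------------------------------------

class TestModelA:
    def test_zero_state_is_fixed_point(self, params_a):
        assert np.all(rhs_model_a([0] * 5, params_a) == 0)

    def test_zero_params_zero_derivative(self):
        p = ParamsModelA(0, 0, 0, 0, 0, 0, 0, 0)
        assert np.all(rhs_model_a([0.2, 0.1, 0.3, 0.1, 0.2], p) == 0)

    def test_hand_evaluated_point(self):
        # S,A,D,L,T = .1,.1,.1,.05,.05 (Z=0.4, room=0.6), rates
        # (a1,b1,c1,e1,f,a2,b2,g) = (.5,.1,.2,.3,.4,.5,.1,.4):
        #   dS = .5·.1·.6 − .1·.1            = 0.02
        #   dA = .1·.1 + .2·.1·.6 − .3·.1    = −0.008
        #   dD = .3·.1 − .4·.1               = −0.01
        #   dL = .5·.05·.6 − .1·.05          = 0.01
        #   dT = .1·.05 − .4·.05             = −0.015
        p = ParamsModelA(0.5, 0.1, 0.2, 0.3, 0.4, 0.5, 0.1, 0.4)
        d = rhs_model_a([0.1, 0.1, 0.1, 0.05, 0.05], p)
        np.testing.assert_allclose(d, [0.02, -0.008, -0.01, 0.01, -0.015],
                                   atol=1e-12)

    def test_full_niche_only_loses_mass(self, params_a):
        """At Z = K every growth term vanishes, so dZ/dt = −f·D − g·T ≤ 0."""
        state = [0.2, 0.2, 0.3, 0.2, 0.1]  # Z = 1 = K
        d = rhs_model_a(state, params_a)
        assert d.sum() == pytest.approx(-params_a.f * 0.3 - params_a.g * 0.1)
        assert d.sum() <= 0

    def test_bad_capacity_rejected(self):
        with pytest.raises(ValueError, match="carrying capacity"):
            ParamsModelA(0.5, 0.1, 0.2, 0.3, 0.4, 0.5, 0.1, 0.4, K=0.0)

    def test_rates_above_one_warn_not_raise(self):
        with pytest.warns(UserWarning, match=r"\[0,1\] prior"):
            ParamsModelA(1.5, 0.1, 0.2, 0.3, 0.4, 0.5, 0.1, 0.4)

    def test_arm_exchange_maps_L_equation_onto_S_equation(self, rng):
        """The L equation equals the S equation under the renaming
        S↔L, a1↔a2, b1↔b2 (structural mirror of the two stem arms)."""
        for _ in range(20):
            a1, b1, c1, e1, f, a2, b2, g = rng.uniform(0, 1, 8)
            S, A, D, L, T = rng.uniform(0, 0.2, 5)
            p = ParamsModelA(a1, b1, c1, e1, f, a2, b2, g)
            p_sw = ParamsModelA(a2, b2, c1, e1, f, a1, b1, g)
            d = rhs_model_a([S, A, D, L, T], p)
            d_sw = rhs_model_a([L, A, D, S, T], p_sw)
            assert d[0] == pytest.approx(d_sw[3], abs=1e-12)   # dS ↔ dL
            assert d[3] == pytest.approx(d_sw[0], abs=1e-12)

    @given(theta=st.lists(rates, min_size=8, max_size=8),
           state=st.lists(pops, min_size=5, max_size=5),
           axis=st.integers(0, 4))
    @hyp_settings(max_examples=60, deadline=None)
    def test_no_outflow_from_empty_compartment(self, theta, state, axis):
        """A species at zero never has a negative derivative (nonnegativity)."""
        state = list(state)
        state[axis] = 0.0
        total = sum(state)
        if total > 0:
            state = [s / max(total, 1.0) for s in state]  # keep Z <= K
            state[axis] = 0.0
        p = ParamsModelA(*theta)
        assert rhs_model_a(state, p)[axis] >= -1e-12


# ---------------------------------------------------------------------------
# model B
# ---------------------------------------------------------------------------

class TestFeedback:
    def test_unit_at_zero_occupancy(self):
        fb = feedback_terms([0, 0, 0, 0, 0], (0.01, 0.01, 0.01))
        assert fb.phi1 == fb.phi2 == fb.phi3 == 1.0

    def test_zero_gamma_always_unit(self):
        fb = feedback_terms([5, 3, 2, 1, 4], (0, 0, 0))
        assert fb.phi1 == fb.phi2 == fb.phi3 == 1.0

    def test_phi1_only_sees_stem_subniche(self):
        g = (0.5, 0.5, 0.5)
        base = feedback_terms([0.1, 0.2, 0.3, 0.1, 0.2], g)
        more_s = feedback_terms([0.8, 0.2, 0.3, 0.1, 0.2], g)
        assert more_s.phi1 < base.phi1
        assert more_s.phi2 == base.phi2 and more_s.phi3 == base.phi3

    def test_exponential_form(self):
        fb = feedback_terms([0.3, 0.5, 0.2, 0.1, 0.4], (0.01, 0.02, 0.03))
        assert fb.phi1 == pytest.approx(np.exp(-0.01 * 0.4))
        assert fb.phi2 == pytest.approx(np.exp(-0.02 * 1.1))
        assert fb.phi3 == pytest.approx(np.exp(-0.03 * 1.1))

    @given(state=st.lists(st.floats(0, 100), min_size=5, max_size=5),
           g=st.lists(rates, min_size=3, max_size=3))
    @hyp_settings(max_examples=60, deadline=None)
    def test_bounds(self, state, g):
        fb = feedback_terms(state, g)
        for phi in (fb.phi1, fb.phi2, fb.phi3):
            assert 0 < phi <= 1


class TestModelB:
    def make(self, **over):
        base = dict(lam1=0.5, lam2=0.2, lam3=0.1, mu4=0.1, lam5=0.1, mu6=0.3,
                    chi1=0.4, mu8=0.3, kap1=0.3, kap2=0.2, kap3=0.1, nu4=0.2,
                    nu8=0.3)
        base.update(over)
        return ParamsModelB(**base)

    def test_zero_state_is_fixed_point(self):
        assert np.all(rhs_model_b([0] * 5, self.make()) == 0)

    def test_leukaemia_free_subspace_invariant(self):
        """With no leukaemic rates and L=T=0, dL=dT=0 identically."""
        p = self.make(kap1=0, kap2=0, kap3=0, nu4=0)
        d = rhs_model_b([0.4, 0.3, 0.2, 0.0, 0.0], p)
        assert d[3] == 0.0 and d[4] == 0.0

    def test_hand_evaluated_point(self):
        # state (S,A,D,L,T) = (.2,.3,.1,.1,.2), γ = .01 each:
        #   Φ1 = exp(−.01·.3), Φ2 = Φ3 = exp(−.01·.6)
        #   dS = .5·.2·Φ1 − .1·.2·Φ2 − .1·.2
        #   dA = (.2+2·.1)·.2·Φ2 + (.1−.3)·.3
        #   dD = .4·.3·Φ2 − .3·.1
        #   dL = .3·.1·Φ1 − .1·.1·Φ3 − .2·.1
        #   dT = (.2+2·.1)·.1·Φ3 − .3·.2
        p = self.make()
        f1 = np.exp(-0.01 * 0.3)
        f2 = np.exp(-0.01 * 0.6)
        expected = [0.1 * f1 - 0.02 * f2 - 0.02,
                    0.08 * f2 - 0.06,
                    0.12 * f2 - 0.03,
                    0.03 * f1 - 0.01 * f2 - 0.02,
                    0.04 * f2 - 0.06]
        d = rhs_model_b([0.2, 0.3, 0.1, 0.1, 0.2], p)
        np.testing.assert_allclose(d, expected, atol=1e-14)

    def test_gamma_zero_reduces_to_linear_model(self):
        """With all γ = 0 the vector field is linear in the state."""
        p = ParamsModelB(0.5, 0.2, 0.1, 0.1, 0.1, 0.3, 0.4, 0.3,
                         0.3, 0.2, 0.1, 0.2, 0.3, gam1=0, gam2=0, gam3=0)
        s1 = np.array([0.2, 0.3, 0.1, 0.1, 0.2])
        s2 = np.array([0.1, 0.05, 0.3, 0.2, 0.1])
        lhs = rhs_model_b(s1 + s2, p)
        np.testing.assert_allclose(lhs, rhs_model_b(s1, p) + rhs_model_b(s2, p),
                                   atol=1e-12)

    @given(theta=st.lists(rates, min_size=13, max_size=13),
           state=st.lists(st.floats(0, 5), min_size=5, max_size=5),
           axis=st.integers(0, 4))
    @hyp_settings(max_examples=60, deadline=None)
    def test_no_outflow_from_empty_compartment(self, theta, state, axis):
        state = list(state)
        state[axis] = 0.0
        p = ParamsModelB(*theta)
        assert rhs_model_b(state, p)[axis] >= -1e-12


# ---------------------------------------------------------------------------
# containers and I/O
# ---------------------------------------------------------------------------

class TestContainers:
    def test_state_vector_rejects_negative_and_nonfinite(self):
        with pytest.raises(DomainError):
            StateVector(-0.1, 0, 0, 0, 0)
        with pytest.raises(DomainError):
            StateVector(np.inf, 0, 0, 0, 0)

    def test_params_csv_round_trip(self, tmp_path, params_a):
        pb = ParamsModelB(*np.linspace(0.05, 0.65, 13))
        for name, plist in (("modelA", [params_a]), ("modelB", [pb])):
            path = tmp_path / f"{name}.csv"
            params_to_csv(plist, path)
            back = params_from_csv(path, name)
            assert len(back) == len(plist)
            for b, orig in zip(back, plist):
                np.testing.assert_allclose(b.to_array(), orig.to_array(),
                                           rtol=1e-12)
        # header names match the published symbol names (ascii)
        header = (tmp_path / "modelA.csv").read_text().splitlines()[0]
        assert header.split(",")[:8] == ["a1", "b1", "c1", "e1", "f",
                                         "a2", "b2", "g"]

    def test_registry_lookup(self):
        assert get_model("modelA").n_species == 5
        with pytest.raises(KeyError):
            get_model("modelC")
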