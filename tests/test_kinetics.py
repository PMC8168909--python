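"""Transport-kinetics unit and property tests.

The ABC steady-state algebra is checked against an independent
mass-action ODE relaxation; Michaelis–Menten limits are checked in
closed form.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from uptakealloc.kinetics import (
    AbcPools,
    MMFit,
    TransportParameters,
    abc_mm_approx,
    abc_steady_state,
    effective_half_saturation,
    mm_least_squares_fit,
    ode_relaxation_oracle,
    pts_uptake,
    specific_affinity,
)
from conftest import random_transport_params


class TestTransportParameters:
    def test_baseline_matches_measured_rate_set(self, baseline):
        # glucose-PTS translocation and dissociation; MalE-like binding protein
        assert baseline.k2 == baseline.k2p == 200.0
        assert baseline.K_T == pytest.approx(0.01)
        assert baseline.K_Tp == pytest.approx(0.01)
        assert baseline.K_D == pytest.approx(0.001)
        assert baseline.k3p == pytest.approx(0.01 * baseline.k2p)
        assert baseline.k1p == pytest.approx(0.01 * baseline.k1, rel=0.02)

    def test_derived_constants_track_rates(self, baseline):
        from dataclasses import replace

        doubled = replace(baseline, k2=2 * baseline.k2)
        assert doubled.K_T == pytest.approx(2 * baseline.K_T)

    @pytest.mark.parametrize("field", ["k1", "k2", "k0f", "k0r", "k1p", "k2p", "k3p"])
    def test_nonpositive_rates_rejected(self, baseline, field):
        from dataclasses import replace

        with pytest.raises(ValueError):
            replace(baseline, **{field: 0.0})


class TestPtsUptake:
    def test_half_saturation_at_K_T(self, baseline):
        v = pts_uptake(baseline.K_T, 1.0, baseline)
        assert v == pytest.approx(0.5 * baseline.k2)

    def test_zero_substrate_zero_rate(self, baseline):
        assert pts_uptake(0.0, 1.0, baseline) == 0.0

    def test_near_saturation_value(self, baseline):
        # S_p = 100*K_T: rate = (100/101)*k2*T_total
        v = pts_uptake(100 * baseline.K_T, 1.0, baseline)
        assert v == pytest.approx(100.0 / 101.0 * baseline.k2 * 1.0, rel=1e-12)

    def test_monotone_and_bounded(self, baseline):
        grid = np.logspace(-6, 2, 50)
        rates = [pts_uptake(s, 0.5, baseline) for s in grid]
        assert all(b >= a for a, b in zip(rates, rates[1:]))
        assert rates[-1] <= baseline.k2 * 0.5

    def test_negative_inputs_rejected(self, baseline):
        with pytest.raises(ValueError):
            pts_uptake(-1.0, 1.0, baseline)
        with pytest.raises(ValueError):
            pts_uptake(1.0, -1.0, baseline)


class TestAbcSteadyState:
    def test_no_carrier_no_flux(self, baseline):
        sol = abc_steady_state(0.5, AbcPools(BP_total=0.0, T_total=0.01), baseline)
        assert sol.v_c == 0.0
        assert sol.S_BP == sol.T_S_BP == 0.0

    def test_conservation_identities(self, baseline):
        pools = AbcPools(BP_total=0.2, T_total=0.003)
        for s_p in (1e-7, 1e-4, 1e-2, 1.0, 50.0):
            sol = abc_steady_state(s_p, pools, baseline)
            r_bp, r_t = sol.conservation_residuals(pools, baseline)
            scale = max(pools.BP_total, pools.T_total)
            assert abs(r_bp) < 1e-8 * scale
            assert abs(r_t) < 1e-8 * scale

    def test_matches_ode_relaxation_on_random_parameters(self):
        rng = np.random.default_rng(20240)
        for _ in range(25):
            params = random_transport_params(rng)
            pools = AbcPools(BP_total=10 ** rng.uniform(-3, 1),
                             T_total=10 ** rng.uniform(-5, -1))
            s_p = 10 ** rng.uniform(-6, 1)
            alg = abc_steady_state(s_p, pools, params)
            ode = ode_relaxation_oracle(s_p, pools, params)
            assert alg.v_c == pytest.approx(ode.v_c, rel=1e-6, abs=1e-18)
            assert alg.S_BP == pytest.approx(ode.S_BP, rel=1e-6, abs=1e-15)
            assert alg.T_S_BP == pytest.approx(ode.T_S_BP, rel=1e-6, abs=1e-15)

    def test_agrees_with_mm_approx_in_validity_regime(self, baseline):
        # many more binding proteins than transport units, S_p well below K_M
        pools = AbcPools(BP_total=0.1, T_total=0.001)
        _, fit = abc_mm_approx(0.0, pools, baseline)
        s_p = fit.K_M / 100.0
        exact = abc_steady_state(s_p, pools, baseline).v_c
        approx, _ = abc_mm_approx(s_p, pools, baseline)
        assert exact == pytest.approx(approx, rel=0.05)

    def test_flux_monotone_in_substrate(self, baseline):
        pools = AbcPools(BP_total=0.05, T_total=0.002)
        rates = [abc_steady_state(s, pools, baseline).v_c
                 for s in np.logspace(-7, 2, 40)]
        assert all(b >= a * (1 - 1e-12) for a, b in zip(rates, rates[1:]))

    def test_flux_vanishes_as_bp_vanishes(self, baseline):
        fluxes = [abc_steady_state(0.01, AbcPools(bp, 0.001), baseline).v_c
                  for bp in (1e-2, 1e-4, 1e-6, 1e-8)]
        assert all(b < a for a, b in zip(fluxes, fluxes[1:]))
        assert fluxes[-1] < 1e-8


class TestAbcMMApprox:
    def test_no_binding_protein_km_equals_kd(self, baseline):
        _, fit = abc_mm_approx(0.0, AbcPools(0.0, 0.001), baseline)
        assert fit.K_M == pytest.approx(baseline.K_D, rel=1e-14)

    def test_vmax_saturates_with_binding_protein(self, baseline):
        kcat = baseline.k2p * baseline.k3p / (baseline.k2p + baseline.k3p)
        _, fit = abc_mm_approx(0.0, AbcPools(1e9, 0.001), baseline)
        assert fit.V_max == pytest.approx(kcat * 0.001, rel=1e-8)

    def test_km_inversely_proportional_to_bp_when_abundant(self, baseline):
        _, f1 = abc_mm_approx(0.0, AbcPools(1.0, 0.001), baseline)
        _, f2 = abc_mm_approx(0.0, AbcPools(2.0, 0.001), baseline)
        assert f1.K_M / f2.K_M == pytest.approx(
            (baseline.K_Tp + 2.0) / (baseline.K_Tp + 1.0), rel=1e-12)


class TestSpecificAffinity:
    def test_identity_case(self):
        assert specific_affinity(MMFit(V_max=1.0, K_M=1.0)) == 1.0

    def test_scales_with_bp_at_low_abundance(self, baseline):
        # a' = V'max/K'M is proportional to BP_total when BP_total << K_Tp
        bp = baseline.K_Tp / 1e4
        _, f1 = abc_mm_approx(0.0, AbcPools(bp, 0.001), baseline)
        _, f2 = abc_mm_approx(0.0, AbcPools(2 * bp, 0.001), baseline)
        assert specific_affinity(f2) == pytest.approx(
            2 * specific_affinity(f1), rel=1e-3)

    def test_pts_affinity_independent_of_substrate(self, baseline):
        a = baseline.k2 * 0.01 / baseline.K_T
        for s in (1e-6, 1e-3, 1.0):
            v = pts_uptake(s, 0.01, baseline)
            assert v / s <= a * (1 + 1e-12)
        # low-concentration slope equals k2*T_total/K_T
        assert pts_uptake(1e-9, 0.01, baseline) / 1e-9 == pytest.approx(a, rel=1e-4)


class TestEffectiveHalfSaturation:
    def test_recovers_exact_mm_curve(self):
        # saturating point far above K_M so V_max carries no truncation bias
        fit = effective_half_saturation(lambda s: 2.0 * s / (5.0 + s),
                                        grid=np.logspace(-3, 3, 50),
                                        saturating_conc=1e12)
        assert fit.K_M == pytest.approx(5.0, rel=1e-9)
        assert fit.V_max == pytest.approx(2.0 * 1e12 / (5.0 + 1e12), rel=1e-12)
        assert fit.max_rel_residual < 1e-6

    def test_km_decreases_with_binding_protein_abundance(self, baseline):
        kms = []
        for bp in (0.001, 0.01, 0.1, 1.0):
            pools = AbcPools(BP_total=bp, T_total=0.001)
            fit = effective_half_saturation(
                lambda s: abc_steady_state(s, pools, baseline).v_c)
            kms.append(fit.K_M)
        assert all(b < a for a, b in zip(kms, kms[1:]))

    def test_exact_km_approaches_approximation_at_high_bp_ratio(self, baseline):
        # validity needs BP >> T and T << k0r/k1p
        t = 1e-5
        rel_errs = []
        for bp in (0.01, 0.1, 1.0):
            pools = AbcPools(BP_total=bp, T_total=t)
            exact = effective_half_saturation(
                lambda s: abc_steady_state(s, pools, baseline).v_c).K_M
            _, mm = abc_mm_approx(0.0, pools, baseline)
            rel_errs.append(abs(exact - mm.K_M) / exact)
        assert all(b <= a for a, b in zip(rel_errs, rel_errs[1:]))
        assert rel_errs[-1] < 0.05

    def test_non_monotone_curve_rejected(self):
        with pytest.raises(ValueError, match="monotone"):
            effective_half_saturation(lambda s: math.sin(10 * s) + 2.0,
                                      grid=np.logspace(-2, 1, 30))

    def test_unbracketed_half_rate_rejected(self):
        # curve saturated everywhere on the grid: half-rate lies below it
        with pytest.raises(ValueError, match="bracket"):
            effective_half_saturation(lambda s: s / (1e-9 + s),
                                      grid=np.logspace(-2, 2, 20))

    def test_least_squares_diagnostic_agrees_on_mm_curve(self):
        grid = np.logspace(-3, 3, 40)
        fit = mm_least_squares_fit(grid, 3.0 * grid / (0.2 + grid))
        assert fit.V_max == pytest.approx(3.0, rel=1e-6)
        assert fit.K_M == pytest.approx(0.2, rel=1e-6)


class TestOdeOracle:
    def test_no_binding_protein_all_zero(self, baseline):
        sol = ode_relaxation_oracle(0.1, AbcPools(0.0, 0.01), baseline)
        assert sol.S_BP == pytest.approx(0.0, abs=1e-12)
        assert sol.v_c == pytest.approx(0.0, abs=1e-12)

    def test_flux_equals_translocation_rate(self, baseline):
        sol = ode_relaxation_oracle(0.01, AbcPools(0.05, 0.002), baseline)
        assert sol.v_c == pytest.approx(baseline.k2p * sol.T_S_BP, rel=1e-12)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    st.floats(min_value=-6, max_value=1),   # log10 S_p
    st.floats(min_value=-4, max_value=1),   # log10 BP_total
    st.floats(min_value=-6, max_value=-1),  # log10 T_total
    st.integers(min_value=0, max_value=10_000),
)
def test_steady_state_invariants_hold_over_parameter_space(ls, lbp, lt, pseed):
    """Nonnegativity and the two conservation identities across random draws."""
    params = random_transport_params(np.random.default_rng(pseed))
    pools = AbcPools(BP_total=10.0 ** lbp, T_total=10.0 ** lt)
    sol = abc_steady_state(10.0 ** ls, pools, params)
    scale = max(pools.BP_total, pools.T_total)
    assert min(sol.S_BP, sol.BP_free, sol.T_free, sol.T_S_BP) >= -1e-12 * scale
    r_bp, r_t = sol.conservation_residuals(pools, params)
    assert abs(r_bp) <= 1e-8 * scale
    assert abs(r_t) <= 1e-8 * scale
    assert 0.0 <= sol.v_c <= params.k2p * pools.T_total * (1 + 1e-9)
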