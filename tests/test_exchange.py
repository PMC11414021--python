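import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import solve_ivp

from fibrilkit.exchange import (
    DESTDataset,
    ExchangeParameters,
    IdentifiabilityWarning,
    SaturationScheme,
    bound_fraction,
    build_generator,
    equilibrium_magnetization,
    fit_dest,
    simulate_attenuation,
    simulate_profile,
)
from fibrilkit.presets import variant_parameters
from fibrilkit.synth import NoiseSpec, gen_dest_dataset

# indices into the homogeneous vector (1, MxA, MyA, MzA, MxB, MyB, MzB)
ZA, ZB = 3, 6


def ode_attenuation(params, offset, rf_field, sat_time, rtol=1e-10, atol=1e-12):
    """Independent oracle: adaptive ODE integration of the same generator."""
    m0 = equilibrium_magnetization(params)
    vals = []
    for rf in (rf_field, 0.0):
        G = build_generator(params, offset, rf)
        sol = solve_ivp(
            lambda t, y: G @ y, (0.0, sat_time), m0,
            method="DOP853", rtol=rtol, atol=atol,
        )
        vals.append(sol.y[ZA, -1])
    return vals[0] / vals[1]


class TestExchangeParameters:
    def test_populations_sum_to_one(self):
        p = ExchangeParameters(kon_app=4.3, koff=900.0)
        assert p.p_bound == pytest.approx(4.3 / 904.3)
        assert p.p_free + p.p_bound == pytest.approx(1.0)
        assert 0 < p.p_bound < 1

    @pytest.mark.parametrize(
        "bad",
        [
            {"kon_app": -1.0, "koff": 900.0},
            {"kon_app": 4.3, "koff": 0.0},
            {"kon_app": 4.3, "koff": -5.0},
            {"kon_app": 4.3, "koff": 900.0, "r2_free": -1.0},
            {"kon_app": 4.3, "koff": 900.0, "r2_dark": 1.0},  # < r2_free
            {"kon_app": float("nan"), "koff": 900.0},
            {"kon_app": 4.3, "koff": float("inf")},
        ],
    )
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            ExchangeParameters(**bad)

    def test_error_names_offending_field(self):
        with pytest.raises(ValueError, match="koff"):
            ExchangeParameters(kon_app=4.3, koff=float("nan"))


class TestSaturationScheme:
    def test_defaults(self, scheme):
        assert scheme.sat_time == 0.7
        assert scheme.rf_fields == (180.0, 350.0)
        assert len(scheme.offsets) == 15
        assert max(scheme.offsets) == 35000.0
        assert min(scheme.offsets) == -35000.0

    def test_invalid(self):
        with pytest.raises(ValueError):
            SaturationScheme(sat_time=0.0)
        with pytest.raises(ValueError):
            SaturationScheme(rf_fields=(-10.0,))
        with pytest.raises(ValueError):
            SaturationScheme(offsets=(float("inf"),))


class TestBuildGenerator:
    def test_pure_exchange_conserves_total_mz(self):
        # all relaxation ~0, rf 0: column sums of the Mz block vanish
        p = ExchangeParameters(
            kon_app=5.0, koff=50.0, r1_free=1e-12, r2_free=1e-12,
            r1_dark=1e-12, r2_dark=1e-12, delta_free=0.0, delta_dark=0.0,
        )
        G = build_generator(p, 0.0, 0.0)
        assert G[ZA, ZA] + G[ZB, ZA] == pytest.approx(0.0, abs=1e-10)
        assert G[ZA, ZB] + G[ZB, ZB] == pytest.approx(0.0, abs=1e-10)

    def test_no_exchange_decouples_mz_blocks(self):
        # with kon_app = 0 the B pool never populates, so the visible-state
        # dynamics are independent of the B-side rates entirely
        p = ExchangeParameters(kon_app=0.0, koff=900.0)
        G = build_generator(p, 1000.0, 200.0)
        assert np.all(G[4:, 1:4] == 0.0)  # nothing flows A -> B
        a = simulate_attenuation(p, 1000.0, 200.0, 0.3)
        b = simulate_attenuation(p.replace(koff=5000.0, r2_dark=90000.0),
                                 1000.0, 200.0, 0.3)
        assert a == pytest.approx(b, abs=1e-12)

    def test_eigenvalues_nonpositive_real_parts(self, rng):
        # brute-force stability check over a grid of physical parameter sets
        for _ in range(40):
            p = ExchangeParameters(
                kon_app=10 ** rng.uniform(-2, 1.5),
                koff=10 ** rng.uniform(1, 4),
                r1_free=rng.uniform(0.5, 5.0),
                r2_free=rng.uniform(1.0, 50.0),
                r1_dark=rng.uniform(0.5, 5.0),
                r2_dark=10 ** rng.uniform(2, 4.6),
                delta_free=rng.uniform(-3000, 3000),
                delta_dark=rng.uniform(-3000, 3000),
            )
            G = build_generator(p, rng.uniform(-35000, 35000),
                                float(rng.choice([180.0, 350.0])))
            eig = np.linalg.eigvals(G[1:, 1:])
            assert np.all(eig.real <= 1e-9)

    def test_paper_regime_eigenvalues(self):
        p = ExchangeParameters(kon_app=4.3, koff=900.0, r1_free=3.0,
                               r2_free=9.1, r1_dark=3.0, r2_dark=31000.0)
        G = build_generator(p, 2000.0, 350.0)
        assert np.all(np.linalg.eigvals(G[1:, 1:]).real <= 1e-9)

    def test_nonfinite_inputs_rejected(self, wt_params):
        with pytest.raises(ValueError, match="offset"):
            build_generator(wt_params, float("nan"), 350.0)
        with pytest.raises(ValueError, match="rf_field"):
            build_generator(wt_params, 0.0, float("inf"))


class TestSimulateAttenuation:
    def test_zero_rf_is_exactly_one(self, wt_params):
        assert simulate_attenuation(wt_params, 5000.0, 0.0, 0.7) == 1.0

    def test_far_offset_is_one(self, wt_params):
        att = simulate_attenuation(wt_params, 1e9, 350.0, 0.7)
        assert att == pytest.approx(1.0, abs=1e-3)

    def test_matches_ode_oracle_at_reference_point(self):
        p = ExchangeParameters(kon_app=4.3, koff=900.0, r1_free=3.0,
                               r2_free=9.1, r1_dark=3.0, r2_dark=31000.0,
                               delta_free=0.0, delta_dark=0.0)
        # short sat_time keeps the oscillatory integration affordable here;
        # the full 700 ms / 35 kHz regime is covered by the acceptance suite
        want = ode_attenuation(p, 5000.0, 350.0, 0.05)
        got = simulate_attenuation(p, 5000.0, 350.0, 0.05)
        assert got == pytest.approx(want, abs=1e-6)

    def test_attenuation_bounded(self, rng):
        for _ in range(25):
            p = ExchangeParameters(
                kon_app=10 ** rng.uniform(-2, 1.5),
                koff=10 ** rng.uniform(1, 4),
                r1_free=rng.uniform(0.5, 5.0),
                r2_free=rng.uniform(1.0, 50.0),
                r1_dark=rng.uniform(0.5, 5.0),
                r2_dark=10 ** rng.uniform(2, 4.6),
                delta_free=rng.uniform(-3000, 3000),
                delta_dark=rng.uniform(-3000, 3000),
            )
            att = simulate_attenuation(
                p, rng.uniform(-35000, 35000),
                float(rng.choice([180.0, 350.0])), 0.7)
            assert -1e-9 <= att <= 1.0 + 1e-9

    def test_on_resonance_below_far_offset(self, wt_params):
        on = simulate_attenuation(wt_params, wt_params.delta_dark, 350.0, 0.7)
        far = simulate_attenuation(wt_params, 1e7, 350.0, 0.7)
        assert on < far

    def test_single_spin_cw_steady_state(self):
        # closed-form continuous-wave saturation limit for an isolated spin
        r1, r2 = 3.0, 9.1
        p = ExchangeParameters(kon_app=0.0, koff=1000.0, r1_free=r1,
                               r2_free=r2, r1_dark=r1, r2_dark=r2,
                               delta_free=0.0, delta_dark=0.0)
        for offset, rf in ((2000.0, 350.0), (5000.0, 180.0)):
            dw = 2 * math.pi * offset
            w1 = 2 * math.pi * rf
            want = r1 * (r2**2 + dw**2) / (r1 * (r2**2 + dw**2) + w1**2 * r2)
            got = simulate_attenuation(p, offset, rf, sat_time=10.0 / r1)
            assert got == pytest.approx(want, rel=0.01)

    def test_invalid_sat_time(self, wt_params):
        with pytest.raises(ValueError):
            simulate_attenuation(wt_params, 0.0, 350.0, sat_time=0.0)


class TestSimulateProfile:
    def test_zero_rf_profile_all_ones(self, wt_params):
        scheme = SaturationScheme(rf_fields=(0.0,),
                                  offsets=(0.0, 5000.0, -20000.0))
        prof = simulate_profile(wt_params, scheme)
        np.testing.assert_allclose(
            prof.table["attenuation"].to_numpy(), 1.0, atol=1e-12)

    def test_symmetric_offsets_on_carrier(self):
        p = ExchangeParameters(kon_app=4.3, koff=900.0,
                               delta_free=0.0, delta_dark=0.0)
        offs = (20000.0, 10000.0, 3000.0)
        scheme = SaturationScheme(rf_fields=(350.0,),
                                  offsets=offs + tuple(-o for o in offs))
        t = simulate_profile(p, scheme).table.set_index("offset_hz")
        for o in offs:
            assert abs(t.loc[o, "attenuation"] - t.loc[-o, "attenuation"]) < 1e-10

    def test_wing_broadening_monotone_in_pb_r2dark(self, wt_params, scheme):
        # halving koff at fixed kon_app raises p_B * r2_dark
        base = simulate_profile(wt_params, scheme).table["attenuation"].to_numpy()
        prev = base
        for koff in (450.0, 225.0):
            cur = simulate_profile(
                wt_params.replace(koff=koff), scheme
            ).table["attenuation"].to_numpy()
            assert np.all(cur <= prev + 1e-12)
            prev = cur

    def test_shape(self, wt_params, scheme):
        prof = simulate_profile(wt_params, scheme)
        assert prof.n_points == len(scheme.rf_fields) * len(scheme.offsets)
        assert prof.rf_fields == sorted(scheme.rf_fields)


class TestDESTDataset:
    def test_rejects_out_of_range_attenuation(self):
        with pytest.raises(ValueError):
            DESTDataset(pd.DataFrame({
                "rf_field_hz": [180.0], "offset_hz": [0.0],
                "attenuation": [1.5]}))

    def test_rejects_duplicate_offsets(self):
        with pytest.raises(ValueError, match="duplicate"):
            DESTDataset(pd.DataFrame({
                "rf_field_hz": [180.0, 180.0], "offset_hz": [0.0, 0.0],
                "attenuation": [0.9, 0.8]}))

    def test_rejects_missing_columns(self):
        with pytest.raises(ValueError, match="missing"):
            DESTDataset(pd.DataFrame({"offset_hz": [0.0]}))


class TestFitDest:
    def test_noiseless_round_trip(self, wt_params, scheme):
        data = simulate_profile(wt_params, scheme)
        res = fit_dest(data, scheme, wt_params.replace(koff=500.0),
                       koff_init=300.0)
        assert res.converged and res.identifiable
        assert res.koff_hat == pytest.approx(900.0, rel=0.01)
        assert res.pB_hat == pytest.approx(
            wt_params.kon_app / (wt_params.kon_app + res.koff_hat))

    def test_noisy_recovery_within_15_percent(self, wt_params, scheme):
        data = gen_dest_dataset(wt_params, scheme,
                                NoiseSpec(sigma=0.01, seed=1))
        res = fit_dest(data, scheme, wt_params, koff_init=1500.0)
        assert res.koff_hat == pytest.approx(900.0, rel=0.15)
        assert res.koff_se > 0

    def test_all_ones_raises_identifiability_warning(self, wt_params, scheme):
        rows = [{"rf_field_hz": rf, "offset_hz": o, "attenuation": 1.0}
                for rf in scheme.rf_fields for o in scheme.offsets]
        data = DESTDataset(pd.DataFrame(rows))
        with pytest.warns(IdentifiabilityWarning):
            res = fit_dest(data, scheme, wt_params)
        assert not res.identifiable
        assert res.koff_se == math.inf

    def test_fixed_params_echoed(self, wt_params, scheme):
        data = simulate_profile(wt_params, scheme)
        res = fit_dest(data, scheme, wt_params)
        assert res.fixed_params["kon_app"] == wt_params.kon_app
        assert res.fixed_params["r2_dark"] == wt_params.r2_dark
        assert res.fixed_params["sat_time"] == scheme.sat_time
        assert "koff" not in res.fixed_params
        assert res.n_points == data.n_points

    def test_bootstrap_se_agrees_in_magnitude(self, wt_params, small_scheme):
        data = gen_dest_dataset(wt_params, small_scheme,
                                NoiseSpec(sigma=0.01, seed=3))
        jac = fit_dest(data, small_scheme, wt_params)
        boot = fit_dest(data, small_scheme, wt_params,
                        n_bootstrap=30, seed=0)
        assert boot.koff_se == pytest.approx(jac.koff_se, rel=1.0)

    def test_invalid_koff_init(self, wt_params, scheme):
        data = simulate_profile(wt_params, scheme)
        with pytest.raises(ValueError):
            fit_dest(data, scheme, wt_params, koff_init=-5.0)


class TestBoundFraction:
    def test_wt_row(self):
        # 4.3 / (4.3 + 900) -> 0.475 %, printed as 0.5 %
        val = bound_fraction(4.3, 900.0)
        assert val == pytest.approx(0.4755, abs=5e-4)
        assert round(val, 1) == 0.5

    def test_dm_row(self):
        val = bound_fraction(4.3, 1900.0)
        assert val == pytest.approx(0.2258, abs=5e-4)
        assert round(val, 1) == 0.2

    def test_zero_kon(self):
        assert bound_fraction(0.0, 900.0) == 0.0

    def test_ratio_formula_exposed(self):
        assert bound_fraction(4.3, 900.0, formula="ratio") == pytest.approx(
            100.0 * 4.3 / 900.0)

    def test_rejects_bad_rates(self):
        with pytest.raises(ValueError):
            bound_fraction(4.3, 0.0)
        with pytest.raises(ValueError):
            bound_fraction(-1.0, 900.0)
        with pytest.raises(ValueError):
            bound_fraction(4.3, 900.0, formula="nope")


def test_qm_preset_has_no_bound_state(scheme):
    qm = variant_parameters("qm")
    assert qm.p_bound == 0.0
    prof = simulate_profile(qm, SaturationScheme(
        sat_time=0.7, rf_fields=(350.0,), offsets=(35000.0, -35000.0)))
    # far from the amide resonance and with p_B = 0, nothing saturates
    np.testing.assert_allclose(
        prof.table["attenuation"].to_numpy(), 1.0, atol=1e-2)
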