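"""Forward degassing model: stepping, mixing, trajectories and their invariants."""

import numpy as np
import pytest

from streamdegas import (
    GroundwaterEndMember,
    ModelParams,
    add_groundwater,
    co2_equilibrium,
    fractionation_factors,
    initial_state,
    simulate,
    step,
    trajectory_curve,
)


def _em_at_atmospheric_equilibrium(temp=4.0, ph=6.0, d13c=-20.0):
    """End-member whose CO2* exactly equals atmospheric equilibrium."""
    co2eq = co2_equilibrium(temp, 380.0)
    probe = initial_state(GroundwaterEndMember(1000.0, ph, d13c, temp))
    dic = 1000.0 * co2eq / probe.carbonate.co2
    return GroundwaterEndMember(dic, ph, d13c, temp)


class TestStep:
    def test_zero_gradient_leaves_concentrations_unchanged(self):
        state = initial_state(_em_at_atmospheric_equilibrium())
        out = step(state, ModelParams(dt=0.01))
        assert out.time == pytest.approx(state.time + 0.01)
        assert out.carbonate.dic == pytest.approx(state.carbonate.dic, rel=1e-12)
        assert out.carbonate.ph == pytest.approx(state.carbonate.ph, abs=1e-9)
        assert out.cum_evaded == pytest.approx(0.0, abs=1e-9)

    def test_isotopes_keep_equilibrating_at_zero_net_flux(self):
        """At CO2 = CO2eq the gross fluxes still exchange carbon, so d13C-CO2
        relaxes toward the atmospheric-equilibrium value d13c_atm + eps_aq_g."""
        params = ModelParams(dt=0.01)
        state = initial_state(_em_at_atmospheric_equilibrium(d13c=-20.0))
        target = params.d13c_atm + fractionation_factors(4.0).eps_aq_g
        gap0 = abs(state.isotope.d13c_co2 - target)
        out = step(state, params)
        assert abs(out.isotope.d13c_co2 - target) < gap0

    def test_zero_k_changes_nothing_but_time(self):
        state = initial_state(GroundwaterEndMember(1200.0, 5.5, -25.0, 4.0))
        out = step(state, ModelParams(k_gas=0.0, dt=0.05))
        assert out.time == pytest.approx(0.05)
        assert out.carbonate.dic == state.carbonate.dic
        assert out.isotope.d13c_dic == pytest.approx(state.isotope.d13c_dic, abs=1e-12)

    def test_halving_dt_changes_end_state_by_less_than_point1_percent(self, fig1_em):
        end = {}
        for dt in (0.004, 0.002):
            params = ModelParams(dt=dt, stop_ratio=1.0, max_time=0.2)
            end[dt] = simulate(fig1_em, params).arrays["DIC_umol_L"][-1]
        assert abs(end[0.002] - end[0.004]) / end[0.002] < 1e-3

    def test_no_overshoot_below_equilibrium_even_with_large_dt(self):
        # one output step of 1 day at k = 15/d must be sub-divided internally
        state = initial_state(GroundwaterEndMember(1200.0, 5.5, -25.0, 4.0))
        out = step(state, ModelParams(dt=1.0))
        assert out.carbonate.co2 >= co2_equilibrium(4.0, 380.0)


class TestAddGroundwater:
    def test_zero_fraction_is_identity(self):
        state = initial_state(GroundwaterEndMember(900.0, 5.2, -26.0, 4.0))
        assert add_groundwater(state, GroundwaterEndMember(1500.0, 5.0, -25.0, 4.0), 0.0) is state

    @pytest.mark.parametrize("fraction", [0.1, 1.0, 7.5])
    def test_mixing_identical_waters_is_identity(self, fraction):
        gw = GroundwaterEndMember(1500.0, 5.0, -25.0, 4.0)
        state = initial_state(gw)
        out = add_groundwater(state, gw, fraction)
        assert out.carbonate.dic == pytest.approx(state.carbonate.dic, rel=1e-12)
        assert out.carbonate.ph == pytest.approx(state.carbonate.ph, abs=1e-9)
        assert out.isotope.d13c_dic == pytest.approx(
            state.isotope.d13c_dic, abs=1e-9
        )

    def test_mass_balance_matches_hand_mixing(self):
        state = initial_state(GroundwaterEndMember(600.0, 5.8, -22.0, 4.0))
        gw = GroundwaterEndMember(1500.0, 5.0, -25.0, 4.0)
        f = 0.4
        out = add_groundwater(state, gw, f)
        assert out.carbonate.dic == pytest.approx((600.0 + f * 1500.0) / (1 + f), rel=1e-12)
        hv_mix = (600.0 * (1 - 0.022) + f * 1500.0 * (1 - 0.025)) / (1 + f)
        assert out.carbonate.dic * (1 + out.isotope.d13c_dic / 1000.0) == pytest.approx(
            hv_mix, rel=1e-12
        )
        assert out.cum_gw_added == pytest.approx(out.carbonate.dic - 600.0, rel=1e-9)
        # mixing with richer groundwater pulls the stream back toward it
        assert out.carbonate.dic > 600.0
        assert out.isotope.d13c_dic < -22.0
        assert out.carbonate.ph < 5.8

    def test_negative_fraction_rejected(self):
        state = initial_state(GroundwaterEndMember(600.0, 5.8, -22.0, 4.0))
        with pytest.raises(ValueError, match="volume_fraction"):
            add_groundwater(state, GroundwaterEndMember(1500.0, 5.0, -25.0, 4.0), -0.1)


class TestSimulateInvariants:
    def test_rejects_undersaturated_end_member(self):
        with pytest.raises(ValueError, match="supersaturated"):
            simulate(GroundwaterEndMember(30.0, 7.0, -20.0, 4.0))

    def test_carbon_conservation_every_state(self, fig1_traj):
        a = fig1_traj.arrays
        dic0 = a["DIC_umol_L"][0]
        resid = dic0 - a["cum_evaded_umol_L"] + a["cum_gw_added_umol_L"] - a["DIC_umol_L"]
        assert np.max(np.abs(resid)) / dic0 < 1e-6

    def test_c13_conservation_every_state(self, fig1_traj):
        a = fig1_traj.arrays
        c13 = 0.011180 * a["DIC_umol_L"] * (1.0 + a["d13C_DIC_permil"] / 1000.0)
        resid = c13[0] - a["cum_evaded_c13"] + a["cum_gw_added_c13"] - c13
        assert np.max(np.abs(resid)) / c13[0] < 1e-6

    def test_held_alkalinity_constant(self, fig1_traj):
        alk = fig1_traj.arrays["alk_ueq_L"]
        assert np.max(np.abs(alk - alk[0])) < 1e-3

    def test_monotone_co2_ph_and_d13c(self, fig1_traj):
        a = fig1_traj.arrays
        assert np.all(np.diff(a["co2_umol_L"]) < 0)
        assert np.all(np.diff(a["pH"]) > 0)
        assert np.all(np.diff(a["d13C_DIC_permil"]) > 0)
        assert np.all(np.diff(a["cum_evaded_umol_L"]) > 0)

    def test_zero_k_trajectory_is_constant(self, fig1_em):
        traj = simulate(fig1_em, ModelParams(k_gas=0.0, max_time=0.05))
        dic = traj.arrays["DIC_umol_L"]
        assert np.ptp(dic) == 0.0
        assert np.ptp(traj.arrays["d13C_DIC_permil"]) == pytest.approx(0.0, abs=1e-12)

    def test_time_strictly_increasing(self, fig1_traj):
        assert np.all(np.diff(fig1_traj.arrays["time_d"]) > 0)


class TestIsotopeBehaviour:
    def test_rayleigh_limit_all_co2_no_invasion(self):
        """With pCO2_atm = 0 and essentially no bicarbonate (pH 3) the bulk
        delta must follow the closed-form Rayleigh law d = d0 + eps_k ln f."""
        em = GroundwaterEndMember(2000.0, 3.0, -25.0, 4.0)
        params = ModelParams(pco2_atm=0.0, stop_ratio=1.0, max_time=0.35, dt=2e-4)
        traj = simulate(em, params)
        f = traj.arrays["DIC_umol_L"] / traj.arrays["DIC_umol_L"][0]
        keep = f >= 0.01
        eps_k = fractionation_factors(4.0).eps_k
        predicted = -25.0 + eps_k * np.log(f[keep])
        assert np.max(np.abs(traj.arrays["d13C_DIC_permil"][keep] - predicted)) < 0.05

    def test_asymptotic_equilibrium_with_atmosphere(self, fig1_em):
        """Run well past the concentration equilibrium so the (slower)
        isotopic equilibration completes: d13C-CO2 -> d13c_atm + eps_aq_g."""
        params = ModelParams(stop_ratio=1.0, max_time=3.0)
        traj = simulate(fig1_em, params)
        target = params.d13c_atm + fractionation_factors(4.0).eps_aq_g
        assert traj.arrays["d13C_CO2_permil"][-1] == pytest.approx(target, abs=0.2)
        assert traj.arrays["co2_umol_L"][-1] == pytest.approx(
            co2_equilibrium(4.0, 380.0), rel=1e-3
        )

    def test_sigmoid_slow_then_fast(self, fig1_traj):
        """Little enrichment over the first quarter of DIC loss, ~2 permil by
        half, accelerating after."""
        a = fig1_traj.arrays
        dic = a["DIC_umol_L"]
        rise = a["d13C_DIC_permil"] - a["d13C_DIC_permil"][0]
        rise_at = lambda frac_dic: np.interp(
            dic[0] * (1 - frac_dic), dic[::-1], rise[::-1]
        )
        assert rise_at(0.25) < 0.8
        assert rise_at(0.50) == pytest.approx(2.0, abs=0.5)
        assert rise_at(0.75) - rise_at(0.50) > rise_at(0.50) - rise_at(0.25)


class TestTrajectoryCurve:
    def test_fraction_axis_well_formed(self, fig1_em):
        curve = trajectory_curve(fig1_em, n_points=120)
        f = curve["fraction_CO2_lost"].to_numpy()
        assert len(curve) == 120
        assert f[0] == 0.0
        assert np.all(np.diff(f) > 0)

    def test_lower_ph_needs_more_loss_for_1_permil_rise(self):
        frac_at_rise = {}
        for ph in (4.0, 5.5):
            curve = trajectory_curve(
                GroundwaterEndMember(1500.0, ph, -25.0, 4.0), n_points=400
            )
            frac_at_rise[ph] = np.interp(
                -24.0, curve["d13C_DIC_permil"], curve["fraction_CO2_lost"]
            )
        assert frac_at_rise[4.0] > frac_at_rise[5.5]


class TestInflow:
    def test_inflow_pulls_stream_toward_groundwater(self):
        """At fixed time, continuous groundwater addition raises DIC, lowers
        pH and lowers d13C-DIC relative to the no-inflow parcel."""
        em = GroundwaterEndMember(1500.0, 5.0, -25.0, 4.0)
        at = {}
        for rate in (0.0, 3.0):
            traj = simulate(em, ModelParams(gw_inflow=rate, stop_ratio=1.0, max_time=0.12))
            a = traj.arrays
            i = np.searchsorted(a["time_d"], 0.1)
            at[rate] = (a["DIC_umol_L"][i], a["pH"][i], a["d13C_DIC_permil"][i])
        assert at[3.0][0] > at[0.0][0]
        assert at[3.0][1] < at[0.0][1]
        assert at[3.0][2] < at[0.0][2]

    def test_bookkeeping_with_inflow(self):
        em = GroundwaterEndMember(1500.0, 5.0, -25.0, 4.0)
        traj = simulate(em, ModelParams(gw_inflow=2.0, stop_ratio=1.0, max_time=0.3))
        a = traj.arrays
        resid = a["DIC_umol_L"][0] - a["cum_evaded_umol_L"] + a["cum_gw_added_umol_L"] - a["DIC_umol_L"]
        assert np.max(np.abs(resid)) / a["DIC_umol_L"][0] < 1e-6
        assert np.all(np.diff(a["fraction_CO2_lost"]) > 0)


@pytest.mark.parametrize(
    "kwargs",
    [
        {"k_gas": -1.0},
        {"dt": 0.0},
        {"stop_ratio": 0.9},
        {"gw_inflow": -0.5},
        {"pco2_atm": -10.0},
    ],
)
def test_invalid_params_rejected(kwargs):
    with pytest.raises(ValueError):
        ModelParams(**kwargs)
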