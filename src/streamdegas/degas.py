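"""Time-forward CO2 degassing of a groundwater-fed stream parcel.

The model follows a small plug of shallow groundwater after it discharges
to the surface.  Each time step:

1. gas exchange removes a gross CO2 flux ``k_gas * CO2 * dt`` carrying
   d13C-CO2(aq) + eps_k, and an atmospheric back-flux ``k_gas * CO2eq * dt``
   invades carrying d13C_atm + eps_k + eps_aq_g (the net flux is the
   familiar ``k_gas * (CO2 - CO2eq) * dt``);
2. the remaining DIC is re-speciated at the pH that holds the
   charge-balance carbonate alkalinity constant (CO2 exchange cannot change
   it), found by a warm-started Newton iteration on [H+];
3. species deltas are re-partitioned from the bulk d13C-DIC.

With that flux labelling, isotopic equilibrium with the atmosphere falls
out correctly: the net 13C flux vanishes exactly when
d13C-CO2(aq) = d13C_atm + eps_aq_g.

Optionally, groundwater is continuously added to the parcel (a constant
fraction of the parcel volume per day), which mixes DIC, alkalinity and
13C conservatively and pulls the stream back toward the end-member.

Steps are forward-Euler with automatic sub-division so that the per-step
gross CO2 turnover ``k_gas * dt_sub`` stays below 5%, which bounds the
discretization error and guarantees no overshoot below atmospheric
equilibrium within a step.

Carbon bookkeeping invariants, exact by construction and asserted in the
test-suite: DIC(t) = DIC(0) - cum_evaded + cum_gw_added, and the same
balance for the linearized 13C pool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .carbonate import (
    CarbonateState,
    equilibrium_constants,
    speciate,
    total_alkalinity,
)
from .isotopes import (
    R_VPDB,
    EpsilonSet,
    IsotopeState,
    fractionation_factors,
    species_deltas,
)

__all__ = [
    "GroundwaterEndMember",
    "ModelParams",
    "StreamState",
    "Trajectory",
    "step",
    "add_groundwater",
    "simulate",
    "trajectory_curve",
    "trajectory_family",
]

#: maximum fraction of the CO2 pool exchanged in one Euler sub-step
_MAX_TURNOVER = 0.05


@dataclass(frozen=True)
class GroundwaterEndMember:
    """Shallow-groundwater end-member: the model's initial condition."""

    dic: float  #: umol/L
    ph: float
    d13c_dic: float  #: permil VPDB
    temperature: float  #: deg C


@dataclass(frozen=True)
class ModelParams:
    """Gas-exchange and integration parameters.

    ``k_gas`` is the first-order gas-exchange coefficient (1/day; default
    15/d, mid-range of the 7-25/d typical of these streams), ``dt`` the
    output time step (days), ``gw_inflow`` the groundwater addition rate as
    a fraction of parcel volume per day, and ``stop_ratio`` the CO2/CO2eq
    ratio at which a simulation stops (or at ``max_time``, whichever is
    first).
    """

    k_gas: float = 15.0
    dt: float = 0.002
    pco2_atm: float = 380.0
    d13c_atm: float = -8.0
    gw_inflow: float = 0.0
    max_time: float = 10.0
    stop_ratio: float = 1.01

    def __post_init__(self) -> None:
        if self.k_gas < 0:
            raise ValueError(f"k_gas must be >= 0, got {self.k_gas!r}")
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt!r}")
        if self.pco2_atm < 0:
            raise ValueError(f"pco2_atm must be >= 0, got {self.pco2_atm!r}")
        if self.gw_inflow < 0:
            raise ValueError(f"gw_inflow must be >= 0, got {self.gw_inflow!r}")
        if self.stop_ratio < 1.0:
            raise ValueError(f"stop_ratio must be >= 1, got {self.stop_ratio!r}")
        if self.max_time <= 0:
            raise ValueError(f"max_time must be > 0, got {self.max_time!r}")


@dataclass(frozen=True)
class StreamState:
    """One instant of the simulated parcel.

    ``cum_evaded`` / ``cum_gw_added`` are net concentration-equivalents
    (umol/L) of CO2 lost to the atmosphere and of DIC gained from
    groundwater mixing since t = 0, defined so that
    DIC(t) = DIC(0) - cum_evaded + cum_gw_added holds exactly.  The
    ``*_c13`` twins carry the same balance for the linearized 13C pool.
    """

    time: float
    carbonate: CarbonateState
    isotope: IsotopeState
    cum_evaded: float = 0.0
    cum_gw_added: float = 0.0
    cum_evaded_c13: float = 0.0
    cum_gw_added_c13: float = 0.0


def _solve_h(
    dic: float, anc: float, k1: float, k2: float, kw: float, h0: float
) -> float:
    """[H+] (mol/L) such that charge-balance alkalinity equals ``anc`` (eq/L).

    Warm-started Newton iteration; alkalinity is strictly decreasing in
    [H+] so the root is unique.  Falls back to a bracketed solve if Newton
    leaves the physical range.
    """
    h = h0
    for _ in range(60):
        a = k1 / h
        b = a * k2 / h
        den = 1.0 + a + b
        g = dic * (a + 2.0 * b) / den + kw / h - h - anc
        if abs(g) < 1e-16:
            return h
        dca = dic * ((a + 2.0 * b) ** 2 - (a + 4.0 * b) * den) / (h * den * den)
        gp = dca - kw / (h * h) - 1.0
        hn = h - g / gp
        if not math.isfinite(hn) or hn <= 1e-13 or hn >= 1e-1:
            break
        if abs(hn - h) <= 1e-15 * h:
            return hn
        h = hn

    def residual(ph: float) -> float:
        hh = 10.0 ** (-ph)
        aa = k1 / hh
        bb = aa * k2 / hh
        dd = 1.0 + aa + bb
        return dic * (aa + 2.0 * bb) / dd + kw / hh - hh - anc

    lo, hi = residual(2.0), residual(12.0)
    if lo * hi > 0.0:
        raise ValueError(
            f"no pH in [2, 12] holds alkalinity {anc * 1e6:.6g} ueq/L "
            f"at DIC {dic * 1e6:.6g} umol/L"
        )
    return 10.0 ** (-brentq(residual, 2.0, 12.0, xtol=1e-13, rtol=8.9e-16))


class _Parcel:
    """Mutable scalar state of the integration (mol/L units internally)."""

    __slots__ = (
        "dic",
        "h",
        "hv",
        "anc",
        "time",
        "volume",
        "cum_evaded",
        "cum_gw_added",
        "cum_evaded_hv",
        "cum_gw_added_hv",
        "evaded_amount",
        "delivered_amount",
    )

    def __init__(self, dic: float, h: float, hv: float, anc: float) -> None:
        self.dic = dic
        self.h = h
        self.hv = hv  # heavy-pool proxy DIC*(1 + d13C/1000), mol/L
        self.anc = anc
        self.time = 0.0
        self.volume = 1.0
        self.cum_evaded = 0.0
        self.cum_gw_added = 0.0
        self.cum_evaded_hv = 0.0
        self.cum_gw_added_hv = 0.0
        self.evaded_amount = 0.0
        self.delivered_amount = 0.0


def _substep(
    p: _Parcel,
    dts: float,
    k_gas: float,
    co2eq: float,
    label_in: float,
    eps: EpsilonSet,
    k1: float,
    k2: float,
    kw: float,
    gw: tuple[float, float, float, float] | None,
    gw_inflow: float,
) -> None:
    """Advance one Euler sub-step: gas exchange, pH re-solve, optional inflow."""
    a = k1 / p.h
    b = a * k2 / p.h
    den = 1.0 + a + b
    co2 = p.dic / den
    d_dic = (p.hv / p.dic - 1.0) * 1000.0
    # species partitioning of the bulk delta (first-order arithmetic)
    d_hco3 = d_dic - (1.0 / den) * eps.eps_co2_hco3 + (b / den) * eps.eps_hco3_co3
    d_out = d_hco3 + eps.eps_co2_hco3 + eps.eps_k  # evading CO2
    f_out = k_gas * co2 * dts
    f_in = k_gas * co2eq * dts
    d_dic_net = f_out - f_in
    d_hv_net = f_out * (1.0 + d_out / 1000.0) - f_in * (1.0 + label_in / 1000.0)
    p.dic -= d_dic_net
    p.hv -= d_hv_net
    p.cum_evaded += d_dic_net
    p.cum_evaded_hv += d_hv_net
    p.evaded_amount += d_dic_net * p.volume
    p.h = _solve_h(p.dic, p.anc, k1, k2, kw, p.h)
    p.time += dts

    if gw is not None and gw_inflow > 0.0:
        w = gw_inflow * dts
        gw_dic, gw_anc, gw_hv, gw_co2 = gw
        dic_new = (p.dic + w * gw_dic) / (1.0 + w)
        hv_new = (p.hv + w * gw_hv) / (1.0 + w)
        p.anc = (p.anc + w * gw_anc) / (1.0 + w)
        p.cum_gw_added += dic_new - p.dic
        p.cum_gw_added_hv += hv_new - p.hv
        p.delivered_amount += gw_co2 * w * p.volume
        p.volume *= 1.0 + w
        p.dic = dic_new
        p.hv = hv_new
        p.h = _solve_h(p.dic, p.anc, k1, k2, kw, p.h)


_RECORD_KEYS = (
    "time_d",
    "DIC_umol_L",
    "pH",
    "co2_umol_L",
    "hco3_umol_L",
    "co3_umol_L",
    "d13C_DIC_permil",
    "d13C_CO2_permil",
    "d13C_HCO3_permil",
    "d13C_CO3_permil",
    "alk_ueq_L",
    "alk_carb_ueq_L",
    "cum_evaded_umol_L",
    "cum_gw_added_umol_L",
    "cum_evaded_c13",
    "cum_gw_added_c13",
    "fraction_CO2_lost",
)


def _record(rows: list[list[float]], p: _Parcel, eps: EpsilonSet, k1: float, k2: float, kw: float) -> None:
    a = k1 / p.h
    b = a * k2 / p.h
    den = 1.0 + a + b
    co2 = p.dic / den
    hco3 = p.dic * a / den
    co3 = p.dic * b / den
    d_dic = (p.hv / p.dic - 1.0) * 1000.0
    d_hco3 = d_dic - (1.0 / den) * eps.eps_co2_hco3 + (b / den) * eps.eps_hco3_co3
    rows.append(
        [
            p.time,
            p.dic * 1e6,
            -math.log10(p.h),
            co2 * 1e6,
            hco3 * 1e6,
            co3 * 1e6,
            d_dic,
            d_hco3 + eps.eps_co2_hco3,
            d_hco3,
            d_hco3 - eps.eps_hco3_co3,
            (p.dic * (a + 2.0 * b) / den + kw / p.h - p.h) * 1e6,
            p.dic * (a + 2.0 * b) / den * 1e6,
            p.cum_evaded * 1e6,
            p.cum_gw_added * 1e6,
            p.cum_evaded_hv * 1e6 * R_VPDB,
            p.cum_gw_added_hv * 1e6 * R_VPDB,
            p.evaded_amount / p.delivered_amount,
        ]
    )


def _run(
    em: GroundwaterEndMember,
    params: ModelParams,
    *,
    stop_dic: float | None = None,
    t_end: float | None = None,
    require_supersaturated: bool = True,
) -> dict[str, np.ndarray]:
    """Integrate the model and return per-``dt`` arrays (umol/L scale).

    ``stop_dic`` (umol/L) lets callers stop once DIC falls below a
    threshold (used by the inverse fitter); ``t_end`` overrides
    ``params.max_time``.
    """
    consts = equilibrium_constants(em.temperature)
    eps = fractionation_factors(em.temperature)
    k1, k2, kw = consts.k1, consts.k2, consts.kw
    co2eq = consts.kh * params.pco2_atm * 1e-6  # mol/L

    h0 = 10.0 ** (-em.ph)
    dic0 = em.dic * 1e-6
    a = k1 / h0
    b = a * k2 / h0
    den = 1.0 + a + b
    co2_0 = dic0 / den
    if require_supersaturated and co2_0 <= co2eq:
        raise ValueError(
            f"end-member CO2 ({co2_0 * 1e6:.3g} umol/L) is not supersaturated "
            f"relative to atmospheric equilibrium ({co2eq * 1e6:.3g} umol/L)"
        )
    anc0 = dic0 * (a + 2.0 * b) / den + kw / h0 - h0
    p = _Parcel(dic0, h0, dic0 * (1.0 + em.d13c_dic / 1000.0), anc0)
    p.delivered_amount = co2_0

    gw_mix = None
    if params.gw_inflow > 0.0:
        gw_mix = (dic0, anc0, p.hv, co2_0)

    n_sub = max(1, math.ceil(params.k_gas * params.dt / _MAX_TURNOVER))
    dts = params.dt / n_sub
    max_time = params.max_time if t_end is None else t_end
    stop_co2 = params.stop_ratio * co2eq

    rows: list[list[float]] = []
    _record(rows, p, eps, k1, k2, kw)
    while p.time < max_time - 1e-12:
        for _ in range(n_sub):
            _substep(
                p, dts, params.k_gas, co2eq, params.d13c_atm + eps.eps_k + eps.eps_aq_g,
                eps, k1, k2, kw, gw_mix, params.gw_inflow,
            )
        _record(rows, p, eps, k1, k2, kw)
        a = k1 / p.h
        b = a * k2 / p.h
        co2_now = p.dic / (1.0 + a + b)
        if params.k_gas > 0.0 and co2_now <= stop_co2:
            break
        if stop_dic is not None and p.dic * 1e6 < stop_dic:
            break

    data = np.asarray(rows, dtype=float)
    return {key: data[:, i] for i, key in enumerate(_RECORD_KEYS)}


def _state_from_row(arrays: dict[str, np.ndarray], i: int, temperature: float) -> StreamState:
    carb = CarbonateState(
        dic=arrays["DIC_umol_L"][i],
        ph=arrays["pH"][i],
        temperature=temperature,
        co2=arrays["co2_umol_L"][i],
        hco3=arrays["hco3_umol_L"][i],
        co3=arrays["co3_umol_L"][i],
        alkalinity=arrays["alk_carb_ueq_L"][i],
    )
    iso = IsotopeState(
        d13c_dic=arrays["d13C_DIC_permil"][i],
        d13c_co2=arrays["d13C_CO2_permil"][i],
        d13c_hco3=arrays["d13C_HCO3_permil"][i],
        d13c_co3=arrays["d13C_CO3_permil"][i],
        c13_dic=R_VPDB
        * arrays["DIC_umol_L"][i]
        * (1.0 + arrays["d13C_DIC_permil"][i] / 1000.0),
    )
    return StreamState(
        time=arrays["time_d"][i],
        carbonate=carb,
        isotope=iso,
        cum_evaded=arrays["cum_evaded_umol_L"][i],
        cum_gw_added=arrays["cum_gw_added_umol_L"][i],
        cum_evaded_c13=arrays["cum_evaded_c13"][i],
        cum_gw_added_c13=arrays["cum_gw_added_c13"][i],
    )


@dataclass
class Trajectory:
    """Time-ordered degassing trajectory with cumulative-loss bookkeeping."""

    end_member: GroundwaterEndMember
    params: ModelParams
    arrays: dict[str, np.ndarray] = field(repr=False)

    @property
    def states(self) -> list[StreamState]:
        t = self.end_member.temperature
        return [_state_from_row(self.arrays, i, t) for i in range(len(self.arrays["time_d"]))]

    @property
    def fraction_co2_lost(self) -> np.ndarray:
        """Net evaded CO2 / CO2 delivered by groundwater, per state."""
        return self.arrays["fraction_CO2_lost"]

    def to_frame(self) -> pd.DataFrame:
        """Trajectory as a DataFrame with unit-suffixed columns."""
        cols = [
            "time_d",
            "DIC_umol_L",
            "pH",
            "co2_umol_L",
            "d13C_DIC_permil",
            "d13C_CO2_permil",
            "fraction_CO2_lost",
            "alk_ueq_L",
        ]
        return pd.DataFrame({c: self.arrays[c] for c in cols})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def step(state: StreamState, params: ModelParams) -> StreamState:
    """Advance one parcel state by ``params.dt`` days of gas exchange.

    Internally sub-divided so per-sub-step CO2 turnover stays below 5%;
    groundwater inflow is not applied here (see ``add_groundwater`` and
    ``simulate``).
    """
    consts = equilibrium_constants(state.carbonate.temperature)
    eps = fractionation_factors(state.carbonate.temperature)
    k1, k2, kw = consts.k1, consts.k2, consts.kw
    co2eq = consts.kh * params.pco2_atm * 1e-6

    dic = state.carbonate.dic * 1e-6
    p = _Parcel(
        dic,
        10.0 ** (-state.carbonate.ph),
        dic * (1.0 + state.isotope.d13c_dic / 1000.0),
        total_alkalinity(state.carbonate) * 1e-6,
    )
    p.time = state.time
    p.cum_evaded = state.cum_evaded * 1e-6
    p.cum_gw_added = state.cum_gw_added * 1e-6
    p.cum_evaded_hv = state.cum_evaded_c13 * 1e-6 / R_VPDB
    p.cum_gw_added_hv = state.cum_gw_added_c13 * 1e-6 / R_VPDB
    p.delivered_amount = 1.0  # unused here

    n_sub = max(1, math.ceil(params.k_gas * params.dt / _MAX_TURNOVER))
    dts = params.dt / n_sub
    for _ in range(n_sub):
        _substep(
            p, dts, params.k_gas, co2eq, params.d13c_atm + eps.eps_k + eps.eps_aq_g,
            eps, k1, k2, kw, None, 0.0,
        )

    carb = speciate(p.dic * 1e6, -math.log10(p.h), state.carbonate.temperature)
    iso = species_deltas((p.hv / p.dic - 1.0) * 1000.0, carb, eps)
    return StreamState(
        time=p.time,
        carbonate=carb,
        isotope=iso,
        cum_evaded=p.cum_evaded * 1e6,
        cum_gw_added=p.cum_gw_added * 1e6,
        cum_evaded_c13=p.cum_evaded_hv * 1e6 * R_VPDB,
        cum_gw_added_c13=p.cum_gw_added_hv * 1e6 * R_VPDB,
    )


def initial_state(em: GroundwaterEndMember) -> StreamState:
    """StreamState at t = 0 for a groundwater end-member."""
    carb = speciate(em.dic, em.ph, em.temperature)
    iso = species_deltas(em.d13c_dic, carb, fractionation_factors(em.temperature))
    return StreamState(time=0.0, carbonate=carb, isotope=iso)


def add_groundwater(
    state: StreamState, gw: GroundwaterEndMember, volume_fraction: float
) -> StreamState:
    """Mix ``volume_fraction`` parcel volumes of groundwater into the parcel.

    DIC, charge-balance alkalinity and the 13C pool mix conservatively
    (volume-weighted); pH is re-solved from the mixed DIC and alkalinity.
    """
    if volume_fraction < 0:
        raise ValueError(f"volume_fraction must be >= 0, got {volume_fraction!r}")
    if volume_fraction == 0.0:
        return state
    if abs(gw.temperature - state.carbonate.temperature) > 1e-9:
        raise ValueError("groundwater and stream temperatures must match")
    f = volume_fraction
    gw_carb = speciate(gw.dic, gw.ph, gw.temperature)

    dic = (state.carbonate.dic + f * gw.dic) / (1.0 + f)
    anc = (total_alkalinity(state.carbonate) + f * total_alkalinity(gw_carb)) / (1.0 + f)
    hv_stream = state.carbonate.dic * (1.0 + state.isotope.d13c_dic / 1000.0)
    hv_gw = gw.dic * (1.0 + gw.d13c_dic / 1000.0)
    hv = (hv_stream + f * hv_gw) / (1.0 + f)

    consts = equilibrium_constants(state.carbonate.temperature)
    h = _solve_h(dic * 1e-6, anc * 1e-6, consts.k1, consts.k2, consts.kw,
                 10.0 ** (-state.carbonate.ph))
    ph = -math.log10(h)
    carb = speciate(dic, ph, state.carbonate.temperature)
    eps = fractionation_factors(state.carbonate.temperature)
    d13c = (hv / dic - 1.0) * 1000.0
    iso = species_deltas(d13c, carb, eps)
    added = dic - state.carbonate.dic
    added_c13 = (hv - hv_stream) * R_VPDB
    return StreamState(
        time=state.time,
        carbonate=carb,
        isotope=iso,
        cum_evaded=state.cum_evaded,
        cum_gw_added=state.cum_gw_added + added,
        cum_evaded_c13=state.cum_evaded_c13,
        cum_gw_added_c13=state.cum_gw_added_c13 + added_c13,
    )


def simulate(em: GroundwaterEndMember, params: ModelParams | None = None) -> Trajectory:
    """Run the degassing model from a supersaturated end-member.

    Iterates gas-exchange steps (with continuous groundwater addition when
    ``params.gw_inflow > 0``) until CO2 falls to ``stop_ratio`` times the
    atmospheric-equilibrium concentration or ``max_time`` is reached.
    Rejects end-members that are not supersaturated.
    """
    params = params or ModelParams()
    arrays = _run(em, params)
    return Trajectory(end_member=em, params=params, arrays=arrays)


def trajectory_curve(
    em: GroundwaterEndMember, params: ModelParams | None = None, n_points: int = 200
) -> pd.DataFrame:
    """Degassing trajectory resampled at ``n_points`` evenly spaced values
    of the fraction of delivered CO2 lost (for plotting and envelopes)."""
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    traj = simulate(em, params)
    f = traj.arrays["fraction_CO2_lost"]
    grid = np.linspace(f[0], f[-1], n_points)
    out = {
        "DIC_umol_L": np.interp(grid, f, traj.arrays["DIC_umol_L"]),
        "d13C_DIC_permil": np.interp(grid, f, traj.arrays["d13C_DIC_permil"]),
        "d13C_CO2_permil": np.interp(grid, f, traj.arrays["d13C_CO2_permil"]),
        "pH": np.interp(grid, f, traj.arrays["pH"]),
        "fraction_CO2_lost": grid,
    }
    return pd.DataFrame(out)


def trajectory_family(
    dic_values,
    ph_values,
    d13c_dic: float,
    temperature: float,
    params: ModelParams | None = None,
    n_points: int = 200,
) -> list[pd.DataFrame]:
    """Curves for a grid of end-members (the landscape 'family' envelope)."""
    return [
        trajectory_curve(
            GroundwaterEndMember(dic, ph, d13c_dic, temperature), params, n_points
        )
        for dic in dic_values
        for ph in ph_values
    ]
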