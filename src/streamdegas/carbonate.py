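"""Freshwater carbonate-system equilibria for dilute, low-ionic-strength waters.

Temperature-dependent equilibrium constants, DIC speciation, carbonate
alkalinity, and pH solving for soft waters where activity coefficients are
taken as unity (conductivities of a few tens of uS justify this; no
ionic-strength correction is applied anywhere in the package).

Constant parameterizations (all for fresh water, zero salinity):

* pK1, CO2* <-> HCO3-:  Harned & Davis (1943) conductance fit,
  ``pK1 = 3404.71/T + 0.032786*T - 14.8435`` (T in kelvin); 6.35 at 25 C.
* pK2, HCO3- <-> CO32-: Harned & Scholes (1941),
  ``pK2 = 2902.39/T + 0.02379*T - 6.4980``; 10.33 at 25 C.
* pKw, water autoionization: Harned & Owen (1958),
  ``pKw = 4470.99/T + 0.017060*T - 6.0875``; 14.0 at 25 C, 14.8 at 4 C.
* KH, Henry's constant for CO2: Weiss (1974) at S = 0,
  ``ln KH = -58.0931 + 90.5069*(100/T) + 22.2940*ln(T/100)`` in mol/L/atm;
  0.0339 mol/L/atm at 25 C, 0.0668 at 4 C (so 380 ppmv ~ 25 umol/L at 4 C).

Units throughout: concentrations in umol/L, alkalinity in ueq/L,
temperature in degrees Celsius, pH on the (activity = concentration)
free scale.  ``equilibrium_constants`` exposes the constants themselves
in mol/L units via the lowercase properties.

Two alkalinity-like quantities appear:

* carbonate alkalinity, CA = [HCO3-] + 2[CO32-] — the charge held by the
  carbonate ions, the quantity conventionally reported for these waters;
* total (charge-balance) alkalinity, CA + [OH-] - [H+] — the acid
  neutralizing capacity of the pure carbonate-water system.  This is the
  quantity that is exactly invariant under CO2 gain or loss and is what the
  degassing model holds constant.  It can be negative below about pH 5 when
  free acidity exceeds the carbonate charge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

__all__ = [
    "ConstantSet",
    "CarbonateState",
    "equilibrium_constants",
    "speciate",
    "carbonate_alkalinity",
    "total_alkalinity",
    "co2_equilibrium",
    "ph_from_dic_alk",
    "TEMP_MIN",
    "TEMP_MAX",
    "PH_MIN",
    "PH_MAX",
]

TEMP_MIN = -2.0  #: lower validity bound of the constant fits, deg C
TEMP_MAX = 40.0  #: upper validity bound of the constant fits, deg C
PH_MIN = 2.0
PH_MAX = 12.0

_LN10 = math.log(10.0)


def _check_temperature(temperature: float) -> None:
    if not math.isfinite(temperature) or not (TEMP_MIN <= temperature <= TEMP_MAX):
        raise ValueError(
            f"temperature {temperature!r} C outside the validity range "
            f"[{TEMP_MIN}, {TEMP_MAX}] C of the freshwater constant fits"
        )


def _check_ph(ph: float) -> None:
    if not math.isfinite(ph) or not (PH_MIN <= ph <= PH_MAX):
        raise ValueError(f"pH {ph!r} outside the supported range [{PH_MIN}, {PH_MAX}]")


@dataclass(frozen=True)
class ConstantSet:
    """Equilibrium constants of the freshwater carbonate system at one temperature.

    ``pK1``/``pK2`` are the first/second dissociation constants of carbonic
    acid (CO2* convention), ``pKw`` the water ion product, and ``logKH``
    log10 of Henry's constant in mol/L/atm.
    """

    temperature: float
    pK1: float
    pK2: float
    pKw: float
    logKH: float

    @property
    def k1(self) -> float:
        return 10.0 ** (-self.pK1)

    @property
    def k2(self) -> float:
        return 10.0 ** (-self.pK2)

    @property
    def kw(self) -> float:
        return 10.0 ** (-self.pKw)

    @property
    def kh(self) -> float:
        """Henry's constant, mol/L/atm."""
        return 10.0 ** self.logKH


def equilibrium_constants(temperature: float) -> ConstantSet:
    """Evaluate K1, K2, Kw and KH at ``temperature`` (deg C).

    Sources: Harned & Davis (1943) for K1, Harned & Scholes (1941) for K2,
    Harned & Owen (1958) for Kw, Weiss (1974, S=0) for KH; see module
    docstring for the formulas.

    Raises ``ValueError`` outside [-2, 40] C.
    """
    _check_temperature(temperature)
    tk = temperature + 273.15
    pk1 = 3404.71 / tk + 0.032786 * tk - 14.8435
    pk2 = 2902.39 / tk + 0.02379 * tk - 6.4980
    pkw = 4470.99 / tk + 0.017060 * tk - 6.0875
    ln_kh = -58.0931 + 90.5069 * (100.0 / tk) + 22.2940 * math.log(tk / 100.0)
    return ConstantSet(temperature, pk1, pk2, pkw, ln_kh / _LN10)


@dataclass(frozen=True)
class CarbonateState:
    """Speciated carbonate system of one parcel of water.

    Concentrations in umol/L; ``alkalinity`` is the carbonate alkalinity
    [HCO3-] + 2[CO32-] in ueq/L.
    """

    dic: float
    ph: float
    temperature: float
    co2: float
    hco3: float
    co3: float
    alkalinity: float


def speciate(dic: float, ph: float, temperature: float) -> CarbonateState:
    """Partition DIC (umol/L) into CO2*, HCO3- and CO32- at given pH and T.

    Standard alpha fractions of K1 and K2 with [H+] = 10**-pH; the species
    sum to DIC by construction.
    """
    if not math.isfinite(dic) or dic < 0:
        raise ValueError(f"DIC must be non-negative and finite, got {dic!r}")
    _check_ph(ph)
    consts = equilibrium_constants(temperature)
    h = 10.0 ** (-ph)
    a1 = consts.k1 / h
    a2 = a1 * consts.k2 / h
    den = 1.0 + a1 + a2
    co2 = dic / den
    hco3 = dic * a1 / den
    co3 = dic * a2 / den
    return CarbonateState(
        dic=dic,
        ph=ph,
        temperature=temperature,
        co2=co2,
        hco3=hco3,
        co3=co3,
        alkalinity=hco3 + 2.0 * co3,
    )


def carbonate_alkalinity(state: CarbonateState) -> float:
    """Carbonate alkalinity [HCO3-] + 2[CO32-] of a speciated state, ueq/L."""
    return state.hco3 + 2.0 * state.co3


def total_alkalinity(state: CarbonateState) -> float:
    """Charge-balance alkalinity CA + [OH-] - [H+] in ueq/L.

    Exactly invariant under CO2 gain/loss; negative at low pH where free
    acidity exceeds the carbonate charge.  This is the quantity the
    degassing model holds constant while re-solving pH.
    """
    consts = equilibrium_constants(state.temperature)
    h = 10.0 ** (-state.ph)
    oh = consts.kw / h
    return state.hco3 + 2.0 * state.co3 + (oh - h) * 1e6


def co2_equilibrium(temperature: float, pco2_atm: float) -> float:
    """Dissolved CO2* (umol/L) in equilibrium with ``pco2_atm`` ppmv.

    KH(T) * pCO2, with pCO2 converted from ppmv to atm (total pressure
    1 atm).  380 ppmv at 4 C gives ~25 umol/L.
    """
    if not math.isfinite(pco2_atm) or pco2_atm < 0:
        raise ValueError(f"pCO2 must be non-negative, got {pco2_atm!r}")
    consts = equilibrium_constants(temperature)
    # mol/L/atm * (ppmv -> atm) * (mol -> umol) collapses to kh * ppmv
    return consts.kh * pco2_atm


def _alkalinity_of_ph(dic: float, ph: float, consts: ConstantSet, kind: str) -> float:
    h = 10.0 ** (-ph)
    a1 = consts.k1 / h
    a2 = a1 * consts.k2 / h
    den = 1.0 + a1 + a2
    ca = dic * (a1 + 2.0 * a2) / den
    if kind == "carbonate":
        return ca
    return ca + (consts.kw / h - h) * 1e6


def ph_from_dic_alk(
    dic: float,
    alkalinity: float,
    temperature: float,
    kind: str = "carbonate",
) -> float:
    """Solve for the unique pH giving ``alkalinity`` (ueq/L) at fixed DIC.

    ``kind`` selects carbonate alkalinity (default) or the full
    charge-balance form (``"total"``); both are strictly increasing in pH
    at fixed DIC, so a bracketed root on pH in [2, 12] is unique.  The
    residual is converged to ~1e-10 ueq/L.

    Raises ``ValueError`` when no root exists in the bracket.
    """
    if not math.isfinite(dic) or dic <= 0:
        raise ValueError(f"DIC must be positive to solve for pH, got {dic!r}")
    if kind not in ("carbonate", "total"):
        raise ValueError(f"kind must be 'carbonate' or 'total', got {kind!r}")
    consts = equilibrium_constants(temperature)

    def residual(ph: float) -> float:
        return _alkalinity_of_ph(dic, ph, consts, kind) - alkalinity

    lo, hi = residual(PH_MIN), residual(PH_MAX)
    if lo > 0.0 or hi < 0.0:
        raise ValueError(
            f"no pH in [{PH_MIN}, {PH_MAX}] yields {kind} alkalinity "
            f"{alkalinity!r} ueq/L at DIC {dic!r} umol/L and {temperature!r} C "
            f"(attainable range [{lo + alkalinity:.6g}, {hi + alkalinity:.6g}])"
        )
    return brentq(residual, PH_MIN, PH_MAX, xtol=1e-12, rtol=8.9e-16)
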