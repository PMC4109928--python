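"""Stable carbon isotope fractionation among DIC species and across the air-water interface.

All fractionations are handled as additive epsilon offsets in permil
(first-order delta arithmetic): eps(A-B) = dA - dB at equilibrium.  At the
delta values of these systems (-30 to 0 permil) the error relative to full
ratio algebra is far below 0.01 permil, which is the paper-level precision
of everything downstream.

Temperature fits (T in kelvin where 1/T appears, Celsius otherwise):

* eps(CO2aq - HCO3-)  = -9866/T + 24.12          (Mook, Bommerson &
  Staverman 1974); -9.0 at 25 C, -11.5 at 4 C.
* eps(HCO3- - CO32-)  = -0.0621*t + 3.56         (difference of the
  HCO3-gas and CO3-gas fits of Zhang, Quay & Wilbur 1995); +3.3 at 4 C.
* eps(CO2aq - CO2g)   = -373/T + 0.19            (Mook et al. 1974 /
  Vogel, Grootes & Mook 1970); -1.1 at 25 C, -1.2 at 4 C.
* eps_k, kinetic fractionation of the gas-transfer step: linear
  interpolation of the Zhang, Quay & Wilbur (1995) measurements
  (-0.95 permil at 5 C, -0.81 at 21 C); 13CO2 transfers slightly slower
  than 12CO2, so eps_k < 0 and the evading flux is depleted relative to
  the dissolved CO2 it leaves from.

The VPDB 13C/12C ratio is fixed at 0.011180; every output of the package
depends only on delta differences, so its absolute value is immaterial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .carbonate import CarbonateState, _check_temperature

__all__ = [
    "R_VPDB",
    "EpsilonSet",
    "IsotopeState",
    "fractionation_factors",
    "species_deltas",
    "delta_to_ratio",
    "ratio_to_delta",
]

R_VPDB = 0.011180  #: 13C/12C of the VPDB standard


def delta_to_ratio(delta: float) -> float:
    """delta13C (permil VPDB) -> 13C/12C isotope ratio."""
    return R_VPDB * (1.0 + delta / 1000.0)


def ratio_to_delta(ratio: float) -> float:
    """13C/12C isotope ratio -> delta13C (permil VPDB)."""
    return (ratio / R_VPDB - 1.0) * 1000.0


@dataclass(frozen=True)
class EpsilonSet:
    """13C fractionation factors (permil) at one temperature.

    Sign convention: eps(A-B) = dA - dB at equilibrium, so e.g.
    ``eps_co2_hco3`` is negative (dissolved CO2 lighter than bicarbonate)
    and ``eps_hco3_co3`` is positive at low temperature.
    """

    temperature: float
    eps_k: float
    eps_aq_g: float
    eps_co2_hco3: float
    eps_hco3_co3: float


def fractionation_factors(temperature: float) -> EpsilonSet:
    """Evaluate the four epsilon fits at ``temperature`` (deg C)."""
    _check_temperature(temperature)
    tk = temperature + 273.15
    return EpsilonSet(
        temperature=temperature,
        eps_k=-0.95 + 0.00875 * (temperature - 5.0),
        eps_aq_g=-373.0 / tk + 0.19,
        eps_co2_hco3=-9866.0 / tk + 24.12,
        eps_hco3_co3=-0.0621 * temperature + 3.56,
    )


@dataclass(frozen=True)
class IsotopeState:
    """delta13C of bulk DIC and of each carbonate species (permil VPDB).

    ``c13_dic`` is the linearized heavy-isotope pool
    R_VPDB * DIC * (1 + d13C/1000) in umol/L; the simulator's conservation
    bookkeeping is exact in this pool.
    """

    d13c_dic: float
    d13c_co2: float
    d13c_hco3: float
    d13c_co3: float
    c13_dic: float


def species_deltas(
    d13c_dic: float, state: CarbonateState, eps: EpsilonSet
) -> IsotopeState:
    """Partition the bulk d13C-DIC among CO2*, HCO3- and CO32-.

    Solves the linear system {fraction-weighted species deltas = bulk
    delta; dCO2 - dHCO3 = eps_co2_hco3; dHCO3 - dCO3 = eps_hco3_co3}
    exactly.  Undefined for DIC = 0.
    """
    if not math.isfinite(d13c_dic):
        raise ValueError(f"d13c_dic must be finite, got {d13c_dic!r}")
    if state.dic <= 0:
        raise ValueError("species deltas are undefined at DIC = 0")
    x_co2 = state.co2 / state.dic
    x_co3 = state.co3 / state.dic
    d_hco3 = d13c_dic - x_co2 * eps.eps_co2_hco3 + x_co3 * eps.eps_hco3_co3
    d_co2 = d_hco3 + eps.eps_co2_hco3
    d_co3 = d_hco3 - eps.eps_hco3_co3
    return IsotopeState(
        d13c_dic=d13c_dic,
        d13c_co2=d_co2,
        d13c_hco3=d_hco3,
        d13c_co3=d_co3,
        c13_dic=R_VPDB * state.dic * (1.0 + d13c_dic / 1000.0),
    )
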