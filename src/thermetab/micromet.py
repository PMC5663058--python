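"""Micrometeorological and aerodynamic quantities for the leaf energy balance.

Everything the energy-balance model consumes that is not a temperature lives
here: psychrometrics (saturation vapour pressure, its slope, vapour pressure
deficit, the psychrometric constant), air density, the boundary-layer and
radiative transfer resistances, and net isothermal radiation.

Units are SI throughout: temperatures in degrees Celsius at the interface,
pressures in Pa, resistances in s m^-1, radiation in W m^-2.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "CP_AIR",
    "LAMBDA_VAP",
    "R_SPECIFIC_AIR",
    "STEFAN_BOLTZMANN",
    "P_STANDARD",
    "MetConditions",
    "AirProperties",
    "ResistanceSet",
    "saturation_vapour_pressure",
    "svp_slope",
    "vapour_pressure_deficit",
    "psychrometric_constant",
    "air_density",
    "boundary_layer_resistances",
    "radiative_resistance",
    "parallel_resistance",
    "net_isothermal_radiation",
    "air_properties",
    "resistance_set",
    "read_weather_csv",
]

#: Specific heat capacity of air at constant pressure (J kg^-1 K^-1).
CP_AIR = 1010.0
#: Latent heat of vaporisation of water (J kg^-1).
LAMBDA_VAP = 2.45e6
#: Specific gas constant of dry air (J kg^-1 K^-1).
R_SPECIFIC_AIR = 287.05
#: Stefan-Boltzmann constant (W m^-2 K^-4).
STEFAN_BOLTZMANN = 5.670374e-8
#: Default atmospheric pressure (Pa), site near sea level.
P_STANDARD = 101325.0

#: Default characteristic leaf dimension (m); matches the width of the
#: artificial reference leaves (ca. 12 x 9 cm).
DEFAULT_LEAF_DIM = 0.09
#: Wind speed floor (m s^-1) so boundary-layer resistances stay finite in
#: calm air.
DEFAULT_U_MIN = 0.5


@dataclass(frozen=True)
class MetConditions:
    """A point weather snapshot driving the energy-balance terms.

    Parameters
    ----------
    Ta : float
        Air temperature (degC).
    RH : float
        Relative humidity (%).
    u : float
        Wind speed (m s^-1).
    SWR : float
        Incoming shortwave radiation (W m^-2).
    P : float
        Atmospheric pressure (Pa).
    """

    Ta: float
    RH: float
    u: float
    SWR: float
    P: float = P_STANDARD

    def __post_init__(self) -> None:
        if not (-40.0 < self.Ta < 60.0):
            raise ValueError(f"air temperature {self.Ta} degC outside (-40, 60)")
        if not (0.0 <= self.RH <= 100.0):
            raise ValueError(f"relative humidity {self.RH} % outside [0, 100]")
        if self.u < 0.0:
            raise ValueError(f"wind speed {self.u} m/s is negative")
        if self.SWR < 0.0:
            raise ValueError(f"shortwave radiation {self.SWR} W/m2 is negative")
        if self.P <= 0.0:
            raise ValueError(f"pressure {self.P} Pa is non-positive")

    def replace(self, **kwargs) -> "MetConditions":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class AirProperties:
    """Thermodynamic air properties at a weather snapshot.

    rho: air density (kg m^-3); cp: specific heat (J kg^-1 K^-1);
    gamma: psychrometric constant (Pa K^-1); s: slope of the saturation
    vapour pressure curve (Pa K^-1); D: vapour pressure deficit (Pa).
    """

    rho: float
    cp: float
    gamma: float
    s: float
    D: float

    def __post_init__(self) -> None:
        for name in ("rho", "cp", "gamma", "s"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"air property {name} must be > 0")
        if self.D < 0.0:
            raise ValueError("vapour pressure deficit must be >= 0")


@dataclass(frozen=True)
class ResistanceSet:
    """Transfer resistances (s m^-1) and net isothermal radiation (W m^-2).

    r_aH / r_aw: boundary-layer resistance to heat / water vapour;
    r_R: radiative transfer resistance; r_HR: parallel combination of r_aH
    and r_R; Rni: net isothermal radiation.
    """

    r_aH: float
    r_aw: float
    r_R: float
    r_HR: float
    Rni: float

    def __post_init__(self) -> None:
        for name in ("r_aH", "r_aw", "r_R", "r_HR"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"resistance {name} must be > 0")
        if self.r_HR >= min(self.r_aH, self.r_R) + 1e-9:
            raise ValueError("r_HR must be below both parallel branches")


def saturation_vapour_pressure(T):
    """Saturation vapour pressure (Pa) over water at temperature ``T`` (degC).

    Tetens form 610.78 * exp(17.27 T / (T + 237.3)); strictly increasing in T.
    """
    T = np.asarray(T, dtype=float)
    out = 610.78 * np.exp(17.27 * T / (T + 237.3))
    return float(out) if out.ndim == 0 else out


def svp_slope(T):
    """Slope of the saturation vapour pressure curve (Pa K^-1) at ``T`` (degC).

    Analytic derivative of the Tetens form: 4098 e_s(T) / (T + 237.3)^2.
    """
    T = np.asarray(T, dtype=float)
    out = 4098.0 * saturation_vapour_pressure(T) / (T + 237.3) ** 2
    return float(out) if out.ndim == 0 else out


def vapour_pressure_deficit(Ta, RH):
    """Vapour pressure deficit D (Pa) from air temperature (degC) and RH (%)."""
    RH = np.asarray(RH, dtype=float)
    if np.any(RH < 0.0) or np.any(RH > 100.0):
        raise ValueError("relative humidity must lie in [0, 100] %")
    out = saturation_vapour_pressure(Ta) * (1.0 - RH / 100.0)
    return float(out) if np.ndim(out) == 0 else out


def psychrometric_constant(P, cp: float = CP_AIR, lam: float = LAMBDA_VAP):
    """Psychrometric constant gamma (Pa K^-1): cp * P / (lambda * 0.622)."""
    P = np.asarray(P, dtype=float)
    out = cp * P / (lam * 0.622)
    return float(out) if out.ndim == 0 else out


def air_density(Ta, P=P_STANDARD):
    """Dry-air density (kg m^-3) from the ideal gas law: P / (R_air * T_K)."""
    Ta = np.asarray(Ta, dtype=float)
    out = np.asarray(P, dtype=float) / (R_SPECIFIC_AIR * (Ta + 273.15))
    return float(out) if out.ndim == 0 else out


def boundary_layer_resistances(
    u: float,
    d: float = DEFAULT_LEAF_DIM,
    u_min: float = DEFAULT_U_MIN,
) -> tuple[float, float]:
    """Boundary-layer resistances to heat and water vapour (s m^-1).

    Flat-plate forced-convection approximation r_aH = 100 sqrt(d / u), with
    the wind speed clamped below by ``u_min`` so calm air does not produce a
    divergent resistance; r_aw = 0.93 r_aH from the heat/vapour molecular
    diffusivity ratio.

    Parameters
    ----------
    u : float
        Wind speed (m s^-1).
    d : float
        Characteristic leaf dimension (m).
    u_min : float
        Lower clamp for the wind speed (m s^-1).
    """
    if d <= 0.0:
        raise ValueError("characteristic dimension d must be > 0")
    u_eff = max(float(u), float(u_min))
    if u_eff <= 0.0:
        raise ValueError("wind speed after clamping must be > 0")
    r_aH = 100.0 * np.sqrt(d / u_eff)
    return float(r_aH), float(0.93 * r_aH)


def radiative_resistance(Ta: float, emissivity: float, P: float = P_STANDARD) -> float:
    """Radiative transfer resistance r_R (s m^-1).

    rho * cp / (4 sigma eps T_K^3): the resistance equivalent of linearised
    longwave exchange at air temperature.
    """
    if not (0.0 < emissivity <= 1.0):
        raise ValueError("emissivity must lie in (0, 1]")
    rho = air_density(Ta, P)
    T_K = Ta + 273.15
    return float(rho * CP_AIR / (4.0 * STEFAN_BOLTZMANN * emissivity * T_K**3))


def parallel_resistance(r_aH: float, r_R: float) -> float:
    """Parallel (harmonic) combination r_aH r_R / (r_aH + r_R)."""
    if r_aH <= 0.0 or r_R <= 0.0:
        raise ValueError("resistances must be > 0")
    return float(r_aH * r_R / (r_aH + r_R))


def net_isothermal_radiation(
    SWR: float, alpha_sw: float = 0.5, L_iso: float = 0.0
) -> float:
    """Net isothermal radiation R_ni (W m^-2): alpha_sw * SWR + L_iso.

    ``alpha_sw`` is the shortwave absorptance of the canopy surface and
    ``L_iso`` an additive isothermal longwave term (default 0, i.e. longwave
    exchange is carried entirely by the radiative resistance).
    """
    if SWR < 0.0:
        raise ValueError("shortwave radiation must be >= 0")
    return float(alpha_sw * SWR + L_iso)


def air_properties(met: MetConditions) -> AirProperties:
    """Bundle the thermodynamic air properties for a weather snapshot."""
    return AirProperties(
        rho=air_density(met.Ta, met.P),
        cp=CP_AIR,
        gamma=psychrometric_constant(met.P),
        s=svp_slope(met.Ta),
        D=vapour_pressure_deficit(met.Ta, met.RH),
    )


def resistance_set(
    met: MetConditions,
    emissivity: float = 0.96,
    d: float = DEFAULT_LEAF_DIM,
    u_min: float = DEFAULT_U_MIN,
    alpha_sw: float = 0.5,
    L_iso: float = 0.0,
) -> ResistanceSet:
    """Assemble the full resistance set for a weather snapshot.

    ``emissivity`` enters the radiative resistance; ``alpha_sw`` and ``L_iso``
    parameterise net isothermal radiation (see
    :func:`net_isothermal_radiation`).
    """
    r_aH, r_aw = boundary_layer_resistances(met.u, d=d, u_min=u_min)
    r_R = radiative_resistance(met.Ta, emissivity, met.P)
    return ResistanceSet(
        r_aH=r_aH,
        r_aw=r_aw,
        r_R=r_R,
        r_HR=parallel_resistance(r_aH, r_R),
        Rni=net_isothermal_radiation(met.SWR, alpha_sw=alpha_sw, L_iso=L_iso),
    )


def read_weather_csv(path) -> MetConditions:
    """Read a point weather record from CSV.

    Expected columns: ``timestamp, Ta_C, RH_pct, u_ms, SWR_Wm2`` and
    optionally ``P_Pa``. A single-row file is valid; with multiple rows the
    column means are used (a flight-window average).
    """
    df = pd.read_csv(path)
    required = ["Ta_C", "RH_pct", "u_ms", "SWR_Wm2"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"weather CSV missing columns: {missing}")
    if df.empty:
        raise ValueError("weather CSV has no rows")
    return MetConditions(
        Ta=float(df["Ta_C"].mean()),
        RH=float(df["RH_pct"].mean()),
        u=float(df["u_ms"].mean()),
        SWR=float(df["SWR_Wm2"].mean()),
        P=float(df["P_Pa"].mean()) if "P_Pa" in df.columns else P_STANDARD,
    )
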