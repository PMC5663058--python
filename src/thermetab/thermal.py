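"""Thermal water-stress indices and the leaf energy-balance model.

Three index formulations normalise canopy temperature between the wet
(fully transpiring) and dry (non-transpiring) reference temperatures:

* CWSI = (Tc - Twet) / (Tdry - Twet), 0 = unstressed, 1 = fully stressed;
* IG   = (Tdry - Tc) / (Tc - Twet), proportional to stomatal conductance;
* I3   = (Tc - Twet) / (Tdry - Tc) = 1 / IG.

The forward leaf energy balance predicts the canopy-air temperature
difference from canopy resistance r_c and micrometeorology,

    Tc - Ta = [r_HR (r_aw + r_c) gamma R_ni - rho cp r_HR D]
              / (rho cp [gamma (r_aw + r_c) + s r_HR]),

and its exact algebraic rearrangement inverts an observed Tc to r_c; canopy
conductance is g_c = 1 / r_c, convertible to molar units with the ideal gas
law.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .micromet import AirProperties, MetConditions, ResistanceSet, air_properties, resistance_set

__all__ = [
    "R_GAS",
    "DEFAULT_RC_MAX",
    "ReferenceTemps",
    "ThermalIndices",
    "ConductanceEstimate",
    "cwsi",
    "ig_index",
    "i3_index",
    "thermal_indices",
    "forward_delta_t",
    "invert_canopy_resistance",
    "resistance_to_molar_conductance",
    "model_reference_temps",
    "estimate_conductance",
]

#: Universal gas constant (J mol^-1 K^-1).
R_GAS = 8.314
#: Clip ceiling for inverted canopy resistance (s m^-1).
DEFAULT_RC_MAX = 1e5


@dataclass(frozen=True)
class ReferenceTemps:
    """Wet and dry reference temperatures (degC); T_dry must exceed T_wet."""

    T_wet: float
    T_dry: float

    def __post_init__(self) -> None:
        if not self.T_dry > self.T_wet:
            raise ValueError(
                f"T_dry ({self.T_dry}) must exceed T_wet ({self.T_wet})"
            )

    @staticmethod
    def unchecked(T_wet: float, T_dry: float) -> "ReferenceTemps":
        """Build a possibly-degenerate pair (T_dry <= T_wet) without raising.

        Used when measured or modelled references collapse, so callers can
        flag downstream indices instead of aborting.
        """
        refs = ReferenceTemps.__new__(ReferenceTemps)
        object.__setattr__(refs, "T_wet", float(T_wet))
        object.__setattr__(refs, "T_dry", float(T_dry))
        return refs


@dataclass(frozen=True)
class ThermalIndices:
    """The three thermal stress indices plus the canopy-air difference (K)."""

    cwsi: float
    ig: float
    i3: float
    delta_t: float


@dataclass(frozen=True)
class ConductanceEstimate:
    """Canopy resistance/conductance for one plant.

    r_c in s m^-1; g_c_ms = 1/r_c in m s^-1; g_c_mol in mol m^-2 s^-1;
    Tc the canopy temperature (degC). ``quality_flag`` is "ok" unless the
    algebraic solution had to be clipped ("clipped_low" for r_c < 0,
    "clipped_high" at/above the dry-limit asymptote).
    """

    r_c: float
    g_c_ms: float
    g_c_mol: float
    Tc: float
    quality_flag: str = "ok"


def _check_refs(T_wet, T_dry) -> None:
    if np.any(np.asarray(T_dry) == np.asarray(T_wet)):
        raise ValueError("degenerate references: T_dry equals T_wet")


def cwsi(Tc, T_wet, T_dry):
    """Crop water stress index (Tc - Twet) / (Tdry - Twet)."""
    _check_refs(T_wet, T_dry)
    out = (np.asarray(Tc, float) - T_wet) / (np.asarray(T_dry, float) - T_wet)
    return float(out) if np.ndim(out) == 0 else out


def ig_index(Tc, T_wet, T_dry):
    """Conductance-proportional index (Tdry - Tc) / (Tc - Twet).

    Tc at the wet reference gives +inf (warned, not raised): noisy pixels can
    legitimately cross the references.
    """
    _check_refs(T_wet, T_dry)
    Tc = np.asarray(Tc, float)
    denom = Tc - np.asarray(T_wet, float)
    if np.any(denom == 0.0):
        warnings.warn("Tc equals T_wet: IG is infinite", RuntimeWarning, stacklevel=2)
    with np.errstate(divide="ignore"):
        out = (np.asarray(T_dry, float) - Tc) / denom
    return float(out) if np.ndim(out) == 0 else out


def i3_index(Tc, T_wet, T_dry):
    """Reciprocal conductance index (Tc - Twet) / (Tdry - Tc) = 1 / IG."""
    _check_refs(T_wet, T_dry)
    Tc = np.asarray(Tc, float)
    denom = np.asarray(T_dry, float) - Tc
    if np.any(denom == 0.0):
        warnings.warn("Tc equals T_dry: I3 is infinite", RuntimeWarning, stacklevel=2)
    with np.errstate(divide="ignore"):
        out = (Tc - np.asarray(T_wet, float)) / denom
    return float(out) if np.ndim(out) == 0 else out


def thermal_indices(Tc: float, refs: ReferenceTemps, Ta: float) -> ThermalIndices:
    """All three indices plus delta-T for one canopy temperature."""
    return ThermalIndices(
        cwsi=cwsi(Tc, refs.T_wet, refs.T_dry),
        ig=ig_index(Tc, refs.T_wet, refs.T_dry),
        i3=i3_index(Tc, refs.T_wet, refs.T_dry),
        delta_t=float(Tc - Ta),
    )


def forward_delta_t(r_c, air: AirProperties, res: ResistanceSet):
    """Forward energy balance: canopy-air temperature difference (K).

    Monotonically increasing in ``r_c``; the r_c -> infinity limit is the
    dry-surface excess r_HR * Rni / (rho cp).
    """
    r_c = np.asarray(r_c, dtype=float)
    if np.any(r_c < 0.0):
        raise ValueError("canopy resistance r_c must be >= 0")
    rho_cp = air.rho * air.cp
    num = res.r_HR * (res.r_aw + r_c) * air.gamma * res.Rni - rho_cp * res.r_HR * air.D
    den = rho_cp * (air.gamma * (res.r_aw + r_c) + air.s * res.r_HR)
    out = num / den
    return float(out) if out.ndim == 0 else out


def invert_canopy_resistance(
    Tc,
    Ta: float,
    air: AirProperties,
    res: ResistanceSet,
    rc_max: float = DEFAULT_RC_MAX,
):
    """Invert observed canopy temperature to canopy resistance r_c (s m^-1).

    Exact rearrangement of the forward balance:

        r_c = -rho cp r_HR [s (Tc - Ta) + D]
              / {gamma [(Tc - Ta) rho cp - r_HR Rni]} - r_aw

    Returns ``(r_c, quality_flag)`` for scalar input, or arrays of both for
    array input. Negative algebraic solutions (Tc below the wet limit, e.g.
    sensor noise) are clipped to 0 and flagged ``clipped_low``; temperatures
    at/above the dry-limit asymptote yield ``rc_max`` flagged
    ``clipped_high``. An exactly singular denominator raises.
    """
    Tc = np.asarray(Tc, dtype=float)
    scalar = Tc.ndim == 0
    Tc = np.atleast_1d(Tc)
    dT = Tc - Ta
    rho_cp = air.rho * air.cp

    # Asymptotic dry-limit temperature difference (r_c -> inf)
    dT_dry = res.r_HR * res.Rni / rho_cp

    den = air.gamma * (dT * rho_cp - res.r_HR * res.Rni)
    r_c = np.empty_like(dT)
    flags = np.full(dT.shape, "ok", dtype=object)

    above = dT >= dT_dry
    r_c[above] = rc_max
    flags[above] = "clipped_high"

    ok = ~above
    if np.any(den[ok] == 0.0):
        raise ZeroDivisionError("singular denominator in energy-balance inversion")
    num = -rho_cp * res.r_HR * (air.s * dT[ok] + air.D)
    r_c[ok] = num / den[ok] - res.r_aw

    low = ok & (r_c < 0.0)
    r_c[low] = 0.0
    flags[low] = "clipped_low"
    high = ok & (r_c > rc_max)
    r_c[high] = rc_max
    flags[high] = "clipped_high"

    if scalar:
        return float(r_c[0]), str(flags[0])
    return r_c, flags


def resistance_to_molar_conductance(r_c, Ta, P):
    """Convert resistance (s m^-1) to molar conductance (mol m^-2 s^-1).

    g_mol = (1/r_c) * P / (R T_K), the ideal-gas molar density conversion.
    Infinite resistance maps to 0.
    """
    r_c = np.asarray(r_c, dtype=float)
    with np.errstate(divide="ignore"):
        g_ms = np.where(np.isinf(r_c), 0.0, 1.0 / r_c)
    out = g_ms * P / (R_GAS * (np.asarray(Ta, float) + 273.15))
    return float(out) if out.ndim == 0 else out


def model_reference_temps(
    Ta: float, air: AirProperties, res: ResistanceSet
) -> ReferenceTemps:
    """Energy-balance reference temperatures when physical references are absent.

    T_wet is the fully transpiring limit (r_c = 0); T_dry the non-transpiring
    limit (r_c -> infinity), Ta + r_HR Rni / (rho cp). T_dry > T_wet whenever
    Rni > 0 or D > 0.
    """
    T_wet = Ta + forward_delta_t(0.0, air, res)
    T_dry = Ta + res.r_HR * res.Rni / (air.rho * air.cp)
    if T_dry <= T_wet:
        warnings.warn(
            "modelled references degenerate (no net energy input): "
            f"T_dry ({T_dry:.3f}) <= T_wet ({T_wet:.3f})",
            RuntimeWarning,
            stacklevel=2,
        )
        return ReferenceTemps.unchecked(T_wet, T_dry)
    return ReferenceTemps(T_wet=float(T_wet), T_dry=float(T_dry))


def estimate_conductance(
    Tc: float,
    met: MetConditions,
    emissivity: float = 0.96,
    rc_max: float = DEFAULT_RC_MAX,
    **res_kwargs,
) -> ConductanceEstimate:
    """One-call conductance estimate from a canopy temperature and weather.

    Builds air properties and resistances from ``met`` (extra keyword
    arguments are passed to :func:`thermetab.micromet.resistance_set`),
    inverts the energy balance, and converts to molar conductance.
    """
    air = air_properties(met)
    res = resistance_set(met, emissivity=emissivity, **res_kwargs)
    r_c, flag = invert_canopy_resistance(Tc, met.Ta, air, res, rc_max=rc_max)
    g_ms = np.inf if r_c == 0.0 else 1.0 / r_c
    return ConductanceEstimate(
        r_c=r_c,
        g_c_ms=float(g_ms),
        g_c_mol=resistance_to_molar_conductance(r_c, met.Ta, met.P)
        if r_c > 0.0
        else float("inf"),
        Tc=float(Tc),
        quality_flag=flag,
    )
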