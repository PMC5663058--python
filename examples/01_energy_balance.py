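"""Canopy conductance from a single canopy temperature.

Builds the midday weather snapshot of a vineyard flight (31.4 degC, 41.7 %
RH, 0.91 m/s wind, 659.5 W/m2 shortwave), computes the wet/dry reference
temperatures from the energy balance, and inverts an observed canopy
temperature to canopy resistance and molar conductance.
"""

from thermetab import (
    air_properties,
    cwsi,
    estimate_conductance,
    generate_met,
    model_reference_temps,
    resistance_set,
)

met = generate_met()  # the default flight conditions
air = air_properties(met)
res = resistance_set(met)
refs = model_reference_temps(met.Ta, air, res)

print(f"weather: Ta={met.Ta} degC, RH={met.RH} %, u={met.u} m/s, SWR={met.SWR} W/m2")
print(f"energy-balance references: T_wet={refs.T_wet:.2f} degC, T_dry={refs.T_dry:.2f} degC")

Tc = 33.0  # an observed canopy temperature, degC
est = estimate_conductance(Tc, met)
stress = cwsi(Tc, refs.T_wet, refs.T_dry)
print(f"canopy at {Tc} degC: CWSI={stress:.3f} (0=unstressed, 1=fully stressed)")
print(
    f"inverted resistance r_c={est.r_c:.1f} s/m -> "
    f"g_c={est.g_c_mol:.4f} mol m-2 s-1 [{est.quality_flag}]"
)
print("a cooler canopy transpires more: lower CWSI, higher g_c")
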