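"""Physical constants shared by every module.

All energies are kcal·mol⁻¹, entropies cal·mol⁻¹·K⁻¹ and temperatures
Kelvin internally; Celsius appears only at I/O boundaries.
"""

#: Gas constant in kcal·mol⁻¹·K⁻¹.
R_KCAL: float = 1.987e-3

#: Gas constant in cal·mol⁻¹·K⁻¹ (used where ΔS° in cal units is involved).
R_CAL: float = 1.987

#: 37 °C in Kelvin, the reference temperature for ΔG°37.
T37: float = 310.15

#: Offset between Celsius and Kelvin.
CELSIUS_OFFSET: float = 273.15

#: ln(10); the "2.303" factor pairing a natural-log thermodynamic relation
#: with a base-10 salt or concentration axis.
LN10: float = 2.302585092994046


def celsius_to_kelvin(t_c: float) -> float:
    return t_c + CELSIUS_OFFSET


def kelvin_to_celsius(t_k: float) -> float:
    return t_k - CELSIUS_OFFSET
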