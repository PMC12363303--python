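"""Unit constants and converters.

The canonical pressure unit throughout the package is the kilopascal;
converters are provided for gauges reporting psi or mmHg.  Volumes are
carried in millilitres (1 mL = 1000 mm^3).
"""

PSI_TO_KPA = 6.894757
MMHG_TO_KPA = 0.1333224
MM3_PER_ML = 1000.0

#: Accepted pressure-unit labels (case-insensitive) and their kPa factor.
PRESSURE_UNIT_FACTORS = {
    "kpa": 1.0,
    "psi": PSI_TO_KPA,
    "mmhg": MMHG_TO_KPA,
}


def pressure_to_kpa(values, unit: str):
    """Convert pressure values from ``unit`` ('kpa', 'psi', 'mmhg') to kPa."""
    try:
        factor = PRESSURE_UNIT_FACTORS[unit.strip().lower()]
    except KeyError:
        raise ValueError(f"unknown pressure unit {unit!r}; expected one of "
                         f"{sorted(PRESSURE_UNIT_FACTORS)}") from None
    return values * factor


def mm3_to_ml(volume_mm3: float) -> float:
    return volume_mm3 / MM3_PER_ML
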