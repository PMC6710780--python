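"""Internal unit system: micrometre - nanonewton - kilopascal.

These units are mutually consistent: 1 nN / um^2 = 1 kPa, so element
stiffnesses (EA in nN), forces (nN), lengths (um) and moduli (kPa) combine
without conversion factors.  Published values (Pa, nm^2, N·m^2) are converted
once at the material-registry boundary.
"""

# moduli / stress
PA_TO_KPA = 1e-3
GPA_TO_KPA = 1e6
MPA_TO_KPA = 1e3

# areas
NM2_TO_UM2 = 1e-6

# forces
PN_TO_NN = 1e-3
N_TO_NN = 1e9

# bending stiffness: 1 N*m^2 = 1e9 nN * 1e12 um^2 = 1e21 nN*um^2
NM2_BENDING_TO_INTERNAL = 1e21


def modulus_to_internal(value: float, unit: str = "Pa") -> float:
    """Convert an elastic modulus to internal kPa; unit in {Pa, kPa, MPa, GPa}."""
    factors = {"Pa": PA_TO_KPA, "kPa": 1.0, "MPa": MPA_TO_KPA, "GPa": GPA_TO_KPA}
    try:
        return value * factors[unit]
    except KeyError:
        raise ValueError(f"unknown modulus unit {unit!r}; expected one of {sorted(factors)}")
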