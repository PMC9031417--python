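"""Unit conversion helpers.

The hemispherical diffusion formula F = 2*pi*r_s*D*(C* - C_s) is evaluated in
CGS-style units (cm, cm^2/s, mol/cm^3, giving mol/s), while every public
interface of the package speaks the laboratory units of the measurement:
micrometres for electrode geometry, micromolar for dissolved oxygen, and
pico-/nanoamperes for reduction currents. All conversions go through the
constants below so there is a single place where the scales live.
"""

#: micrometres -> centimetres
UM_TO_CM = 1.0e-4

#: micromolar (umol/L) -> mol/cm^3  (1 uM = 1e-6 mol/L = 1e-9 mol/cm^3)
UM_CONC_TO_MOL_PER_CM3 = 1.0e-9

#: picoamperes -> nanoamperes
PA_TO_NA = 1.0e-3

#: microlitres -> millilitres
UL_TO_ML = 1.0e-3


def um_to_cm(value_um: float) -> float:
    return value_um * UM_TO_CM


def uM_to_mol_per_cm3(value_uM: float) -> float:
    return value_uM * UM_CONC_TO_MOL_PER_CM3


def mol_per_cm3_to_uM(value: float) -> float:
    return value / UM_CONC_TO_MOL_PER_CM3


def pA_to_nA(value_pA: float) -> float:
    return value_pA * PA_TO_NA


def nA_to_pA(value_nA: float) -> float:
    return value_nA / PA_TO_NA


def uL_to_mL(value_uL: float) -> float:
    return value_uL * UL_TO_ML
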