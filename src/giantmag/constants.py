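"""Physical constants and magnetite room-temperature material values (SI)."""

#: Boltzmann constant (J/K), 2019 SI definition.
K_B = 1.380649e-23

#: Vacuum permeability (T·m/A).
MU_0 = 1.25663706212e-6

#: Saturation magnetization of magnetite at room temperature (A/m).
MAGNETITE_MS = 4.80768e5

#: First cubic magnetocrystalline anisotropy constant of magnetite (J/m^3).
MAGNETITE_K1 = -1.32658e4

#: Exchange constant of magnetite (J/m).
MAGNETITE_AEX = 1.33487e-11
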