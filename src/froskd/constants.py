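"""Physical constants shared across modules."""

#: Avogadro's number, molecules per mole.
AVOGADRO = 6.02214076e23

#: Number density of a 1 nM solution, molecules per cubic micrometre.
#: 1 nM = 1e-9 mol/L x N_A / (1e15 um^3/L) = 0.6022 molecules/um^3.
MOLECULES_PER_UM3_PER_NM = AVOGADRO * 1e-9 / 1e15
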