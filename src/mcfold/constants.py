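"""Physical constants and unit conventions.

All energies are kcal/mol, lengths Å, temperatures K throughout the package.
"""

#: Gas constant in kcal/mol/K.
R_KCAL = 1.98720425864083e-3

#: Default heavy-atom contact cutoff (Å).
CONTACT_CUTOFF = 4.5

#: Default water-probe radius for solvent accessibility (Å).
PROBE_RADIUS = 1.4

#: Van der Waals radii (Å), Bondi (1964) values for the elements that occur
#: in protein heavy atoms plus a generic bead.
VDW_RADII = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
    "P": 1.80,
    "X": 1.70,  # generic coarse-grained bead
}
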