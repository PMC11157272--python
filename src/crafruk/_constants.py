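"""Physical constants and reference values shared across modules."""

# Avogadro constant, exact SI value, Da per gram.
AVOGADRO = 6.02214076e23

# Protein partial specific volume (ml/g) derived from solvent-excluded
# volumes of the Cra regulatory-domain and ribokinase crystal structures.
SPECIFIC_VOLUME_ML_PER_G = 0.67

# Theoretical monomer masses (Da) of the two proteins, from their UniProt
# sequences (Cra P0ACP1, FruK P0AEW9).
CRA_MONOMER_DA = 37_999.0
FRUK_MONOMER_DA = 33_756.0

# Bondi van der Waals radii (Angstrom) for elements common in proteins
# and nucleic acids.
VDW_RADII_A = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "SE": 1.90,
    "BR": 1.85,
    "I": 1.98,
}
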