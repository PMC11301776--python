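"""Physical constants for peptide mass and hydropathy calculations.

Residue masses are monoisotopic masses of the amino-acid *residues*
(i.e. the amino acid minus one water, as incorporated in a peptide
chain).  Hydropathy values are the Kyte-Doolittle scale, whose mean
over a peptide is the GRAVY index.
"""

# Monoisotopic residue masses (Da), 20 standard amino acids.
RESIDUE_MONO_MASS: dict[str, float] = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}

#: Monoisotopic mass of water (Da); one water is condensed out per peptide bond,
#: so the neutral peptide mass is the residue-mass sum plus one water.
WATER_MONO = 18.010565

#: Mass of a proton (Da) used for m/z at positive charge states.
PROTON = 1.007276

# Kyte-Doolittle hydropathy scale (dimensionless).
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: The 20 standard one-letter amino-acid codes.
STANDARD_RESIDUES = frozenset(RESIDUE_MONO_MASS)

#: Ambiguity / non-standard codes rejected in strict mode, flagged in lenient mode.
NONSTANDARD_RESIDUES = frozenset("BJOUXZ")
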