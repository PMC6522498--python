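"""Bundled chemical-shift reference data.

Random-coil reference shifts and the fully-formed helix/strand average
secondary shifts used to normalise SSP scores. Both sets are plain module
constants so that alternative references can be passed explicitly to every
function that consumes them.
"""

from __future__ import annotations

NUCLEI = ("H", "N", "HA", "CA", "CB")

#: Random-coil backbone chemical shifts (ppm), per residue type.
#: Values after Wishart et al. (1995) J. Biomol. NMR 5, 67-81.
#: Gly has no CB; Pro has no amide H.
RANDOM_COIL_PROVENANCE = (
    "Wishart et al. (1995) J. Biomol. NMR 5, 67-81; "
    "1H/13C/15N random-coil shifts of the common amino acids"
)

RANDOM_COIL: dict[str, dict[str, float]] = {
    #       H      N      HA     CA     CB
    "A": {"H": 8.24, "N": 123.8, "HA": 4.32, "CA": 52.5, "CB": 19.1},
    "R": {"H": 8.23, "N": 120.5, "HA": 4.34, "CA": 56.0, "CB": 30.9},
    "N": {"H": 8.40, "N": 118.7, "HA": 4.74, "CA": 52.8, "CB": 37.9},
    "D": {"H": 8.34, "N": 120.4, "HA": 4.64, "CA": 54.2, "CB": 41.1},
    "C": {"H": 8.32, "N": 118.8, "HA": 4.55, "CA": 56.9, "CB": 28.9},
    "E": {"H": 8.42, "N": 120.2, "HA": 4.35, "CA": 56.6, "CB": 29.9},
    "Q": {"H": 8.32, "N": 119.8, "HA": 4.34, "CA": 55.7, "CB": 29.4},
    "G": {"H": 8.33, "N": 108.8, "HA": 3.96, "CA": 45.1},
    "H": {"H": 8.42, "N": 118.2, "HA": 4.73, "CA": 55.0, "CB": 29.0},
    "I": {"H": 8.00, "N": 119.9, "HA": 4.17, "CA": 61.1, "CB": 38.8},
    "L": {"H": 8.16, "N": 121.8, "HA": 4.34, "CA": 55.1, "CB": 42.4},
    "K": {"H": 8.29, "N": 120.4, "HA": 4.32, "CA": 56.2, "CB": 33.1},
    "M": {"H": 8.28, "N": 119.6, "HA": 4.48, "CA": 55.4, "CB": 32.9},
    "F": {"H": 8.30, "N": 120.3, "HA": 4.62, "CA": 57.7, "CB": 39.6},
    "P": {"N": 136.8, "HA": 4.42, "CA": 63.3, "CB": 32.1},
    "S": {"H": 8.31, "N": 115.7, "HA": 4.47, "CA": 58.3, "CB": 63.8},
    "T": {"H": 8.15, "N": 113.6, "HA": 4.35, "CA": 61.8, "CB": 69.8},
    "W": {"H": 8.25, "N": 121.3, "HA": 4.66, "CA": 57.5, "CB": 29.6},
    "Y": {"H": 8.12, "N": 120.3, "HA": 4.55, "CA": 57.9, "CB": 38.8},
    "V": {"H": 8.03, "N": 119.2, "HA": 4.12, "CA": 62.2, "CB": 32.9},
}

AMINO_ACIDS = tuple(sorted(RANDOM_COIL))

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLU": "E", "GLN": "Q", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: Average secondary shifts (observed minus random coil, ppm) of a residue in
#: a fully-formed alpha-helix / extended beta-strand. Consensus values after
#: Wishart & Sykes (1994, CSI) and Marsh et al. (2006) Protein Sci 15, 2795.
OFFSET_PROVENANCE = (
    "Consensus fully-formed helix/strand secondary shifts after "
    "Wishart & Sykes (1994) J. Biomol. NMR 4, 171-180 and "
    "Marsh et al. (2006) Protein Sci 15, 2795-2804"
)

HELIX_OFFSET: dict[str, float] = {
    "CA": 2.8, "CB": -0.5, "HA": -0.38, "H": -0.25, "N": -2.5,
}
STRAND_OFFSET: dict[str, float] = {
    "CA": -1.6, "CB": 2.3, "HA": 0.45, "H": 0.30, "N": 1.9,
}

#: Relative weight of each nucleus in the SSP windowed average. Carbon shifts
#: dominate; amide H/N are down-weighted because they respond strongly to
#: non-structural factors (H-bonding to solvent, pH, temperature).
NUCLEUS_WEIGHT: dict[str, float] = {
    "CA": 1.0, "CB": 1.0, "HA": 0.8, "H": 0.3, "N": 0.3,
}

#: Correction to the random-coil value of a residue followed by proline.
#: Only the large, well-established Calpha effect is applied by default.
PRO_SUCCESSOR_CORRECTION: dict[str, float] = {"CA": -2.0}
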