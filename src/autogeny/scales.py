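"""Per-residue physicochemical scales shipped as fixed constants.

One published scale per protein profile track:

* ``HELIX``  -- Chou & Fasman alpha-helix conformational propensity (P_alpha).
* ``SHEET``  -- Chou & Fasman beta-sheet conformational propensity (P_beta).
* ``HBOND``  -- side-chain hydrogen-bond donor + acceptor capacity
  (count of side-chain atoms that can donate or accept an H bond).
* ``POLAR``  -- Grantham polarity.

plus the scales used by the disorder surrogate:

* ``KD_HYDROPATHY`` -- Kyte & Doolittle hydropathy.
* ``CHARGE``        -- formal side-chain charge at neutral pH (His 0.1).

``X`` is handled by the consumers (it contributes the scale mean).
"""

from __future__ import annotations

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

HELIX = {
    "A": 1.42, "C": 0.70, "D": 1.01, "E": 1.51, "F": 1.13,
    "G": 0.57, "H": 1.00, "I": 1.08, "K": 1.16, "L": 1.21,
    "M": 1.45, "N": 0.67, "P": 0.57, "Q": 1.11, "R": 0.98,
    "S": 0.77, "T": 0.83, "V": 1.06, "W": 1.08, "Y": 0.69,
}

SHEET = {
    "A": 0.83, "C": 1.19, "D": 0.54, "E": 0.37, "F": 1.38,
    "G": 0.75, "H": 0.87, "I": 1.60, "K": 0.74, "L": 1.30,
    "M": 1.05, "N": 0.89, "P": 0.55, "Q": 1.10, "R": 0.93,
    "S": 0.75, "T": 1.19, "V": 1.70, "W": 1.37, "Y": 1.47,
}

# donor + acceptor capacity of the side chain
HBOND = {
    "A": 0.0, "C": 1.0, "D": 2.0, "E": 2.0, "F": 0.0,
    "G": 0.0, "H": 2.0, "I": 0.0, "K": 2.0, "L": 0.0,
    "M": 0.0, "N": 4.0, "P": 0.0, "Q": 4.0, "R": 4.0,
    "S": 2.0, "T": 2.0, "V": 0.0, "W": 1.0, "Y": 2.0,
}

POLAR = {
    "A": 8.1, "C": 5.5, "D": 13.0, "E": 12.3, "F": 5.2,
    "G": 9.0, "H": 10.4, "I": 5.2, "K": 11.3, "L": 4.9,
    "M": 5.7, "N": 11.6, "P": 8.0, "Q": 10.5, "R": 10.5,
    "S": 9.2, "T": 8.6, "V": 5.9, "W": 5.4, "Y": 6.2,
}

KD_HYDROPATHY = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8,
    "G": -0.4, "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8,
    "M": 1.9, "N": -3.5, "P": -1.6, "Q": -3.5, "R": -4.5,
    "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3,
}

CHARGE = {
    "A": 0.0, "C": 0.0, "D": -1.0, "E": -1.0, "F": 0.0,
    "G": 0.0, "H": 0.1, "I": 0.0, "K": 1.0, "L": 0.0,
    "M": 0.0, "N": 0.0, "P": 0.0, "Q": 0.0, "R": 0.0,
    "S": 0.0, "T": 0.0, "V": 0.0, "W": 0.0, "Y": 0.0,
}
# Arg carries +1 at neutral pH
CHARGE["R"] = 1.0

# background amino-acid composition (UniProt/Swiss-Prot average frequencies),
# used for random reference sequences and synthetic backgrounds
AA_BACKGROUND = {
    "A": 0.0826, "C": 0.0139, "D": 0.0546, "E": 0.0672, "F": 0.0387,
    "G": 0.0707, "H": 0.0228, "I": 0.0591, "K": 0.0580, "L": 0.0965,
    "M": 0.0241, "N": 0.0406, "P": 0.0475, "Q": 0.0393, "R": 0.0553,
    "S": 0.0665, "T": 0.0536, "V": 0.0686, "W": 0.0110, "Y": 0.0292,
}

NUCLEOTIDES = "ACGU"

# uniform RNA background
NT_BACKGROUND = {"A": 0.25, "C": 0.25, "G": 0.25, "U": 0.25}


def scale_mean(scale: dict[str, float]) -> float:
    return sum(scale.values()) / len(scale)
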