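"""Versioned default configuration constants for the surrogate scorer.

Everything numeric about the shipped default model lives here, never inline
in logic.  The affine calibration (slope/intercept) was fixed once against
the default synthetic background (random pathway-annotated catalogs drawn
from the shipped residue compositions) so that random background pairs have
a sample mean propensity of ~16 and a standard deviation of ~6; on this
scale the 50/100/150 threshold grid singles out increasingly specific
interactions and planted strong binders typically exceed 50.
"""

from __future__ import annotations

import numpy as np

from .propensity import PROTEIN_TRACKS, RNA_TRACKS, InteractionModel

CONFIG_SCHEMA_VERSION = "1"

#: fixed-dimensional profile representation size
DEFAULT_N_COEFF = 50

#: coefficients carrying weight in the default model (beyond: zero)
WEIGHTED_COEFFS = 40

#: channel weights of the default bilinear model.  Only the hydrogen-bonding
#: protein track couples to the RNA tracks: H-bonding is the dominant
#: chemistry of protein-RNA contacts, and a sparse model keeps the score
#: interpretable.  The DC (k=0) weight is kept small so bulk composition
#: alone cannot dominate positional agreement between the two molecules.
W_HBOND_GC = 1.0
W_HBOND_GC_DC = 0.05
#: the pairedness track comes from a long (101 nt) folding window, so only
#: its low-frequency shape is meaningful; weighting it beyond the first few
#: coefficients would only inject noise
W_HBOND_PAIRING = 0.1
W_HBOND_PAIRING_DC = 0.05
PAIRING_COEFFS = 8

#: affine calibration of the raw bilinear score (fixed once, see module doc)
CAL_SLOPE = 864.72
CAL_INTERCEPT = -51.41

#: propensity gained by a fully planted binder pair at the default
#: calibration; the synthetic generator maps its motif_strength onto the
#: planted-feature mixing coefficient through this reference value
FULL_STRENGTH_BOOST = 67.0

#: generator default: planted binders gain ~ this much propensity
DEFAULT_MOTIF_STRENGTH = 67.0

DEFAULT_SMOOTHING_WINDOW = 7
DEFAULT_PAIRING_WINDOW = 101
DEFAULT_GC_WINDOW = 7


def default_weights(n_coeff: int = DEFAULT_N_COEFF) -> np.ndarray:
    w = np.zeros((len(PROTEIN_TRACKS), len(RNA_TRACKS), n_coeff))
    i_hbond = PROTEIN_TRACKS.index("hbond")
    j_pairing = RNA_TRACKS.index("pairing")
    j_gc = RNA_TRACKS.index("gc")
    k_max = min(WEIGHTED_COEFFS, n_coeff)
    w[i_hbond, j_gc, 1:k_max] = W_HBOND_GC
    w[i_hbond, j_gc, 0] = W_HBOND_GC_DC
    w[i_hbond, j_pairing, 1 : min(PAIRING_COEFFS, n_coeff)] = W_HBOND_PAIRING
    w[i_hbond, j_pairing, 0] = W_HBOND_PAIRING_DC
    return w


def default_model(n_coeff: int = DEFAULT_N_COEFF) -> InteractionModel:
    return InteractionModel(
        n_coeff=n_coeff,
        weights=default_weights(n_coeff),
        slope=CAL_SLOPE,
        intercept=CAL_INTERCEPT,
        smoothing_window=DEFAULT_SMOOTHING_WINDOW,
        pairing_window=DEFAULT_PAIRING_WINDOW,
        gc_window=DEFAULT_GC_WINDOW,
    )
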