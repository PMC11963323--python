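"""Bundled reference tables for worked examples and validation.

A ten-granule external-validation campaign: for each reference granule a
placebo was formulated from the model's predicted pigment doses, both
powders were measured, and the pair was scored with delta E (on Lab) and
RGB cosine similarity, alongside a 20-rater sensory panel. The printed
measurements are shipped here so the headline numbers (mean delta E
2.7734, mean COS 0.9999, six pairs at delta E <= 3, manual similarity
0.9366) can be recomputed from raw inputs at any time.
"""

from __future__ import annotations

import pandas as pd

from .colors import LabColor, RGBColor
from .dataio import PigmentFormula
from .evaluate import ColorPair

__all__ = [
    "external_validation_pairs",
    "external_validation_table",
    "manual_evaluation_table",
    "predicted_formulas",
]

# name, (ref B, G, R), (ref L, a, b), (pla B, G, R), (pla L, a, b)
_VALIDATION_ROWS = [
    ("No.1", (166, 205, 224), (83, 1, 22), (166, 209, 229), (84, 0, 24)),
    ("No.2", (144, 185, 203), (76, 0, 23), (148, 186, 203), (76, 0, 21)),
    ("No.3", (127, 159, 176), (66, 1, 19), (129, 161, 181), (67, 2, 19)),
    ("No.4", (83, 127, 146), (54, 1, 27), (92, 134, 152), (57, 1, 25)),
    ("No.5", (43, 70, 89), (31, 4, 19), (37, 63, 80), (28, 4, 19)),
    ("No.6", (142, 165, 169), (68, -3, 12), (151, 173, 181), (71, -1, 12)),
    ("No.7", (96, 135, 157), (57, 3, 24), (105, 142, 166), (60, 4, 23)),
    ("No.8", (80, 119, 142), (51, 3, 25), (92, 130, 154), (56, 4, 24)),
    ("No.9", (153, 195, 215), (79, 1, 24), (150, 194, 214), (79, 0, 25)),
    ("No.10", (130, 168, 189), (70, 2, 22), (132, 171, 195), (71, 3, 23)),
]

# name, drug A mean, drug A SD, drug B mean, drug B SD, paired-t p, manual COS
_MANUAL_ROWS = [
    ("No.1", 2.20, 0.70, 2.55, 0.60, 0.069, 0.9460),
    ("No.2", 2.35, 0.59, 2.10, 0.72, 0.135, 0.9526),
    ("No.3", 2.45, 0.60, 2.05, 0.69, 0.017, 0.9570),
    ("No.4", 1.95, 0.89, 2.10, 0.72, 0.481, 0.9258),
    ("No.5", 2.10, 0.64, 1.80, 0.70, 0.110, 0.9254),
    ("No.6", 2.10, 0.85, 2.30, 0.73, 0.330, 0.9285),
    ("No.7", 1.95, 0.60, 1.65, 0.75, 0.083, 0.9107),
    ("No.8", 1.95, 0.76, 1.70, 0.73, 0.204, 0.9101),
    ("No.9", 2.35, 0.67, 2.15, 0.59, 0.258, 0.9490),
    ("No.10", 2.40, 0.60, 2.10, 0.64, 0.055, 0.9610),
]

# name, caramel mg, lemon yellow mg, carmine mg, indigo mg (per 20.00 g)
_FORMULA_ROWS = [
    ("No.1", 25.79, 3.19, 7.22, 0.00),
    ("No.2", 45.14, 4.56, 8.41, 0.00),
    ("No.3", 91.85, 3.81, 15.36, 0.00),
    ("No.4", 181.83, 20.31, 25.11, 0.05),
    ("No.5", 797.40, 153.02, 265.12, 0.00),
    ("No.6", 85.53, 0.16, 3.25, 0.73),
    ("No.7", 155.01, 13.74, 8.37, 0.00),
    ("No.8", 181.84, 17.42, 56.61, 0.00),
    ("No.9", 34.74, 3.55, 7.94, 0.00),
    ("No.10", 70.5, 5.53, 17.11, 0.02),
]


def external_validation_pairs() -> list[ColorPair]:
    """The ten reference/placebo pairs with measured RGB and Lab."""
    pairs = []
    for name, (rb, rg, rr), (rl, ra, rbb), (pb, pg, pr), (pl, pa, pbb) in _VALIDATION_ROWS:
        pairs.append(
            ColorPair(
                name=name,
                reference_rgb=RGBColor(rr, rg, rb),
                placebo_rgb=RGBColor(pr, pg, pb),
                reference_lab=LabColor(rl, ra, rbb),
                placebo_lab=LabColor(pl, pa, pbb),
            )
        )
    return pairs


def external_validation_table() -> pd.DataFrame:
    """Same data in tabular form (channels in the B, G, R column order
    used by the measurement software)."""
    cols = ["name", "ref_B", "ref_G", "ref_R", "ref_L", "ref_a", "ref_b",
            "pla_B", "pla_G", "pla_R", "pla_L", "pla_a", "pla_b"]
    rows = [
        (name, *ref_bgr, *ref_lab, *pla_bgr, *pla_lab)
        for name, ref_bgr, ref_lab, pla_bgr, pla_lab in _VALIDATION_ROWS
    ]
    return pd.DataFrame(rows, columns=cols)


def manual_evaluation_table() -> pd.DataFrame:
    """Sensory-panel summary: per formulation, mean +/- SD of the 0-3
    scores in both blinded arms, paired-t p-value, and the manual
    similarity (COS) value."""
    return pd.DataFrame(
        _MANUAL_ROWS,
        columns=["name", "drug_a_mean", "drug_a_sd", "drug_b_mean", "drug_b_sd", "p_value", "cos"],
    )


def predicted_formulas() -> dict[str, PigmentFormula]:
    """The pigment formulas that produced the ten placebos."""
    return {
        name: PigmentFormula(c, l, m, i, excipient_g=20.00)
        for name, c, l, m, i in _FORMULA_ROWS
    }
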