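"""Similarity assessment between reference granules and placebos.

Each reference/placebo pair is scored with the CIELAB color difference
(delta E, computed on supplied Lab values when available, otherwise on
Lab derived from RGB) and the cosine similarity of the raw RGB vectors.
Aggregates report the mean delta E and COS plus counts under the
perceptibility thresholds delta E < 6 (at most slightly perceptible) and
delta E <= 3 (not noticeable to the naked eye).

Human sensory panels score drug/placebo pairs on a 0-3 identity scale;
the paired t-test compares the two arms' scores at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .colors import LabColor, RGBColor, classify_delta_e, cosine_similarity, delta_e, rgb_to_lab

__all__ = ["ColorPair", "SimilarityReport", "PairedScores", "evaluate_pairs", "paired_t_test", "manual_summary"]


@dataclass(frozen=True)
class ColorPair:
    """Reference granule and candidate placebo; Lab is optional and,
    when supplied (e.g. transcribed from a colorimeter), authoritative."""

    name: str
    reference_rgb: RGBColor
    placebo_rgb: RGBColor
    reference_lab: LabColor | None = None
    placebo_lab: LabColor | None = None


@dataclass
class SimilarityReport:
    rows: pd.DataFrame
    mean_delta_e: float
    mean_cos: float
    n_delta_e_below_6: int
    n_delta_e_le_3: int


def evaluate_pairs(pairs: Sequence[ColorPair]) -> SimilarityReport:
    """Score every pair and aggregate; raises on an empty list."""
    if not pairs:
        raise ValueError("no color pairs to evaluate")
    records = []
    for p in pairs:
        ref_lab = p.reference_lab if p.reference_lab is not None else rgb_to_lab(p.reference_rgb)
        pla_lab = p.placebo_lab if p.placebo_lab is not None else rgb_to_lab(p.placebo_rgb)
        de = delta_e(ref_lab, pla_lab)
        cos = cosine_similarity(p.reference_rgb, p.placebo_rgb)
        records.append(
            {
                "name": p.name,
                "ref_R": p.reference_rgb.r, "ref_G": p.reference_rgb.g, "ref_B": p.reference_rgb.b,
                "pla_R": p.placebo_rgb.r, "pla_G": p.placebo_rgb.g, "pla_B": p.placebo_rgb.b,
                "ref_L": ref_lab.L, "ref_a": ref_lab.a, "ref_b": ref_lab.b,
                "pla_L": pla_lab.L, "pla_a": pla_lab.a, "pla_b": pla_lab.b,
                "delta_e": de,
                "band": classify_delta_e(de).label,
                "cos": cos,
            }
        )
    rows = pd.DataFrame(records)
    return SimilarityReport(
        rows=rows,
        mean_delta_e=float(rows["delta_e"].mean()),
        mean_cos=float(rows["cos"].mean()),
        n_delta_e_below_6=int((rows["delta_e"] < 6.0).sum()),
        n_delta_e_le_3=int((rows["delta_e"] <= 3.0).sum()),
    )


@dataclass
class PairedScores:
    """Per-rater similarity scores (0-3 integers) for the two blinded
    arms, plus the test's significance level."""

    drug_a: np.ndarray
    drug_b: np.ndarray
    alpha: float = 0.05

    def __post_init__(self) -> None:
        self.drug_a = np.asarray(self.drug_a, dtype=float)
        self.drug_b = np.asarray(self.drug_b, dtype=float)
        if self.drug_a.shape != self.drug_b.shape:
            raise ValueError("paired score vectors must have equal length")
        for arr in (self.drug_a, self.drug_b):
            if not np.all(np.isin(arr, [0, 1, 2, 3])):
                raise ValueError("scores must be integers on the 0-3 scale")


def paired_t_test(scores: PairedScores) -> tuple[float, float, bool]:
    """Classical paired t-test on A-B differences (df = n-1); returns
    (t, two-sided p, reject at alpha).

    All-zero differences give the degenerate but well-defined t = 0,
    p = 1; a nonzero constant difference has zero variance and no finite
    t, which raises instead.
    """
    d = scores.drug_a - scores.drug_b
    n = d.size
    if n < 2:
        raise ValueError("need at least 2 paired observations")
    if np.ptp(d) == 0:
        if d[0] == 0:
            return 0.0, 1.0, False
        raise ValueError("constant nonzero differences: t statistic is unbounded")
    res = stats.ttest_rel(scores.drug_a, scores.drug_b)
    t, p = float(res.statistic), float(res.pvalue)
    return t, p, p < scores.alpha


def manual_summary(cos_values: Sequence[float]) -> float:
    """Arithmetic mean of per-formulation manual similarity values,
    reported at 4 decimals."""
    vals = np.asarray(list(cos_values), dtype=float)
    if vals.size == 0:
        raise ValueError("no manual similarity values supplied")
    return float(np.round(vals.mean(), 4))
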