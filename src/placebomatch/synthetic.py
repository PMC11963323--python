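"""Forward pigment-mixing simulator and library generator.

Real pigment/color libraries for granule placebos are proprietary, so
end-to-end testing uses a physically motivated stand-in: each pigment
attenuates the three camera channels exponentially (optical-density
additivity, a Beer-Lambert-style law), darkening the near-white excipient
base color

    channel_c = base_c * exp(-sum_j K[c, j] * dose_j) + noise.

The default attenuation matrix encodes the pigments' hues: caramel (brown)
absorbs B > G > R, lemon yellow absorbs blue, carmine absorbs green,
indigo absorbs red strongest. The library design draws doses from a
light and a dark regime (split on caramel, the dominant pigment), giving
the two-population color structure that motivates cluster-then-regress,
with dose ranges spanning the realistic formulation space (caramel up to
800 mg, lemon yellow 155 mg, carmine 265 mg, indigo fractions of a mg per
20 g excipient batch).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .colors import RGBColor
from .dataio import GranuleSample, PigmentFormula

__all__ = ["ForwardModel", "forward_mix", "generate_library", "generate_queries"]

#: rows: R, G, B; columns: caramel, lemon yellow, carmine, indigo (per mg)
DEFAULT_K = np.array(
    [
        [0.0015, 0.0002, 0.0005, 0.060],
        [0.0016, 0.0005, 0.0016, 0.030],
        [0.0020, 0.0035, 0.0012, 0.005],
    ]
)

DEFAULT_BASE = RGBColor(253.0, 251.0, 250.0)


@dataclass
class ForwardModel:
    """Exponential-attenuation color formation model.

    ``attenuation`` is the 3x4 per-mg optical density matrix, ``base_color``
    the pure-excipient powder color, ``noise_sd`` the Gaussian measurement
    noise in channel units (0 disables noise).
    """

    attenuation: np.ndarray = field(default_factory=lambda: DEFAULT_K.copy())
    base_color: RGBColor = DEFAULT_BASE
    noise_sd: float = 2.0
    seed: int = 42

    def __post_init__(self) -> None:
        self.attenuation = np.asarray(self.attenuation, dtype=float)
        if self.attenuation.shape != (3, 4):
            raise ValueError("attenuation matrix must be 3 channels x 4 pigments")
        if np.any(self.attenuation <= 0):
            raise ValueError("attenuation coefficients must be positive")
        self._rng = np.random.default_rng(self.seed)


def forward_mix(
    model: ForwardModel,
    formula: PigmentFormula,
    rng: np.random.Generator | None = None,
) -> RGBColor:
    """Render the powder color of a formula; deterministic at noise 0,
    strictly decreasing in every dose on every channel."""
    doses = formula.doses()
    channels = np.array([model.base_color.r, model.base_color.g, model.base_color.b])
    channels = channels * np.exp(-model.attenuation @ doses)
    if model.noise_sd > 0:
        gen = rng if rng is not None else model._rng
        channels = channels + gen.normal(0.0, model.noise_sd, size=3)
    channels = np.clip(channels, 0.0, 255.0)
    return RGBColor(*channels)


def _draw_formulas(n: int, design: str, rng: np.random.Generator) -> list[PigmentFormula]:
    if design == "paperlike":
        # light/dark regimes split on caramel; lemon & carmine stay small
        # in light formulations, matching real placebo recipes
        dark = rng.random(n) < 0.5
        caramel = np.where(
            dark,
            200.0 + 600.0 * rng.beta(1.5, 1.5, size=n),
            200.0 * rng.beta(1.0, 1.5, size=n),
        )
        lemon = np.where(dark, rng.uniform(0.0, 155.0, n), 25.0 * rng.beta(1.0, 2.0, size=n))
        carmine = np.where(dark, rng.uniform(0.0, 265.0, n), 60.0 * rng.beta(1.0, 2.0, size=n))
    elif design == "uniform":
        caramel = rng.uniform(0.0, 800.0, n)
        lemon = rng.uniform(0.0, 155.0, n)
        carmine = rng.uniform(0.0, 265.0, n)
    else:
        raise ValueError(f"unknown design {design!r}")
    indigo = np.where(rng.random(n) < 0.8, 0.0, rng.uniform(0.0, 1.0, n))
    return [
        PigmentFormula(float(c), float(l), float(m), float(i))
        for c, l, m, i in zip(caramel, lemon, carmine, indigo)
    ]


def generate_library(
    model: ForwardModel | None = None,
    n: int = 323,
    design: str = "paperlike",
    seed: int = 42,
) -> list[GranuleSample]:
    """Generate a simulated pigment/color training library.

    Every sample carries its formula; colors include the model's
    measurement noise. Reproducible from ``seed`` alone (the model's own
    seed is not consumed).
    """
    if n < 2:
        raise ValueError("need at least 2 library samples")
    model = model or ForwardModel()
    rng = np.random.default_rng(seed)
    formulas = _draw_formulas(n, design, rng)
    return [
        GranuleSample(
            sample_id=f"SIM{i + 1:04d}",
            color=forward_mix(model, f, rng=rng),
            formula=f,
            source="simulated",
        )
        for i, f in enumerate(formulas)
    ]


def generate_queries(
    model: ForwardModel | None = None,
    n: int = 50,
    design: str = "paperlike",
    seed: int = 7,
) -> tuple[list[GranuleSample], list[PigmentFormula]]:
    """Fresh query colors from the same dose regimes, with the hidden
    ground-truth formulas returned separately for recovery scoring."""
    if n == 0:
        return [], []
    model = model or ForwardModel()
    rng = np.random.default_rng(seed)
    formulas = _draw_formulas(n, design, rng)
    queries = [
        GranuleSample(
            sample_id=f"Q{i + 1:04d}",
            color=forward_mix(model, f, rng=rng),
            formula=None,
            source="measured",
        )
        for i, f in enumerate(formulas)
    ]
    return queries, formulas
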