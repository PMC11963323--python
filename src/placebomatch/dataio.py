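"""Dataset schema, CSV readers/writers and the z-score standardizer.

The on-disk format is a plain comma-separated table with a mandatory
header. A *training* file carries colors plus known pigment doses, a
*query* file carries colors only::

    sample_id,R,G,B,caramel_mg,lemon_yellow_mg,carmine_mg,indigo_mg,excipient_g
    S1,224,205,166,25.79,3.19,7.22,0.00,20.00

Doses are mg of pigment per fixed excipient batch (20.00 g of a 4:1
lactose/dextrin base by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .colors import RGBColor

__all__ = [
    "PigmentFormula",
    "GranuleSample",
    "Standardizer",
    "PIGMENT_COLUMNS",
    "read_dataset",
    "write_dataset",
    "samples_to_frame",
    "save_model",
    "load_model",
]

PIGMENT_COLUMNS = ("caramel_mg", "lemon_yellow_mg", "carmine_mg", "indigo_mg")
_COLOR_COLUMNS = ("R", "G", "B")
_ALL_COLUMNS = ("sample_id", *_COLOR_COLUMNS, *PIGMENT_COLUMNS, "excipient_g")

DatasetKind = Literal["training", "query", "evaluation"]


@dataclass(frozen=True)
class PigmentFormula:
    """Doses (mg) of the four-pigment system per excipient batch.

    Caramel supplies the brown base tone; lemon yellow, carmine and
    indigo fine-tune hue. Indigo doses are typically fractions of a mg.
    """

    caramel_mg: float
    lemon_yellow_mg: float
    carmine_mg: float
    indigo_mg: float
    excipient_g: float = 20.00

    def __post_init__(self) -> None:
        for name in PIGMENT_COLUMNS:
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0.0:
                raise ValueError(f"{name}={v!r} must be a finite non-negative dose")
        if not math.isfinite(self.excipient_g) or self.excipient_g <= 0.0:
            raise ValueError(f"excipient_g={self.excipient_g!r} must be positive")

    def doses(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PIGMENT_COLUMNS], dtype=float)


@dataclass
class GranuleSample:
    """One powder sample: its measured mean color, optionally the pigment
    formula that produced it and a cluster assignment."""

    sample_id: str
    color: RGBColor
    formula: PigmentFormula | None = None
    cluster: int | None = None
    source: Literal["measured", "simulated"] = "measured"

    def __post_init__(self) -> None:
        if self.source not in ("measured", "simulated"):
            raise ValueError(f"unknown source {self.source!r}")
        if self.source == "simulated" and self.formula is None:
            raise ValueError(f"simulated sample {self.sample_id!r} must carry a formula")
        if self.cluster is not None and self.cluster < 0:
            raise ValueError("cluster label must be non-negative")


def _parse_error(path: Path | str, row: int, column: str, msg: str) -> ValueError:
    return ValueError(f"{path}: row {row}, column {column!r}: {msg}")


def read_dataset(path: str | Path, kind: DatasetKind = "training") -> list[GranuleSample]:
    """Read a granule dataset CSV; validates channel bounds and dose
    non-negativity, reporting the offending row/column on failure.

    ``kind='query'`` requires only the color columns; ``'training'`` and
    ``'evaluation'`` read doses when the columns are present.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["sample_id", *_COLOR_COLUMNS]
    if kind == "training":
        required += list(PIGMENT_COLUMNS)
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    has_doses = all(c in df.columns for c in PIGMENT_COLUMNS)

    samples: list[GranuleSample] = []
    for i, rec in enumerate(df.to_dict("records")):
        rownum = i + 2  # header is line 1
        vals: dict[str, float] = {}
        for col in df.columns:
            if col == "sample_id":
                continue
            raw = rec[col]
            try:
                vals[col] = float(raw)
            except (TypeError, ValueError):
                raise _parse_error(path, rownum, col, f"non-numeric value {raw!r}") from None
        for col in _COLOR_COLUMNS:
            if not 0.0 <= vals[col] <= 255.0:
                raise _parse_error(path, rownum, col, f"channel {vals[col]} outside [0, 255]")
        formula = None
        if has_doses:
            for col in PIGMENT_COLUMNS:
                if vals[col] < 0.0:
                    raise _parse_error(path, rownum, col, f"negative dose {vals[col]}")
            formula = PigmentFormula(
                *(vals[c] for c in PIGMENT_COLUMNS),
                excipient_g=vals.get("excipient_g", 20.00),
            )
        samples.append(
            GranuleSample(
                sample_id=str(rec["sample_id"]),
                color=RGBColor(vals["R"], vals["G"], vals["B"]),
                formula=formula,
                source="simulated" if formula is not None else "measured",
            )
        )
    return samples


def samples_to_frame(samples: Sequence[GranuleSample], with_doses: bool | None = None) -> pd.DataFrame:
    """Tabulate samples; ``with_doses=None`` includes dose columns iff
    every sample carries a formula."""
    if with_doses is None:
        with_doses = len(samples) > 0 and all(s.formula is not None for s in samples)
    rows = []
    for s in samples:
        row: dict[str, object] = {
            "sample_id": s.sample_id,
            "R": s.color.r,
            "G": s.color.g,
            "B": s.color.b,
        }
        if with_doses:
            if s.formula is None:
                raise ValueError(f"sample {s.sample_id!r} has no formula")
            for col in PIGMENT_COLUMNS:
                row[col] = getattr(s.formula, col)
            row["excipient_g"] = s.formula.excipient_g
        rows.append(row)
    cols = list(_ALL_COLUMNS) if with_doses else ["sample_id", *_COLOR_COLUMNS]
    return pd.DataFrame(rows, columns=cols)


def write_dataset(samples: Sequence[GranuleSample], path: str | Path, kind: DatasetKind = "training") -> None:
    """Write samples as CSV; round-trips losslessly through
    :func:`read_dataset` (doses at full double precision)."""
    with_doses = kind != "query" and all(s.formula is not None for s in samples)
    df = samples_to_frame(samples, with_doses=with_doses)
    df.to_csv(Path(path), index=False, float_format="%.17g")


@dataclass
class Standardizer:
    """Per-channel z-scoring fitted on training colors.

    Uses the sample standard deviation (n-1 denominator). New data is
    always transformed with the *training* statistics, never refitted.
    """

    mean_: np.ndarray | None = None
    sd_: np.ndarray | None = None
    feature_names: tuple[str, ...] = _COLOR_COLUMNS

    @property
    def fitted(self) -> bool:
        return self.mean_ is not None

    def fit(self, colors: "Iterable[RGBColor] | np.ndarray") -> "Standardizer":
        X = _colors_to_array(colors)
        if X.shape[0] < 2:
            raise ValueError("need at least 2 samples to fit a standardizer")
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        for j, s in enumerate(sd):
            if s <= 0.0:
                raise ValueError(
                    f"channel {self.feature_names[j]!r} is constant across samples; "
                    "cannot standardize a degenerate feature"
                )
        self.mean_, self.sd_ = mean, sd
        return self

    def _check(self) -> None:
        if not self.fitted:
            raise ValueError("standardizer is not fitted")

    def transform(self, colors: "Iterable[RGBColor] | np.ndarray") -> np.ndarray:
        self._check()
        return (_colors_to_array(colors) - self.mean_) / self.sd_

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        self._check()
        return np.asarray(Z, dtype=float) * self.sd_ + self.mean_


def _colors_to_array(colors: "Iterable[RGBColor] | np.ndarray") -> np.ndarray:
    if isinstance(colors, np.ndarray):
        X = np.atleast_2d(np.asarray(colors, dtype=float))
    else:
        X = np.array(
            [c.as_array() if isinstance(c, RGBColor) else np.asarray(c, dtype=float) for c in colors]
        )
        X = np.atleast_2d(X)
    if X.ndim != 2 or X.shape[1] != 3:
        raise ValueError(f"expected an (n, 3) array of colors, got shape {X.shape}")
    return X


def save_model(bundle, path: str | Path) -> None:
    """Persist a fitted pipeline archive (see :mod:`placebomatch.pipeline`)."""
    from .pipeline import save_model as _save

    _save(bundle, path)


def load_model(path: str | Path):
    """Load and self-verify a fitted pipeline archive."""
    from .pipeline import load_model as _load

    return _load(path)
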