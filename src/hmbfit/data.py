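"""Rate-versus-time datasets.

The atomic datum is one observation of evolutionary change over an
interval: a numerator (magnitude of change, e.g. |x2 - x1| in trait
units), a duration, and their ratio, the rate.  A dataset is a column
store of such observations plus the transform used on the rate scale
when fitting (natural log, or log1p when zero rates are present).

Tree-derived rates (e.g. birth rates from a clade) carry a separate
``denominator`` — the total branch length actually dividing the event
count — while ``time`` stores the clade age used for plotting and
fitting.  For paired comparisons the two coincide.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Literal, NamedTuple

import numpy as np
import pandas as pd

from .errors import ValidationError

Transform = Literal["log", "log1p"]

#: Relative tolerance for the rate == numerator / denominator invariant.
_RATE_RTOL = 1e-6


class RateObservation(NamedTuple):
    """One (numerator, time, rate) triple.

    ``denominator`` is the quantity the numerator is divided by to give
    the rate; it equals ``time`` except for tree-derived rates where it
    is the total branch length and ``time`` is the clade age.
    """

    numerator: float
    time: float
    rate: float
    denominator: float


def compute_rate(numerator: float, time: float) -> float:
    """Rate as magnitude of change divided by elapsed time.

    Raises ``ValidationError`` for non-positive time.
    """
    if time <= 0:
        raise ValidationError(f"time must be positive, got {time}")
    if numerator < 0:
        raise ValidationError(f"numerator is a magnitude and must be >= 0, got {numerator}")
    return numerator / time


def apply_transform(x: np.ndarray, transform: Transform) -> np.ndarray:
    """Natural log or log1p of an array of rates/predictions."""
    if transform == "log":
        return np.log(x)
    if transform == "log1p":
        return np.log1p(x)
    raise ValidationError(f"unknown transform {transform!r}")


@dataclass
class RateDataset:
    """A column-store of rate observations.

    Parameters
    ----------
    time:
        Interval durations (clade ages for tree-derived data), > 0.
    rate:
        Rates, >= 0.
    numerator:
        Magnitudes of change.  If omitted, imputed as ``rate * denominator``.
    denominator:
        Divisor of the numerator; defaults to ``time``.
    transform:
        ``"log"`` or ``"log1p"``; resolved automatically when ``None``
        (log1p if and only if a zero rate is present).
    source_kind:
        ``"paired-comparison"`` or ``"tree-derived"``.
    """

    time: np.ndarray
    rate: np.ndarray
    numerator: np.ndarray | None = None
    denominator: np.ndarray | None = None
    name: str = ""
    transform: Transform | None = None
    source_kind: Literal["paired-comparison", "tree-derived"] = "paired-comparison"
    ground_truth: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if self.time.ndim != 1 or self.time.size == 0:
            raise ValidationError("dataset must contain at least one observation")
        if self.rate.shape != self.time.shape:
            raise ValidationError("time and rate must have equal length")
        if np.any(~np.isfinite(self.time)) or np.any(self.time <= 0):
            bad = int(np.flatnonzero(~(self.time > 0))[0])
            raise ValidationError(f"non-positive or non-finite time at row {bad}")
        if np.any(~np.isfinite(self.rate)) or np.any(self.rate < 0):
            bad = int(np.flatnonzero(~(self.rate >= 0))[0])
            raise ValidationError(f"negative or non-finite rate at row {bad}")
        if self.denominator is None:
            self.denominator = self.time.copy()
        else:
            self.denominator = np.asarray(self.denominator, dtype=float)
            if self.denominator.shape != self.time.shape or np.any(self.denominator <= 0):
                raise ValidationError("denominator must be positive and match length")
        if self.numerator is None:
            self.numerator = self.rate * self.denominator
        else:
            self.numerator = np.asarray(self.numerator, dtype=float)
            if self.numerator.shape != self.time.shape:
                raise ValidationError("numerator must match length")
            if np.any(self.numerator < 0):
                raise ValidationError("numerator is a magnitude and must be >= 0")
            implied = self.numerator / self.denominator
            scale = np.maximum(np.abs(self.rate), 1e-12)
            if np.any(np.abs(implied - self.rate) > _RATE_RTOL * scale + 1e-12):
                bad = int(np.argmax(np.abs(implied - self.rate)))
                raise ValidationError(
                    f"rate != numerator / denominator at row {bad}: "
                    f"{self.rate[bad]} vs {implied[bad]}"
                )
        if self.transform is None:
            self.transform = choose_transform_for_rates(self.rate)
        elif self.transform == "log" and np.any(self.rate == 0):
            raise ValidationError("log transform invalid: dataset contains zero rates")
        elif self.transform not in ("log", "log1p"):
            raise ValidationError(f"unknown transform {self.transform!r}")

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return int(self.time.size)

    def __iter__(self) -> Iterator[RateObservation]:
        return iter(self.observations)

    @property
    def observations(self) -> list[RateObservation]:
        return [
            RateObservation(float(n), float(t), float(r), float(d))
            for n, t, r, d in zip(self.numerator, self.time, self.rate, self.denominator)
        ]

    @property
    def transformed_rate(self) -> np.ndarray:
        return apply_transform(self.rate, self.transform)

    # -- constructors / converters ------------------------------------------

    @classmethod
    def from_frame(cls, df: pd.DataFrame, name: str = "", **kwargs) -> "RateDataset":
        cols = {c.lower(): c for c in df.columns}
        if "time" not in cols or "rate" not in cols:
            raise ValidationError("columns 'time' and 'rate' are required")
        return cls(
            time=df[cols["time"]].to_numpy(float),
            rate=df[cols["rate"]].to_numpy(float),
            numerator=df[cols["numerator"]].to_numpy(float) if "numerator" in cols else None,
            denominator=df[cols["denominator"]].to_numpy(float) if "denominator" in cols else None,
            name=name,
            **kwargs,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.time,
                "rate": self.rate,
                "numerator": self.numerator,
                "denominator": self.denominator,
            }
        )

    def with_rates(self, numerator: np.ndarray, name: str | None = None) -> "RateDataset":
        """New dataset with the same times/denominators but a new numerator vector."""
        numerator = np.asarray(numerator, dtype=float)
        return replace(
            self,
            numerator=numerator,
            rate=numerator / self.denominator,
            transform=None,
            name=self.name if name is None else name,
            ground_truth={},
        )


def choose_transform_for_rates(rate: np.ndarray) -> Transform:
    rate = np.asarray(rate, dtype=float)
    if np.any(rate < 0):
        raise ValidationError("rates must be non-negative")
    return "log1p" if np.any(rate == 0) else "log"


def choose_transform(dataset: RateDataset) -> Transform:
    """log1p when any rate is exactly zero, else natural log.

    The chosen tag is stored on the dataset and returned.
    """
    tag = choose_transform_for_rates(dataset.rate)
    dataset.transform = tag
    return tag
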