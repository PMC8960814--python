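"""Real-time amplification curve analysis and clinical concordance.

The isothermal analogue of qPCR's Ct is the threshold time Tt: the first
time at which the fluorescence signal reaches 20 % of its maximum.  The
baseline (curve minimum) is subtracted before applying the fraction, which
makes Tt invariant to detector offset and to affine rescaling of the
signal; linear interpolation between samples matches common qPCR-software
behaviour.  Percentages are reported to one decimal, rounding half up.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "KineticCurve",
    "ThresholdTime",
    "ConcordanceTable",
    "ConcordanceResult",
    "normalize_curve",
    "threshold_time",
    "concordance",
    "relative_speedup",
    "read_curves",
]


@dataclass(frozen=True)
class KineticCurve:
    """A real-time fluorescence trace for one well/sample."""

    time_min: tuple
    signal: tuple
    sample_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.time_min, dtype=float)
        y = np.asarray(self.signal, dtype=float)
        if t.ndim != 1 or y.ndim != 1 or t.size != y.size:
            raise ValueError("time and signal must be equal-length 1-D vectors")
        if t.size < 2:
            raise ValueError("a kinetic curve needs at least 2 points")
        if not np.all(np.diff(t) > 0):
            raise ValueError("time points must be strictly increasing")
        object.__setattr__(self, "time_min", tuple(float(x) for x in t))
        object.__setattr__(self, "signal", tuple(float(x) for x in y))

    @property
    def t(self) -> np.ndarray:
        return np.asarray(self.time_min)

    @property
    def y(self) -> np.ndarray:
        return np.asarray(self.signal)


@dataclass(frozen=True)
class ThresholdTime:
    tt_min: Optional[float]  # None when the threshold is never reached
    fraction: float

    @property
    def defined(self) -> bool:
        return self.tt_min is not None


def normalize_curve(curve: KineticCurve) -> KineticCurve:
    """Min-max scale the signal to [0, 1]; affine-invariant, idempotent."""
    y = curve.y
    lo, hi = float(y.min()), float(y.max())
    if hi == lo:
        raise ValueError(f"curve {curve.sample_id!r}: constant signal cannot be normalised")
    return replace(curve, signal=tuple((y - lo) / (hi - lo)))


def threshold_time(
    curve: KineticCurve,
    fraction: float = 0.20,
    subtract_baseline: bool = True,
) -> ThresholdTime:
    """First time the signal reaches ``fraction`` of its maximum.

    With ``subtract_baseline`` (default) the curve minimum is removed first,
    so the 20 % rule applies to the amplitude above baseline.  Crossing
    times are linearly interpolated between adjacent samples; a curve that
    never reaches the level (e.g. all-zero) yields an undefined Tt.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    y = curve.y.copy()
    if subtract_baseline:
        y = y - y.min()
    peak = float(y.max())
    if peak <= 0:
        return ThresholdTime(None, fraction)
    level = fraction * peak
    t = curve.t
    above = y >= level
    if not above.any():
        return ThresholdTime(None, fraction)
    i = int(np.argmax(above))
    if i == 0:
        return ThresholdTime(float(t[0]), fraction)
    frac = (level - y[i - 1]) / (y[i] - y[i - 1])
    return ThresholdTime(float(t[i - 1] + frac * (t[i] - t[i - 1])), fraction)


@dataclass(frozen=True)
class ConcordanceTable:
    """2x2 method-agreement counts against a reference (gold-standard) method.

    Field order follows (test+/ref+, test-/ref+, test+/ref-, test-/ref-).
    """

    test_pos_ref_pos: int
    test_neg_ref_pos: int
    test_pos_ref_neg: int
    test_neg_ref_neg: int

    def __post_init__(self) -> None:
        counts = (
            self.test_pos_ref_pos,
            self.test_neg_ref_pos,
            self.test_pos_ref_neg,
            self.test_neg_ref_neg,
        )
        if any((not isinstance(c, int)) or c < 0 for c in counts):
            raise ValueError("concordance counts must be non-negative integers")
        if sum(counts) == 0:
            raise ValueError("concordance table total must be > 0")

    @property
    def total(self) -> int:
        return (
            self.test_pos_ref_pos
            + self.test_neg_ref_pos
            + self.test_pos_ref_neg
            + self.test_neg_ref_neg
        )


@dataclass(frozen=True)
class ConcordanceResult:
    overall_pct: float
    positive_pct: Optional[float]  # agreement among reference-positives
    negative_pct: Optional[float]  # agreement among reference-negatives


def _pct(numer: int, denom: int) -> Optional[float]:
    if denom == 0:
        return None
    raw = Decimal(100 * numer) / Decimal(denom)
    return float(raw.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def concordance(table: ConcordanceTable) -> ConcordanceResult:
    """Overall / positive / negative percent agreement, one decimal."""
    concordant = table.test_pos_ref_pos + table.test_neg_ref_neg
    return ConcordanceResult(
        overall_pct=_pct(concordant, table.total),
        positive_pct=_pct(
            table.test_pos_ref_pos, table.test_pos_ref_pos + table.test_neg_ref_pos
        ),
        negative_pct=_pct(
            table.test_neg_ref_neg, table.test_neg_ref_neg + table.test_pos_ref_neg
        ),
    )


def relative_speedup(tt_a: Optional[float], tt_b: Optional[float]) -> Optional[float]:
    """Percent speed-up of Tt_a relative to baseline Tt_b (positive = faster).

    Undefined inputs propagate to an undefined result.
    """
    if tt_a is None or tt_b is None:
        return None
    if tt_b <= 0:
        raise ValueError("baseline threshold time must be positive")
    return 100.0 * (tt_b - tt_a) / tt_b


def read_curves(path) -> list:
    """Read per-well curves from delimited text (time_min, signal, sample_id)."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"time_min", "signal", "sample_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"curve file {path}: missing column(s) {sorted(missing)}")
    curves = []
    for sid, sub in df.groupby("sample_id", sort=True):
        sub = sub.sort_values("time_min")
        curves.append(
            KineticCurve(
                time_min=tuple(sub["time_min"].astype(float)),
                signal=tuple(sub["signal"].astype(float)),
                sample_id=str(sid),
            )
        )
    return curves
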