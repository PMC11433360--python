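"""Shared containers for per-frame / per-stroke feature sequences.

A :class:`FeatureSeries` is the universal currency between the extraction
pipelines (speech, handwriting) and the lag-correlation imaging stage: a
named 1-D sequence of real values, one per analysis frame, glottal period,
or stroke.  Frames for which an estimator declines to produce a value
(unvoiced frames, unstable LPC fits) carry ``NaN`` as an explicit sentinel
and are dropped — never zero-filled — before correlation imaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FeatureSeries",
    "ValidationError",
    "FEATURE_VOCABULARY",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


#: Registered feature-series names.  Speech entries mirror the six acoustic
#: manifestation families; writing entries mirror the series-valued
#: handwriting attributes.
FEATURE_VOCABULARY = frozenset(
    {
        # speech
        "squared_energy",
        "tk_energy",
        "pitch",
        "phonatory_range",
        "zcr",
        "jitter_local_pct",
        "shimmer_local_pct",
        "f1_hz",
        "f2_hz",
        "nasality",
        "voice_breaks",
        # writing
        "slant_angle_deg",
        "uniformity",
        "writing_tremor_px",
    }
)


@dataclass
class FeatureSeries:
    """A named 1-D real-valued sequence with units.

    Parameters
    ----------
    name : str
        Identifier from :data:`FEATURE_VOCABULARY`.
    values : ndarray
        1-D float array.  ``NaN`` marks frames excluded by the estimator.
    units : str
        Physical units ("Hz", "dB", "%", "px", or "" for dimensionless).
    """

    name: str
    values: np.ndarray
    units: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.name not in FEATURE_VOCABULARY:
            raise ValidationError(
                f"unknown feature name {self.name!r}; expected one of "
                f"{sorted(FEATURE_VOCABULARY)}"
            )
        if np.any(np.isinf(self.values)):
            raise ValidationError(f"{self.name}: infinite values are not allowed")

    def __len__(self) -> int:
        return self.values.size

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    def valid_values(self) -> np.ndarray:
        """Values with sentinel (NaN) entries removed, order preserved."""
        return self.values[self.valid_mask]

    def dropna(self) -> "FeatureSeries":
        return FeatureSeries(self.name, self.valid_values(), self.units, dict(self.meta))


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with window shrinkage at the edges.

    The first/last points average over however much of the window fits
    inside the sequence, so output length equals input length and a linear
    ramp is reproduced exactly at interior points.
    """
    x = np.asarray(x, dtype=float)
    if window < 1:
        raise ValidationError("window must be >= 1")
    if x.size == 0:
        return x.copy()
    n = x.size
    half = window // 2
    csum = np.concatenate(([0.0], np.cumsum(x)))
    idx = np.arange(n)
    # symmetric shrinkage at the edges keeps the filter centered, so a
    # linear ramp is reproduced exactly everywhere (not just the interior)
    h = np.minimum(np.minimum(idx, n - 1 - idx), half)
    lo = idx - h
    hi = idx + h
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)
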