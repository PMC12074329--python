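"""Core data containers for CTG traces and model-ready windows.

A raw cardiotocography (CTG) recording carries two channels sampled on a
common grid: fetal heart rate (FHR, beats per minute) and uterine tone
(TOCO, relative units 0-100).  Missing samples are marked with the sentinel
``-1`` on the raw scale.  After unit scaling the sentinel disappears and
missingness is carried as an explicit boolean validity mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError

#: Sentinel marking a missing sample on the raw (unscaled) channels.
MISSING = -1.0

#: Number of samples in one standardised one-hour window.
WINDOW_LEN = 960

#: Seconds between consecutive samples (one hour / 960 steps).
SAMPLE_PERIOD_S = 3600.0 / WINDOW_LEN


@dataclass
class CTGTrace:
    """A raw two-channel CTG recording with clinical metadata.

    Parameters
    ----------
    trace_id : str
        Unique identifier.
    fhr, toco : ndarray, shape (T,)
        Fetal heart rate (bpm) and uterine tone (0-100); ``-1`` marks
        missing samples on either channel.
    label : int
        1 = adverse pregnancy outcome, 0 = normal.
    days_to_delivery : int
        Days between the recording and delivery (non-negative).
    covariates : dict
        Named numeric clinical covariates used for cohort matching.
    """

    trace_id: str
    fhr: np.ndarray
    toco: np.ndarray
    label: int
    days_to_delivery: int = 0
    covariates: dict = field(default_factory=dict)

    def __post_init__(self):
        self.fhr = np.asarray(self.fhr, dtype=np.float64)
        self.toco = np.asarray(self.toco, dtype=np.float64)
        if self.fhr.ndim != 1 or self.toco.ndim != 1:
            raise ValidationError("channels must be one-dimensional")
        if self.fhr.shape != self.toco.shape:
            raise ValidationError("fhr and toco must have equal length")
        if self.label not in (0, 1):
            raise ValidationError(f"label must be 0 or 1, got {self.label}")
        if self.days_to_delivery < 0:
            raise ValidationError("days_to_delivery must be non-negative")

    def __len__(self) -> int:
        return self.fhr.shape[0]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean (2, T) array, True where a sample is missing."""
        return np.stack([self.fhr == MISSING, self.toco == MISSING])

    def missing_fraction(self) -> float:
        """Fraction of missing samples pooled over both channels."""
        return float(self.missing_mask.mean())


@dataclass
class ScaledTrace:
    """A cleaned trace mapped to the unit interval with an explicit mask.

    ``values`` is (2, T) with row 0 = FHR, row 1 = TOCO, every observed
    sample in [0, 1]; ``valid_mask`` is True where the sample was observed.
    Masked positions hold the fill value 0.0 and carry no information.
    """

    trace_id: str
    values: np.ndarray
    valid_mask: np.ndarray
    label: int
    days_to_delivery: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.values.shape != self.valid_mask.shape or self.values.shape[0] != 2:
            raise ValidationError("values and valid_mask must both be (2, T)")


@dataclass
class CTGWindow:
    """One fixed-length model input: 2 x 960 unit-scaled values plus mask."""

    values: np.ndarray
    valid_mask: np.ndarray
    trace_id: str
    window_index: int
    label: int
    days_to_delivery: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.values.shape != (2, WINDOW_LEN) or self.valid_mask.shape != (2, WINDOW_LEN):
            raise ValidationError(f"window arrays must be (2, {WINDOW_LEN})")


def windows_to_arrays(windows: list[CTGWindow]):
    """Stack windows into model-ready arrays.

    Returns
    -------
    X : ndarray, shape (n, 2, 960)
        Values with NaN at unobserved positions (the estimator derives the
        validity mask from NaNs).
    y : ndarray, shape (n,)
        Binary labels.
    days : ndarray, shape (n,)
        Days to delivery per window.
    """
    X = np.stack([w.values for w in windows])
    mask = np.stack([w.valid_mask for w in windows])
    X = np.where(mask, X, np.nan)
    y = np.array([w.label for w in windows], dtype=int)
    days = np.array([w.days_to_delivery for w in windows], dtype=int)
    return X, y, days
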