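"""Smoothed relative error (SRE) and the MODER model-validation statistic.

The minimax fit is judged on a scale-free error.  A plain relative error
|f - f^| / f(t) explodes wherever the observed output f(t) is near zero, so
the relative denominator is swapped for the profile mean on low points:

    SRE(t) = |f(t) - f^(t)| / f(t)      when f(t) >  0.15 * mean(f)
    SRE(t) = |f(t) - f^(t)| / mean(f)   when f(t) <= 0.15 * mean(f)

MODER = max_t SRE(t).  Both branches are invariant under positive scaling of
(f, f^) jointly.  A motif is validated when MODER does not exceed a
user-chosen threshold; no threshold is canonical, the default here is 0.15
(the same order as the displayed fit errors and the clustering radius) and
it is always echoed in reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

__all__ = [
    "QualityReport",
    "smoothed_relative_error",
    "moder",
    "validate_motif",
    "DEFAULT_MODER_THRESHOLD",
]

DEFAULT_MODER_THRESHOLD = 0.15

#: Fraction of the profile mean below which the smoothed branch takes over.
_LOW_LEVEL_FRACTION = 0.15


def smoothed_relative_error(f, f_hat, f_bar: float | None = None) -> np.ndarray:
    """SRE series for observed ``f`` against predicted ``f_hat``.

    ``f_bar`` defaults to ``mean(f)``; pass it explicitly when ``f`` is a
    sub-series of a longer profile whose mean should set the scale.
    """
    f = np.asarray(f, dtype=float)
    f_hat = np.asarray(f_hat, dtype=float)
    if f.shape != f_hat.shape:
        raise ValueError("observed and predicted series differ in length")
    if f_bar is None:
        f_bar = float(np.mean(f))
    if not f_bar > 0:
        raise ValueError(
            f"profile mean must be positive for SRE (got {f_bar}); "
            "apply positive-shift normalization first"
        )
    err = np.abs(f - f_hat)
    relative = f > _LOW_LEVEL_FRACTION * f_bar  # strict split, per definition
    return np.where(relative, err / np.where(relative, f, 1.0), err / f_bar)


def moder(sre: np.ndarray) -> float:
    """MODER = max over the grid of the SRE series."""
    sre = np.asarray(sre, dtype=float)
    if sre.size == 0:
        raise ValueError("SRE series is empty")
    return float(np.max(sre))


@dataclass(frozen=True)
class QualityReport:
    """SRE series, its maximum, and the validation verdict at a threshold."""

    sre: np.ndarray
    moder: float
    threshold: float
    validated: bool

    def as_dict(self) -> dict:
        return {
            "sre": list(map(float, self.sre)),
            "moder": self.moder,
            "threshold": self.threshold,
            "validated": self.validated,
        }


def validate_motif(f, f_hat, threshold: float = DEFAULT_MODER_THRESHOLD,
                   f_bar: float | None = None) -> QualityReport:
    """Build a :class:`QualityReport`; validated iff MODER <= threshold."""
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    sre = smoothed_relative_error(f, f_hat, f_bar)
    m = moder(sre)
    return QualityReport(sre, m, float(threshold), m <= threshold)
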