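"""Minimax (Chebyshev) parameter estimation for the kinetic motif models.

The estimator exploits the structure of the telescoped predictors: once the
Hill parameters U = [(u_1, S_1), ...] are fixed, the residuals are *linear*
in the remaining rates, so the minimax problem

    min_w ERR(w) = min max_j | residual_j(w) |

splits into an outer exhaustive search over a finite affinity grid for U and
an inner linear program per grid point:

    minimize z  subject to  z >= +/- residual_j(rates),  rates >= 0, z >= 0.

The affinity grids are built by median inversion: for s fraction levels
h_1..h_s equally spaced in the open interval (0, 1) (h_j = j/(s+1)), each h
is read as the median of the regulator's Hill factor, and with the median
regulator level known the Hill equation inverts in closed form to

    u = (1/median_level) * ((1/h)^(1/S) - 1).

Grid sizes shrink with the number of regulators k to keep the search at
(S_max * s)^k manageable: s = 99 for k = 1, 60 for k = 2, 20 for k >= 3,
capped at N_max = 1e5 combinations.

A parsimony gate rejects over-parameterized motifs: with p time points the
data provide p-1 one-step equations, and robust estimation demands
n_par <= (p-1)/4.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy.optimize import linprog

__all__ = [
    "FitConfig",
    "AffinityGrid",
    "GridCapError",
    "ParsimonyError",
    "h_levels",
    "invert_median_fraction",
    "parsimony_check",
    "lp_minimax",
    "fit_ti",
    "fit_td",
]

#: Default h-grid sizes keyed by the number of Hill-regulated terms k.
DEFAULT_S_BY_K = {1: 99, 2: 60, 3: 20}
DEFAULT_S_FALLBACK = 20       # for k >= 4; no canonical value exists
DEFAULT_N_MAX = 100_000


class GridCapError(ValueError):
    """Raised when the affinity-grid search would exceed the combination cap."""


class ParsimonyError(ValueError):
    """Raised when a motif has too many parameters for the grid length."""


@dataclass(frozen=True)
class FitConfig:
    """Tunable knobs of the grid + LP estimator.

    Attributes
    ----------
    s_by_k : mapping from the number of Hill terms k to the h-grid size s.
    s : explicit override of the grid size (applies for every k).
    s_max : largest admissible Hill exponent (binding-site count).
    n_max : cap on the total number of (S, u) combinations searched.
    check_parsimony : enforce n_par <= (q-1)/4 before fitting.
    moder_threshold : MODER cutoff used for the validation verdict.
    """

    s_by_k: Dict[int, int] = field(default_factory=lambda: dict(DEFAULT_S_BY_K))
    s: int | None = None
    s_max: int = 5
    n_max: int = DEFAULT_N_MAX
    check_parsimony: bool = True
    moder_threshold: float = 0.15

    def s_for(self, k: int) -> int:
        if self.s is not None:
            return self.s
        return self.s_by_k.get(k, DEFAULT_S_FALLBACK)

    def as_dict(self) -> dict:
        return {
            "s_by_k": dict(self.s_by_k),
            "s": self.s,
            "s_max": self.s_max,
            "n_max": self.n_max,
            "check_parsimony": self.check_parsimony,
            "moder_threshold": self.moder_threshold,
        }


def h_levels(s: int) -> np.ndarray:
    """s fraction levels equally spaced in the open interval (0, 1)."""
    if s < 1:
        raise ValueError("grid size s must be >= 1")
    return np.arange(1, s + 1, dtype=float) / (s + 1)


def invert_median_fraction(median_level: float, h: float, S: int) -> float:
    """Affinity u such that the Hill factor at the median level equals h.

    Inverts ``h = 1 / (1 + u * median_level)^S`` to
    ``u = (1/median_level) * ((1/h)^(1/S) - 1)``; the round trip through the
    Hill factor reproduces h to machine precision.
    """
    if not median_level > 0:
        raise ValueError("median level must be positive")
    if not 0.0 < h < 1.0:
        raise ValueError("median fraction h must lie in the open interval (0, 1)")
    if S < 1:
        raise ValueError("sites S must be >= 1")
    return (1.0 / median_level) * ((1.0 / h) ** (1.0 / S) - 1.0)


def parsimony_check(n_par: int, q: int) -> bool:
    """True iff n_par <= (q - 1) / 4: the data can support the parameters."""
    if q < 2:
        raise ValueError("need at least 2 time points")
    return n_par <= (q - 1) / 4


@dataclass(frozen=True)
class AffinityGrid:
    """Per-regulator (S, h, u) candidate lists and their cross product.

    Entries per regulator are ordered S ascending, then h ascending; the
    cross product enumerates regulators in motif order with the first
    regulator varying slowest, so the search order (and hence tie-breaking
    on equal minimax error) is deterministic.
    """

    regulator_ids: Tuple[str, ...]
    entries: Tuple[Tuple[Tuple[int, float, float], ...], ...]  # per regulator: (S, h, u)

    @classmethod
    def from_medians(cls, regulator_ids: Sequence[str],
                     median_levels: Sequence[float],
                     s: int, s_max: int = 5,
                     n_max: int = DEFAULT_N_MAX) -> "AffinityGrid":
        if len(regulator_ids) != len(median_levels):
            raise ValueError("one median level per regulator is required")
        hs = h_levels(s)
        entries = []
        for rid, med in zip(regulator_ids, median_levels):
            if not med > 0:
                raise ValueError(
                    f"regulator {rid!r}: median level must be positive "
                    "(positive-shift normalize the profiles first)"
                )
            entries.append(tuple(
                (S, float(h), invert_median_fraction(med, float(h), S))
                for S in range(1, s_max + 1)
                for h in hs
            ))
        grid = cls(tuple(regulator_ids), tuple(entries))
        if grid.n_combinations > n_max:
            raise GridCapError(
                f"{grid.n_combinations} affinity combinations exceed the cap "
                f"{n_max}; reduce the grid size s or the number of regulators"
            )
        return grid

    @property
    def n_combinations(self) -> int:
        return int(np.prod([len(e) for e in self.entries])) if self.entries else 1

    def combinations(self):
        """Iterate over tuples of (S, h, u), one per regulator, in search order."""
        if not self.entries:
            yield ()
            return
        yield from itertools.product(*self.entries)


def lp_minimax(constants: np.ndarray, columns: Sequence[np.ndarray],
               signs: Sequence[float]) -> Tuple[np.ndarray, float]:
    """Inner minimax solve: best non-negative rates for linear residuals.

    Residuals are ``r_j = constants_j + sum_c signs_c * columns_c[j] * rate_c``.
    Minimizes ``z`` subject to ``z >= |r_j|``, ``rate_c >= 0`` and ``z >= 0``
    — with q-1 residual rows and C rate columns this is 2(q-1) + C + 1 linear
    inequalities.  Returns ``(rates, z_star)`` at an optimal vertex; the
    optimal objective z_star is unique even when the optimal rate face is not.
    """
    constants = np.asarray(constants, dtype=float)
    if constants.ndim != 1 or constants.size == 0:
        raise ValueError("need at least one residual row")
    M = np.column_stack([s * np.asarray(c, dtype=float) for s, c in zip(signs, columns)])
    if len(signs) != len(columns) or M.shape[0] != constants.size:
        raise ValueError("inconsistent residual system")
    ncol = M.shape[1]
    obj = np.zeros(ncol + 1)
    obj[-1] = 1.0
    ones = np.ones((M.shape[0], 1))
    A_ub = np.vstack([np.hstack([M, -ones]), np.hstack([-M, -ones])])
    b_ub = np.concatenate([-constants, constants])
    res = linprog(obj, A_ub=A_ub, b_ub=b_ub,
                  bounds=[(0.0, None)] * (ncol + 1), method="highs")
    if not res.success:
        raise RuntimeError(f"minimax LP failed unexpectedly: {res.message}")
    rates = np.maximum(res.x[:ncol], 0.0)
    return rates, float(res.x[-1])


def fit_ti(motif, data, config: FitConfig | None = None):
    """Fit a TI motif; convenience wrapper over the model class.

    Equivalent to ``TranslationInhibitionModel(motif, data, config).fit()``.
    """
    from .models import TranslationInhibitionModel

    return TranslationInhibitionModel(motif, data, config).fit()


def fit_td(motif, data, config: FitConfig | None = None):
    """Fit a TD motif; convenience wrapper over the model class."""
    from .models import TranscriptionDegradationModel

    return TranscriptionDegradationModel(motif, data, config).fit()
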