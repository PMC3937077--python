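"""Expression-profile containers and affine-invariant profile geometry.

Microarray intensities are, to a first approximation, unknown affine
transformations ``a * c(t) + b`` of the underlying molecular concentrations
``c(t)``, with coefficients that differ between chemical species and
acquisition runs.  Every comparison between profiles in this package
therefore goes through quantities invariant under orientation-preserving
(``a > 0``) affine maps:

* the normalized profile ``nor(r) = (r - mean(r)) / sqrt(var(r))``,
* the Pearson correlation ``corr(r1, r2)``, and
* the distance ``D(r1, r2) = sqrt(2 - 2 * corr(r1, r2))``

which ranges over ``[0, 2]`` and equals the Euclidean distance between the
vectors ``nor(r) / sqrt(q)``.  Mean and variance use the population (1/q)
convention throughout, matching the definition the distance is built on.

The module also provides monotone PCHIP resampling onto a common grid and
the positive-shift normalization ``m^(t) = (m - mean) / ||m - mean||_2 + 1``
used to map raw intensity profiles into ``[0, 2]`` ahead of kinetic fitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

__all__ = [
    "DegenerateProfileError",
    "TimeGrid",
    "ExpressionProfile",
    "AffineMap",
    "ProfileSet",
    "ROLES",
    "summarize",
    "normalize",
    "profile_correlation",
    "profile_distance",
    "pairwise_distances",
    "pchip_resample",
    "positive_shift_normalize",
]

ROLES = ("miRNA", "mRNA", "protein")

#: Tolerance used to decide whether a grid is uniformly spaced.
_UNIFORM_TOL = 1e-9


class DegenerateProfileError(ValueError):
    """Raised when an operation needs a non-constant profile but got one."""


@dataclass(frozen=True)
class TimeGrid:
    """Strictly increasing time points (in days) shared by a set of profiles."""

    points: tuple

    def __post_init__(self):
        pts = tuple(float(t) for t in self.points)
        if len(pts) < 2:
            raise ValueError("a time grid needs at least 2 points")
        if any(b <= a for a, b in zip(pts, pts[1:])):
            raise ValueError("time points must be strictly increasing")
        object.__setattr__(self, "points", pts)

    @classmethod
    def uniform(cls, start: float = 0.0, stop: float = 6.0, num: int = 19) -> "TimeGrid":
        """Uniform grid; the default is the 19-point day grid 0, 1/3, ..., 6."""
        return cls(tuple(np.linspace(start, stop, num)))

    @property
    def q(self) -> int:
        return len(self.points)

    @property
    def is_uniform(self) -> bool:
        d = np.diff(self.points)
        return bool(np.all(np.abs(d - d[0]) <= _UNIFORM_TOL))

    @property
    def spacing(self) -> float:
        if not self.is_uniform:
            raise ValueError("grid is not uniformly spaced")
        return self.points[1] - self.points[0]

    def asarray(self) -> np.ndarray:
        return np.asarray(self.points, dtype=float)

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class ExpressionProfile:
    """One species' expression values aligned to a :class:`TimeGrid`."""

    species_id: str
    role: str
    values: np.ndarray
    grid: TimeGrid

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or len(vals) != self.grid.q:
            raise ValueError(
                f"profile {self.species_id!r}: {len(vals)} values for a "
                f"{self.grid.q}-point grid"
            )
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"profile {self.species_id!r} has non-finite values")
        vals.setflags(write=False)
        object.__setattr__(self, "values", vals)

    def with_values(self, values: np.ndarray, grid: TimeGrid | None = None) -> "ExpressionProfile":
        return ExpressionProfile(self.species_id, self.role, values, grid or self.grid)


@dataclass(frozen=True)
class AffineMap:
    """Orientation-preserving affine intensity recalibration r -> a*r + b.

    Negative scales flip the sign of the normalized profile and break the
    invariance of the distance D, so ``scale > 0`` is required.
    """

    scale: float
    offset: float = 0.0

    def __post_init__(self):
        if not self.scale > 0:
            raise ValueError("affine profile maps must have scale a > 0")

    def __call__(self, r):
        if isinstance(r, ExpressionProfile):
            return r.with_values(self.scale * r.values + self.offset)
        return self.scale * np.asarray(r, dtype=float) + self.offset


class ProfileSet:
    """Insertion-ordered collection of profiles on one shared grid.

    The insertion order is part of the reproducibility contract: clustering
    ties are broken by this order.
    """

    def __init__(self, grid: TimeGrid, profiles: Iterable[ExpressionProfile] = ()):
        self.grid = grid
        self._profiles: Dict[str, ExpressionProfile] = {}
        for p in profiles:
            self.add(p)

    def add(self, profile: ExpressionProfile) -> None:
        if profile.grid != self.grid:
            raise ValueError(
                f"profile {profile.species_id!r} is on a different time grid"
            )
        if profile.species_id in self._profiles:
            raise ValueError(f"duplicate species_id {profile.species_id!r}")
        self._profiles[profile.species_id] = profile

    @property
    def ids(self) -> list:
        return list(self._profiles)

    def by_role(self, role: str) -> "ProfileSet":
        return ProfileSet(
            self.grid, (p for p in self if p.role == role)
        )

    def subset(self, ids: Sequence[str]) -> "ProfileSet":
        return ProfileSet(self.grid, (self[i] for i in ids))

    def values_matrix(self, ids: Sequence[str] | None = None) -> np.ndarray:
        ids = self.ids if ids is None else list(ids)
        return np.array([self[i].values for i in ids], dtype=float)

    def map_values(self, func) -> "ProfileSet":
        """Apply ``func`` to each profile's value vector, keeping ids/roles."""
        return ProfileSet(
            self.grid, (p.with_values(func(p.values)) for p in self)
        )

    def __getitem__(self, species_id: str) -> ExpressionProfile:
        try:
            return self._profiles[species_id]
        except KeyError:
            raise KeyError(f"no profile for species {species_id!r}") from None

    def __contains__(self, species_id: str) -> bool:
        return species_id in self._profiles

    def __iter__(self) -> Iterator[ExpressionProfile]:
        return iter(self._profiles.values())

    def __len__(self) -> int:
        return len(self._profiles)


def _values(r) -> np.ndarray:
    if isinstance(r, ExpressionProfile):
        return r.values
    return np.asarray(r, dtype=float)


def summarize(r) -> tuple:
    """Mean and population (1/q) variance of a profile."""
    v = _values(r)
    if len(v) < 2:
        raise ValueError("need at least 2 time points")
    mean = float(np.mean(v))
    var = float(np.mean((v - mean) ** 2))
    return mean, var


def normalize(r) -> np.ndarray:
    """``nor(r) = (r - mean) / sqrt(var)``: mean 0, 1/q-variance 1.

    Invariant under affine maps with positive scale; undefined (and raising
    :class:`DegenerateProfileError`) for constant profiles.
    """
    v = _values(r)
    mean, var = summarize(v)
    if var <= 0.0:
        sid = getattr(r, "species_id", None)
        label = f" {sid!r}" if sid else ""
        raise DegenerateProfileError(
            f"profile{label} is constant: normalization undefined"
        )
    return (v - mean) / math.sqrt(var)


def profile_correlation(r1, r2) -> float:
    """Pearson correlation between two profiles on the same grid.

    Equals ``<nor(r1), nor(r2)> / q``: the inner product of the normalized
    profiles must be divided by q for the correlation to land in [-1, 1]
    and for ``D^2 = 2 - 2*corr`` to stay non-negative.
    """
    n1, n2 = normalize(r1), normalize(r2)
    if len(n1) != len(n2):
        raise ValueError("profiles are on grids of different lengths")
    c = float(np.dot(n1, n2) / len(n1))
    return min(1.0, max(-1.0, c))


def profile_distance(r1, r2) -> float:
    """Affine-invariant distance ``D = sqrt(2 - 2 corr)`` in [0, 2]."""
    return math.sqrt(max(0.0, 2.0 - 2.0 * profile_correlation(r1, r2)))


def pairwise_distances(profiles: ProfileSet, ids: Sequence[str] | None = None) -> np.ndarray:
    """Full symmetric matrix of D over the set (order = insertion order).

    Computed through the embedding ``x = nor(r)/sqrt(q)``, under which D is
    the plain Euclidean distance.
    """
    ids = profiles.ids if ids is None else list(ids)
    if not ids:
        return np.zeros((0, 0))
    X = np.array([normalize(profiles[i]) for i in ids]) / math.sqrt(profiles.grid.q)
    gram = X @ X.T
    d2 = 2.0 - 2.0 * np.clip(gram, -1.0, 1.0)
    np.fill_diagonal(d2, 0.0)
    return np.sqrt(np.maximum(d2, 0.0))


def pchip_resample(r: ExpressionProfile, target: TimeGrid) -> ExpressionProfile:
    """Resample a profile onto ``target`` by monotone cubic (PCHIP) interpolation.

    The interpolant passes through the source points exactly and preserves
    monotonicity between monotone data.  Extrapolation outside the source
    grid is refused.
    """
    src = r.grid.asarray()
    tgt = target.asarray()
    if tgt[0] < src[0] - 1e-12 or tgt[-1] > src[-1] + 1e-12:
        raise ValueError(
            f"target grid [{tgt[0]}, {tgt[-1]}] extends outside the source "
            f"grid [{src[0]}, {src[-1]}]: extrapolation is not supported"
        )
    interp = PchipInterpolator(src, r.values)
    return ExpressionProfile(r.species_id, r.role, interp(tgt), target)


def positive_shift_normalize(r):
    """Positive-shift normalization ``m^ = (m - mean) / sigma + 1``.

    ``sigma`` is the root of the *un-divided* centered sum of squares,
    ``sqrt(sum_t (m(t) - mean)^2)``, so the centered, scaled profile has unit
    Euclidean norm and every output value lies in ``[0, 2]``.  The output has
    mean exactly 1 and is invariant under positive scaling of the input.
    """
    v = _values(r)
    mean = float(np.mean(v))
    sigma = float(np.linalg.norm(v - mean))
    if sigma <= 0.0:
        sid = getattr(r, "species_id", None)
        label = f" {sid!r}" if sid else ""
        raise DegenerateProfileError(
            f"profile{label} is constant: positive-shift normalization undefined"
        )
    out = (v - mean) / sigma + 1.0
    if isinstance(r, ExpressionProfile):
        return r.with_values(out)
    return out
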