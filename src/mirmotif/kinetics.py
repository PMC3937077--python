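"""Discretized chemical-kinetics models of TD and TI regulatory motifs.

Two motif architectures are modeled on a uniform time grid, with rates
expressed per grid interval (the discretization absorbs the step):

Translation-Inhibition (TI): miRNAs M_1..M_k inhibit translation of protein
P from mRNA G,

    p(t_{j+1}) - p(t_j) = -gamma * p(t_j) + lambda * g(t_j) * H(t_j)

where the commitment H(t) in (0, 1] is the fraction of G molecules free to
translate, a product of Hill-type factors 1/(1 + u_i m_i(t))^{S_i}.

Transcription-Degradation (TD): one miRNA M degrades mRNA G whose
transcription is driven by repressor proteins R_i and activator proteins A_j,

    g(t_{j+1}) - g(t_j) = -beta * g(t_j) - v * g(t_j) * m(t_j) + kappa * F(t_j)

with F(t) = REP(t) * (1 - ACT(t)), both again products of Hill factors.
Note that with no modeled activators the empty ACT product is 1 and F is
structurally 0: such a gene cannot be transcribed under this model.

Summing the recursions telescopes into cumulative-sum predictors that are
*linear* in the rates, which is what makes the minimax estimation an LP:

    p^(t_{j+1}) = p(t_1) - gamma * Q(t_j) + lambda * L(t_j),
        Q(t_j) = sum_{n<=j} p(t_n),  L(t_j) = sum_{n<=j} g(t_n) H(t_n)

(and the analogous B, V, K sums for TD).  Forward simulation and the
cumulative predictor agree identically on model-generated data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence, Tuple

import numpy as np

__all__ = [
    "S_MAX_DEFAULT",
    "RegulatorTerm",
    "TIMotif",
    "TDMotif",
    "TIParams",
    "TDParams",
    "hill_factor",
    "ti_commitment",
    "td_commitment",
    "simulate_ti_forward",
    "simulate_td_forward",
    "predict_ti",
    "predict_td",
    "TIPrediction",
    "TDPrediction",
]

#: Default cap on Hill exponents: very few mRNAs carry more than a handful
#: of functional binding sites, so S is restricted to 1..5 by default.
S_MAX_DEFAULT = 5


@dataclass(frozen=True)
class RegulatorTerm:
    """One regulator's Hill factor: affinity u > 0 and integer sites S."""

    species_id: str
    affinity: float
    sites: int
    s_max: int = S_MAX_DEFAULT

    def __post_init__(self):
        if not self.affinity > 0:
            raise ValueError(f"{self.species_id}: affinity must be > 0")
        if not (isinstance(self.sites, (int, np.integer)) and 1 <= self.sites <= self.s_max):
            raise ValueError(
                f"{self.species_id}: sites must be an integer in [1, {self.s_max}]"
            )


@dataclass(frozen=True)
class TIMotif:
    """Translation-inhibition architecture: P translated from G, inhibited by miRNAs."""

    protein_id: str
    mrna_id: str
    inhibitors: Tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "inhibitors", tuple(self.inhibitors))
        ids = (self.protein_id, self.mrna_id, *self.inhibitors)
        if len(set(ids)) != len(ids):
            raise ValueError("motif species ids must be distinct")

    @property
    def k(self) -> int:
        return len(self.inhibitors)

    @property
    def n_par(self) -> int:
        return 2 + 2 * self.k


@dataclass(frozen=True)
class TDMotif:
    """Transcription-degradation architecture: M degrades G, TFs drive transcription."""

    mrna_id: str
    mirna_id: str
    repressors: Tuple[str, ...] = ()
    activators: Tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "repressors", tuple(self.repressors))
        object.__setattr__(self, "activators", tuple(self.activators))
        ids = (self.mrna_id, self.mirna_id, *self.repressors, *self.activators)
        if len(set(ids)) != len(ids):
            raise ValueError("motif species ids must be distinct")

    @property
    def regulators(self) -> Tuple[str, ...]:
        return self.repressors + self.activators

    @property
    def n_par(self) -> int:
        return 3 + 2 * (len(self.repressors) + len(self.activators))


@dataclass(frozen=True)
class TIParams:
    """TI parameter vector w = [gamma, lambda, u_1, S_1, ..., u_k, S_k]."""

    gamma: float
    lam: float
    inhibitor_terms: Tuple[RegulatorTerm, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "inhibitor_terms", tuple(self.inhibitor_terms))
        if self.gamma < 0 or self.lam < 0:
            raise ValueError("rates must be non-negative")

    @property
    def n_par(self) -> int:
        return 2 + 2 * len(self.inhibitor_terms)

    def as_dict(self) -> dict:
        d = {"gamma": self.gamma, "lambda": self.lam}
        for i, t in enumerate(self.inhibitor_terms, start=1):
            d[f"u_{i}"] = t.affinity
            d[f"S_{i}"] = t.sites
        return d


@dataclass(frozen=True)
class TDParams:
    """TD parameter vector w = [beta, v, kappa, (u_i, S_i) per regulator]."""

    beta: float
    v: float
    kappa: float
    repressor_terms: Tuple[RegulatorTerm, ...] = ()
    activator_terms: Tuple[RegulatorTerm, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "repressor_terms", tuple(self.repressor_terms))
        object.__setattr__(self, "activator_terms", tuple(self.activator_terms))
        if self.beta < 0 or self.v < 0 or self.kappa < 0:
            raise ValueError("rates must be non-negative")

    @property
    def n_par(self) -> int:
        return 3 + 2 * (len(self.repressor_terms) + len(self.activator_terms))

    def as_dict(self) -> dict:
        d = {"beta": self.beta, "v": self.v, "kappa": self.kappa}
        for i, t in enumerate(self.repressor_terms + self.activator_terms, start=1):
            d[f"u_{i}"] = t.affinity
            d[f"S_{i}"] = t.sites
        return d


def hill_factor(level, u: float, S: int):
    """Hill-type occupancy factor ``1 / (1 + u * level)**S`` in (0, 1].

    Strictly decreasing in the level, the affinity and the exponent for
    positive levels; equals 1 at level 0.
    """
    level = np.asarray(level, dtype=float)
    if np.any(level < 0):
        raise ValueError("expression levels must be non-negative")
    if not u > 0:
        raise ValueError("affinity u must be > 0")
    if S < 1:
        raise ValueError("sites S must be >= 1")
    out = 1.0 / (1.0 + u * level) ** S
    return out if out.ndim else float(out)


def ti_commitment(inhibitor_terms: Sequence[RegulatorTerm], levels):
    """Translation commitment H = product of inhibitor Hill factors (1 for k=0).

    ``levels`` holds one level (scalar or time series) per inhibitor term.
    """
    levels = [np.asarray(l, dtype=float) for l in levels]
    if len(levels) != len(inhibitor_terms):
        raise ValueError(
            f"{len(inhibitor_terms)} inhibitor terms but {len(levels)} level series"
        )
    h = np.asarray(1.0)
    for term, lev in zip(inhibitor_terms, levels):
        h = h * hill_factor(lev, term.affinity, term.sites)
    return h if np.ndim(h) else float(h)


def td_commitment(repressor_terms: Sequence[RegulatorTerm],
                  activator_terms: Sequence[RegulatorTerm],
                  repressor_levels, activator_levels):
    """Transcription commitment F = REP * (1 - ACT) in [0, 1).

    REP and ACT are products of Hill factors over the repressors and
    activators.  With no activators the empty ACT product is 1 and F == 0.
    """
    rep = ti_commitment(repressor_terms, repressor_levels)
    act = ti_commitment(activator_terms, activator_levels)
    return rep * (1.0 - act)


def _warn_large_rate(name: str, value: float) -> None:
    if value >= 1.0:
        warnings.warn(
            f"{name} = {value} >= 1 per grid interval: the one-step recursion "
            "can flip sign",
            RuntimeWarning,
            stacklevel=3,
        )


def simulate_ti_forward(params: TIParams, g: np.ndarray, m: np.ndarray,
                        p_initial: float) -> np.ndarray:
    """Forward-iterate the TI recursion from ``p_initial`` over the grid.

    ``m`` has shape (k, q), one row per inhibitor, aligned with
    ``params.inhibitor_terms``.
    """
    g = np.asarray(g, dtype=float)
    m = np.atleast_2d(np.asarray(m, dtype=float)) if len(params.inhibitor_terms) else np.zeros((0, len(g)))
    if m.shape != (len(params.inhibitor_terms), len(g)):
        raise ValueError("inhibitor level matrix shape does not match terms/grid")
    _warn_large_rate("gamma", params.gamma)
    h = np.broadcast_to(ti_commitment(params.inhibitor_terms, list(m)), g.shape)
    p = np.empty_like(g)
    p[0] = p_initial
    for j in range(len(g) - 1):
        p[j + 1] = p[j] - params.gamma * p[j] + params.lam * g[j] * h[j]
    return p


def simulate_td_forward(params: TDParams, m: np.ndarray,
                        repressor_levels, activator_levels,
                        g_initial: float) -> np.ndarray:
    """Forward-iterate the TD recursion from ``g_initial`` over the grid."""
    m = np.asarray(m, dtype=float)
    q = len(m)
    _warn_large_rate("beta", params.beta)
    f = np.broadcast_to(
        td_commitment(params.repressor_terms, params.activator_terms,
                      repressor_levels, activator_levels),
        m.shape,
    )
    g = np.empty(q, dtype=float)
    g[0] = g_initial
    for j in range(q - 1):
        g[j + 1] = g[j] - params.beta * g[j] - params.v * g[j] * m[j] + params.kappa * f[j]
    return g


class TIPrediction(NamedTuple):
    predicted: np.ndarray   # p^(t_2..t_q), length q-1
    residuals: np.ndarray   # p(t_{j+1}) - p^(t_{j+1}), length q-1
    pi: np.ndarray          # p(t_{j+1}) - p(t_1)
    mu: np.ndarray          # Q(t_j) = cumulative sum of p
    nu: np.ndarray          # L(t_j) = cumulative sum of g*H
    h: np.ndarray           # commitment series H(t)


class TDPrediction(NamedTuple):
    predicted: np.ndarray
    residuals: np.ndarray
    tau: np.ndarray         # g(t_{j+1}) - g(t_1)
    rho: np.ndarray         # B(t_j) = cumsum g
    eta: np.ndarray         # V(t_j) = cumsum g*m
    theta: np.ndarray       # K(t_j) = cumsum F
    f: np.ndarray           # commitment series F(t)


def ti_coefficients(p: np.ndarray, g: np.ndarray, h: np.ndarray):
    """Residual coefficients (pi, mu, nu) of the telescoped TI predictor.

    The recursion summed from t_1 to t_j gives, for j = 1..q-1,
    ``p(t_{j+1}) - p(t_1) = -gamma Q(t_j) + lambda L(t_j)`` with Q the running
    sum of the *output* p (the summation of the one-step recursion forces the
    output variable here) and L the running sum of g*H.
    """
    p = np.asarray(p, dtype=float)
    pi = p[1:] - p[0]
    mu = np.cumsum(p)[:-1]
    nu = np.cumsum(np.asarray(g, dtype=float) * h)[:-1]
    return pi, mu, nu


def td_coefficients(g: np.ndarray, m: np.ndarray, f: np.ndarray):
    """Residual coefficients (tau, rho, eta, theta) of the telescoped TD predictor."""
    g = np.asarray(g, dtype=float)
    m = np.asarray(m, dtype=float)
    tau = g[1:] - g[0]
    rho = np.cumsum(g)[:-1]
    eta = np.cumsum(g * m)[:-1]
    theta = np.cumsum(np.broadcast_to(f, g.shape))[:-1]
    return tau, rho, eta, theta


def predict_ti(params: TIParams, p: np.ndarray, g: np.ndarray,
               m: np.ndarray) -> TIPrediction:
    """Cumulative-sum predictor p^ and its q-1 residuals against observed p."""
    p = np.asarray(p, dtype=float)
    g = np.asarray(g, dtype=float)
    if len(p) != len(g):
        raise ValueError("p and g are on grids of different lengths")
    m = np.atleast_2d(np.asarray(m, dtype=float)) if len(params.inhibitor_terms) else np.zeros((0, len(g)))
    if m.shape != (len(params.inhibitor_terms), len(g)):
        raise ValueError("inhibitor level matrix shape does not match terms/grid")
    h = np.broadcast_to(ti_commitment(params.inhibitor_terms, list(m)), g.shape)
    pi, mu, nu = ti_coefficients(p, g, h)
    predicted = p[0] - params.gamma * mu + params.lam * nu
    residuals = p[1:] - predicted
    return TIPrediction(predicted, residuals, pi, mu, nu, np.asarray(h))


def predict_td(params: TDParams, g: np.ndarray, m: np.ndarray,
               repressor_levels, activator_levels) -> TDPrediction:
    """Cumulative-sum predictor g^ and its q-1 residuals against observed g."""
    g = np.asarray(g, dtype=float)
    m = np.asarray(m, dtype=float)
    if len(g) != len(m):
        raise ValueError("g and m are on grids of different lengths")
    f = np.broadcast_to(
        td_commitment(params.repressor_terms, params.activator_terms,
                      repressor_levels, activator_levels),
        g.shape,
    )
    tau, rho, eta, theta = td_coefficients(g, m, f)
    predicted = g[0] - params.beta * rho - params.v * eta + params.kappa * theta
    residuals = g[1:] - predicted
    return TDPrediction(predicted, residuals, tau, rho, eta, theta, np.asarray(f))
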