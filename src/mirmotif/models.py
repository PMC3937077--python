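"""Model / Results classes for fitting kinetic motif models to profile data.

The user-facing surface follows the statsmodels convention: a model object
is built from data and a motif architecture, ``fit()`` runs the outer
affinity-grid search with the inner minimax LP, and returns a results object
carrying the optimal parameters, the minimax error ERR(w*), residuals, the
SRE/MODER quality report and a ``summary()`` table.

    >>> model = TranslationInhibitionModel(motif, profile_set)
    >>> res = model.fit()
    >>> print(res.summary())

Rates are per grid interval (the uniform-grid discretization absorbs the
time step).  The model-level strict positivity constraints (rates > 0) are relaxed
to >= 0 for the LP; rates estimated exactly at the boundary are listed in
``results.boundary_rates``.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .estimation import (
    AffinityGrid,
    FitConfig,
    ParsimonyError,
    lp_minimax,
    parsimony_check,
)
from .kinetics import (
    RegulatorTerm,
    TDMotif,
    TDParams,
    TIMotif,
    TIParams,
    hill_factor,
    predict_td,
    predict_ti,
    simulate_td_forward,
    simulate_ti_forward,
)
from .profiles import ProfileSet
from .quality import QualityReport, validate_motif

__all__ = [
    "TranslationInhibitionModel",
    "TranscriptionDegradationModel",
    "MotifFitResults",
]


@dataclass(frozen=True)
class MotifFitResults:
    """Estimation results for one motif fit.

    Attributes
    ----------
    params : TIParams or TDParams
        Optimal parameter vector w*.
    err_star : float
        Minimax residual ERR(w*) = max_j |f(t_{j+1}) - f^(t_{j+1})|.
    fittedvalues : ndarray, length q-1
        Cumulative-sum predictions f^(t_2..t_q).
    residuals : ndarray, length q-1
        Observed minus predicted.
    quality : QualityReport or None
        SRE series / MODER verdict; None when the observed output has a
        non-positive mean (quality is defined for positive profiles).
    n_combinations_searched : int
        Number of (S, u) grid points enumerated by the outer search.
    boundary_rates : tuple of str
        Rate names estimated exactly at the 0 boundary.
    """

    model: object
    params: object
    err_star: float
    fittedvalues: np.ndarray
    residuals: np.ndarray
    quality: Optional[QualityReport]
    n_combinations_searched: int
    boundary_rates: Tuple[str, ...]
    config: FitConfig

    @property
    def moder(self) -> float:
        if self.quality is None:
            raise ValueError("quality undefined: observed output mean is not positive")
        return self.quality.moder

    @property
    def sre(self) -> np.ndarray:
        if self.quality is None:
            raise ValueError("quality undefined: observed output mean is not positive")
        return self.quality.sre

    @property
    def validated(self) -> bool:
        return self.quality is not None and self.quality.validated

    def simulate(self, initial: float | None = None) -> np.ndarray:
        """Forward-simulate the fitted recursion over the model's grid."""
        return self.model._simulate(self.params, initial)

    def to_dict(self) -> dict:
        d = {
            "motif": self.model.motif_dict(),
            "params": self.params.as_dict(),
            "err_star": self.err_star,
            "n_combinations_searched": self.n_combinations_searched,
            "boundary_rates": list(self.boundary_rates),
            "residuals": list(map(float, self.residuals)),
            "fittedvalues": list(map(float, self.fittedvalues)),
            "quality": None if self.quality is None else self.quality.as_dict(),
            "config": self.config.as_dict(),
        }
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def summary(self) -> str:
        lines = []
        title = self.model._TITLE
        lines.append(title)
        lines.append("=" * len(title))
        lines.append(self.model._describe_motif())
        q = self.model.data.grid.q
        lines.append(
            f"Time points: {q}    n_par: {self.params.n_par}    "
            f"grid points searched: {self.n_combinations_searched}"
        )
        for name, value in self.params.as_dict().items():
            if isinstance(value, (int, np.integer)):
                lines.append(f"  {name:<8s} = {value}")
            else:
                flag = "  (at 0 boundary)" if name in self.boundary_rates else ""
                lines.append(f"  {name:<8s} = {value:.6g}{flag}")
        lines.append(f"ERR(w*) = {self.err_star:.6g}")
        if self.quality is not None:
            verdict = "VALIDATED" if self.quality.validated else "rejected"
            lines.append(
                f"MODER   = {self.quality.moder:.6g}  "
                f"[{verdict} at threshold {self.quality.threshold}]"
            )
        else:
            lines.append("MODER   = undefined (non-positive output mean)")
        return "\n".join(lines)


class _MotifModel:
    """Shared machinery of the TI and TD model classes."""

    _TITLE = "Motif model"
    _RATE_NAMES: Tuple[str, ...] = ()
    _RATE_SIGNS: Tuple[float, ...] = ()

    def __init__(self, motif, data: ProfileSet, config: FitConfig | None = None):
        self.motif = motif
        self.data = data
        self.config = config or FitConfig()
        self._validate_inputs()
        if self.config.check_parsimony and not parsimony_check(motif.n_par, data.grid.q):
            raise ParsimonyError(
                f"motif has n_par = {motif.n_par} parameters but the "
                f"{data.grid.q}-point grid admits at most (q-1)/4 = "
                f"{(data.grid.q - 1) / 4:g}; drop regulators or record more "
                "time points (set check_parsimony=False to override)"
            )

    # -- subclass hooks -------------------------------------------------
    def _validate_inputs(self):  # pragma: no cover - overridden
        raise NotImplementedError

    def _regulator_ids(self) -> Tuple[str, ...]:
        raise NotImplementedError

    def _fixed_columns(self):
        """(constants, fixed coefficient columns) independent of the Hill combo."""
        raise NotImplementedError

    def _combo_column(self, series_per_regulator):
        """Coefficient column that depends on the Hill combination."""
        raise NotImplementedError

    def _build_params(self, rates, combo) -> object:
        raise NotImplementedError

    def _observed_output(self) -> np.ndarray:
        raise NotImplementedError

    def _simulate(self, params, initial):
        raise NotImplementedError

    def motif_dict(self) -> dict:
        raise NotImplementedError

    def _describe_motif(self) -> str:
        raise NotImplementedError

    # -- fitting --------------------------------------------------------
    def fit(self) -> MotifFitResults:
        """Exhaustive affinity-grid search with an inner minimax LP per point.

        The search order is deterministic (S ascending, h ascending,
        regulators in motif order); on ties in the minimax error the first
        combination encountered wins.
        """
        reg_ids = self._regulator_ids()
        constants, fixed_cols = self._fixed_columns()
        best = None
        n_searched = 0
        if not reg_ids:
            column = self._combo_column(())
            rates, z = lp_minimax(constants, [*fixed_cols, column], self._RATE_SIGNS)
            best = (z, rates, ())
            n_searched = 1
        else:
            levels = self.data.values_matrix(reg_ids)
            medians = [float(np.median(row)) for row in levels]
            grid = AffinityGrid.from_medians(
                reg_ids, medians, s=self.config.s_for(len(reg_ids)),
                s_max=self.config.s_max, n_max=self.config.n_max,
            )
            # Pre-compute each regulator's Hill series for every grid entry.
            series = [
                np.array([hill_factor(levels[i], u, S) for (S, _h, u) in entries])
                for i, entries in enumerate(grid.entries)
            ]
            for combo_idx in itertools.product(*(range(len(e)) for e in grid.entries)):
                combo = tuple(grid.entries[i][j] for i, j in enumerate(combo_idx))
                combo_series = [series[i][j] for i, j in enumerate(combo_idx)]
                column = self._combo_column(combo_series)
                rates, z = lp_minimax(constants, [*fixed_cols, column], self._RATE_SIGNS)
                n_searched += 1
                if best is None or z < best[0]:
                    best = (z, rates, combo)
        z_star, rates, combo = best
        params = self._build_params(rates, combo)
        return self._results(params, n_searched)

    def _results(self, params, n_searched: int) -> MotifFitResults:
        pred = self._predict(params)
        observed = self._observed_output()
        boundary = tuple(
            name for name, value in zip(self._RATE_NAMES, self._rate_values(params))
            if value == 0.0
        )
        f_bar = float(np.mean(observed))
        quality = None
        if f_bar > 0:
            quality = validate_motif(
                observed[1:], pred.predicted,
                threshold=self.config.moder_threshold, f_bar=f_bar,
            )
        return MotifFitResults(
            model=self,
            params=params,
            err_star=float(np.max(np.abs(pred.residuals))),
            fittedvalues=pred.predicted,
            residuals=pred.residuals,
            quality=quality,
            n_combinations_searched=n_searched,
            boundary_rates=boundary,
            config=self.config,
        )

    def _predict(self, params):
        raise NotImplementedError

    def _rate_values(self, params):
        raise NotImplementedError


class TranslationInhibitionModel(_MotifModel):
    """TI motif: protein P translated from mRNA G, inhibited by k miRNAs.

    Free rates: gamma (degradation of P) and lambda (translation), plus one
    (u, S) Hill pair per inhibitor searched on the affinity grid.
    n_par = 2 + 2k.
    """

    _TITLE = "Translation-Inhibition Motif Fit (minimax grid + LP)"
    _RATE_NAMES = ("gamma", "lambda")
    _RATE_SIGNS = (1.0, -1.0)  # residual = pi + gamma*mu - lambda*nu

    def _validate_inputs(self):
        motif, data = self.motif, self.data
        needed = (motif.protein_id, motif.mrna_id, *motif.inhibitors)
        missing = [sid for sid in needed if sid not in data]
        if missing:
            raise KeyError(f"profiles missing from the data set: {missing}")
        self._p = data[motif.protein_id].values
        self._g = data[motif.mrna_id].values
        self._m = data.values_matrix(motif.inhibitors) if motif.inhibitors \
            else np.zeros((0, data.grid.q))

    def _regulator_ids(self):
        return self.motif.inhibitors

    def _fixed_columns(self):
        p = self._p
        pi = p[1:] - p[0]
        mu = np.cumsum(p)[:-1]
        return pi, [mu]

    def _combo_column(self, series_per_regulator):
        h = np.ones_like(self._g)
        for s in series_per_regulator:
            h = h * s
        return np.cumsum(self._g * h)[:-1]

    def _build_params(self, rates, combo):
        terms = tuple(
            RegulatorTerm(rid, affinity=u, sites=S, s_max=self.config.s_max)
            for rid, (S, _h, u) in zip(self.motif.inhibitors, combo)
        )
        return TIParams(gamma=float(rates[0]), lam=float(rates[1]),
                        inhibitor_terms=terms)

    def _observed_output(self):
        return self._p

    def _predict(self, params):
        return predict_ti(params, self._p, self._g, self._m)

    def _rate_values(self, params):
        return (params.gamma, params.lam)

    def _simulate(self, params, initial):
        p0 = self._p[0] if initial is None else initial
        return simulate_ti_forward(params, self._g, self._m, p0)

    def motif_dict(self) -> dict:
        return {
            "type": "TI",
            "protein": self.motif.protein_id,
            "mrna": self.motif.mrna_id,
            "inhibitors": list(self.motif.inhibitors),
        }

    def _describe_motif(self) -> str:
        inh = ", ".join(self.motif.inhibitors) or "(none)"
        return (
            f"Output: protein {self.motif.protein_id}    "
            f"mRNA: {self.motif.mrna_id}    inhibitors: {inh}"
        )


class TranscriptionDegradationModel(_MotifModel):
    """TD motif: miRNA M degrades mRNA G; TF proteins drive transcription.

    Free rates: beta (decay of G), v (G-M reaction) and kappa (transcription
    drive), plus one (u, S) Hill pair per repressor/activator.
    n_par = 3 + 2(n_rep + n_act).  With no activators the transcription
    commitment F is structurally zero and kappa is unidentifiable; the model
    warns in that case.
    """

    _TITLE = "Transcription-Degradation Motif Fit (minimax grid + LP)"
    _RATE_NAMES = ("beta", "v", "kappa")
    _RATE_SIGNS = (1.0, 1.0, -1.0)  # residual = tau + beta*rho + v*eta - kappa*theta

    def _validate_inputs(self):
        motif, data = self.motif, self.data
        needed = (motif.mrna_id, motif.mirna_id, *motif.regulators)
        missing = [sid for sid in needed if sid not in data]
        if missing:
            raise KeyError(f"profiles missing from the data set: {missing}")
        self._g = data[motif.mrna_id].values
        self._m = data[motif.mirna_id].values
        self._n_rep = len(motif.repressors)
        if not motif.activators:
            warnings.warn(
                "TD motif has no activators: the transcription commitment F "
                "is structurally 0 and kappa is unidentifiable",
                RuntimeWarning,
                stacklevel=4,
            )

    def _regulator_ids(self):
        return self.motif.regulators

    def _fixed_columns(self):
        g, m = self._g, self._m
        tau = g[1:] - g[0]
        rho = np.cumsum(g)[:-1]
        eta = np.cumsum(g * m)[:-1]
        return tau, [rho, eta]

    def _combo_column(self, series_per_regulator):
        rep = np.ones_like(self._g)
        for s in series_per_regulator[:self._n_rep]:
            rep = rep * s
        act = np.ones_like(self._g)
        for s in series_per_regulator[self._n_rep:]:
            act = act * s
        f = rep * (1.0 - act) if len(series_per_regulator) > self._n_rep \
            else np.zeros_like(self._g)
        return np.cumsum(f)[:-1]

    def _build_params(self, rates, combo):
        ids = self.motif.regulators
        terms = [
            RegulatorTerm(rid, affinity=u, sites=S, s_max=self.config.s_max)
            for rid, (S, _h, u) in zip(ids, combo)
        ]
        return TDParams(
            beta=float(rates[0]), v=float(rates[1]), kappa=float(rates[2]),
            repressor_terms=tuple(terms[:self._n_rep]),
            activator_terms=tuple(terms[self._n_rep:]),
        )

    def _observed_output(self):
        return self._g

    def _predict(self, params):
        rep_levels = [self.data[r].values for r in self.motif.repressors]
        act_levels = [self.data[a].values for a in self.motif.activators]
        return predict_td(params, self._g, self._m, rep_levels, act_levels)

    def _rate_values(self, params):
        return (params.beta, params.v, params.kappa)

    def _simulate(self, params, initial):
        g0 = self._g[0] if initial is None else initial
        rep_levels = [self.data[r].values for r in self.motif.repressors]
        act_levels = [self.data[a].values for a in self.motif.activators]
        return simulate_td_forward(params, self._m, rep_levels, act_levels, g0)

    def motif_dict(self) -> dict:
        return {
            "type": "TD",
            "mrna": self.motif.mrna_id,
            "mirna": self.motif.mirna_id,
            "repressors": list(self.motif.repressors),
            "activators": list(self.motif.activators),
        }

    def _describe_motif(self) -> str:
        return (
            f"Output: mRNA {self.motif.mrna_id}    miRNA: {self.motif.mirna_id}    "
            f"repressors: {', '.join(self.motif.repressors) or '(none)'}    "
            f"activators: {', '.join(self.motif.activators) or '(none)'}"
        )
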