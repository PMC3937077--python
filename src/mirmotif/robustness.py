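"""Perturb-and-refit study of estimator stability under measurement noise.

Microarray intensities carry replicate-level noise; the study quantifies how
much that noise moves the fitted parameters.  Starting from a completed fit:

1. perturb the miRNA input profiles with independent zero-mean noise of
   prescribed per-point standard deviation sigma_i(t);
2. push the perturbed inputs through the *fitted* forward recursion to
   obtain a simulated downstream profile pd(t);
3. re-run the full estimator on pd(t) together with the original upstream
   profiles, and record the re-estimated parameter vector.

Repeating this (100 times by default) yields an ensemble whose spread around
the original estimates measures robustness.  Perturbed levels are not
truncated at zero — clipping would bias the injected standard deviation —
and Hill-factor levels are floored at 0 only where a commitment function is
evaluated.  All randomness derives from one master seed via per-replicate
spawned streams, so individual replicates are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .kinetics import TDParams, TIParams, simulate_td_forward, simulate_ti_forward
from .models import MotifFitResults, TranscriptionDegradationModel, TranslationInhibitionModel
from .profiles import ExpressionProfile, ProfileSet

__all__ = ["PerturbationStudy", "perturb_profiles", "robustness_study", "sd_from_fraction"]


def sd_from_fraction(levels: np.ndarray, fraction: float) -> np.ndarray:
    """Constant-per-species sd series: ``fraction`` of each row's median level."""
    levels = np.atleast_2d(np.asarray(levels, dtype=float))
    med = np.median(levels, axis=1, keepdims=True)
    return np.broadcast_to(np.abs(med) * fraction, levels.shape).copy()


def perturb_profiles(levels: np.ndarray, noise_sd, rng: np.random.Generator,
                     law: str = "gaussian") -> np.ndarray:
    """Add independent noise per species and time point.

    ``noise_sd`` broadcasts against ``levels`` (shape (k, q)); the default
    law is Gaussian with mean 0, ``law="uniform"`` draws uniform noise with
    the same standard deviation.  Deterministic for a fixed generator state.
    """
    levels = np.atleast_2d(np.asarray(levels, dtype=float))
    sd = np.broadcast_to(np.asarray(noise_sd, dtype=float), levels.shape)
    if np.any(sd < 0):
        raise ValueError("noise standard deviations must be >= 0")
    if law == "gaussian":
        noise = rng.normal(0.0, 1.0, size=levels.shape) * sd
    elif law == "uniform":
        half_width = sd * np.sqrt(3.0)  # uniform on [-w, w] has sd w/sqrt(3)
        noise = rng.uniform(-1.0, 1.0, size=levels.shape) * half_width
    else:
        raise ValueError(f"unknown noise law {law!r}")
    return levels + noise


@dataclass(frozen=True)
class PerturbationStudy:
    """Ensemble of re-estimated parameter vectors under injected noise."""

    original: Dict[str, float]
    estimates: pd.DataFrame          # one row per successful replicate
    n_reps: int
    seed: int
    failures: Tuple[int, ...]        # replicate indices whose re-fit failed

    def summary(self, quantiles=(0.05, 0.25, 0.5, 0.75, 0.95)) -> pd.DataFrame:
        """Per-parameter quantiles of the re-estimated ensemble."""
        return self.estimates.quantile(list(quantiles))

    def spread(self) -> pd.Series:
        """Per-parameter standard deviation of the ensemble."""
        return self.estimates.std(ddof=0)


def _perturbed_ids(results: MotifFitResults) -> List[str]:
    model = results.model
    if isinstance(model, TranslationInhibitionModel):
        return list(model.motif.inhibitors)
    if isinstance(model, TranscriptionDegradationModel):
        return [model.motif.mirna_id]
    raise TypeError(f"unsupported model type {type(model).__name__}")


def _simulate_downstream(results: MotifFitResults, perturbed: np.ndarray) -> np.ndarray:
    """Fitted forward recursion driven by the perturbed miRNA levels."""
    model = results.model
    params = results.params
    if isinstance(model, TranslationInhibitionModel):
        # Hill factors need non-negative levels; floor only here.
        m = np.maximum(perturbed, 0.0)
        return simulate_ti_forward(params, model._g, m, model._p[0])
    rep_levels = [model.data[r].values for r in model.motif.repressors]
    act_levels = [model.data[a].values for a in model.motif.activators]
    return simulate_td_forward(params, perturbed[0], rep_levels, act_levels,
                               model._g[0])


def robustness_study(results: MotifFitResults, noise_sd,
                     n_reps: int = 100, seed: int = 0,
                     law: str = "gaussian") -> PerturbationStudy:
    """Run the perturb-and-refit procedure on a completed motif fit.

    ``noise_sd`` is a per-miRNA per-time array (broadcastable to the
    perturbed level matrix) or a scalar absolute standard deviation.
    Replicates whose re-fit fails are recorded, not fatal.
    """
    model = results.model
    perturbed_ids = _perturbed_ids(results)
    base_levels = model.data.values_matrix(perturbed_ids)
    output_id = (model.motif.protein_id
                 if isinstance(model, TranslationInhibitionModel)
                 else model.motif.mrna_id)
    streams = np.random.SeedSequence(seed).spawn(n_reps)
    rows = []
    failures = []
    for rep, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        perturbed = perturb_profiles(base_levels, noise_sd, rng, law=law)
        downstream = _simulate_downstream(results, perturbed)
        try:
            refit_data = ProfileSet(model.data.grid)
            for prof in model.data:
                if prof.species_id == output_id:
                    refit_data.add(prof.with_values(downstream))
                else:
                    refit_data.add(prof)
            refit = type(model)(model.motif, refit_data, model.config).fit()
            rows.append(refit.params.as_dict())
        except (ValueError, KeyError, RuntimeError):
            failures.append(rep)
    estimates = pd.DataFrame(rows)
    return PerturbationStudy(
        original=results.params.as_dict(),
        estimates=estimates,
        n_reps=n_reps,
        seed=seed,
        failures=tuple(failures),
    )
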