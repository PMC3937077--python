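"""Synthetic motifs and expression datasets with known ground truth.

Emulates the shape of day-course differentiation microarray data: strictly
positive profiles on a uniform 19-point grid over days 0-6, smooth in time
(the real data are PCHIP-resampled day courses), with optional Gaussian
measurement noise.  Upstream profiles are sums of 2-4 scaled logistic and
sinusoid components over a positive baseline; downstream outputs are
produced by the exact forward recursions, so a noiseless dataset is fit by
the estimator with zero minimax error.

"Exact-recovery mode" (the default) draws the true affinities u on the same
median-inversion grid the estimator searches, so recovery assertions can
demand equality rather than closeness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .estimation import DEFAULT_S_BY_K, DEFAULT_S_FALLBACK, h_levels, invert_median_fraction
from .kinetics import (
    RegulatorTerm,
    TDMotif,
    TDParams,
    TIMotif,
    TIParams,
    simulate_td_forward,
    simulate_ti_forward,
)
from .profiles import AffineMap, ExpressionProfile, ProfileSet, TimeGrid, profile_distance

__all__ = [
    "SyntheticSpec",
    "smooth_positive_curve",
    "generate_ti_dataset",
    "generate_td_dataset",
    "generate_cluster_testset",
    "generate_screen_dataset",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic dataset.

    noise_fraction is the measurement-noise standard deviation expressed as
    a fraction of each profile's median level (0 = noiseless).
    """

    motif: object
    seed: int = 0
    grid: TimeGrid = field(default_factory=TimeGrid.uniform)
    noise_fraction: float = 0.0
    exact_recovery: bool = True
    s: Optional[int] = None       # h-grid size for on-grid affinity draws
    s_max: int = 5

    def s_for(self, k: int) -> int:
        if self.s is not None:
            return self.s
        return DEFAULT_S_BY_K.get(k, DEFAULT_S_FALLBACK)


def smooth_positive_curve(rng: np.random.Generator, t: np.ndarray) -> np.ndarray:
    """Smooth, strictly positive curve: baseline + 2-4 logistic/sine components."""
    t = np.asarray(t, dtype=float)
    span = t[-1] - t[0]
    vals = np.full_like(t, rng.uniform(0.5, 1.5))
    for _ in range(rng.integers(2, 5)):
        amp = rng.uniform(0.3, 1.2)
        if rng.integers(2) == 0:
            center = rng.uniform(t[0], t[-1])
            width = rng.uniform(0.4, 1.5)
            vals = vals + amp / (1.0 + np.exp(-(t - center) / width))
        else:
            freq = rng.uniform(0.3, 1.0)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            vals = vals + amp * 0.5 * (1.0 + np.sin(2.0 * np.pi * freq * (t - t[0]) / span + phase))
    return vals


def _add_noise(values: np.ndarray, fraction: float, rng: np.random.Generator) -> np.ndarray:
    if fraction <= 0:
        return values
    sd = fraction * float(np.median(values))
    return values + rng.normal(0.0, sd, size=values.shape)


def _draw_term(rid: str, levels: np.ndarray, spec: SyntheticSpec, k: int,
               rng: np.random.Generator) -> RegulatorTerm:
    S = int(rng.integers(1, spec.s_max + 1))
    median = float(np.median(levels))
    if spec.exact_recovery:
        hs = h_levels(spec.s_for(k))
        h = float(hs[rng.integers(len(hs))])
        u = invert_median_fraction(median, h, S)
    else:
        u = float(rng.lognormal(mean=np.log(1.0 / median), sigma=0.5))
    return RegulatorTerm(rid, affinity=u, sites=S, s_max=spec.s_max)


def generate_ti_dataset(spec: SyntheticSpec) -> Tuple[ProfileSet, TIParams]:
    """Synthetic TI dataset: smooth upstream g and m_i, simulated protein p."""
    motif: TIMotif = spec.motif
    rng = np.random.default_rng(spec.seed)
    t = spec.grid.asarray()
    g = smooth_positive_curve(rng, t)
    m = np.array([smooth_positive_curve(rng, t) for _ in motif.inhibitors])
    k = motif.k
    terms = tuple(
        _draw_term(rid, m[i], spec, k, rng) for i, rid in enumerate(motif.inhibitors)
    )
    params = TIParams(
        gamma=float(rng.uniform(0.05, 0.5)),
        lam=float(rng.uniform(0.1, 0.8)),
        inhibitor_terms=terms,
    )
    p = simulate_ti_forward(params, g, m, p_initial=float(rng.uniform(0.5, 2.0)))
    profiles = ProfileSet(spec.grid)
    profiles.add(ExpressionProfile(motif.protein_id, "protein",
                                   _add_noise(p, spec.noise_fraction, rng), spec.grid))
    profiles.add(ExpressionProfile(motif.mrna_id, "mRNA",
                                   _add_noise(g, spec.noise_fraction, rng), spec.grid))
    for i, rid in enumerate(motif.inhibitors):
        profiles.add(ExpressionProfile(rid, "miRNA",
                                       _add_noise(m[i], spec.noise_fraction, rng), spec.grid))
    return profiles, params


def generate_td_dataset(spec: SyntheticSpec) -> Tuple[ProfileSet, TDParams]:
    """Synthetic TD dataset: smooth m/TF profiles, simulated mRNA g.

    Requires at least one activator — with an empty activator set the
    transcription commitment is structurally zero and the motif cannot
    produce transcription.
    """
    motif: TDMotif = spec.motif
    if not motif.activators:
        raise ValueError("a TD dataset needs at least one activator (F == 0 otherwise)")
    rng = np.random.default_rng(spec.seed)
    t = spec.grid.asarray()
    m = smooth_positive_curve(rng, t)
    rep_levels = np.array([smooth_positive_curve(rng, t) for _ in motif.repressors])
    act_levels = np.array([smooth_positive_curve(rng, t) for _ in motif.activators])
    k = len(motif.regulators)
    rep_terms = tuple(
        _draw_term(rid, rep_levels[i], spec, k, rng)
        for i, rid in enumerate(motif.repressors)
    )
    act_terms = tuple(
        _draw_term(rid, act_levels[i], spec, k, rng)
        for i, rid in enumerate(motif.activators)
    )
    params = TDParams(
        beta=float(rng.uniform(0.05, 0.3)),
        v=float(rng.uniform(0.01, 0.1)),
        kappa=float(rng.uniform(0.2, 0.8)),
        repressor_terms=rep_terms,
        activator_terms=act_terms,
    )
    g = simulate_td_forward(params, m, list(rep_levels), list(act_levels),
                            g_initial=float(rng.uniform(0.5, 2.0)))
    profiles = ProfileSet(spec.grid)
    profiles.add(ExpressionProfile(motif.mrna_id, "mRNA",
                                   _add_noise(g, spec.noise_fraction, rng), spec.grid))
    profiles.add(ExpressionProfile(motif.mirna_id, "miRNA",
                                   _add_noise(m, spec.noise_fraction, rng), spec.grid))
    for i, rid in enumerate(motif.repressors):
        profiles.add(ExpressionProfile(rid, "protein",
                                       _add_noise(rep_levels[i], spec.noise_fraction, rng), spec.grid))
    for i, rid in enumerate(motif.activators):
        profiles.add(ExpressionProfile(rid, "protein",
                                       _add_noise(act_levels[i], spec.noise_fraction, rng), spec.grid))
    return profiles, params


def generate_cluster_testset(n_clusters: int, members_per_cluster: int,
                             within_spread: float, seed: int = 0,
                             grid: TimeGrid | None = None,
                             min_separation: float = 1.0,
                             ) -> Tuple[ProfileSet, Dict[str, int]]:
    """Profiles planted around well-separated template curves.

    Each member is an affine image (a in [0.5, 2], b in [-1, 1]) of its
    cluster template plus small noise, with the noise shrunk until the
    affine-invariant distance to the template is at most ``within_spread``.
    Templates are rejection-sampled to be pairwise farther than
    ``min_separation`` apart.  Returns the profiles and ground-truth labels.
    """
    rng = np.random.default_rng(seed)
    grid = grid or TimeGrid.uniform()
    t = grid.asarray()
    templates = []
    attempts = 0
    while len(templates) < n_clusters:
        attempts += 1
        if attempts > 200 * n_clusters:
            raise RuntimeError(
                "could not place templates with the requested separation; "
                "lower min_separation or n_clusters"
            )
        cand = smooth_positive_curve(rng, t)
        if np.var(cand) <= 0:
            continue
        if all(profile_distance(cand, tpl) > min_separation for tpl in templates):
            templates.append(cand)
    profiles = ProfileSet(grid)
    labels: Dict[str, int] = {}
    for ci, tpl in enumerate(templates):
        scale = float(np.std(tpl))
        for mi in range(members_per_cluster):
            sigma = 0.2 * within_spread * scale
            values = AffineMap(rng.uniform(0.5, 2.0), rng.uniform(-1.0, 1.0))(tpl)
            while sigma > 0:
                noisy = values + rng.normal(0.0, sigma, size=values.shape)
                if profile_distance(noisy, tpl) <= within_spread:
                    values = noisy
                    break
                sigma /= 2.0
            sid = f"mir-c{ci}-{mi}"
            profiles.add(ExpressionProfile(sid, "miRNA", values, grid))
            labels[sid] = ci
    return profiles, labels


def generate_screen_dataset(n_clusters: int = 4, members_per_cluster: int = 4,
                            seed: int = 0, grid: TimeGrid | None = None,
                            within_spread: float = 0.05,
                            ) -> Tuple[ProfileSet, str, TIParams]:
    """Multi-cluster miRNA set plus a protein driven by one planted miRNA.

    The protein profile is simulated from the *positive-shift-normalized*
    planted miRNA (the screening pipeline fits on normalized miRNA levels).
    Returns the profiles (miRNAs raw, plus mRNA 'G' and protein 'P'), the
    planted miRNA id, and the true TI parameters.
    """
    from .profiles import positive_shift_normalize

    rng = np.random.default_rng(seed)
    grid = grid or TimeGrid.uniform()
    mirnas, _labels = generate_cluster_testset(
        n_clusters, members_per_cluster, within_spread, seed=seed + 1, grid=grid,
    )
    planted = mirnas.ids[0]
    m_hat = positive_shift_normalize(mirnas[planted].values)
    g = smooth_positive_curve(rng, grid.asarray())
    spec = SyntheticSpec(motif=TIMotif("P", "G", (planted,)), seed=seed, grid=grid)
    term = _draw_term(planted, m_hat, spec, k=1, rng=rng)
    params = TIParams(gamma=float(rng.uniform(0.1, 0.4)),
                      lam=float(rng.uniform(0.2, 0.6)),
                      inhibitor_terms=(term,))
    p = simulate_ti_forward(params, g, m_hat[None, :], p_initial=1.0)
    profiles = ProfileSet(grid)
    profiles.add(ExpressionProfile("P", "protein", p, grid))
    profiles.add(ExpressionProfile("G", "mRNA", g, grid))
    for prof in mirnas:
        profiles.add(prof)
    return profiles, planted, params
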