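"""Screening pipeline: normalize -> cluster -> fit representatives -> propagate.

Reproduces the application workflow at library level: positive-shift
normalize the miRNA profiles, condense them by minimal-net clustering at a
radius epsilon, fit one TI motif per cluster representative against a target
protein/mRNA pair, and validate clusters whose representative fit reaches
MODER <= threshold.  Because the kinetic model family is form-invariant
under affine recalibration and cluster members sit within epsilon of their
representative, a validated representative flags every member of its
cluster as a potential repressor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import pandas as pd

from .estimation import FitConfig
from .kinetics import TIMotif
from .models import MotifFitResults, TranslationInhibitionModel
from .netclust import NetClustering, cluster
from .profiles import ProfileSet, positive_shift_normalize

log = logging.getLogger("mirmotif")

__all__ = ["ScreenReport", "run_screen"]


@dataclass(frozen=True)
class ScreenReport:
    """Outcome of a screening run over all miRNA clusters."""

    clustering: NetClustering
    fits: Dict[str, MotifFitResults]          # representative id -> fit
    validated_representatives: Tuple[str, ...]
    validated_members: Tuple[str, ...]        # propagated to whole clusters
    epsilon: float
    moder_threshold: float

    def table(self) -> pd.DataFrame:
        rows = []
        for rep in self.clustering.representatives:
            fit = self.fits[rep]
            rows.append({
                "representative": rep,
                "n_members": len(self.clustering.members(rep)),
                "err_star": fit.err_star,
                "moder": fit.moder if fit.quality is not None else float("nan"),
                "validated": rep in self.validated_representatives,
            })
        return pd.DataFrame(rows)


def run_screen(profiles: ProfileSet, protein_id: str, mrna_id: str,
               epsilon: float = 0.15,
               fit_config: FitConfig | None = None) -> ScreenReport:
    """Screen every miRNA cluster as a candidate translation inhibitor.

    ``profiles`` must contain the protein and mRNA profiles plus the miRNA
    pool (role "miRNA").  Deterministic given the input order.
    """
    fit_config = fit_config or FitConfig()
    mirnas = profiles.by_role("miRNA")
    if len(mirnas) == 0:
        raise ValueError("no miRNA profiles in the input set")
    normalized = mirnas.map_values(positive_shift_normalize)
    log.info("screen: %d miRNA profiles normalized", len(normalized))
    clustering = cluster(normalized, epsilon)
    log.info("screen: %d clusters at epsilon=%g (max diameter %.4g)",
             clustering.n_clusters, epsilon, clustering.max_diameter)
    fits: Dict[str, MotifFitResults] = {}
    validated_reps: List[str] = []
    validated_members: List[str] = []
    for rep in clustering.representatives:
        data = ProfileSet(profiles.grid)
        data.add(profiles[protein_id])
        data.add(profiles[mrna_id])
        data.add(normalized[rep])
        motif = TIMotif(protein_id, mrna_id, (rep,))
        fit = TranslationInhibitionModel(motif, data, fit_config).fit()
        fits[rep] = fit
        if fit.validated:
            validated_reps.append(rep)
            validated_members.extend(clustering.members(rep))
    log.info("screen: %d/%d clusters validated (threshold %g)",
             len(validated_reps), clustering.n_clusters,
             fit_config.moder_threshold)
    return ScreenReport(
        clustering=clustering,
        fits=fits,
        validated_representatives=tuple(validated_reps),
        validated_members=tuple(validated_members),
        epsilon=epsilon,
        moder_threshold=fit_config.moder_threshold,
    )
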