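"""Mature-sequence similarity versus expression-profile proximity.

Mature miRNAs of similar sequence tend to target overlapping sites, so one
expects sequence-similar miRNAs to show similar expression dynamics.  The
analysis scores every unordered miRNA pair by its Needleman-Wunsch global
alignment score (NWA, linear gap penalty) and by the Euclidean distance
between the positive-shift-normalized expression profiles, splits the pairs
into GroupHigh (NWA > threshold) and GroupLow (NWA <= threshold), and
compares the two distance distributions with a two-sample
Kolmogorov-Smirnov test and quantile curves.

The alignment scoring scheme is a free choice; the default
(match +1, mismatch -1, gap -2) makes thresholds of 10-15 meaningful for
~22-nt mature sequences.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import Align
from scipy import stats

from .profiles import ProfileSet, positive_shift_normalize

__all__ = [
    "MatureSequence",
    "AlignmentScoring",
    "nw_score",
    "iter_pairs",
    "pair_analysis",
    "ks_two_sample",
    "quantile_curve",
]

_ALPHABET = frozenset("ACGU")


@dataclass(frozen=True)
class MatureSequence:
    """A mature miRNA sequence over the RNA alphabet {A, C, G, U}.

    Input is uppercased and T is normalized to U on construction.
    """

    species_id: str
    sequence: str

    def __post_init__(self):
        seq = self.sequence.upper().replace("T", "U")
        if not seq:
            raise ValueError(f"{self.species_id}: empty sequence")
        bad = set(seq) - _ALPHABET
        if bad:
            raise ValueError(
                f"{self.species_id}: invalid characters {sorted(bad)} "
                "(alphabet is A, C, G, U)"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AlignmentScoring:
    """Linear-gap global alignment scoring (match must exceed mismatch)."""

    match: float = 1.0
    mismatch: float = -1.0
    gap: float = -2.0

    def __post_init__(self):
        if not self.match > self.mismatch:
            raise ValueError("match score must exceed mismatch score")

    def aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = self.match
        aligner.mismatch_score = self.mismatch
        aligner.open_gap_score = self.gap
        aligner.extend_gap_score = self.gap
        return aligner


def nw_score(s1, s2, scoring: AlignmentScoring = AlignmentScoring()) -> float:
    """Optimal Needleman-Wunsch global alignment score (symmetric)."""
    seq1 = s1.sequence if isinstance(s1, MatureSequence) else MatureSequence("s1", s1).sequence
    seq2 = s2.sequence if isinstance(s2, MatureSequence) else MatureSequence("s2", s2).sequence
    return float(scoring.aligner().score(seq1, seq2))


def iter_pairs(ids: Sequence[str]) -> Iterable[Tuple[str, str]]:
    """All n(n-1)/2 unordered pairs in input order."""
    return itertools.combinations(ids, 2)


def pair_analysis(profiles: ProfileSet, sequences: Dict[str, MatureSequence] | Sequence[MatureSequence],
                  scoring: AlignmentScoring = AlignmentScoring(),
                  nwa_threshold: float = 10.0,
                  normalize: bool = True) -> pd.DataFrame:
    """Score all unordered profile pairs by NWA and expression distance.

    Returns a DataFrame with columns ``id1, id2, nwa, distance, group``
    where group is "High" iff nwa strictly exceeds the threshold.  The
    expression distance is Euclidean between positive-shift-normalized
    profiles (set ``normalize=False`` for raw values).
    """
    if not isinstance(sequences, dict):
        sequences = {s.species_id: s for s in sequences}
    ids = profiles.ids
    missing = [i for i in ids if i not in sequences]
    if missing:
        raise KeyError(f"no mature sequence for profiled miRNAs: {missing}")
    vectors = {}
    for i in ids:
        v = profiles[i].values
        vectors[i] = positive_shift_normalize(v) if normalize else np.asarray(v, float)
    aligner = scoring.aligner()
    rows = []
    for id1, id2 in iter_pairs(ids):
        nwa = float(aligner.score(sequences[id1].sequence, sequences[id2].sequence))
        dist = float(np.linalg.norm(vectors[id1] - vectors[id2]))
        rows.append((id1, id2, nwa, dist, "High" if nwa > nwa_threshold else "Low"))
    table = pd.DataFrame(rows, columns=["id1", "id2", "nwa", "distance", "group"])
    table.attrs["nwa_threshold"] = nwa_threshold
    table.attrs["scoring"] = (scoring.match, scoring.mismatch, scoring.gap)
    return table


def ks_two_sample(a, b) -> Tuple[float, float]:
    """Two-sample KS statistic (sup ECDF gap) with asymptotic p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def quantile_curve(values, probs) -> np.ndarray:
    """Empirical quantiles at the given probabilities (monotone in probs)."""
    values = np.asarray(values, dtype=float)
    probs = np.asarray(probs, dtype=float)
    if values.size == 0:
        raise ValueError("sample is empty")
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    return np.quantile(values, probs)
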