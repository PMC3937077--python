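"""Greedy minimal-net (epsilon-net) clustering under the affine-invariant distance.

Expression data sets are far too large to fit a kinetic model per profile, so
profiles are condensed into clusters of controlled diameter before modeling.
Unlike k-means or hierarchical clustering, the greedy net construction bounds
every cluster's diameter by ``2 * epsilon``:

1. seed the net with the farthest pair of profiles;
2. while the farthest point from the net is more than ``epsilon`` away,
   promote that point to a representative;
3. assign every profile to its nearest representative.

All argmax/argmin ties are broken by position in the input order, which makes
the clustering deterministic and part of the reproducibility contract.  The
construction is greedy: it guarantees the covering radius and the diameter
bound, not minimum cardinality of the net.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .profiles import DegenerateProfileError, ProfileSet, pairwise_distances, summarize

__all__ = [
    "NetClustering",
    "farthest_pair",
    "build_minimal_net",
    "assign_clusters",
    "cluster_diameter",
    "cluster",
]


@dataclass(frozen=True)
class NetClustering:
    """Result of a minimal-net clustering run."""

    epsilon: float
    representatives: Tuple[str, ...]
    assignment: Dict[str, str]
    diameters: Dict[str, float]

    @property
    def n_clusters(self) -> int:
        return len(self.representatives)

    def members(self, representative: str) -> List[str]:
        return [sid for sid, rep in self.assignment.items() if rep == representative]

    @property
    def max_diameter(self) -> float:
        return max(self.diameters.values())

    def summary(self) -> dict:
        return {
            "epsilon": self.epsilon,
            "n_clusters": self.n_clusters,
            "max_diameter": self.max_diameter,
            "representatives": list(self.representatives),
        }


def _check_degenerate(profiles: ProfileSet) -> None:
    bad = [p.species_id for p in profiles if summarize(p)[1] <= 0.0]
    if bad:
        raise DegenerateProfileError(
            f"constant profiles cannot be clustered: {bad}"
        )


def farthest_pair(profiles: ProfileSet, dist: np.ndarray | None = None):
    """Pair of profiles attaining the maximum pairwise D (ties: lowest index pair).

    Returns ``(id_a, id_b, distance)`` with ``id_a`` before ``id_b`` in input
    order.
    """
    ids = profiles.ids
    if len(ids) < 2:
        raise ValueError("need at least 2 profiles to find a farthest pair")
    if dist is None:
        _check_degenerate(profiles)
        dist = pairwise_distances(profiles)
    iu, ju = np.triu_indices(len(ids), k=1)
    best = int(np.argmax(dist[iu, ju]))  # first max in (i, j) lexicographic order
    i, j = int(iu[best]), int(ju[best])
    return ids[i], ids[j], float(dist[i, j])


def build_minimal_net(profiles: ProfileSet, epsilon: float,
                      dist: np.ndarray | None = None) -> List[str]:
    """Greedy construction of the epsilon-net representative list.

    Seeds with the farthest pair, then repeatedly promotes the profile
    farthest from the current net while that distance exceeds ``epsilon``.
    Representatives added after the seed pair are therefore pairwise more
    than ``epsilon`` apart, and on return every profile lies within
    ``epsilon`` of the net.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    ids = profiles.ids
    if len(ids) == 1:
        # Degenerate singleton input: one trivial cluster.
        return list(ids)
    if dist is None:
        _check_degenerate(profiles)
        dist = pairwise_distances(profiles)
    a, b, _ = farthest_pair(profiles, dist)
    rep_idx = [ids.index(a), ids.index(b)]
    to_net = np.minimum(dist[rep_idx[0]], dist[rep_idx[1]])
    while True:
        far = int(np.argmax(to_net))  # first max = lowest input index
        if to_net[far] <= epsilon:
            break
        rep_idx.append(far)
        to_net = np.minimum(to_net, dist[far])
    return [ids[i] for i in rep_idx]


def assign_clusters(profiles: ProfileSet, representatives: Sequence[str],
                    epsilon: float | None = None,
                    dist: np.ndarray | None = None) -> NetClustering:
    """Assign each profile to its nearest representative (ties: earliest listed)."""
    if not representatives:
        raise ValueError("representative list is empty")
    ids = profiles.ids
    missing = [r for r in representatives if r not in profiles]
    if missing:
        raise ValueError(f"representatives not in the profile set: {missing}")
    if dist is None:
        _check_degenerate(profiles)
        dist = pairwise_distances(profiles)
    rep_idx = [ids.index(r) for r in representatives]
    sub = dist[np.ix_(range(len(ids)), rep_idx)]
    nearest = np.argmin(sub, axis=1)  # first min = earliest-listed representative
    assignment = {ids[i]: representatives[int(k)] for i, k in enumerate(nearest)}
    diameters = {}
    for rep in representatives:
        member_idx = [i for i, sid in enumerate(ids) if assignment[sid] == rep]
        diameters[rep] = _diameter_from_matrix(dist, member_idx)
    eps = float("nan") if epsilon is None else float(epsilon)
    return NetClustering(eps, tuple(representatives), assignment, diameters)


def _diameter_from_matrix(dist: np.ndarray, member_idx: Sequence[int]) -> float:
    if len(member_idx) < 2:
        return 0.0
    sub = dist[np.ix_(member_idx, member_idx)]
    return float(np.max(sub))


def cluster_diameter(members: Sequence) -> float:
    """Max pairwise D over a cluster's member profiles; 0 for a singleton."""
    from .profiles import profile_distance

    members = list(members)
    if not members:
        raise ValueError("cluster is empty")
    if len(members) == 1:
        return 0.0
    return max(
        profile_distance(members[i], members[j])
        for i in range(len(members))
        for j in range(i + 1, len(members))
    )


def cluster(profiles: ProfileSet, epsilon: float) -> NetClustering:
    """Full pipeline: build the net at ``epsilon`` and assign all profiles."""
    _check_degenerate(profiles)
    dist = pairwise_distances(profiles)
    reps = build_minimal_net(profiles, epsilon, dist)
    return assign_clusters(profiles, reps, epsilon, dist)
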