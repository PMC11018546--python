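"""Community cohesion scores, connectivity loss, and target prioritization.

Each community G_k is treated as a functional unit and scored by weighted
global efficiency,

    E_k = 1 / (N (N - 1)) * sum_{X != Y in G_k} 1 / d(X, Y),

where d(X, Y) is the weighted shortest path with edge length 1/w (strong
interactions are short) and disconnected pairs contribute zero to the sum.
The community cohesion score is the ratio of E_k in a sample's
individualized network to E_k in the normal-tissue reference: 1 means the
community is fully intact, 0 fully disconnected.

Per-gene connectivity loss is the flagged fraction of a gene's incident
edge weight; druggable genes in the most-affected community are ranked by
it (ties broken by normal-network strength, then lexicographically).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path

from .individualize import PerturbationSet
from .network import TissueNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "CohesionProfile",
    "ConnectivityLossProfile",
    "network_efficiency",
    "cohesion_score",
    "cohesion_profile",
    "connectivity_loss",
    "connectivity_loss_profile",
    "prioritize_targets",
]


# ----------------------------------------------------------------------
# efficiency
# ----------------------------------------------------------------------
def _community_length_matrix(
    network: TissueNetwork, community: str, removed: set | None = None
) -> tuple[list[str], np.ndarray]:
    genes = sorted(network.communities[community])
    pos = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    lengths = np.zeros((n, n))
    for (a, b), w in network.community_edges(community).items():
        if removed and (a, b) in removed:
            continue
        lengths[pos[a], pos[b]] = lengths[pos[b], pos[a]] = 1.0 / w
    return genes, lengths


def _efficiency_from_lengths(lengths: np.ndarray) -> float:
    n = lengths.shape[0]
    if n < 2:
        raise ValueError("community too small to score")
    dist = shortest_path(lengths, method="D", directed=False)
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    inv[~np.isfinite(inv)] = 0.0  # disconnected pairs contribute nothing
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def network_efficiency(network: TissueNetwork, community: str) -> float:
    """Weighted global efficiency of one community's subgraph."""
    if community not in network.communities:
        raise ValueError(f"unknown community {community!r}")
    _, lengths = _community_length_matrix(network, community)
    return _efficiency_from_lengths(lengths)


def cohesion_score(
    reference: TissueNetwork, individualized: TissueNetwork, community: str
) -> float:
    """Efficiency ratio individualized / reference for one community."""
    if set(individualized.edges) - set(reference.edges):
        raise ValueError("individualized edges must be a subset of the reference")
    eff_ref = network_efficiency(reference, community)
    if eff_ref == 0:
        raise ValueError(f"unscored community {community!r}: reference efficiency is 0")
    return network_efficiency(individualized, community) / eff_ref


# ----------------------------------------------------------------------
# profiles
# ----------------------------------------------------------------------
@dataclass
class CohesionProfile:
    """One sample's cohesion score per community, with both efficiencies."""

    sample_id: str
    scores: dict[str, float]
    efficiencies: dict[str, tuple[float, float]]  # label -> (individual, normal)

    def min_score_community(self) -> str:
        return min(self.scores, key=lambda k: (self.scores[k], k))


@dataclass
class ConnectivityLossProfile:
    """One sample's per-gene connectivity-loss scores with tie-break fields."""

    sample_id: str
    loss: dict[str, float]
    normal_strength: dict[str, float]
    normal_degree: dict[str, int]


def cohesion_profile(
    reference: TissueNetwork,
    perturbed: PerturbationSet,
    reference_efficiency: dict[str, float] | None = None,
) -> CohesionProfile:
    """Score every community of one sample's individualized network.

    ``reference_efficiency`` may carry precomputed normal efficiencies to
    avoid recomputing them per sample in batch runs.
    """
    removed = perturbed.edges()
    scores: dict[str, float] = {}
    efficiencies: dict[str, tuple[float, float]] = {}
    for label in sorted(reference.communities):
        if len(reference.communities[label]) < 2:
            raise ValueError(f"community {label!r} too small to score")
        if reference_efficiency is not None and label in reference_efficiency:
            eff_ref = reference_efficiency[label]
        else:
            eff_ref = network_efficiency(reference, label)
        if eff_ref == 0:
            raise ValueError(f"unscored community {label!r}: reference efficiency is 0")
        _, lengths = _community_length_matrix(reference, label, removed=removed)
        eff_ind = _efficiency_from_lengths(lengths)
        scores[label] = eff_ind / eff_ref
        efficiencies[label] = (eff_ind, eff_ref)
    return CohesionProfile(perturbed.sample_id, scores, efficiencies)


def connectivity_loss(
    reference: TissueNetwork, perturbed: PerturbationSet, gene: str
) -> float:
    """Flagged fraction of a gene's incident edge weight in the reference."""
    incident = reference.incident_edges(gene)
    if not incident:
        raise ValueError(f"gene {gene!r} has no incident reference edges")
    flagged = perturbed.edges()
    hit = [e for e in sorted(incident) if e in flagged]
    if len(hit) == len(incident):
        return 1.0  # exact at the boundary: summation order must not break ties
    lost = sum(incident[e] for e in hit)
    return min(1.0, float(lost / sum(incident[e] for e in sorted(incident))))


def connectivity_loss_profile(
    reference: TissueNetwork, perturbed: PerturbationSet
) -> ConnectivityLossProfile:
    """Connectivity loss for every gene with at least one reference edge.

    Genes without incident edges are excluded (their loss is undefined)
    with a log entry.
    """
    strength: dict[str, float] = {}
    degree: dict[str, int] = {}
    lost: dict[str, float] = {}
    lost_count: dict[str, int] = {}
    for (a, b) in sorted(reference.edges):
        w = reference.edges[(a, b)]
        for g in (a, b):
            strength[g] = strength.get(g, 0.0) + w
            degree[g] = degree.get(g, 0) + 1
            lost.setdefault(g, 0.0)
            lost_count.setdefault(g, 0)
    for (a, b) in sorted(perturbed.edges()):
        w = reference.edges[(a, b)]
        for g in (a, b):
            lost[g] += w
            lost_count[g] += 1
    n_isolated = len(set(reference.nodes)) - len(strength)
    if n_isolated:
        logger.info("%d gene(s) without reference edges excluded from loss profile",
                    n_isolated)
    # totally disconnected genes get exactly 1.0 so that ties are decided by
    # the documented strength tie-break, not by float summation order
    loss = {
        g: 1.0 if lost_count[g] == degree[g] else min(1.0, lost[g] / strength[g])
        for g in strength
    }
    return ConnectivityLossProfile(perturbed.sample_id, loss, strength, degree)


# ----------------------------------------------------------------------
# target prioritization
# ----------------------------------------------------------------------
def prioritize_targets(
    cohesion: CohesionProfile,
    loss: ConnectivityLossProfile,
    reference: TissueNetwork,
    druggable: set[str],
    community: str | None = None,
) -> pd.DataFrame:
    """Rank druggable genes in the most-affected community.

    The community defaults to the sample's minimum-cohesion community.
    Within it, druggable genes are sorted by connectivity loss descending,
    ties broken by normal-network strength (sum of incident weights)
    descending, remaining ties lexicographically.  Returns a DataFrame
    (rank, gene, loss, tie_break_strength, degree, community); empty when
    the community holds no druggable gene.
    """
    if not druggable & set(reference.nodes):
        raise ValueError("no druggable gene is present in the network")
    if community is None:
        community = cohesion.min_score_community()
    members = reference.communities[community]
    candidates = sorted(druggable & members)
    candidates = [g for g in candidates if g in loss.loss]
    if not candidates:
        logger.info("no druggable gene in community %s; empty ranking", community)
    candidates.sort(key=lambda g: (-loss.loss[g], -loss.normal_strength[g], g))
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(candidates) + 1),
            "gene": candidates,
            "loss": [loss.loss[g] for g in candidates],
            "tie_break_strength": [loss.normal_strength[g] for g in candidates],
            "degree": [loss.normal_degree[g] for g in candidates],
            "community": community,
        }
    )
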