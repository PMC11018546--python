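"""End-to-end orchestration: reference build and batch case scoring."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .cohesion import (
    CohesionProfile,
    ConnectivityLossProfile,
    cohesion_profile,
    connectivity_loss_profile,
    network_efficiency,
)
from .edge_models import EdgeModel, fit_all_edges
from .expression import ExpressionMatrix
from .individualize import PerturbationSet, flag_perturbed_fast
from .network import (
    PreservationReport,
    TissueNetwork,
    communities_from_assignment,
    compute_adjacency,
    compute_tom,
    detect_communities,
    pick_soft_power,
    preservation_filter,
    retain_top_edges,
    split_controls,
)

logger = logging.getLogger(__name__)

__all__ = ["ReferenceResult", "ScoreResult", "build_reference", "score_cases"]


@dataclass
class ReferenceResult:
    """Reference network plus the construction diagnostics."""

    network: TissueNetwork
    preservation: PreservationReport
    soft_power: int
    assignment: dict[str, str] = field(repr=False)


def build_reference(
    controls: ExpressionMatrix,
    power: int | str = "auto",
    candidate_powers=tuple(range(1, 21)),
    r2_cutoff: float = 0.8,
    top_fraction: float = 0.1,
    min_community_size: int = 30,
    n_permutations: int = 200,
    z_cutoff: float = 10.0,
    split_seed: int = 17,
    test_fraction: float = 0.2,
) -> ReferenceResult:
    """Build the normal-tissue reference network from control samples.

    Controls are split 80/20; adjacency/TOM and community detection run on
    the training split, the held-out split feeds the permutation
    preservation filter, and the kept communities retain their top-weight
    edge fraction.
    """
    train, test = split_controls(controls, test_fraction=test_fraction, seed=split_seed)
    if power == "auto":
        power = pick_soft_power(train, candidate_powers, r2_cutoff)
    power = int(power)
    tom_train = compute_tom(compute_adjacency(train, power))
    tom_test = compute_tom(compute_adjacency(test, power))
    assignment = detect_communities(tom_train, train.gene_ids, min_size=min_community_size)
    communities = communities_from_assignment(assignment)
    if not communities:
        raise ValueError("no community reached the minimum size")
    report = preservation_filter(
        tom_train, tom_test, train.gene_ids, communities,
        n_permutations=n_permutations, z_cutoff=z_cutoff, seed=split_seed,
    )
    kept = {k: communities[k] for k in report.kept}
    logger.info("%d/%d communities preserved", len(kept), len(communities))
    if not kept:
        raise ValueError("no community passed the preservation filter")
    network = retain_top_edges(
        tom_train, train.gene_ids, kept, fraction=top_fraction, soft_power=power
    )
    return ReferenceResult(network, report, power, assignment)


@dataclass
class ScoreResult:
    """Batch scoring output over a case cohort."""

    cohesion: pd.DataFrame = field(repr=False)  # samples x communities
    loss: pd.DataFrame = field(repr=False)  # samples x genes
    perturbations: list[PerturbationSet] = field(repr=False)
    profiles: list[CohesionProfile] = field(repr=False)
    loss_profiles: list[ConnectivityLossProfile] = field(repr=False)


def score_cases(
    reference: TissueNetwork,
    models: dict[tuple[str, str], EdgeModel],
    cases: ExpressionMatrix,
    alpha: float = 0.001,
) -> ScoreResult:
    """Individualize and score every case sample against the reference.

    Each case is processed independently: flag perturbed edges, then
    compute per-community cohesion scores and per-gene connectivity loss.
    """
    ref_eff = {
        label: network_efficiency(reference, label)
        for label in sorted(reference.communities)
    }
    perturbations = flag_perturbed_fast(models, cases, alpha=alpha)
    profiles, loss_profiles = [], []
    for pset in perturbations:
        profiles.append(cohesion_profile(reference, pset, reference_efficiency=ref_eff))
        loss_profiles.append(connectivity_loss_profile(reference, pset))
    cohesion = pd.DataFrame(
        [p.scores for p in profiles], index=[p.sample_id for p in profiles]
    )
    cohesion.index.name = "sample_id"
    loss = pd.DataFrame(
        [lp.loss for lp in loss_profiles], index=[lp.sample_id for lp in loss_profiles]
    )
    loss.index.name = "sample_id"
    return ScoreResult(cohesion, loss, perturbations, profiles, loss_profiles)
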