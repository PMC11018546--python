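"""Synthetic data with the statistical structure the method assumes.

Controls are multivariate-normal draws with block-diagonal correlation:
each planted community is a single-factor block whose genes load on a
shared factor with mildly heterogeneous loadings (so every block has a
hub-to-periphery connectivity gradient, as real co-expression modules
do), calibrated so the mean pairwise within-block correlation equals
``within_correlation``; between-block correlation is 0 and background
genes are independent noise.  The first gene of each block carries the
largest loading and is the designated hub.  Case samples come
from the same distribution, after which co-expression inside one target
community is destroyed by re-drawing a subset of its genes independently
— the method detects deviation from co-expression, so breaking an edge
means decorrelating its endpoints, not shifting means.  In hub mode only
one designated gene is re-drawn, emulating a sample whose hub loses all
its connectivity.  Survival times are exponential with a hazard-ratio
bump for low-cohesion samples and uniform censoring.

All generators are pure functions of (config, seed): the same config
yields byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix

__all__ = [
    "CommunitySpec",
    "PerturbationConfig",
    "SurvivalConfig",
    "SimulationConfig",
    "CaseTruth",
    "generate_controls",
    "generate_cases",
    "generate_survival",
    "generate_cutpoint_cohort",
]


@dataclass(frozen=True)
class CommunitySpec:
    size: int
    within_correlation: float

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ValueError("community size must be >= 2")
        if not (0.0 < self.within_correlation < 1.0):
            raise ValueError("within_correlation must be in (0, 1)")


@dataclass(frozen=True)
class PerturbationConfig:
    target_community: int = 0
    fraction_edges_broken: float = 1.0
    hub_gene_mode: bool = False
    noise_sd_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction_edges_broken <= 1.0):
            raise ValueError("fraction_edges_broken must be in [0, 1]")
        if self.noise_sd_multiplier < 1.0:
            raise ValueError("noise_sd_multiplier must be >= 1")


@dataclass(frozen=True)
class SurvivalConfig:
    baseline_hazard: float = 0.2
    hazard_ratio: float = 3.0
    true_threshold: float = 0.5
    censor_max: float = 10.0

    def __post_init__(self) -> None:
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be positive")
        if not (0.0 <= self.true_threshold <= 1.0):
            raise ValueError("true_threshold must be in [0, 1]")
        if self.censor_max <= 0:
            raise ValueError("censor_max must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic fixtures.

    Defaults give 300 genes in five equicorrelated communities of sizes
    40-80 (rho = 0.9), 500 controls and 200 cases — enough samples for
    stable per-edge distance distributions at a desk-scale runtime.
    """

    n_genes: int = 300
    n_controls: int = 500
    n_cases: int = 200
    communities: tuple[CommunitySpec, ...] = (
        CommunitySpec(40, 0.9),
        CommunitySpec(50, 0.9),
        CommunitySpec(60, 0.9),
        CommunitySpec(70, 0.9),
        CommunitySpec(80, 0.9),
    )
    perturbation: PerturbationConfig = field(default_factory=PerturbationConfig)
    survival: SurvivalConfig = field(default_factory=SurvivalConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(c.size for c in self.communities) > self.n_genes:
            raise ValueError("community sizes exceed n_genes")
        if self.n_controls < 3 or self.n_cases < 1:
            raise ValueError("need at least 3 controls and 1 case")
        if not (0 <= self.perturbation.target_community < len(self.communities)):
            raise ValueError("target_community index out of range")

    # ------------------------------------------------------------------
    def gene_names(self) -> list[str]:
        width = max(4, len(str(self.n_genes)))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    def community_genes(self, which: int) -> list[str]:
        names = self.gene_names()
        start = sum(c.size for c in self.communities[:which])
        return names[start : start + self.communities[which].size]


# ----------------------------------------------------------------------
_LOADING_SPREAD = 0.1  # hub-to-periphery relative loading gradient per block


def _block_loadings(size: int, rho: float) -> np.ndarray:
    """Factor loadings giving mean pairwise correlation rho with a hub gradient.

    Loadings decrease linearly by ``_LOADING_SPREAD`` from the first gene
    (the hub) to the last, rescaled so the mean over pairs of
    lambda_i * lambda_j equals rho.
    """
    u = np.linspace(1.0, 1.0 - _LOADING_SPREAD, size)
    s, q = u.sum(), (u**2).sum()
    scale2 = rho * size * (size - 1) / (s**2 - q)
    lam = np.sqrt(scale2) * u
    if lam[0] > 1.0:
        raise ValueError(
            f"within_correlation {rho} infeasible with the hub loading gradient"
        )
    return lam


def _draw_expression(config: SimulationConfig, n_samples: int, rng) -> np.ndarray:
    """Block-correlated draws, genes x samples."""
    values = rng.standard_normal((config.n_genes, n_samples))
    offset = 0
    for b, spec in enumerate(config.communities):
        try:
            lam = _block_loadings(spec.size, spec.within_correlation)
        except ValueError as exc:
            raise ValueError(f"community block {b}: {exc}") from exc
        factor = rng.standard_normal(n_samples)
        block = values[offset : offset + spec.size]
        values[offset : offset + spec.size] = (
            lam[:, None] * factor[None, :] + np.sqrt(1.0 - lam**2)[:, None] * block
        )
        offset += spec.size
    return values


def generate_controls(config: SimulationConfig) -> ExpressionMatrix:
    """Control cohort: block-correlated multivariate-normal expression."""
    rng = np.random.default_rng([config.seed, 0])
    values = _draw_expression(config, config.n_controls, rng)
    width = max(4, len(str(config.n_controls)))
    samples = [f"CTRL{i:0{width}d}" for i in range(1, config.n_controls + 1)]
    return ExpressionMatrix(config.gene_names(), samples, values)


# ----------------------------------------------------------------------
@dataclass(frozen=True)
class CaseTruth:
    """Ground truth of the planted perturbation, per case sample."""

    target_community_genes: tuple[str, ...]
    hub_gene: str | None
    redrawn: dict[str, tuple[str, ...]]  # sample -> genes re-drawn independently

    def broken_pairs(self, sample: str) -> set[tuple[str, str]]:
        broken = set(self.redrawn[sample])
        out = set()
        genes = self.target_community_genes
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                if genes[i] in broken or genes[j] in broken:
                    out.add(tuple(sorted((genes[i], genes[j]))))
        return out

    def write(self, path) -> None:
        rows = [(s, ";".join(g)) for s, g in sorted(self.redrawn.items())]
        pd.DataFrame(rows, columns=["sample_id", "redrawn_genes"]).to_csv(
            path, sep="\t", index=False
        )


def _n_redrawn_for_fraction(k: int, fraction: float) -> int:
    """Smallest gene count whose incident pairs cover the broken fraction."""
    total = k * (k - 1) // 2
    goal = fraction * total
    for s in range(k + 1):
        covered = total - (k - s) * (k - s - 1) // 2
        if covered >= goal - 1e-9:
            return s
    return k


def generate_cases(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, CaseTruth]:
    """Case cohort with the configured community perturbation planted.

    Each case is drawn from the control distribution; inside the target
    community a per-sample random gene subset (sized so its incident pairs
    cover ``fraction_edges_broken`` of the community's pairs) is replaced
    by independent noise.  In hub mode the designated hub gene (the
    community's first gene) is the only one re-drawn.
    """
    rng = np.random.default_rng([config.seed, 1])
    values = _draw_expression(config, config.n_cases, rng)
    width = max(4, len(str(config.n_cases)))
    samples = [f"CASE{i:0{width}d}" for i in range(1, config.n_cases + 1)]
    pert = config.perturbation
    target_genes = config.community_genes(pert.target_community)
    names = config.gene_names()
    pos = {g: i for i, g in enumerate(names)}
    hub = target_genes[0] if pert.hub_gene_mode else None

    redrawn: dict[str, tuple[str, ...]] = {}
    for j, sample in enumerate(samples):
        if pert.hub_gene_mode:
            chosen = [hub]
        else:
            s = _n_redrawn_for_fraction(len(target_genes), pert.fraction_edges_broken)
            chosen = sorted(
                rng.choice(np.array(target_genes), size=s, replace=False).tolist()
            ) if s else []
        for g in chosen:
            values[pos[g], j] = rng.standard_normal() * pert.noise_sd_multiplier
        redrawn[sample] = tuple(chosen)
    truth = CaseTruth(tuple(target_genes), hub, redrawn)
    return ExpressionMatrix(names, samples, values), truth


# ----------------------------------------------------------------------
def generate_survival(
    config: SimulationConfig, low_cohesion: pd.Series
) -> pd.DataFrame:
    """Exponential survival with a hazard bump for low-cohesion samples.

    ``low_cohesion`` is a boolean Series indexed by sample id; low samples
    get hazard baseline * hazard_ratio, the rest the baseline.  Censoring
    is uniform on (0, censor_max].  Returns a time/event frame.
    """
    surv = config.survival
    rng = np.random.default_rng([config.seed, 2])
    low = low_cohesion.astype(bool)
    hazard = np.where(low.to_numpy(), surv.baseline_hazard * surv.hazard_ratio,
                      surv.baseline_hazard)
    event_time = rng.exponential(1.0 / hazard)
    censor_time = rng.uniform(0.0, surv.censor_max, size=len(low))
    censor_time = np.maximum(censor_time, 1e-9)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    return pd.DataFrame({"time": time, "event": event}, index=low.index)


def generate_cutpoint_cohort(
    config: SimulationConfig, n_samples: int
) -> tuple[pd.Series, pd.DataFrame]:
    """Cohort for cutpoint-recovery studies: uniform scores + survival.

    Cohesion scores are uniform on [0, 1]; samples below the configured
    true threshold are the high-risk (low-cohesion) group.
    """
    rng = np.random.default_rng([config.seed, 3])
    width = max(4, len(str(n_samples)))
    ids = [f"S{i:0{width}d}" for i in range(1, n_samples + 1)]
    scores = pd.Series(rng.uniform(0.0, 1.0, size=n_samples), index=ids)
    low = scores < config.survival.true_threshold
    surv = config.survival
    hazard = np.where(low.to_numpy(), surv.baseline_hazard * surv.hazard_ratio,
                      surv.baseline_hazard)
    event_time = rng.exponential(1.0 / hazard)
    censor_time = np.maximum(rng.uniform(0.0, surv.censor_max, size=n_samples), 1e-9)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    survival = pd.DataFrame({"time": time, "event": event}, index=ids)
    survival.index.name = "sample_id"
    return scores, survival
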