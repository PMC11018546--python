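"""Single-sample network individualization.

A case sample's expression point is scored against every edge's control
regression model: the perpendicular distance d_j is standardized by the
robust modified z-score

    z = (d_j - median) / (1.486 * MAD),

and converted to a one-tailed p-value from the standard-normal upper tail
(large distances signal a perturbed interaction; unusually small ones are
never flagged).  Edges with p < alpha (default 0.001) are the sample's
individualized perturbed interactions; removing them from the reference
network yields the individualized gene network.

The 1.486 MAD scaling is the normal-consistency constant as printed in
the method's definition; ``mad_constant`` may be set to 1.4826 if desired.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .edge_models import EdgeModel, perpendicular_distance
from .network import TissueNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "PerturbationSet",
    "case_distance",
    "modified_zscore",
    "flag_perturbed",
    "individualize_network",
    "MAD_CONSTANT",
]

MAD_CONSTANT = 1.486


@dataclass
class PerturbationSet:
    """A case sample's flagged (perturbed) edges with their statistics."""

    sample_id: str
    alpha: float
    flagged: pd.DataFrame = field(repr=False)  # gene_a, gene_b, d_case, mod_z, p_value

    def edges(self) -> set[tuple[str, str]]:
        return {
            (a, b) for a, b in zip(self.flagged["gene_a"], self.flagged["gene_b"])
        }

    def n_flagged(self) -> int:
        return len(self.flagged)

    def write(self, path) -> None:
        self.flagged.to_csv(path, sep="\t", index=False)


def case_distance(model: EdgeModel, x_case: float, y_case: float) -> float:
    """Perpendicular distance of a case point to the edge's fitted line."""
    return float(perpendicular_distance(model.beta0, model.beta1, x_case, y_case))


def modified_zscore(
    model: EdgeModel, d_case: float, mad_constant: float = MAD_CONSTANT
) -> float:
    """Robust standardization of a case distance against the control spread.

    A zero MAD (more than half the control distances identical) makes the
    scale degenerate: any excess over the median is reported as +inf, and
    a case at or below the median as 0.
    """
    if model.d_mad == 0:
        logger.warning(
            "degenerate-scale edge (%s, %s): MAD = 0", model.gene_x, model.gene_y
        )
        return float("inf") if d_case > model.d_median else 0.0
    return (d_case - model.d_median) / (mad_constant * model.d_mad)


def flag_perturbed(
    models: dict[tuple[str, str], EdgeModel],
    case_expr,
    alpha: float = 0.001,
    sample_id: str = "case",
    mad_constant: float = MAD_CONSTANT,
) -> PerturbationSet:
    """Flag a case sample's individualized perturbed interactions.

    ``case_expr`` maps gene id -> expression value (a dict or Series).
    Edges whose genes lack a case value are skipped and logged, never
    silently treated as unperturbed.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must be in (0, 1]")
    rows = []
    n_skipped = 0
    for (a, b) in sorted(models):
        m = models[(a, b)]
        try:
            x, y = case_expr[a], case_expr[b]
        except KeyError:
            n_skipped += 1
            continue
        d = case_distance(m, float(x), float(y))
        z = modified_zscore(m, d, mad_constant)
        p = float(stats.norm.sf(z))
        if p < alpha:
            rows.append((a, b, d, z, p))
    if n_skipped:
        logger.warning(
            "sample %s: %d edge(s) skipped for missing case values", sample_id, n_skipped
        )
    flagged = pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "d_case", "mod_z", "p_value"]
    )
    return PerturbationSet(sample_id, alpha, flagged)


def flag_perturbed_fast(
    models: dict[tuple[str, str], EdgeModel],
    case_matrix,
    alpha: float = 0.001,
    mad_constant: float = MAD_CONSTANT,
) -> list[PerturbationSet]:
    """Vectorized :func:`flag_perturbed` over the columns of a case matrix.

    ``case_matrix`` is an :class:`~cohesionnet.expression.ExpressionMatrix`;
    every model gene must be present.  Returns one PerturbationSet per case
    sample, identical to the per-sample routine.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must be in (0, 1]")
    edges = sorted(models)
    if not edges:
        return [
            PerturbationSet(s, alpha, pd.DataFrame(
                columns=["gene_a", "gene_b", "d_case", "mod_z", "p_value"]))
            for s in case_matrix.sample_ids
        ]
    idx = case_matrix.gene_index()
    missing = {g for e in edges for g in e if g not in idx}
    if missing:
        raise ValueError(f"{len(missing)} model genes missing from the case matrix")
    ia = np.array([idx[a] for a, _ in edges])
    ib = np.array([idx[b] for _, b in edges])
    b0 = np.array([models[e].beta0 for e in edges])
    b1 = np.array([models[e].beta1 for e in edges])
    med = np.array([models[e].d_median for e in edges])
    mad = np.array([models[e].d_mad for e in edges])
    x = case_matrix.values[ia]  # edges x samples
    y = case_matrix.values[ib]
    d = np.abs(b1[:, None] * x - y + b0[:, None]) / np.sqrt(b1**2 + 1.0)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (d - med[:, None]) / (mad_constant * mad)[:, None]
    zero_scale = mad == 0
    if zero_scale.any():
        logger.warning("%d degenerate-scale edge(s) (MAD = 0)", int(zero_scale.sum()))
        excess = d[zero_scale] > med[zero_scale][:, None]
        z[zero_scale] = np.where(excess, np.inf, 0.0)
    p = stats.norm.sf(z)
    out = []
    genes_a = np.array([a for a, _ in edges])
    genes_b = np.array([b for _, b in edges])
    for j, sample in enumerate(case_matrix.sample_ids):
        hit = p[:, j] < alpha
        flagged = pd.DataFrame(
            {
                "gene_a": genes_a[hit],
                "gene_b": genes_b[hit],
                "d_case": d[hit, j],
                "mod_z": z[hit, j],
                "p_value": p[hit, j],
            }
        )
        out.append(PerturbationSet(sample, alpha, flagged))
    return out


def individualize_network(
    reference: TissueNetwork, perturbed: PerturbationSet
) -> TissueNetwork:
    """Remove a sample's perturbed interactions from the reference network.

    The node set and community map are preserved exactly; only edges are
    deleted, so genes isolated by the removal remain as nodes.
    """
    return reference.remove_edges(perturbed.edges())
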