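"""Per-edge regression models over control samples.

Every retained network edge (X, Y) gets a simple OLS fit Y^ = b0 + b1*X
over the control samples, with X fixed as the lexicographically smaller
gene id (the distance is not orientation-invariant, so the convention is
pinned).  The control-sample perpendicular distances to the fitted line,

    d_i = |b1*x_i - y_i + b0| / sqrt(b1^2 + 1),

are summarized by their median and MAD; case samples are later scored
against this robust reference distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .network import TissueNetwork

logger = logging.getLogger(__name__)

__all__ = ["EdgeModel", "fit_edge_model", "fit_all_edges", "perpendicular_distance",
           "write_edge_models", "read_edge_models"]


@dataclass(frozen=True)
class EdgeModel:
    """OLS line plus robust summary of control perpendicular distances."""

    gene_x: str  # regressor, lexicographically smaller id
    gene_y: str
    beta0: float
    beta1: float
    d_median: float
    d_mad: float

    @property
    def edge(self) -> tuple[str, str]:
        return (self.gene_x, self.gene_y)


def perpendicular_distance(beta0: float, beta1: float, x, y):
    """Orthogonal distance from points (x, y) to the line y = beta0 + beta1*x."""
    return np.abs(beta1 * np.asarray(x) - np.asarray(y) + beta0) / np.sqrt(
        beta1**2 + 1.0
    )


def fit_edge_model(expr: ExpressionMatrix, edge: tuple[str, str]) -> EdgeModel:
    """Fit one edge's OLS model and distance summary on control samples."""
    gx, gy = sorted(edge)
    x = expr.row(gx)
    y = expr.row(gy)
    if x.size < 3:
        raise ValueError("need at least 3 control samples")
    if np.var(x) == 0:
        raise ValueError(f"degenerate edge ({gx}, {gy}): zero-variance regressor")
    beta1, beta0 = np.polyfit(x, y, 1)
    d = perpendicular_distance(beta0, beta1, x, y)
    d_median = float(np.median(d))
    d_mad = float(np.median(np.abs(d - d_median)))
    return EdgeModel(gx, gy, float(beta0), float(beta1), d_median, d_mad)


def fit_all_edges(
    expr: ExpressionMatrix,
    network: TissueNetwork,
    max_degenerate_fraction: float = 0.1,
) -> dict[tuple[str, str], EdgeModel]:
    """Fit one EdgeModel per retained edge; drop degenerate edges.

    Degenerate edges (zero-variance regressor) are removed with a logged
    count; more than ``max_degenerate_fraction`` of them signals malformed
    input and raises.
    """
    missing = set()
    for a, b in network.edges:
        missing.update({a, b} - set(expr.gene_ids))
    if missing:
        raise ValueError(f"{len(missing)} network genes missing from expression matrix")
    idx = expr.gene_index()
    values = expr.values
    models: dict[tuple[str, str], EdgeModel] = {}
    n_degenerate = 0
    for (a, b) in sorted(network.edges):
        x, y = values[idx[a]], values[idx[b]]
        if np.var(x) == 0:
            n_degenerate += 1
            continue
        beta1, beta0 = np.polyfit(x, y, 1)
        d = perpendicular_distance(beta0, beta1, x, y)
        d_median = float(np.median(d))
        models[(a, b)] = EdgeModel(
            a, b, float(beta0), float(beta1),
            d_median, float(np.median(np.abs(d - d_median))),
        )
    n_edges = len(network.edges)
    if n_edges and n_degenerate / n_edges > max_degenerate_fraction:
        raise ValueError(
            f"{n_degenerate}/{n_edges} edges degenerate; input looks malformed"
        )
    if n_degenerate:
        logger.warning("dropped %d degenerate edge(s) from the model set", n_degenerate)
    return models


# ----------------------------------------------------------------------
def write_edge_models(models: dict[tuple[str, str], EdgeModel], path) -> None:
    rows = [
        (m.gene_x, m.gene_y, m.beta0, m.beta1, m.d_median, m.d_mad)
        for m in (models[e] for e in sorted(models))
    ]
    pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "beta0", "beta1", "d_median", "d_mad"]
    ).to_csv(path, sep="\t", index=False)


def read_edge_models(path) -> dict[tuple[str, str], EdgeModel]:
    df = pd.read_csv(path, sep="\t")
    out = {}
    for row in df.itertuples(index=False):
        m = EdgeModel(
            str(row.gene_a), str(row.gene_b),
            float(row.beta0), float(row.beta1),
            float(row.d_median), float(row.d_mad),
        )
        out[m.edge] = m
    return out
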