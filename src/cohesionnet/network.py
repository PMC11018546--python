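"""Normal-tissue reference network construction.

Implements the unsigned weighted co-expression pipeline: soft-thresholded
adjacency from absolute Pearson correlation, topological overlap matrix
(TOM) as edge-weight source, average-linkage hierarchical community
detection with a modularity-selected static cut, a permutation-based
community preservation filter on a held-out control split, and per-community
retention of the top-weight fraction of gene pairs.

Communities are treated as functional units throughout the downstream
scoring, so only intra-community edges are ever retained: cross-community
pairs never enter any score.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "TissueNetwork",
    "PreservationReport",
    "compute_adjacency",
    "pick_soft_power",
    "compute_tom",
    "detect_communities",
    "preservation_filter",
    "retain_top_edges",
    "split_controls",
]

UNASSIGNED = "unassigned"


# ----------------------------------------------------------------------
# containers
# ----------------------------------------------------------------------
@dataclass
class TissueNetwork:
    """Weighted undirected reference network with community assignments.

    Edges are unordered gene pairs stored with lexicographically sorted
    endpoints; all weights are in (0, 1] (TOM values), which guarantees
    positive inverse-weight path lengths.  Every edge is intra-community.
    """

    nodes: list[str]
    edges: dict[tuple[str, str], float]
    communities: dict[str, frozenset[str]]
    soft_power: int | None = None

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        comm_of: dict[str, str] = {}
        for label, genes in self.communities.items():
            if not genes <= node_set:
                raise ValueError(f"community {label!r} has genes outside the node set")
            for g in genes:
                if g in comm_of:
                    raise ValueError(f"gene {g!r} assigned to two communities")
                comm_of[g] = label
        for (a, b), w in self.edges.items():
            if a >= b:
                raise ValueError(f"edge {(a, b)} not in sorted order")
            if not (0.0 < w <= 1.0):
                raise ValueError(f"edge {(a, b)} weight {w} outside (0, 1]")
            if comm_of.get(a) is None or comm_of.get(a) != comm_of.get(b):
                raise ValueError(f"edge {(a, b)} is not intra-community")
        self._community_of = comm_of

    # ------------------------------------------------------------------
    @property
    def community_of(self) -> dict[str, str]:
        """Map gene -> community label (assigned genes only)."""
        return dict(self._community_of)

    def n_edges(self) -> int:
        return len(self.edges)

    def community_edges(self, label: str) -> dict[tuple[str, str], float]:
        genes = self.communities[label]
        return {e: w for e, w in self.edges.items() if e[0] in genes}

    def incident_edges(self, gene: str) -> dict[tuple[str, str], float]:
        return {e: w for e, w in self.edges.items() if gene in e}

    def strength(self, gene: str) -> float:
        """Normal-network connectivity: sum of incident edge weights."""
        return float(sum(self.incident_edges(gene).values()))

    def degree(self, gene: str) -> int:
        return len(self.incident_edges(gene))

    def remove_edges(self, removed) -> "TissueNetwork":
        """Return a network with the given edges deleted (nodes retained)."""
        removed = {tuple(sorted(e)) for e in removed}
        unknown = removed - set(self.edges)
        if unknown:
            raise ValueError(f"{len(unknown)} removed edges are not in the network")
        kept = {e: w for e, w in self.edges.items() if e not in removed}
        return TissueNetwork(list(self.nodes), kept, dict(self.communities), self.soft_power)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for n in self.nodes:
            g.add_node(n, community=self._community_of.get(n, UNASSIGNED))
        for (a, b), w in self.edges.items():
            g.add_edge(a, b, weight=w)
        return g

    # ------------------------------------------------------------------
    def write(self, edge_path, community_path) -> None:
        """Write a 3-column edge list TSV and a community-assignment TSV."""
        rows = [(a, b, w) for (a, b), w in sorted(self.edges.items())]
        pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight"]).to_csv(
            edge_path, sep="\t", index=False
        )
        assign = [
            (g, self._community_of.get(g, UNASSIGNED)) for g in sorted(self.nodes)
        ]
        pd.DataFrame(assign, columns=["gene", "community"]).to_csv(
            community_path, sep="\t", index=False
        )

    @classmethod
    def read(cls, edge_path, community_path, soft_power: int | None = None) -> "TissueNetwork":
        edges_df = pd.read_csv(edge_path, sep="\t")
        assign = pd.read_csv(community_path, sep="\t")
        communities: dict[str, set[str]] = {}
        for gene, label in zip(assign["gene"], assign["community"]):
            if label != UNASSIGNED:
                communities.setdefault(str(label), set()).add(str(gene))
        edges = {
            tuple(sorted((str(a), str(b)))): float(w)
            for a, b, w in zip(edges_df["gene_a"], edges_df["gene_b"], edges_df["weight"])
        }
        return cls(
            [str(g) for g in assign["gene"]],
            edges,
            {k: frozenset(v) for k, v in communities.items()},
            soft_power,
        )

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)


@dataclass
class PreservationReport:
    """Per-community preservation statistics from the permutation test.

    ``Zsummary`` averages the density z-score (mean intra-community TOM in
    the held-out split) and the connectivity-correlation z-score
    (train-vs-test correlation of intra-community connectivity); a
    community is kept when Zsummary exceeds the cutoff (default 10).
    """

    table: pd.DataFrame = field(repr=False)
    z_cutoff: float = 10.0

    @property
    def kept(self) -> list[str]:
        return list(self.table.loc[self.table["kept"], "community"])

    @property
    def dropped(self) -> list[str]:
        return list(self.table.loc[~self.table["kept"], "community"])

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------------
# adjacency / soft power / TOM
# ----------------------------------------------------------------------
def compute_adjacency(expr: ExpressionMatrix, power: int) -> np.ndarray:
    """Unsigned soft-threshold adjacency a_ij = |cor(x_i, x_j)|^power.

    Constant genes (zero variance) get correlation 0 against every partner,
    with a warning.  The diagonal is zero.
    """
    if power < 1:
        raise ValueError("power must be a positive integer")
    values = expr.values
    sd = values.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.warning(
            "%d constant gene(s); their correlations are set to 0", int(constant.sum())
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values)
    corr = np.nan_to_num(corr, nan=0.0)
    adj = np.abs(corr) ** power
    np.fill_diagonal(adj, 0.0)
    return np.clip(adj, 0.0, 1.0)


def scale_free_fit(adjacency: np.ndarray, n_bins: int = 10) -> float:
    """Signed R-squared of the scale-free topology fit.

    Bins node connectivity k_i = sum_j a_ij, regresses log10 frequency on
    log10 mean connectivity per occupied bin, and signs the R-squared by
    the negated slope so that a decreasing (scale-free-like) degree
    distribution yields a positive index.
    """
    k = adjacency.sum(axis=1)
    k = k[k > 0]
    if k.size < 2:
        raise ValueError("degenerate connectivity distribution")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    freq = np.bincount(which, minlength=n_bins).astype(float)
    occupied = freq > 0
    if occupied.sum() < 2:
        raise ValueError("degenerate connectivity distribution")
    mean_k = np.array(
        [k[which == b].mean() if occupied[b] else np.nan for b in range(n_bins)]
    )
    x = np.log10(mean_k[occupied])
    y = np.log10(freq[occupied] / freq.sum())
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(-np.sign(slope) * r2)


def pick_soft_power(
    expr: ExpressionMatrix,
    candidate_powers=tuple(range(1, 21)),
    r2_cutoff: float = 0.8,
) -> int:
    """Smallest power whose scale-free-topology fit reaches ``r2_cutoff``.

    Falls back to the argmax-fit power (with a warning) when no candidate
    reaches the cutoff.
    """
    powers = list(candidate_powers)
    if not powers:
        raise ValueError("candidate_powers must be nonempty")
    if sorted(powers) != powers:
        raise ValueError("candidate_powers must be sorted ascending")
    fits = []
    for p in powers:
        fit = scale_free_fit(compute_adjacency(expr, p))
        fits.append(fit)
        if fit >= r2_cutoff:
            return int(p)
    best = int(powers[int(np.argmax(fits))])
    logger.warning(
        "no candidate power reached fit %.2f; falling back to power %d (fit %.3f)",
        r2_cutoff,
        best,
        max(fits),
    )
    return best


def compute_tom(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    k_i = sum_u a_iu; the diagonal is 1.  Entries stay in [0, 1] for any
    adjacency with entries in [0, 1] and zero diagonal.
    """
    a = np.asarray(adjacency, dtype=float)
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T):
        raise ValueError("adjacency must be square and symmetric")
    if np.any(np.diag(a) != 0):
        raise ValueError("adjacency must have a zero diagonal")
    shared = a @ a  # zero diagonal makes u=i and u=j terms vanish
    k = a.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


# ----------------------------------------------------------------------
# community detection
# ----------------------------------------------------------------------
def _weighted_modularity(tom: np.ndarray, labels: np.ndarray) -> float:
    """Newman modularity of a partition on the complete TOM-weighted graph."""
    w = tom.copy()
    np.fill_diagonal(w, 0.0)
    total = w.sum()  # 2 * total edge weight
    if total == 0:
        return 0.0
    strength = w.sum(axis=1)
    q = 0.0
    for lab in np.unique(labels):
        mask = labels == lab
        q += w[np.ix_(mask, mask)].sum() / total - (strength[mask].sum() / total) ** 2
    return float(q)


def detect_communities(
    tom: np.ndarray,
    gene_ids: list[str],
    min_size: int = 30,
    max_cut_candidates: int = 50,
) -> dict[str, str]:
    """Average-linkage clustering on 1 - TOM with a modularity-picked cut.

    The dendrogram is cut at the static height (among candidate merge
    heights) maximizing weighted modularity of the induced partition;
    clusters smaller than ``min_size`` are relabelled ``unassigned``.
    Returns a map gene -> community label; labels are ``C1``, ``C2``, ...
    in decreasing community size.
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    n = tom.shape[0]
    if n != len(gene_ids):
        raise ValueError("gene_ids length does not match the TOM")
    diss = 1.0 - tom
    np.fill_diagonal(diss, 0.0)
    diss = np.clip((diss + diss.T) / 2.0, 0.0, None)
    z = linkage(squareform(diss, checks=False), method="average")
    merge_heights = np.unique(z[:, 2])
    if merge_heights.size > max_cut_candidates:
        idx = np.linspace(0, merge_heights.size - 1, max_cut_candidates).astype(int)
        merge_heights = merge_heights[idx]
    eps = 1e-12
    best_labels, best_q = None, -np.inf
    for h in merge_heights:
        labels = fcluster(z, t=h + eps, criterion="distance")
        if labels.max() == 1:
            continue  # single cluster carries no modularity signal
        q = _weighted_modularity(tom, labels)
        if q > best_q:
            best_q, best_labels = q, labels
    if best_labels is None:
        logger.warning("all genes merge into one cluster at every cut height")
        best_labels = np.ones(n, dtype=int)

    clusters: dict[int, list[str]] = {}
    for gene, lab in zip(gene_ids, best_labels):
        clusters.setdefault(int(lab), []).append(gene)
    sized = [c for c in clusters.values() if len(c) >= min_size]
    sized.sort(key=lambda c: (-len(c), min(c)))
    assignment = {g: UNASSIGNED for g in gene_ids}
    for i, genes in enumerate(sized, start=1):
        for g in genes:
            assignment[g] = f"C{i}"
    if not sized:
        logger.warning("no cluster reached min_size=%d; all genes unassigned", min_size)
    return assignment


def communities_from_assignment(assignment: dict[str, str]) -> dict[str, frozenset[str]]:
    """Group an assignment map into label -> gene set, dropping unassigned."""
    out: dict[str, set[str]] = {}
    for gene, label in assignment.items():
        if label != UNASSIGNED:
            out.setdefault(label, set()).add(gene)
    return {k: frozenset(v) for k, v in out.items()}


# ----------------------------------------------------------------------
# preservation filter
# ----------------------------------------------------------------------
def _community_stats(
    tom_train: np.ndarray, tom_test: np.ndarray, idx: np.ndarray
) -> tuple[float, float]:
    """(test density, train/test intra-community connectivity correlation)."""
    sub_test = tom_test[np.ix_(idx, idx)]
    sub_train = tom_train[np.ix_(idx, idx)]
    m = idx.size
    off = ~np.eye(m, dtype=bool)
    density = float(sub_test[off].mean())
    k_train = sub_train.sum(axis=1) - 1.0  # remove unit diagonal
    k_test = sub_test.sum(axis=1) - 1.0
    if k_train.std() == 0 or k_test.std() == 0:
        corr = 0.0
    else:
        corr = float(np.corrcoef(k_train, k_test)[0, 1])
    return density, corr


def _perm_z(observed: float, null: np.ndarray) -> float:
    mean, sd = float(null.mean()), float(null.std(ddof=1))
    if sd == 0:
        logger.warning("zero permutation spread; z set to +/-inf")
        return math.inf if observed > mean else -math.inf
    return (observed - mean) / sd


def preservation_filter(
    tom_train: np.ndarray,
    tom_test: np.ndarray,
    gene_ids: list[str],
    communities: dict[str, frozenset[str]],
    n_permutations: int = 200,
    z_cutoff: float = 10.0,
    seed: int = 17,
) -> PreservationReport:
    """Permutation preservation test of each community in the held-out split.

    For each community, the observed test-split TOM density and the
    train/test connectivity correlation are compared to their null
    distributions over random gene sets of the same size; the two z-scores
    are averaged into Zsummary and the community is kept iff
    Zsummary > ``z_cutoff``.
    """
    if tom_train.shape != tom_test.shape:
        raise ValueError("train and test TOM must cover the same gene universe")
    if n_permutations < 50:
        raise ValueError("need at least 50 permutations")
    rng = np.random.default_rng(seed)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    n = len(gene_ids)
    rows = []
    for label in sorted(communities):
        genes = sorted(communities[label])
        idx = np.array([gene_pos[g] for g in genes])
        obs_density, obs_corr = _community_stats(tom_train, tom_test, idx)
        null_density = np.empty(n_permutations)
        null_corr = np.empty(n_permutations)
        for p in range(n_permutations):
            perm = rng.choice(n, size=idx.size, replace=False)
            null_density[p], null_corr[p] = _community_stats(tom_train, tom_test, perm)
        z_density = _perm_z(obs_density, null_density)
        z_corr = _perm_z(obs_corr, null_corr)
        zsummary = (z_density + z_corr) / 2.0
        rows.append(
            {
                "community": label,
                "size": len(genes),
                "density_obs": obs_density,
                "density_perm_mean": float(null_density.mean()),
                "density_perm_sd": float(null_density.std(ddof=1)),
                "z_density": z_density,
                "conn_cor_obs": obs_corr,
                "conn_cor_perm_mean": float(null_corr.mean()),
                "conn_cor_perm_sd": float(null_corr.std(ddof=1)),
                "z_conn_cor": z_corr,
                "zsummary": zsummary,
                "kept": bool(zsummary > z_cutoff),
            }
        )
    return PreservationReport(pd.DataFrame(rows), z_cutoff=z_cutoff)


# ----------------------------------------------------------------------
# edge retention
# ----------------------------------------------------------------------
def retain_top_edges(
    tom: np.ndarray,
    gene_ids: list[str],
    communities: dict[str, frozenset[str]],
    fraction: float = 0.1,
    soft_power: int | None = None,
) -> TissueNetwork:
    """Keep the top-weight fraction of intra-community pairs per community.

    Each community contributes exactly ceil(fraction * C(n_k, 2)) edges
    (its highest-TOM pairs); boundary ties break by lexicographic gene-pair
    order so builds are deterministic.  Genes outside any community are
    retained as isolated nodes.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    edges: dict[tuple[str, str], float] = {}
    for label in sorted(communities):
        genes = sorted(communities[label])
        if len(genes) < 2:
            logger.warning("community %s has <2 genes; no edges retained", label)
            continue
        pairs = [
            (genes[i], genes[j])
            for i in range(len(genes))
            for j in range(i + 1, len(genes))
        ]
        weighted = [(tom[gene_pos[a], gene_pos[b]], a, b) for a, b in pairs]
        weighted.sort(key=lambda t: (-t[0], t[1], t[2]))
        n_keep = math.ceil(fraction * len(pairs))
        for w, a, b in weighted[:n_keep]:
            if w <= 0:
                logger.warning("skipping zero-weight pair (%s, %s)", a, b)
                continue
            edges[(a, b)] = float(w)
    return TissueNetwork(list(gene_ids), edges, dict(communities), soft_power)


# ----------------------------------------------------------------------
# train/test split
# ----------------------------------------------------------------------
def split_controls(
    expr: ExpressionMatrix, test_fraction: float = 0.2, seed: int = 17
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Seeded random split of control columns into train and test sets."""
    if not (0.0 < test_fraction < 1.0):
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n = expr.n_samples
    n_test = max(1, int(round(test_fraction * n)))
    if n - n_test < 3 or n_test < 3:
        raise ValueError("too few samples for an informative split")
    perm = rng.permutation(n)
    test_cols = sorted(perm[:n_test])
    train_cols = sorted(perm[n_test:])
    samples = expr.sample_ids
    return (
        expr.subset_samples([samples[i] for i in train_cols]),
        expr.subset_samples([samples[i] for i in test_cols]),
    )
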