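"""Outcome-guided mutual-information networks and graph-Laplacian penalties.

The network-construction pipeline is:

1. ``complete_mi_network`` -- score every unordered gene pair (g_i, g_j)
   by I(g_i, g_j; Y), the mutual information between the pair and the
   binarized survival outcome Y, producing a complete weighted graph.
2. ``permutation_threshold`` -- permute the outcome labels repeatedly,
   recompute all pair scores, average per pair across permutations and
   take theta = the maximum of these per-pair means. theta is the base
   significance cutoff: no pair should beat what the most optimistic pair
   achieves on label-scrambled data.
3. ``filter_network`` -- keep edges with weight >= theta * (1 + sigma);
   sigma >= 0 tightens the cutoff beyond the permutation baseline.

The filtered graph G_sigma enters the Cox penalty through the normalized
adjacency S = R^(-1/2) G_sigma C^(-1/2) and Gamma = (1 - alpha) (I - S)
+ alpha I, built by ``build_penalty``. A co-expression comparator network
(absolute Pearson correlation) is provided for benchmarking.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .data import SurvivalData, validate_expression
from .information import BinaryOutcome, binarize_outcome, discretize

__all__ = [
    "MINetwork",
    "PenaltyMatrix",
    "complete_mi_network",
    "permutation_threshold",
    "filter_network",
    "coexpression_network",
    "build_penalty",
    "network_stats",
    "pairwise_pair_outcome_mi",
    "OutcomeGuidedMINetwork",
]


@dataclass(frozen=True)
class MINetwork:
    """An undirected weighted gene network with its threshold metadata.

    ``edges`` maps unordered gene pairs (stored in ``genes``-list order,
    first index < second) to weights -- MI in bits for outcome-guided
    networks, |Pearson r| for co-expression networks.
    """

    genes: tuple
    edges: dict
    theta: float = 0.0
    sigma: float = 0.0
    complete: bool = False
    kind: str = "mi"

    def __post_init__(self) -> None:
        for (a, b) in self.edges:
            if a == b:
                raise ValueError(f"self-loop on gene {a!r}")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def weights(self) -> np.ndarray:
        return np.fromiter(self.edges.values(), dtype=float, count=len(self.edges))

    def adjacency(self, weighted: bool = False) -> np.ndarray:
        """Dense symmetric adjacency over the full gene list."""
        pos = {g: i for i, g in enumerate(self.genes)}
        A = np.zeros((self.n_genes, self.n_genes))
        for (a, b), w in self.edges.items():
            i, j = pos[a], pos[b]
            A[i, j] = A[j, i] = w if weighted else 1.0
        return A

    def to_frame(self) -> pd.DataFrame:
        """Edge list as a DataFrame, gene_a < gene_b lexicographically."""
        rows = [
            (min(a, b), max(a, b), w) for (a, b), w in self.edges.items()
        ]
        rows.sort()
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight"])

    def degrees(self) -> dict:
        deg: dict = {g: 0 for g in self.genes}
        for (a, b) in self.edges:
            deg[a] += 1
            deg[b] += 1
        return deg

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.genes)
        g.add_weighted_edges_from((a, b, w) for (a, b), w in self.edges.items())
        return g


@dataclass(frozen=True)
class PenaltyMatrix:
    """The quadratic-form penalty matrices of network-regularized Cox.

    S is the degree-normalized adjacency R^(-1/2) A C^(-1/2) (rows and
    columns of isolated genes are zero), L = I - S, and
    Gamma = (1 - alpha) L + alpha I. For a symmetric adjacency the penalty
    beta' Gamma beta decomposes as alpha * ||beta||^2 plus a Laplacian
    smoothness term (1 - alpha) * [sum_i beta_i^2 - sum_ij S_ij beta_i
    beta_j] that shrinks differences between connected genes.
    """

    S: np.ndarray
    L: np.ndarray
    Gamma: np.ndarray
    alpha: float
    row_sums: np.ndarray
    col_sums: np.ndarray
    genes: tuple = field(default=())

    def quad_form(self, beta: np.ndarray) -> float:
        beta = np.asarray(beta, dtype=float)
        return float(beta @ self.Gamma @ beta)


# ---------------------------------------------------------------------------
# pairwise pair-vs-outcome mutual information
# ---------------------------------------------------------------------------

def _discretize_matrix(expr: pd.DataFrame, n_bins: int) -> np.ndarray:
    codes = np.empty(expr.shape, dtype=np.int64)
    for j, g in enumerate(expr.columns):
        codes[:, j] = discretize(expr[g].to_numpy(), n_bins).codes
    return codes


def _entropy_rows(counts: np.ndarray, n: int) -> np.ndarray:
    # counts: (m, K) nonnegative ints summing to n per row; rows sorted so
    # the float sum is exactly invariant to cell relabeling (matches the
    # scalar entropy path)
    p = np.sort(counts, axis=1) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p), 0.0)
    return -terms.sum(axis=1)


def pairwise_pair_outcome_mi(codes: np.ndarray, y: np.ndarray, n_bins: int) -> np.ndarray:
    """I(g_i, g_j; Y) for every unordered gene pair, as a condensed vector.

    ``codes`` is the (n_samples, p) integer matrix of discretized gene
    values (each code < ``n_bins``), ``y`` a binary label vector. Returns
    the upper-triangular (i < j, row-major) vector of MI values in bits.

    Pairs are processed in per-gene blocks; the total cost is
    O(p^2 * n) scatter operations plus O(p^2 * B^2) table work.
    """
    n, p = codes.shape
    y = np.asarray(y, dtype=np.int64)
    if y.size != n:
        raise ValueError("y must align with the rows of codes")
    ny = int(y.max()) + 1 if y.size else 1
    B = int(n_bins)
    K = B * B * ny
    hy = _entropy_rows(np.bincount(y, minlength=ny)[None, :], n)[0]
    out = np.empty(p * (p - 1) // 2, dtype=float)
    offset = 0
    for i in range(p - 1):
        m = p - 1 - i
        pair = codes[:, i][:, None] * B + codes[:, i + 1 :]  # (n, m)
        flat = (pair * ny + y[:, None]) + np.arange(m)[None, :] * K
        joint = np.bincount(flat.ravel(), minlength=m * K).reshape(m, K)
        h_joint = _entropy_rows(joint, n)
        h_pair = _entropy_rows(joint.reshape(m, B * B, ny).sum(axis=2), n)
        out[offset : offset + m] = np.maximum(h_pair + hy - h_joint, 0.0)
        offset += m
    return out


def _condensed_pairs(genes) -> list:
    return [(genes[i], genes[j]) for i in range(len(genes) - 1) for j in range(i + 1, len(genes))]


def _resolve_outcome(expr: pd.DataFrame, outcome) -> BinaryOutcome:
    if isinstance(outcome, BinaryOutcome):
        return outcome
    if isinstance(outcome, SurvivalData):
        return binarize_outcome(outcome)
    labels = np.asarray(outcome, dtype=np.int64)
    return BinaryOutcome(
        labels=labels, threshold_months=np.nan, kept_mask=np.ones(labels.size, dtype=bool)
    )


def _kept_codes(expr: pd.DataFrame, outcome: BinaryOutcome, n_bins: int):
    expr = validate_expression(expr)
    if outcome.kept_mask.size != expr.shape[0]:
        raise ValueError("outcome and expression matrix are not aligned")
    kept = expr.loc[outcome.kept_mask.astype(bool)]
    y = outcome.labels[outcome.kept_mask]
    codes = _discretize_matrix(kept, n_bins)
    return codes, y


def complete_mi_network(expr: pd.DataFrame, outcome, n_bins: int = 3) -> MINetwork:
    """Score every gene pair by I(g_i, g_j; Y) -> complete weighted network.

    ``outcome`` may be a :class:`BinaryOutcome`, a :class:`SurvivalData`
    (binarized at the default 36-month threshold), or a raw label vector.
    """
    out = _resolve_outcome(expr, outcome)
    if expr.shape[1] < 2:
        raise ValueError("need at least 2 genes")
    codes, y = _kept_codes(expr, out, n_bins)
    if codes.shape[0] < 4:
        raise ValueError("need at least 4 kept samples")
    if np.unique(y).size < 2:
        raise ValueError("outcome labels are all identical; MI is degenerate")
    mi = pairwise_pair_outcome_mi(codes, y, n_bins)
    genes = tuple(expr.columns)
    edges = dict(zip(_condensed_pairs(genes), mi.tolist()))
    return MINetwork(genes=genes, edges=edges, theta=0.0, sigma=0.0, complete=True)


def permutation_threshold(
    expr: pd.DataFrame,
    outcome,
    n_bins: int = 3,
    n_perm: int = 100,
    seed=None,
) -> float:
    """Permutation-derived base cutoff theta for MI edges.

    For each of ``n_perm`` uniformly random permutations of the outcome
    labels, all pair scores I(g_i, g_j; Y_perm) are recomputed; each pair's
    scores are averaged over permutations, and theta is the maximum of
    these per-pair means.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    out = _resolve_outcome(expr, outcome)
    codes, y = _kept_codes(expr, out, n_bins)
    rng = np.random.default_rng(seed)
    p = codes.shape[1]
    sums = np.zeros(p * (p - 1) // 2)
    for _ in range(n_perm):
        sums += pairwise_pair_outcome_mi(codes, rng.permutation(y), n_bins)
    return float((sums / n_perm).max())


def filter_network(net: MINetwork, theta: float, sigma: float = 0.0) -> MINetwork:
    """Keep edges with weight >= theta * (1 + sigma).

    Ties at the cutoff are kept (>= comparison). The returned network
    records theta and sigma; the edge count is non-increasing in sigma.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if theta < 0:
        raise ValueError("theta must be >= 0")
    cutoff = theta * (1.0 + sigma)
    edges = {pair: w for pair, w in net.edges.items() if w >= cutoff}
    return replace(net, edges=edges, theta=float(theta), sigma=float(sigma), complete=False)


def coexpression_network(expr: pd.DataFrame, cutoff: float = 0.0) -> MINetwork:
    """Co-expression comparator: edge weight = |Pearson correlation|.

    Edges below ``cutoff`` are dropped; constant genes (undefined
    correlation) get no edges.
    """
    expr = validate_expression(expr)
    if expr.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if not (0.0 <= cutoff <= 1.0):
        raise ValueError("cutoff must lie in [0, 1]")
    X = expr.to_numpy()
    sd = X.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(X, rowvar=False)
    genes = tuple(expr.columns)
    edges = {}
    p = len(genes)
    for i in range(p - 1):
        for j in range(i + 1, p):
            if sd[i] == 0 or sd[j] == 0:
                continue
            w = abs(C[i, j])
            if w >= cutoff:
                edges[(genes[i], genes[j])] = float(w)
    return MINetwork(genes=genes, edges=edges, theta=float(cutoff), sigma=0.0, kind="coexpression")


def build_penalty(net: MINetwork, alpha: float, weighted: bool = False) -> PenaltyMatrix:
    """Normalized-adjacency penalty matrices S, L = I - S, Gamma.

    The adjacency entering S is binary by default (an edge either survived
    filtering or it did not); set ``weighted=True`` to carry the MI edge
    weights instead. Isolated genes get a zero row/column in S, so their
    penalty degenerates to plain ridge. For alpha in (0, 1], Gamma is
    symmetric positive definite with eigenvalues >= alpha.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha must lie in (0, 1], got {alpha}")
    A = net.adjacency(weighted=weighted)
    r = A.sum(axis=1)
    c = A.sum(axis=0)
    with np.errstate(divide="ignore"):
        r_inv = np.where(r > 0, 1.0 / np.sqrt(np.where(r > 0, r, 1.0)), 0.0)
        c_inv = np.where(c > 0, 1.0 / np.sqrt(np.where(c > 0, c, 1.0)), 0.0)
    S = r_inv[:, None] * A * c_inv[None, :]
    p = A.shape[0]
    L = np.eye(p) - S
    Gamma = (1.0 - alpha) * L + alpha * np.eye(p)
    return PenaltyMatrix(
        S=S, L=L, Gamma=Gamma, alpha=float(alpha), row_sums=r, col_sums=c, genes=net.genes
    )


def network_stats(net: MINetwork) -> dict:
    """Basic topology summary over genes incident to at least one edge."""
    if net.n_edges == 0:
        return {
            "n_nodes": 0,
            "n_edges": 0,
            "n_components": 0,
            "density": 0.0,
            "average_neighbors": 0.0,
        }
    g = net.to_networkx()
    g.remove_nodes_from([v for v in g.nodes if g.degree(v) == 0])
    n = g.number_of_nodes()
    m = g.number_of_edges()
    return {
        "n_nodes": n,
        "n_edges": m,
        "n_components": nx.number_connected_components(g),
        "density": nx.density(g),
        "average_neighbors": 2.0 * m / n,
    }


class OutcomeGuidedMINetwork(BaseEstimator):
    """Estimator interface for the outcome-guided MI network pipeline.

    ``fit(X, y)`` binarizes the survival outcome, scores every gene pair
    by I(g_i, g_j; Y), derives the permutation cutoff theta, and stores the
    network filtered at ``sigma``. The complete network and theta are kept
    so other sigma values can be re-applied without repeating the
    permutation work (:meth:`filtered`).

    Parameters
    ----------
    n_bins : int
        Histogram bins for per-gene discretization.
    threshold_months : float
        Long/short-term survival cut used to binarize the outcome.
    n_perm : int
        Number of label permutations behind theta.
    sigma : float or None
        Significance amplification; edges need weight >= theta*(1+sigma).
        ``None`` keeps the complete (unfiltered) network.
    random_state : int or None
        Seed for the permutation draws.

    Attributes
    ----------
    complete_network_ : MINetwork
        The all-pairs weighted network.
    theta_ : float
        Permutation base threshold.
    network_ : MINetwork
        Filtered network at ``sigma`` (the complete one when sigma=None).
    """

    def __init__(
        self,
        n_bins: int = 3,
        threshold_months: float = 36.0,
        n_perm: int = 100,
        sigma: float | None = 0.0,
        random_state=None,
    ):
        self.n_bins = n_bins
        self.threshold_months = threshold_months
        self.n_perm = n_perm
        self.sigma = sigma
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y):
        if isinstance(y, SurvivalData):
            outcome = binarize_outcome(y, self.threshold_months)
        else:
            outcome = _resolve_outcome(X, y)
        self.outcome_ = outcome
        self.complete_network_ = complete_mi_network(X, outcome, self.n_bins)
        self.theta_ = permutation_threshold(
            X, outcome, self.n_bins, self.n_perm, self.random_state
        )
        self.network_ = self.filtered(self.sigma)
        return self

    def filtered(self, sigma: float | None) -> MINetwork:
        """Re-filter the fitted complete network at another sigma."""
        if not hasattr(self, "complete_network_"):
            raise AttributeError("estimator is not fitted")
        if sigma is None:
            return self.complete_network_
        return filter_network(self.complete_network_, self.theta_, sigma)
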