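"""SparCC co-occurrence inference and the centrality-difference keystone screen.

SparCC estimates "basis" (absolute-abundance) correlations from compositional
count data.  For each pair of taxa the log-ratio variance

    t_ij = var(log x_i - log x_j) = w_i^2 + w_j^2 - 2 r_ij w_i w_j

links observed fractions to basis variances w^2 and correlations r.  Under
the sparsity assumption (most r_ij ~ 0) the basis variances solve a linear
system in the row sums of T; pairs that come out strongly correlated are
iteratively excluded from that system and the variances re-solved, so a few
strong correlations do not bias the rest.  The whole procedure is repeated
over outer iterations with fractions resampled from the per-sample Dirichlet
posterior of the counts, and the final correlation matrix is the
element-wise median over iterations.

Networks keep taxa with total abundance strictly > 10 as nodes and pairs with
|r| >= 0.3 as signed weighted edges; communities come from Louvain modularity
maximization on |r|-weighted edges.  Keystone candidates are flagged by
differencing each node's normalized degree centrality (degree/(n-1), on the
node's own network) between the control and case networks and marking Tukey
1.5 x IQR outliers of the delta distribution.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .otu_processing import OtuTable

logger = logging.getLogger(__name__)

__all__ = [
    "CooccurrenceNetwork",
    "sparcc_correlations",
    "build_cooccurrence_network",
    "louvain_partition",
    "representative_species",
    "centrality_difference",
]


@dataclass
class CooccurrenceNetwork:
    graph: nx.Graph
    community: dict | None = field(default=None)
    modularity: float | None = field(default=None)

    @property
    def degree_centrality(self) -> dict:
        return nx.degree_centrality(self.graph)

    def edge_list(self) -> pd.DataFrame:
        rows = [
            {"source": u, "target": v, "weight": d["weight"],
             "sign": "positive" if d["weight"] > 0 else "negative",
             "strength": abs(d["weight"])}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "weight", "sign", "strength"])

    def to_graphml(self, path) -> None:
        g = self.graph.copy()
        if self.community is not None:
            nx.set_node_attributes(g, self.community, "community")
        nx.write_graphml(g, path)


def _basis_variances(t: np.ndarray, allowed: np.ndarray) -> np.ndarray:
    """Solve the sparse-approximation linear system for basis variances.

    t : pairwise log-ratio variance matrix; allowed : boolean mask of pairs
    still included in the variance system (diagonal False).
    """
    d = t.shape[0]
    m = allowed.astype(float)
    np.fill_diagonal(m, allowed.sum(axis=1))
    rhs = (t * allowed).sum(axis=1)
    try:
        w2 = np.linalg.solve(m, rhs)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"singular basis-variance system (excluded too many pairs): {exc}"
        ) from exc
    return np.clip(w2, 1e-12, None)


def _sparcc_once(frac: np.ndarray, exclusion_threshold: float,
                 max_exclusion_rounds: int) -> np.ndarray:
    """One SparCC pass on a fractions matrix (taxa x samples)."""
    logf = np.log(frac)
    v = np.cov(logf)
    diag = np.diag(v)
    t = diag[:, None] + diag[None, :] - 2 * v
    d = t.shape[0]
    allowed = ~np.eye(d, dtype=bool)
    for _ in range(max_exclusion_rounds + 1):
        w2 = _basis_variances(t, allowed)
        w = np.sqrt(w2)
        rho = (w2[:, None] + w2[None, :] - t) / (2 * np.outer(w, w))
        rho = np.clip(rho, -1.0, 1.0)
        np.fill_diagonal(rho, 1.0)
        # exclude the strongest remaining pair if it exceeds the threshold
        masked = np.where(allowed, np.abs(rho), 0.0)
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        if masked[i, j] <= exclusion_threshold:
            break
        if allowed[i].sum() <= 2 or allowed[j].sum() <= 2:
            break
        allowed[i, j] = allowed[j, i] = False
    return rho


def sparcc_correlations(
    counts: OtuTable | pd.DataFrame,
    outer_iterations: int = 20,
    exclusion_threshold: float = 0.1,
    max_exclusion_rounds: int = 10,
    seed: int | None = None,
) -> pd.DataFrame:
    """Iterative SparCC basis-correlation estimate (taxa x taxa).

    The first pass uses the pseudocount point estimate of fractions,
    (count + 1) / (total + n_taxa); subsequent passes resample fractions from
    Dirichlet(counts + 1) per sample.  The returned matrix is the element-wise
    median over all passes, symmetric with unit diagonal, clipped to [-1, 1].
    """
    if isinstance(counts, OtuTable):
        counts = counts.counts
    x = counts.to_numpy(dtype=float)
    d, n = x.shape
    if d < 4:
        raise ValueError("SparCC needs >= 4 taxa (basis-variance system)")
    if n < 3:
        raise ValueError("SparCC needs >= 3 samples")
    # per-sample RNG streams keyed by column content, so the estimate is
    # invariant to sample (column) reordering
    col_keys = [
        int.from_bytes(hashlib.sha256(x[:, s].tobytes()).digest()[:4], "little")
        for s in range(n)
    ]
    mats = []
    for it in range(outer_iterations):
        if it == 0:
            frac = (x + 1.0) / (x.sum(axis=0) + d)
        else:
            frac = np.column_stack(
                [
                    np.random.default_rng([seed or 0, it, col_keys[s]])
                    .dirichlet(x[:, s] + 1.0)
                    for s in range(n)
                ]
            )
            frac = np.clip(frac, 1e-12, None)
        mats.append(_sparcc_once(frac, exclusion_threshold, max_exclusion_rounds))
    rho = np.median(np.stack(mats), axis=0)
    rho = np.clip((rho + rho.T) / 2, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=counts.index, columns=counts.index)


def build_cooccurrence_network(
    corr: pd.DataFrame,
    table: OtuTable | pd.DataFrame,
    node_min_total: int = 10,
    edge_threshold: float = 0.3,
) -> CooccurrenceNetwork:
    """Signed co-occurrence graph from a correlation matrix.

    Nodes: taxa with total abundance strictly > node_min_total.  Edges: pairs
    with |r| >= edge_threshold; edge weight is the signed correlation and
    strength its magnitude.
    """
    if not np.allclose(corr.values, corr.values.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    counts = table.counts if isinstance(table, OtuTable) else table
    totals = counts.sum(axis=1)
    nodes = [t for t in corr.index if t in totals.index and totals[t] > node_min_total]
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for a_i, a in enumerate(nodes):
        for b in nodes[a_i + 1:]:
            r = float(corr.loc[a, b])
            if abs(r) >= edge_threshold:
                g.add_edge(a, b, weight=r, abs_weight=abs(r))
    return CooccurrenceNetwork(graph=g)


def louvain_partition(
    network: CooccurrenceNetwork, resolution: float = 1.0, seed: int = 0
) -> tuple[dict, float]:
    """Louvain communities on the |weight|-weighted graph; returns (map, Q)."""
    g = network.graph
    if g.number_of_edges() == 0:
        raise ValueError("modularity undefined on an edgeless network")
    comms = nx.community.louvain_communities(
        g, weight="abs_weight", resolution=resolution, seed=seed
    )
    comms = sorted((sorted(c) for c in comms), key=lambda c: c[0])
    mapping = {node: i for i, c in enumerate(comms) for node in c}
    q = nx.community.modularity(g, comms, weight="abs_weight", resolution=resolution)
    network.community = mapping
    network.modularity = float(q)
    return mapping, float(q)


def representative_species(network: CooccurrenceNetwork, top_k: int = 20) -> dict:
    """Per community, its max-degree node iff globally in the top_k by degree.

    Mirrors the labeling rule: within each Louvain community the taxon with
    the highest degree centrality represents the community only if it ranks
    among the global top-k; degree ties break to the lexicographically
    smaller name.
    """
    if network.community is None:
        raise ValueError("assign communities first (louvain_partition)")
    dc = network.degree_centrality
    ranked = sorted(dc, key=lambda t: (-dc[t], str(t)))
    top = set(ranked[:top_k])
    out = {}
    for comm in sorted(set(network.community.values())):
        members = [t for t, c in network.community.items() if c == comm]
        best = min(members, key=lambda t: (-dc[t], str(t)))
        out[comm] = best if best in top else None
    return out


def centrality_difference(
    network_control: CooccurrenceNetwork,
    network_case: CooccurrenceNetwork,
    iqr_factor: float = 1.5,
) -> pd.DataFrame:
    """Normalized degree-centrality difference (control - case) with outliers.

    Positive delta = more influential in the control network.  Nodes absent
    from one network contribute centrality 0 there.  Outliers are flagged by
    Tukey fences at iqr_factor x IQR of the delta distribution.
    """
    if (network_control.graph.number_of_nodes() == 0
            and network_case.graph.number_of_nodes() == 0):
        raise ValueError("both networks are empty")
    dc_c = network_control.degree_centrality
    dc_d = network_case.degree_centrality
    taxa = sorted(set(dc_c) | set(dc_d), key=str)
    out = pd.DataFrame(
        {
            "centrality_control": [dc_c.get(t, 0.0) for t in taxa],
            "centrality_case": [dc_d.get(t, 0.0) for t in taxa],
        },
        index=pd.Index(taxa, name="taxon"),
    )
    out["delta"] = out["centrality_control"] - out["centrality_case"]
    q1, q3 = np.percentile(out["delta"], [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - iqr_factor * iqr, q3 + iqr_factor * iqr
    out["outlier"] = (out["delta"] < lo) | (out["delta"] > hi)
    return out
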