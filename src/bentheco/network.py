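"""Compositionality-robust co-occurrence networks.

SparCC estimates OTU-OTU correlations from relative-abundance data by
working with log-ratio variances ``t_ij = var(log(x_i / x_j))``, which are
invariant to each sample's total.  Under a sparsity assumption (most pairs
uncorrelated) the basis variances ``w_i^2`` solve the linear system
``sum_j t_ij = (d - 2) w_i^2 + sum_j w_j^2`` and correlations follow from
``r_ij = (w_i^2 + w_j^2 - t_ij) / (2 w_i w_j)``.  Strongly correlated pairs
violate the assumption, so the most correlated pair above an exclusion
threshold is removed from the system and the basis re-solved, for a fixed
number of rounds.  Fractions are integrated over Dirichlet posterior draws
(unit pseudocount), and significance comes from a permutation null with
Benjamini-Hochberg FDR control before thresholding edges at |r| > 0.4 and
adjusted p < 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._util import logger
from .data_model import OtuTable, TaxonomyTable

__all__ = [
    "filter_min_count",
    "sparcc",
    "bootstrap_pvalues",
    "fdr_bh",
    "build_network",
    "topology_metrics",
    "edge_sign_summary",
    "CorrelationMatrix",
]


@dataclass
class CorrelationMatrix:
    """Symmetric OTU correlation estimates, optionally with p-values."""

    otu_ids: list[str]
    r: np.ndarray = field(repr=False)
    p: np.ndarray | None = field(repr=False, default=None)


def filter_min_count(table: OtuTable, min_total: int = 20) -> OtuTable:
    """Keep OTUs with total count strictly greater than ``min_total``.

    Mirrors the pre-network prevalence filter (OTUs represented by more
    than 20 reads are retained).  Sample set is unchanged.
    """
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    totals = table.otu_totals()
    keep = [o for o, t in zip(table.otu_ids, totals) if t > min_total]
    if not keep:
        raise ValueError(
            f"no OTU exceeds {min_total} total reads; lower the threshold"
        )
    return table.select_otus(keep)


def _basis_correlations(
    log_frac: np.ndarray, n_iterations: int, exclusion_threshold: float
) -> np.ndarray:
    """Solve for basis correlations from log-fraction data, one draw."""
    d = log_frac.shape[1]
    cov = np.cov(log_frac, rowvar=False)
    var = np.diag(cov)
    # variation matrix: t_ij = var(log x_i) + var(log x_j) - 2 cov_ij
    t = var[:, None] + var[None, :] - 2.0 * cov
    excluded = np.zeros((d, d), dtype=bool)
    r = np.zeros((d, d))
    for _ in range(max(n_iterations, 1)):
        active = ~excluded
        np.fill_diagonal(active, False)
        m = active.astype(float)
        np.fill_diagonal(m, active.sum(axis=1))
        t_i = (t * active).sum(axis=1)
        try:
            w2 = np.linalg.solve(m, t_i)
        except np.linalg.LinAlgError:
            w2, *_ = np.linalg.lstsq(m, t_i, rcond=None)
        w2 = np.clip(w2, 1e-10, None)
        w = np.sqrt(w2)
        r = (w2[:, None] + w2[None, :] - t) / (2.0 * np.outer(w, w))
        r = np.clip(r, -1.0, 1.0)
        np.fill_diagonal(r, 1.0)
        # exclude the currently strongest pair if it breaks sparsity
        masked = np.abs(np.where(active, r, 0.0))
        np.fill_diagonal(masked, 0.0)
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        if masked[i, j] <= exclusion_threshold:
            break
        excluded[i, j] = excluded[j, i] = True
    return r


def sparcc(
    table: OtuTable,
    n_iterations: int = 20,
    exclusion_threshold: float = 0.1,
    n_dirichlet: int = 20,
    seed: int = 0,
) -> CorrelationMatrix:
    """SparCC correlation estimate for a count table.

    Averages the basis solution over ``n_dirichlet`` posterior fraction
    draws (Dirichlet with unit pseudocount).  Requires >= 10 samples and
    >= 5 OTUs; with fewer than 4 OTUs the basis system is underdetermined.
    """
    if table.n_otus < 4:
        raise ValueError("SparCC needs at least 4 OTUs (basis system underdetermined)")
    if table.n_otus < 5 or table.n_samples < 10:
        raise ValueError("SparCC needs >= 10 samples and >= 5 OTUs")
    rng = np.random.default_rng(seed)
    alpha = table.counts + 1.0
    acc = np.zeros((table.n_otus, table.n_otus))
    for _ in range(n_dirichlet):
        frac = np.vstack([rng.dirichlet(a) for a in alpha])
        acc += _basis_correlations(np.log(frac), n_iterations, exclusion_threshold)
    r = acc / n_dirichlet
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(list(table.otu_ids), r)


def bootstrap_pvalues(
    table: OtuTable,
    observed: CorrelationMatrix,
    n_boot: int = 100,
    seed: int = 0,
    method: str = "shuffle",
    n_iterations: int = 20,
    exclusion_threshold: float = 0.1,
    n_dirichlet: int = 5,
) -> np.ndarray:
    """Permutation/bootstrap pseudo p-values for SparCC correlations.

    ``method='shuffle'`` (default) permutes each OTU's counts across
    samples independently, destroying all between-OTU association while
    preserving marginals — a proper null for calibrated p-values.
    ``method='bootstrap'`` resamples samples with replacement instead.
    Two-sided: p = (#{|r_null| >= |r_obs|} + 1) / (n_boot + 1).
    """
    if n_boot < 99:
        raise ValueError("n_boot must be >= 99")
    if method not in ("shuffle", "bootstrap"):
        raise ValueError("method must be 'shuffle' or 'bootstrap'")
    rng = np.random.default_rng(seed)
    abs_obs = np.abs(observed.r)
    exceed = np.zeros_like(abs_obs)
    for b in range(n_boot):
        if method == "shuffle":
            counts = np.empty_like(table.counts)
            for j in range(table.n_otus):
                counts[:, j] = table.counts[rng.permutation(table.n_samples), j]
        else:
            idx = rng.integers(table.n_samples, size=table.n_samples)
            counts = table.counts[idx]
        boot = OtuTable(
            [f"b{i}" for i in range(table.n_samples)], list(table.otu_ids), counts
        )
        r_null = sparcc(
            boot,
            n_iterations=n_iterations,
            exclusion_threshold=exclusion_threshold,
            n_dirichlet=n_dirichlet,
            seed=int(rng.integers(2**31)),
        ).r
        exceed += np.abs(r_null) >= abs_obs
    p = (exceed + 1.0) / (n_boot + 1.0)
    np.fill_diagonal(p, 1.0)
    return p


def fdr_bh(p: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment over the unique pair vector.

    The input symmetric p matrix is reduced to its m = N(N-1)/2 upper
    triangle, adjusted, and reflected back; monotonicity is enforced by the
    step-up procedure.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim == 1:
        return multipletests(p, alpha=alpha, method="fdr_bh")[1]
    iu, ju = np.triu_indices(p.shape[0], k=1)
    adj = multipletests(p[iu, ju], alpha=alpha, method="fdr_bh")[1]
    out = np.ones_like(p)
    out[iu, ju] = adj
    out[ju, iu] = adj
    return out


def build_network(
    corr: CorrelationMatrix,
    p_adj: np.ndarray,
    r_threshold: float = 0.4,
    p_threshold: float = 0.01,
) -> nx.Graph:
    """Threshold correlations into an undirected signed graph.

    An edge requires |r| strictly greater than ``r_threshold`` AND adjusted
    p strictly below ``p_threshold``.  Nodes without any edge are not part
    of the graph (reported node counts follow the connected convention).
    """
    if not (0 < r_threshold < 1 and 0 < p_threshold < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    g = nx.Graph()
    ids = corr.otu_ids
    n = len(ids)
    for i in range(n - 1):
        for j in range(i + 1, n):
            r = corr.r[i, j]
            if abs(r) > r_threshold and p_adj[i, j] < p_threshold:
                g.add_edge(ids[i], ids[j], r=float(r), sign=1 if r > 0 else -1)
    if g.number_of_edges() == 0:
        logger.warning("no edge passed |r| > %g and p < %g", r_threshold, p_threshold)
    return g


def topology_metrics(net: nx.Graph, modularity_seed: int = 0) -> dict[str, float]:
    """Topology summary of a thresholded co-occurrence network.

    Diameter and average path length are computed on the largest connected
    component with unweighted shortest paths; modularity uses greedy
    modularity community detection on the unweighted graph.
    """
    n = net.number_of_nodes()
    e = net.number_of_edges()
    if n == 0:
        raise ValueError("empty network")
    out: dict[str, float] = {
        "nodes": float(n),
        "edges": float(e),
        "average_degree": 2.0 * e / n,
        "density": 2.0 * e / (n * (n - 1)) if n > 1 else 0.0,
        "average_clustering": nx.average_clustering(net) if n > 1 else 0.0,
    }
    components = sorted(nx.connected_components(net), key=len, reverse=True)
    giant = net.subgraph(components[0])
    if giant.number_of_nodes() > 1:
        out["diameter"] = float(nx.diameter(giant))
        out["average_path_length"] = float(nx.average_shortest_path_length(giant))
    else:
        out["diameter"] = 0.0
        out["average_path_length"] = 0.0
    if e > 0:
        communities = nx.community.greedy_modularity_communities(net)
        out["modularity"] = float(nx.community.modularity(net, communities))
        positive = sum(1 for _, _, d in net.edges(data=True) if d.get("sign", 1) > 0)
        out["percent_positive_edges"] = 100.0 * positive / e
    else:
        out["modularity"] = 0.0
        out["percent_positive_edges"] = float("nan")
    return out


def edge_sign_summary(
    net: nx.Graph, tax: TaxonomyTable, group_pairs: list[tuple[str, str]], rank: int = 1
) -> pd.DataFrame:
    """Percent of positive edges among edges linking two taxon groups.

    Group names are lineage labels at ``rank``.  Pairs with no inter-group
    edge are flagged (NaN percent) rather than reported as 0.
    """
    node_group = {node: tax.rank_label(node, rank) for node in net.nodes}
    available = sorted(set(node_group.values()))
    rows = []
    for a, b in group_pairs:
        for name in (a, b):
            if name not in available:
                raise ValueError(
                    f"unknown taxon group {name!r}; available: {', '.join(available)}"
                )
        pos = tot = 0
        for u, v, d in net.edges(data=True):
            gu, gv = node_group[u], node_group[v]
            if {gu, gv} == {a, b}:
                tot += 1
                pos += d.get("sign", 1) > 0
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "n_edges": tot,
                "percent_positive": 100.0 * pos / tot if tot else np.nan,
                "flag": "" if tot else "no_inter_group_edges",
            }
        )
    return pd.DataFrame(rows)
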