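"""Rarefaction, alpha diversity, beta diversity, and ordination.

Conventions (fixed and tested):

* Shannon entropy in bits (log base 2), matching the common QIIME 1 default.
* Faith's PD uses the rooted convention: the branch path from the present
  tips up to the root is included, so a single-tip sample already has
  positive PD.
* One seeded rarefaction draw without replacement; samples below the target
  depth are dropped with a warning rather than raising.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity

from ._util import logger
from .data_model import OtuTable

__all__ = [
    "rarefy",
    "alpha_diversity",
    "bray_curtis",
    "unweighted_unifrac",
    "pcoa",
]


def rarefy(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped (warned).
    All-zero OTU columns are retained so identifiers stay aligned across
    tables.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.sample_totals()
    keep = totals >= depth
    if not keep.all():
        dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
        logger.warning(
            "rarefy dropped %d sample(s) below depth %d: %s",
            len(dropped), depth, ", ".join(dropped),
        )
    rows = []
    ids = []
    for i, sid in enumerate(table.sample_ids):
        if not keep[i]:
            continue
        if totals[i] == depth:
            rows.append(table.counts[i].copy())
        else:
            rows.append(rng.multivariate_hypergeometric(table.counts[i], depth))
        ids.append(sid)
    if not rows:
        raise ValueError(f"no sample reaches rarefaction depth {depth}")
    return OtuTable(ids, list(table.otu_ids), np.vstack(rows))


def _faith_pd(presence: np.ndarray, tree: TreeNode, otu_index: dict[str, int]) -> float:
    """Sum of branch lengths on paths from present tips to the root."""
    pd_sum = 0.0
    stack: dict[int, bool] = {}
    for node in tree.postorder(include_self=True):
        if not node.children:
            idx = otu_index.get(node.name)
            has = bool(idx is not None and presence[idx])
        else:
            has = any(stack.pop(id(c)) for c in node.children)
        stack[id(node)] = has
        if has and node.parent is not None:
            pd_sum += node.length or 0.0
    return pd_sum


def alpha_diversity(table: OtuTable, tree: TreeNode | None = None) -> pd.DataFrame:
    """Per-sample OTU richness, Shannon (bits), and Faith's PD.

    PD requires every table OTU present in the table to be a tree tip;
    omit the tree to skip PD.  Empty samples yield all-zero records and a
    warning.
    """
    rel = table.relative_abundance()
    richness = (table.counts > 0).sum(axis=1)
    shannon = np.zeros(table.n_samples)
    for i in range(table.n_samples):
        p = rel[i][rel[i] > 0]
        shannon[i] = float(-(p * np.log2(p)).sum()) if p.size else 0.0
    out = pd.DataFrame(
        {"sample_id": table.sample_ids, "richness": richness, "shannon": shannon}
    )
    if tree is not None:
        tips = {t.name for t in tree.tips()}
        present_otus = set(np.array(table.otu_ids)[table.otu_totals() > 0])
        missing = present_otus - tips
        if missing:
            raise ValueError(
                f"{len(missing)} OTU(s) with reads are not tips of the tree "
                f"(e.g. {sorted(missing)[0]!r})"
            )
        otu_index = {o: j for j, o in enumerate(table.otu_ids)}
        out["pd"] = [
            _faith_pd(table.counts[i] > 0, tree, otu_index) for i in range(table.n_samples)
        ]
    empty = table.sample_totals() == 0
    if empty.any():
        logger.warning("alpha_diversity: %d empty sample(s)", int(empty.sum()))
    return out


def bray_curtis(table: OtuTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity, BC = 1 - 2*sum(min)/sum(total)."""
    if table.n_samples < 2:
        raise ValueError("need at least two samples")
    x = table.counts.astype(float)
    totals = x.sum(axis=1)
    if (totals == 0).sum() >= 2:
        logger.warning("Bray-Curtis between all-zero samples defined as 0")
    d = squareform(_bray_curtis_condensed(x))
    return DistanceMatrix(d, ids=table.sample_ids)


def _bray_curtis_condensed(x: np.ndarray) -> np.ndarray:
    n = x.shape[0]
    out = np.empty(n * (n - 1) // 2)
    k = 0
    for i in range(n - 1):
        mins = np.minimum(x[i], x[i + 1:]).sum(axis=1)
        sums = x[i].sum() + x[i + 1:].sum(axis=1)
        with np.errstate(invalid="ignore"):
            d = 1.0 - 2.0 * mins / sums
        d[sums == 0] = 0.0
        out[k : k + n - 1 - i] = d
        k += n - 1 - i
    return out


def unweighted_unifrac(table: OtuTable, tree: TreeNode) -> DistanceMatrix:
    """Unweighted UniFrac: fraction of branch length unique to one sample.

    Presence/absence only; requires a rooted tree whose tips cover the
    table's OTUs.
    """
    if table.n_samples < 2:
        raise ValueError("need at least two samples")
    return beta_diversity(
        "unweighted_unifrac",
        table.counts,
        ids=table.sample_ids,
        taxa=table.otu_ids,
        tree=tree,
    )


def pcoa(dm: DistanceMatrix) -> pd.DataFrame:
    """Principal coordinates analysis by Gower double-centering.

    Returns a DataFrame of sample coordinates on axes with positive
    eigenvalues; eigenvalues (including negative ones) and the proportion
    explained — computed over positive eigenvalues only — are attached as
    ``.attrs['eigenvalues']`` and ``.attrs['proportion_explained']``.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("PCoA needs at least three samples")
    d2 = np.asarray(dm.data) ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > 1e-10
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    prop = np.zeros_like(eigvals)
    if pos.any():
        prop[pos] = eigvals[pos] / eigvals[pos].sum()
    out = pd.DataFrame(
        coords,
        index=dm.ids,
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )
    out.attrs["eigenvalues"] = eigvals
    out.attrs["proportion_explained"] = prop
    return out
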