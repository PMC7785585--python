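"""Null-model quantification of community assembly processes.

Per sample pair the pipeline computes

* abundance-weighted beta mean nearest taxon distance (betaMNTD) — the mean
  phylogenetic distance from each taxon to its closest relative in the
  paired community;
* betaNTI — the standardized effect size of betaMNTD against a null that
  shuffles OTU labels across the tips of the phylogeny ("taxa shuffle"),
  999 randomizations by default;
* RCbray — a Raup-Crick metric on Bray-Curtis dissimilarity against a null
  that preserves each sample's richness and total abundance while drawing
  taxa by occurrence frequency and abundances by regional relative
  abundance, rescaled to [-1, 1].

Pairs are then partitioned into five processes:

=====================  =======================================
betaNTI > 2            variable selection
betaNTI < -2           homogeneous selection
|betaNTI| <= 2, RC > 0.95    dispersal limitation
|betaNTI| <= 2, RC < -0.95   homogenizing dispersal
|betaNTI| <= 2, |RC| <= 0.95 undominated (a.k.a. "drift")
=====================  =======================================

Ties at exactly |betaNTI| = 2 or |RC| = 0.95 fall on the stochastic /
undominated side; the selection test precedes the dispersal test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix, TreeNode

from ._util import logger
from .data_model import OtuTable
from .diversity import _bray_curtis_condensed

__all__ = [
    "PairMatrix",
    "bmntd",
    "bnti",
    "raup_crick_bray",
    "partition_processes",
    "quantify_assembly",
    "AssemblyPartition",
    "PROCESS_LABELS",
]

PROCESS_LABELS = (
    "variable_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "undominated",
)


@dataclass
class AssemblyPartition:
    """Fraction of sample pairs assigned to each assembly process."""

    fractions: dict[str, float]
    n_pairs: int
    n_undefined: int = 0


def _patristic(table: OtuTable, tree: TreeNode) -> np.ndarray:
    tips = {t.name for t in tree.tips()}
    missing = set(table.otu_ids) - tips
    if missing:
        raise ValueError(
            f"{len(missing)} table OTU(s) missing from tree (e.g. {sorted(missing)[0]!r})"
        )
    dm = tree.tip_tip_distances(list(table.otu_ids))
    # reorder to the table's OTU order
    order = [dm.index(o) for o in table.otu_ids]
    return np.asarray(dm.data)[np.ix_(order, order)]


def _communities(table: OtuTable, weighted: bool):
    totals = table.sample_totals()
    if (totals == 0).any():
        bad = table.sample_ids[int(np.argmax(totals == 0))]
        raise ValueError(f"sample {bad!r} has zero total abundance")
    idx_list, w_list = [], []
    for i in range(table.n_samples):
        idx = np.flatnonzero(table.counts[i] > 0)
        idx_list.append(idx)
        if weighted:
            w = table.counts[i, idx] / totals[i]
        else:
            w = np.full(idx.size, 1.0 / idx.size)
        w_list.append(w)
    return idx_list, w_list


def _bmntd_condensed(D: np.ndarray, idx_list, w_list) -> np.ndarray:
    """All-pairs betaMNTD given taxon positions and weights per community."""
    n_s = len(idx_list)
    # minimum distance from every taxon position to each community
    M = np.empty((D.shape[0], n_s))
    for m, idx in enumerate(idx_list):
        M[:, m] = D[:, idx].min(axis=1)
    out = np.empty(n_s * (n_s - 1) // 2)
    k = 0
    for i in range(n_s - 1):
        for j in range(i + 1, n_s):
            out[k] = 0.5 * (
                w_list[i] @ M[idx_list[i], j] + w_list[j] @ M[idx_list[j], i]
            )
            k += 1
    return out


def bmntd(table: OtuTable, tree: TreeNode, weighted: bool = True) -> DistanceMatrix:
    """Beta mean nearest taxon distance for every sample pair.

    With ``weighted=True`` (default) taxa are weighted by their
    within-sample relative abundance; otherwise uniformly over present taxa.
    """
    D = _patristic(table, tree)
    idx_list, w_list = _communities(table, weighted)
    return DistanceMatrix(squareform(_bmntd_condensed(D, idx_list, w_list)), ids=table.sample_ids)


def bnti(
    table: OtuTable,
    tree: TreeNode,
    n_null: int = 999,
    seed: int = 0,
    weighted: bool = True,
) -> PairMatrix:
    """betaNTI: standardized effect size of betaMNTD under a taxa shuffle.

    Each randomization permutes OTU labels across tree tips (equivalently,
    permutes rows/columns of the patristic distance matrix), preserving both
    the table and the tree shape.
    betaNTI = (obs - mean(null)) / sd(null); pairs with sd(null) = 0 are
    returned as NaN and logged.
    """
    if n_null < 99:
        raise ValueError("n_null must be >= 99")
    D = _patristic(table, tree)
    idx_list, w_list = _communities(table, weighted)
    obs = _bmntd_condensed(D, idx_list, w_list)
    rng = np.random.default_rng(seed)
    n_t = D.shape[0]
    nulls = np.empty((n_null, obs.size))
    for it in range(n_null):
        perm = rng.permutation(n_t)
        nulls[it] = _bmntd_condensed(D, [perm[idx] for idx in idx_list], w_list)
    mu = nulls.mean(axis=0)
    sd = nulls.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (obs - mu) / sd
    z[sd == 0] = np.nan
    if np.isnan(z).any():
        logger.warning("betaNTI undefined (zero null sd) for %d pair(s)", int(np.isnan(z).sum()))
    return _condensed_to_pm(z, table.sample_ids)


@dataclass
class PairMatrix:
    """Symmetric per-pair matrix of signed values (betaNTI, RCbray).

    Shares the ``ids`` / ``data`` surface of :class:`skbio.DistanceMatrix`
    but allows negative entries and NaN (undefined pairs).
    """

    ids: tuple[str, ...]
    data: np.ndarray

    def __post_init__(self) -> None:
        self.ids = tuple(self.ids)
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.ids)
        if self.data.shape != (n, n):
            raise ValueError("data shape does not match ids")
        if not np.allclose(self.data, self.data.T, atol=1e-12, equal_nan=True):
            raise ValueError("data must be symmetric")

    def condensed(self) -> np.ndarray:
        iu, ju = np.triu_indices(len(self.ids), k=1)
        return self.data[iu, ju]

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(self.data[self.ids.index(a), self.ids.index(b)])


def _condensed_to_pm(v: np.ndarray, ids) -> PairMatrix:
    n = len(ids)
    m = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    m[iu, ju] = v
    m[ju, iu] = v
    return PairMatrix(tuple(ids), m)


def raup_crick_bray(
    table: OtuTable,
    n_null: int = 999,
    seed: int = 0,
    occupancy_weights: np.ndarray | None = None,
    regional_abundance: np.ndarray | None = None,
) -> PairMatrix:
    """Abundance-based Raup-Crick metric on Bray-Curtis dissimilarity.

    The null preserves each sample's observed richness and total count:
    taxa are drawn without replacement with probability proportional to
    their occurrence frequency across samples, seeded with one individual
    each, and the remaining individuals are assigned multinomially with
    probability proportional to regional relative abundance.  Each null
    round redraws every sample once and compares all pairs, so a pair's
    null Bray-Curtis values are independent draws from its pairwise null.

    By default the regional pool (occurrence frequencies and regional
    abundances) is estimated from the table itself; both can be supplied
    explicitly to describe a wider regional species pool.

    RCbray = (((#null < obs) + 0.5 * #ties) / n_null - 0.5) * 2, in [-1, 1].
    """
    if table.n_samples < 2:
        raise ValueError("need at least two samples")
    if n_null < 99:
        raise ValueError("n_null must be >= 99")
    counts = table.counts
    if occupancy_weights is None:
        occupancy = (counts > 0).sum(axis=0).astype(float)
    else:
        occupancy = np.asarray(occupancy_weights, dtype=float)
        if occupancy.shape != (table.n_otus,) or (occupancy < 0).any():
            raise ValueError("occupancy_weights must be non-negative, one per OTU")
    if regional_abundance is None:
        regional = counts.sum(axis=0).astype(float)
    else:
        regional = np.asarray(regional_abundance, dtype=float)
        if regional.shape != (table.n_otus,) or (regional < 0).any():
            raise ValueError("regional_abundance must be non-negative, one per OTU")
    if (counts.sum(axis=1) == 0).any():
        raise ValueError("samples with zero total abundance are not allowed")
    p_occ = occupancy / occupancy.sum()
    richness = (counts > 0).sum(axis=1)
    totals = counts.sum(axis=1)
    n_s, n_t = counts.shape
    obs = _bray_curtis_condensed(counts.astype(float))
    rng = np.random.default_rng(seed)
    less = np.zeros(obs.size)
    ties = np.zeros(obs.size)
    null_counts = np.empty((n_s, n_t))
    for _ in range(n_null):
        null_counts[:] = 0.0
        for i in range(n_s):
            chosen = rng.choice(n_t, size=richness[i], replace=False, p=p_occ)
            null_counts[i, chosen] = 1.0
            extra = totals[i] - richness[i]
            if extra > 0:
                pr = regional[chosen]
                pr = pr / pr.sum()
                null_counts[i, chosen] += rng.multinomial(extra, pr)
        bc = _bray_curtis_condensed(null_counts)
        less += bc < obs - 1e-12
        ties += np.abs(bc - obs) <= 1e-12
    rc = ((less + 0.5 * ties) / n_null - 0.5) * 2.0
    return _condensed_to_pm(rc, table.sample_ids)


def classify_pair(bnti_value: float, rc_value: float) -> str:
    """Assign one sample pair to an assembly process (see module docstring)."""
    if np.isnan(bnti_value):
        raise ValueError("betaNTI undefined for this pair")
    if bnti_value > 2:
        return "variable_selection"
    if bnti_value < -2:
        return "homogeneous_selection"
    if rc_value > 0.95:
        return "dispersal_limitation"
    if rc_value < -0.95:
        return "homogenizing_dispersal"
    return "undominated"


def partition_processes(
    bnti_dm: PairMatrix, rc_dm: PairMatrix
) -> tuple[pd.DataFrame, AssemblyPartition]:
    """Label every sample pair and summarize the five process fractions.

    Pairs with undefined (NaN) betaNTI are excluded from the denominators;
    their count is reported on the partition.
    """
    if tuple(bnti_dm.ids) != tuple(rc_dm.ids):
        raise ValueError("betaNTI and RCbray matrices must share id order")
    ids = list(bnti_dm.ids)
    z = squareform(np.asarray(bnti_dm.data), checks=False)
    rc = squareform(np.asarray(rc_dm.data), checks=False)
    if np.any(np.abs(rc) > 1 + 1e-12):
        raise ValueError("RCbray values outside [-1, 1]")
    iu, ju = np.triu_indices(len(ids), k=1)
    rows = []
    n_undefined = 0
    for k in range(z.size):
        if np.isnan(z[k]):
            n_undefined += 1
            label = "undefined"
        else:
            label = classify_pair(z[k], rc[k])
        rows.append(
            {
                "sample_a": ids[iu[k]],
                "sample_b": ids[ju[k]],
                "bnti": z[k],
                "rc_bray": rc[k],
                "process": label,
            }
        )
    df = pd.DataFrame(rows)
    defined = df[df["process"] != "undefined"]
    n_pairs = len(defined)
    if n_pairs == 0:
        raise ValueError("no pair has a defined betaNTI")
    fractions = {
        lab: float((defined["process"] == lab).sum()) / n_pairs for lab in PROCESS_LABELS
    }
    return df, AssemblyPartition(fractions, n_pairs, n_undefined)


def quantify_assembly(
    table: OtuTable,
    tree: TreeNode,
    n_null: int = 999,
    seed: int = 0,
    weighted: bool = True,
) -> tuple[pd.DataFrame, AssemblyPartition]:
    """Full per-pair assembly analysis: betaMNTD, betaNTI, RCbray, labels."""
    obs = bmntd(table, tree, weighted=weighted)
    z = bnti(table, tree, n_null=n_null, seed=seed, weighted=weighted)
    rc = raup_crick_bray(table, n_null=n_null, seed=seed + 1)
    df, partition = partition_processes(z, rc)
    obs_cond = squareform(np.asarray(obs.data), checks=False)
    df.insert(2, "bmntd", obs_cond)
    return df, partition
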