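"""Domain types and file I/O shared by every pipeline stage.

The canonical in-memory layout for count data is samples x OTUs.  Trees are
:class:`skbio.TreeNode` objects (rooted, branch lengths in substitutions per
site); distance matrices are :class:`skbio.DistanceMatrix`; sample metadata
and taxonomy live in :class:`pandas.DataFrame` with a fixed documented schema.
All writers emit UTF-8, LF-terminated, tab-separated text with full float
precision so that read(write(x)) round-trips exactly.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from ._util import logger

__all__ = [
    "OtuTable",
    "TaxonomyTable",
    "METADATA_REQUIRED_COLUMNS",
    "read_otu_table",
    "write_otu_table",
    "read_taxonomy",
    "write_taxonomy",
    "read_newick",
    "write_newick",
    "read_metadata",
    "write_metadata",
    "read_distance_matrix",
    "write_distance_matrix",
    "align_datasets",
    "aggregate_by_taxon",
    "exclude_lineages",
]


@dataclass
class OtuTable:
    """Integer count matrix over samples (rows) and OTUs (columns).

    Parameters
    ----------
    sample_ids : list of str
        Unique sample identifiers, one per row.
    otu_ids : list of str
        Unique OTU identifiers, one per column.
    counts : ndarray of int, shape (n_samples, n_otus)
        Non-negative read counts.
    """

    sample_ids: list[str]
    otu_ids: list[str]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.otu_ids = [str(o) for o in self.otu_ids]
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                bad = np.argwhere(np.mod(counts, 1) != 0)[0]
                raise ValueError(
                    f"non-integer count at sample {self.sample_ids[bad[0]]!r}, "
                    f"OTU {self.otu_ids[bad[1]]!r}"
                )
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            bad = np.argwhere(counts < 0)[0]
            raise ValueError(
                f"negative count at sample {self.sample_ids[bad[0]]!r}, "
                f"OTU {self.otu_ids[bad[1]]!r}"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample identifiers")
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise ValueError("duplicate OTU identifiers")
        self.counts = counts.astype(np.int64)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def otu_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def relative_abundance(self) -> np.ndarray:
        """Row-normalized proportions; all-zero rows stay all-zero."""
        totals = self.sample_totals().astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = self.counts / totals[:, None]
        rel[totals == 0] = 0.0
        return rel

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)

    def select_samples(self, sample_ids: list[str]) -> "OtuTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return OtuTable(list(sample_ids), list(self.otu_ids), self.counts[idx])

    def select_otus(self, otu_ids: list[str]) -> "OtuTable":
        idx = [self.otu_ids.index(o) for o in otu_ids]
        return OtuTable(list(self.sample_ids), list(otu_ids), self.counts[:, idx])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OtuTable):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.otu_ids == other.otu_ids
            and np.array_equal(self.counts, other.counts)
        )


@dataclass
class TaxonomyTable:
    """OTU -> lineage mapping.

    Lineages are ordered rank labels from supergroup down to the lowest
    assigned rank, e.g. ``["Alveolata", "Ciliophora", "Spirotrichea"]``.
    """

    lineages: dict[str, list[str]]

    def __post_init__(self) -> None:
        for otu, lin in self.lineages.items():
            if not lin:
                raise ValueError(f"empty lineage for OTU {otu!r}")

    @property
    def otu_ids(self) -> list[str]:
        return list(self.lineages)

    def rank_label(self, otu_id: str, rank: int) -> str:
        """Taxon label at 0-based rank; 'unclassified' when unassigned."""
        lin = self.lineages.get(otu_id)
        if lin is None or rank >= len(lin):
            return "unclassified"
        return lin[rank]

    def select(self, otu_ids: list[str]) -> "TaxonomyTable":
        return TaxonomyTable({o: list(self.lineages[o]) for o in otu_ids})


METADATA_REQUIRED_COLUMNS = [
    "sample_id",
    "site",
    "latitude",
    "longitude",
    "water_depth",
    "sediment_depth",
    "bottom_temperature",
    "bottom_salinity",
    "As",
    "Cd",
    "Cr",
    "Cu",
    "Hg",
    "Pb",
    "Zn",
    "clay",
    "silt",
    "sand",
]

_METAL_COLUMNS = ["As", "Cd", "Cr", "Cu", "Hg", "Pb", "Zn"]
_GRAIN_COLUMNS = ["clay", "silt", "sand"]


def _validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in METADATA_REQUIRED_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing required column(s): {', '.join(missing)}")
    for col in METADATA_REQUIRED_COLUMNS:
        if meta[col].isna().any():
            sample = meta.loc[meta[col].isna(), "sample_id"].iloc[0]
            raise ValueError(f"missing value for field {col!r} in sample {sample!r}")
    if meta["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in metadata")
    grain_sum = meta[_GRAIN_COLUMNS].sum(axis=1)
    bad = (grain_sum - 100.0).abs() > 0.5
    if bad.any():
        sid = meta.loc[bad, "sample_id"].iloc[0]
        raise ValueError(
            f"grain-size fractions of sample {sid!r} sum to "
            f"{grain_sum[bad].iloc[0]:g}, expected 100 +/- 0.5"
        )
    sd = meta["sediment_depth"]
    if not sd.isin([1, 2, 3, 4, 5]).all():
        sid = meta.loc[~sd.isin([1, 2, 3, 4, 5]), "sample_id"].iloc[0]
        raise ValueError(f"sediment_depth of sample {sid!r} outside 1..5")
    if (meta[_METAL_COLUMNS] < 0).any().any():
        raise ValueError("negative metal concentration in metadata")
    if (meta["latitude"].abs() > 90).any() or (meta["longitude"].abs() > 180).any():
        raise ValueError("coordinates out of range")
    return meta.reset_index(drop=True)


def read_otu_table(path, orientation: str = "samples-in-rows") -> OtuTable:
    """Read a tab-separated count table with a header row and id column.

    ``orientation`` declares the file layout ("samples-in-rows" or
    "otus-in-rows"); the returned table is always samples x OTUs.
    """
    if orientation not in ("samples-in-rows", "otus-in-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if orientation == "otus-in-rows":
        df = df.T
    values = np.empty(df.shape, dtype=np.int64)
    for i, (sid, row) in enumerate(df.iterrows()):
        for j, cell in enumerate(row):
            try:
                v = int(cell)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-integer count {cell!r} at sample {sid!r}, "
                    f"OTU {df.columns[j]!r}"
                ) from None
            if v < 0:
                raise ValueError(
                    f"negative count {v} at sample {sid!r}, OTU {df.columns[j]!r}"
                )
            values[i, j] = v
    return OtuTable(list(df.index), list(df.columns), values)


def write_otu_table(table: OtuTable, path) -> None:
    df = table.to_dataframe()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", lineterminator="\n")


def read_taxonomy(path) -> TaxonomyTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "otu_id" not in df.columns or "lineage" not in df.columns:
        raise ValueError("taxonomy file needs 'otu_id' and 'lineage' columns")
    if df["otu_id"].duplicated().any():
        dup = df.loc[df["otu_id"].duplicated(), "otu_id"].iloc[0]
        raise ValueError(f"duplicate OTU id {dup!r} in taxonomy")
    lineages = {
        row.otu_id: [r for r in str(row.lineage).split(";") if r]
        for row in df.itertuples()
    }
    return TaxonomyTable(lineages)


def write_taxonomy(tax: TaxonomyTable, path) -> None:
    df = pd.DataFrame(
        {"otu_id": tax.otu_ids, "lineage": [";".join(tax.lineages[o]) for o in tax.otu_ids]}
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_newick(path) -> TreeNode:
    """Read a single Newick tree; validate tips, root, and branch lengths.

    Unrooted trees (basal trifurcation) are midpoint-rooted; missing branch
    lengths are imputed as 0; both actions are logged.
    """
    tree = TreeNode.read(path, format="newick")
    tips = [t.name for t in tree.tips()]
    if len(set(tips)) != len(tips):
        seen, dup = set(), None
        for t in tips:
            if t in seen:
                dup = t
                break
            seen.add(t)
        raise ValueError(f"duplicate tip label {dup!r} in tree")
    n_missing = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
            n_missing += 1
        elif node.length < 0:
            raise ValueError(f"negative branch length on node {node.name!r}")
    if n_missing:
        logger.warning("imputed %d missing branch length(s) as 0", n_missing)
    if len(tree.children) > 2:
        logger.warning("input tree is unrooted (basal multifurcation); midpoint-rooting")
        tree = tree.root_at_midpoint()
        for node in tree.traverse(include_self=False):
            if node.length is None:
                node.length = 0.0
    return tree


def write_newick(tree: TreeNode, path) -> None:
    tree.write(path, format="newick")


def total_branch_length(tree: TreeNode) -> float:
    return float(sum(n.length or 0.0 for n in tree.traverse(include_self=False)))


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    if "sample_id" in meta.columns:
        meta["sample_id"] = meta["sample_id"].astype(str)
    return _validate_metadata(meta)


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.values, ids=[str(i) for i in df.index])


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    df = pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids)
    df.index.name = "id"
    df.to_csv(path, sep="\t", lineterminator="\n")


def align_datasets(
    table: OtuTable,
    tree: TreeNode | None = None,
    meta: pd.DataFrame | None = None,
    tax: TaxonomyTable | None = None,
):
    """Restrict all datasets to shared samples and OTUs.

    Samples are restricted to table ∩ metadata; OTUs to table ∩ tree tips
    ∩ taxonomy (whichever of tree/taxonomy are supplied).  Returns the
    aligned ``(table, tree, meta, tax)`` quadruple; dropped counts are
    logged.  The operation is idempotent.
    """
    samples = list(table.sample_ids)
    if meta is not None:
        keep = set(meta["sample_id"].astype(str))
        samples = [s for s in samples if s in keep]
        if not samples:
            raise ValueError("no samples shared between OTU table and metadata")
    otus = list(table.otu_ids)
    if tree is not None:
        tips = {t.name for t in tree.tips()}
        otus = [o for o in otus if o in tips]
    if tax is not None:
        known = set(tax.otu_ids)
        otus = [o for o in otus if o in known]
    if not otus:
        raise ValueError("no OTUs shared among OTU table, tree, and taxonomy")

    n_s_drop = table.n_samples - len(samples)
    n_o_drop = table.n_otus - len(otus)
    if n_s_drop or n_o_drop:
        logger.info("align_datasets dropped %d sample(s), %d OTU(s)", n_s_drop, n_o_drop)

    out_table = table.select_samples(samples).select_otus(otus)
    out_tree = None
    if tree is not None:
        tip_names = [t.name for t in tree.tips()]
        if set(tip_names) - set(otus):
            out_tree = tree.shear(otus)
        else:
            out_tree = tree
    out_meta = None
    if meta is not None:
        out_meta = (
            meta[meta["sample_id"].astype(str).isin(samples)]
            .set_index("sample_id")
            .loc[samples]
            .reset_index()
        )
    out_tax = tax.select(otus) if tax is not None else None
    return out_table, out_tree, out_meta, out_tax


def aggregate_by_taxon(table: OtuTable, tax: TaxonomyTable, rank: int) -> pd.DataFrame:
    """Relative abundance of taxon groups at a lineage rank (0-based).

    OTUs unassigned at that rank are pooled as "unclassified".  Row sums are
    1 for non-empty samples; empty samples yield all-zero rows (logged).
    """
    if rank < 0:
        raise ValueError("rank must be >= 0")
    groups = [tax.rank_label(o, rank) for o in table.otu_ids]
    rel = table.relative_abundance()
    df = pd.DataFrame(rel, index=table.sample_ids, columns=groups)
    out = df.T.groupby(level=0).sum().T
    empty = table.sample_totals() == 0
    if empty.any():
        logger.warning("%d empty sample(s) yield all-zero taxon rows", int(empty.sum()))
    return out


def exclude_lineages(table: OtuTable, tax: TaxonomyTable, names: list[str]) -> OtuTable:
    """Drop OTUs whose lineage contains any of the given rank labels.

    Mirrors the removal of non-target lineages (e.g. Bacteria, Archaea,
    plastidial, Metazoa reads) before community analysis.
    """
    banned = set(names)
    keep = [
        o
        for o in table.otu_ids
        if not banned.intersection(tax.lineages.get(o, []))
    ]
    logger.info("exclude_lineages removed %d OTU(s)", table.n_otus - len(keep))
    return table.select_otus(keep)
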