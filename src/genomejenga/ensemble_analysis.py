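"""Summaries of a Jenga ensemble: presence/absence matrices over genes,
essential genes or reactions; core/variable partitions; size and
essentiality distributions; and a clustering order that exposes the block
structure of alternative minimal-network topologies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage as scipy_linkage
from scipy.spatial.distance import pdist

from .gene_sets import GeneSet
from .jenga import JengaEnsemble

__all__ = [
    "ITEM_KINDS",
    "PresenceMatrix",
    "CoreVariableSummary",
    "build_matrix",
    "core_variable",
    "distribution_summary",
    "cluster_order",
    "export_core_gene_set",
]

ITEM_KINDS = ("gene", "essential_gene", "reaction")


@dataclass
class PresenceMatrix:
    """Boolean replicate x item matrix; row r reproduces replicate r's set."""

    frame: pd.DataFrame  # index: replicate ids; columns: item ids (sorted)
    item_kind: str

    @property
    def replicate_ids(self) -> list[int]:
        return list(self.frame.index)

    @property
    def items(self) -> list[str]:
        return list(self.frame.columns)

    def row_set(self, replicate_id) -> frozenset[str]:
        row = self.frame.loc[replicate_id]
        return frozenset(row.index[row])


@dataclass
class CoreVariableSummary:
    """Partition of an ensemble's items into core (present in every
    replicate) and variable (present in some but not all)."""

    item_kind: str
    core_items: frozenset[str]
    variable_items: frozenset[str]
    counts_per_replicate: pd.Series  # row sums, indexed by replicate id


def _replicate_items(minimal, item_kind: str):
    if item_kind == "gene":
        return minimal.retained_genes
    if item_kind == "essential_gene":
        return minimal.essential_genes
    if item_kind == "reaction":
        return minimal.active_reactions
    raise ValueError(f"unknown item_kind {item_kind!r}; expected one of {ITEM_KINDS}")


def build_matrix(ensemble: JengaEnsemble, item_kind: str) -> PresenceMatrix:
    """Presence/absence matrix for one item kind, columns sorted
    lexicographically over the union of per-replicate sets."""
    if len(ensemble) == 0:
        raise ValueError("ensemble is empty")
    per_replicate = {
        m.replicate_id: _replicate_items(m, item_kind) for m in ensemble.replicates
    }
    columns = sorted(set().union(*per_replicate.values())) if per_replicate else []
    data = np.zeros((len(per_replicate), len(columns)), dtype=bool)
    col_index = {c: j for j, c in enumerate(columns)}
    replicate_ids = sorted(per_replicate)
    for i, rid in enumerate(replicate_ids):
        for item in per_replicate[rid]:
            data[i, col_index[item]] = True
    frame = pd.DataFrame(data, index=replicate_ids, columns=columns)
    return PresenceMatrix(frame=frame, item_kind=item_kind)


def core_variable(matrix: PresenceMatrix) -> CoreVariableSummary:
    """Core = all-true columns (items in every replicate); everything else
    in the column set is variable."""
    all_true = matrix.frame.all(axis=0)
    core = frozenset(matrix.frame.columns[all_true])
    variable = frozenset(matrix.frame.columns[~all_true])
    return CoreVariableSummary(
        item_kind=matrix.item_kind,
        core_items=core,
        variable_items=variable,
        counts_per_replicate=matrix.frame.sum(axis=1),
    )


def distribution_summary(matrix: PresenceMatrix) -> pd.DataFrame:
    """Histogram of per-replicate set sizes: columns (value, frequency),
    sorted by value; frequencies sum to the number of replicates."""
    counts = matrix.frame.sum(axis=1).value_counts().sort_index()
    return pd.DataFrame({"value": counts.index.astype(int), "frequency": counts.values})


def cluster_order(
    matrix: PresenceMatrix, linkage: str = "complete", distance: str = "jaccard"
) -> np.ndarray:
    """Hierarchical-clustering leaf order of the replicates (a permutation
    of row positions), grouping replicates with similar content.

    Complete linkage on Jaccard distance by default; all-identical rows come
    back in input (replicate-id) order.
    """
    if linkage != "complete" or distance != "jaccard":
        raise ValueError("only complete linkage on jaccard distance is supported")
    values = matrix.frame.to_numpy(dtype=bool)
    if values.shape[0] < 2:
        raise ValueError("need at least two replicates to cluster")
    dists = pdist(values, metric="jaccard")
    dists = np.nan_to_num(dists, nan=0.0)  # two all-false rows are identical
    if np.all(dists == 0.0):
        return np.arange(values.shape[0])
    tree = scipy_linkage(dists, method="complete")
    return np.asarray(leaves_list(tree))


def export_core_gene_set(
    summary: CoreVariableSummary, path, name: str = "jenga_core_genes"
) -> GeneSet:
    """Write the core genes as a plain-text gene list consumable by the
    STIMS pipeline, closing the loop from reductive simulation back to the
    selection test."""
    if summary.item_kind != "gene":
        raise ValueError("core gene export requires a gene matrix")
    if not summary.core_items:
        raise ValueError("core gene set is empty; nothing to export")
    gene_set = GeneSet(name=name, members=frozenset(summary.core_items))
    from .io_formats import write_gene_set

    write_gene_set(gene_set, path)
    return gene_set
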