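"""Depth-related COG screening, intersection, and bootstrap clustering.

Within each reference water column every COG is tested for a difference in
relative abundance between every pair of depths with an exact count test;
p-values are BH-adjusted jointly across all (COG, depth pair) hypotheses of
the column, and a COG is depth-related if any pair's adjusted p falls at or
below the significance level (default 0.01). COGs significant in every
reference column form the global depth-related set used downstream.

Dataset relationships are summarized by average-linkage hierarchical
clustering of Z-scored profiles (Euclidean distance over COG dimensions)
with node support estimated by resampling COGs with replacement: the
support of an internal node is the percentage of replicate trees containing
the same leaf set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch

from .errors import ValidationError
from .io import COGCountMatrix, DatasetMetadata
from .stats import bh_fdr, binomial_exact_counts, fisher_exact_many

__all__ = [
    "ColumnDesign",
    "DepthCOGSet",
    "Dendrogram",
    "column_depth_cogs",
    "intersect_depth_cogs",
    "cluster_datasets",
    "photic_label",
]

TestFlavor = Literal["fisher", "binomial"]


@dataclass(frozen=True)
class ColumnDesign:
    """A water column as an ordered (shallow to deep) list of dataset ids."""

    site: str
    dataset_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.dataset_ids) < 2:
            raise ValidationError(f"column {self.site}: needs >= 2 datasets")
        if len(set(self.dataset_ids)) != len(self.dataset_ids):
            raise ValidationError(f"column {self.site}: duplicate dataset ids")


@dataclass
class DepthCOGSet:
    """Depth-related COGs of one column with their best pair and adjusted p."""

    site: str
    cog_ids: list[str]
    table: pd.DataFrame  # columns: cog_id, pair, statistic, p_value, p_adjusted
    alpha: float

    def __post_init__(self) -> None:
        if len(self.table):
            member = self.table[self.table["cog_id"].isin(self.cog_ids)]
            best = member.groupby("cog_id")["p_adjusted"].min()
            if (best > self.alpha).any():
                raise ValidationError("DepthCOGSet contains non-significant members")


def column_depth_cogs(
    matrix: COGCountMatrix,
    column: ColumnDesign,
    alpha: float = 0.01,
    test: TestFlavor = "fisher",
) -> DepthCOGSet:
    """Screen one column for COGs varying between at least two depths.

    For every COG and every unordered depth pair the configured exact count
    test compares (COG count, remaining count) between the two datasets; BH
    adjustment is applied jointly across all (COG, pair) hypotheses of the
    column.
    """
    if not 0.0 < alpha < 1.0:
        raise ValidationError(f"alpha must lie in (0, 1), got {alpha}")
    missing = [d for d in column.dataset_ids if d not in matrix.counts.columns]
    if missing:
        raise ValidationError(f"column {column.site}: datasets absent: {missing}")
    counts = matrix.counts
    libs = counts.sum(axis=0)
    cogs = np.asarray(counts.index, dtype=object)

    frames = []
    ids = column.dataset_ids
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            d1, d2 = ids[i], ids[j]
            x1 = counts[d1].to_numpy()
            x2 = counts[d2].to_numpy()
            n1, n2 = int(libs[d1]), int(libs[d2])
            if test == "fisher":
                p = fisher_exact_many(x1, x2, n1, n2)
            elif test == "binomial":
                p = np.array(
                    [binomial_exact_counts(a, b, n1, n2).p_value
                     for a, b in zip(x1, x2)]
                )
            else:
                raise ValidationError(f"unknown test flavor {test!r}")
            with np.errstate(divide="ignore", invalid="ignore"):
                stat = np.where(
                    (x2 / n2) > 0, (x1 / n1) / np.where(x2 > 0, x2 / n2, 1.0), np.inf
                )
                stat[(x1 == 0) & (x2 == 0)] = np.nan
            frames.append(
                pd.DataFrame(
                    {
                        "cog_id": cogs,
                        "pair": f"{d1}|{d2}",
                        "statistic": stat,
                        "p_value": p,
                    }
                )
            )
    table = pd.concat(frames, ignore_index=True)
    table["p_adjusted"] = bh_fdr(table["p_value"].to_numpy())
    hits = table[table["p_adjusted"] <= alpha]
    members = sorted(hits["cog_id"].unique().tolist())
    return DepthCOGSet(site=column.site, cog_ids=members, table=table, alpha=alpha)


def intersect_depth_cogs(
    sets: Sequence[DepthCOGSet],
    presence: COGCountMatrix | None = None,
    columns: Sequence[ColumnDesign] | None = None,
) -> list[str]:
    """COGs depth-related in every column, sorted.

    With ``presence`` and ``columns`` given, additionally require a nonzero
    count in at least one dataset of each column (the presence filter).
    """
    if len(sets) < 2:
        raise ValidationError("need at least 2 depth COG sets to intersect")
    common: set[str] = set(sets[0].cog_ids)
    for s in sets[1:]:
        common &= set(s.cog_ids)
    if presence is not None:
        if columns is None:
            raise ValidationError("presence filter requires the column designs")
        for col in columns:
            sub = presence.counts.loc[:, list(col.dataset_ids)]
            present = set(sub.index[(sub > 0).any(axis=1)])
            common &= present
    return sorted(common)


@dataclass
class Dendrogram:
    """Rooted binary merge tree over datasets with bootstrap node support.

    ``linkage`` is a scipy linkage matrix over ``leaf_names`` (in input
    order); ``support`` maps each internal node's leaf set (frozenset of
    names) to a bootstrap percentage in [0, 100].
    """

    linkage: np.ndarray
    leaf_names: list[str]
    support: dict[frozenset, float] = field(default_factory=dict)

    def clusters(self) -> list[frozenset]:
        """Leaf sets of all internal nodes, in merge order."""
        return _linkage_clusters(self.linkage, self.leaf_names)

    def top_split(self) -> tuple[frozenset, frozenset]:
        """The two leaf sets created by the root (the last merge)."""
        n = len(self.leaf_names)
        tree = sch.to_tree(self.linkage)
        left = frozenset(self.leaf_names[i] for i in tree.left.pre_order())
        right = frozenset(self.leaf_names[i] for i in tree.right.pre_order())
        assert len(left) + len(right) == n
        return left, right

    def to_newick(self, digits: int = 6) -> str:
        """Newick string with bootstrap supports as internal node labels."""
        tree = sch.to_tree(self.linkage)

        def fmt(node, parent_height: float) -> str:
            length = round(float(parent_height - node.dist), digits)
            if node.is_leaf():
                return f"{self.leaf_names[node.id]}:{length}"
            leaves = frozenset(self.leaf_names[i] for i in node.pre_order())
            label = ""
            if leaves in self.support:
                label = f"{self.support[leaves]:g}"
            children = f"{fmt(node.left, node.dist)},{fmt(node.right, node.dist)}"
            return f"({children}){label}:{length}"

        if tree.is_leaf():
            return f"{self.leaf_names[tree.id]};"
        leaves = frozenset(self.leaf_names)
        label = f"{self.support[leaves]:g}" if leaves in self.support else ""
        children = f"{fmt(tree.left, tree.dist)},{fmt(tree.right, tree.dist)}"
        return f"({children}){label};"


def _linkage_clusters(Z: np.ndarray, names: Sequence[str]) -> list[frozenset]:
    n = len(names)
    sets: list[frozenset] = [frozenset([nm]) for nm in names]
    out = []
    for a, b, _, _ in Z:
        merged = sets[int(a)] | sets[int(b)]
        sets.append(merged)
        out.append(merged)
    return out


def cluster_datasets(
    z: pd.DataFrame, n_boot: int = 1000, seed: int = 0
) -> Dendrogram:
    """Average-linkage clustering of datasets with COG-bootstrap support.

    ``z`` holds Z-scored normalized abundances (rows = COGs, columns =
    datasets). Distances are Euclidean over the COG dimensions. Support of
    each internal node is the percentage of ``n_boot`` replicate trees —
    each built from COGs resampled with replacement — whose cluster sets
    contain the node's exact leaf set.
    """
    if z.shape[1] < 3:
        raise ValidationError("clustering needs >= 3 datasets")
    values = z.to_numpy(dtype=float)
    nonconst = values.std(axis=1) > 0
    if nonconst.sum() < 2:
        raise ValidationError("clustering needs >= 2 non-constant COGs")
    values = values[nonconst]
    names = list(z.columns)
    Z = sch.linkage(values.T, method="average", metric="euclidean")
    nodes = _linkage_clusters(Z, names)
    hit = {leaves: 0 for leaves in nodes}
    rng = np.random.default_rng(seed)
    m = values.shape[0]
    for _ in range(n_boot):
        idx = rng.integers(0, m, size=m)
        Zb = sch.linkage(values[idx].T, method="average", metric="euclidean")
        boot_nodes = set(_linkage_clusters(Zb, names))
        for leaves in hit:
            if leaves in boot_nodes:
                hit[leaves] += 1
    support = {leaves: 100.0 * k / n_boot for leaves, k in hit.items()}
    return Dendrogram(linkage=Z, leaf_names=names, support=support)


def photic_label(
    meta: DatasetMetadata, photic_fraction: float = 0.01
) -> Literal["photic", "aphotic"]:
    """Zone call from the PAR rule: photic iff PAR(z) >= fraction × PAR(0).

    Uses the measured ``par_at_depth`` when present, otherwise Beer–Lambert
    decay from ``par_surface`` and ``attenuation_k``.
    """
    from .simulate import par_at_depth as _par

    if meta.par_surface is None:
        raise ValidationError(f"{meta.dataset_id}: par_surface required for zone call")
    if meta.par_at_depth is not None:
        par_z = meta.par_at_depth
    elif meta.attenuation_k is not None:
        par_z = _par(meta.par_surface, meta.attenuation_k, meta.depth_m)
    else:
        raise ValidationError(
            f"{meta.dataset_id}: need par_at_depth or attenuation_k for zone call"
        )
    return "photic" if par_z >= photic_fraction * meta.par_surface else "aphotic"
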