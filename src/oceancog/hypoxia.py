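"""Oxygen-minimum-zone gene content and the hypoxia response threshold.

Candidates come from the same pairwise exact-test screen applied to the OMZ
water column; the photic/aphotic core is excluded so that light-driven
abundance changes do not masquerade as oxygen effects. Remaining candidates
are tested with the exact Wilcoxon rank-sum test between the low-oxygen
datasets (dissolved O2 below a cutoff, default 20 µmol·kg⁻¹) and all
others, BH-adjusted, and the significant set is partitioned into two
abundance-profile groups by a k = 2 cut of the COG-wise average-linkage
tree. Group I is the group with the higher mean abundance in the
low-oxygen datasets (the hypoxia-induced profile).

The oxygen threshold of the group-I response is estimated by a change-point
search: datasets are ordered by O2 and the split maximizing the
standardized mean difference of the group-I mean abundance is chosen; the
reported threshold is the midpoint of the O2 gap at that split.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch

from .core_sets import CoreSets
from .depth import ColumnDesign, column_depth_cogs, TestFlavor
from .errors import DegenerateDataError, ValidationError
from .io import COGCountMatrix
from .normalize import zscore_rows
from .stats import bh_fdr, ranksum_exact_rows

__all__ = [
    "OMZSet",
    "ThresholdEstimate",
    "omz_candidates",
    "exclude_core",
    "omz_cogs",
    "oxygen_threshold",
    "DEFAULT_LOW_O2_CUTOFF",
    "DEFAULT_MIN_SEPARATION",
]

#: dissolved-O2 cutoff (µmol·kg⁻¹) defining the low-oxygen dataset group
DEFAULT_LOW_O2_CUTOFF = 20.0

#: standardized mean difference below which a threshold estimate is flagged
#: as low-confidence; smooth monotone trends rarely exceed ~4 pooled-SD
#: units at their best split, while a genuine switch is far above it
DEFAULT_MIN_SEPARATION = 5.0


@dataclass
class OMZSet:
    """Significant oxygen-associated COGs with group I/II assignment."""

    cog_ids: list[str]
    table: pd.DataFrame  # cog_id, statistic, p_value, p_adjusted, group
    low_o2_dataset_ids: list[str]
    alpha: float

    def __post_init__(self) -> None:
        if len(self.table):
            if (self.table["p_adjusted"] > self.alpha).any():
                raise ValidationError("OMZSet contains non-significant members")
            if not set(self.table["group"]) <= {"I", "II"}:
                raise ValidationError("groups must partition into I and II")

    def group_members(self, group: str) -> list[str]:
        return sorted(self.table.loc[self.table["group"] == group, "cog_id"])


@dataclass(frozen=True)
class ThresholdEstimate:
    """Change-point estimate of the hypoxia response threshold."""

    threshold_o2: float
    separation: float
    confident: bool


def omz_candidates(
    matrix: COGCountMatrix,
    omz_column: ColumnDesign,
    alpha: float = 0.01,
    test: TestFlavor = "fisher",
) -> list[str]:
    """Depth-screen the OMZ column; returns its depth-related COG ids."""
    return column_depth_cogs(matrix, omz_column, alpha=alpha, test=test).cog_ids


def exclude_core(candidates: Sequence[str], core: CoreSets) -> list[str]:
    """Remove the photic/aphotic core from a candidate list (sorted)."""
    excluded = set(core.photic_cogs) | set(core.aphotic_cogs)
    return sorted(set(candidates) - excluded)


def omz_cogs(
    norm: pd.DataFrame,
    candidates: Sequence[str],
    low_o2_ids: Sequence[str],
    alpha: float = 0.05,
) -> OMZSet:
    """Exact rank-sum screen of candidates between low- and high-O2 datasets.

    ``norm`` holds normalized abundances (rows = COGs, columns = datasets).
    BH adjustment runs across the candidates only. Significant COGs are
    split into groups I/II by cutting their average-linkage profile tree at
    k = 2; group I has the higher low-O2 mean abundance.
    """
    if not 0.0 < alpha < 1.0:
        raise ValidationError(f"alpha must lie in (0, 1), got {alpha}")
    low = [d for d in norm.columns if d in set(low_o2_ids)]
    high = [d for d in norm.columns if d not in set(low_o2_ids)]
    if not low or not high:
        raise ValidationError(
            f"need >= 1 dataset in each O2 group (low {len(low)}, high {len(high)})"
        )
    missing = [c for c in candidates if c not in norm.index]
    if missing:
        raise ValidationError(f"candidates absent from matrix: {missing[:5]}")
    candidates = sorted(candidates)
    if not candidates:
        return OMZSet([], _empty_omz_table(), list(low), alpha)
    values = norm.loc[candidates].to_numpy(dtype=float)
    low_idx = [norm.columns.get_loc(d) for d in low]
    # constant rows are uninformative: every assignment ties, p = 1 by the
    # enumeration rule, so they drop out at any alpha
    w, p = ranksum_exact_rows(values[:, :], low_idx)
    q = bh_fdr(p)
    table = pd.DataFrame(
        {"cog_id": candidates, "statistic": w, "p_value": p, "p_adjusted": q}
    )
    sig = table[table["p_adjusted"] <= alpha].reset_index(drop=True)
    sig["group"] = _assign_groups(norm, list(sig["cog_id"]), low)
    return OMZSet(
        cog_ids=sorted(sig["cog_id"]),
        table=sig,
        low_o2_dataset_ids=list(low),
        alpha=alpha,
    )


def _empty_omz_table() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["cog_id", "statistic", "p_value", "p_adjusted", "group"]
    )


def _assign_groups(
    norm: pd.DataFrame, members: list[str], low: list[str]
) -> list[str]:
    if not members:
        return []
    if len(members) == 1:
        return ["I"]
    z = zscore_rows(norm.loc[members], drop_constant=False)
    Z = sch.linkage(z.to_numpy(), method="average", metric="euclidean")
    cut = sch.fcluster(Z, t=2, criterion="maxclust")
    low_means = {}
    for label in np.unique(cut):
        rows = [m for m, c in zip(members, cut) if c == label]
        low_means[label] = float(norm.loc[rows, low].to_numpy().mean())
    group_i = max(low_means, key=lambda k: (low_means[k], -k))
    return ["I" if c == group_i else "II" for c in cut]


def oxygen_threshold(
    group_mean: pd.Series,
    o2: pd.Series,
    min_separation: float = DEFAULT_MIN_SEPARATION,
) -> ThresholdEstimate:
    """Change-point estimate of the O2 level where the response switches on.

    ``group_mean`` is the per-dataset mean abundance of the group-I COGs and
    ``o2`` the per-dataset dissolved oxygen; both indexed by dataset id.
    Over all splits of the O2-ordered datasets the standardized mean
    difference (pooled-SD units, low side minus high side) is maximized;
    the threshold is the midpoint of the O2 gap at the best split.
    """
    common = group_mean.index.intersection(o2.index)
    if len(common) < len(group_mean) or len(common) < len(o2):
        raise ValidationError("group_mean and o2 must be indexed by the same datasets")
    y = group_mean.loc[common].to_numpy(dtype=float)
    x = o2.loc[common].to_numpy(dtype=float)
    if len(np.unique(x)) < 4:
        raise ValidationError("need >= 4 datasets with distinct O2 values")
    if np.all(y == y[0]):
        raise DegenerateDataError("group-I mean abundance is constant; no threshold")
    order = np.argsort(x, kind="stable")
    x_sorted, y_sorted = x[order], y[order]
    best = (-np.inf, np.nan)
    for i in range(1, len(x_sorted)):
        if x_sorted[i] == x_sorted[i - 1]:
            continue  # split must fall in a genuine O2 gap
        lo, hi = y_sorted[:i], y_sorted[i:]
        n1, n2 = len(lo), len(hi)
        var_lo = lo.var(ddof=1) if n1 > 1 else 0.0
        var_hi = hi.var(ddof=1) if n2 > 1 else 0.0
        pooled = np.sqrt(
            ((n1 - 1) * var_lo + (n2 - 1) * var_hi) / max(n1 + n2 - 2, 1)
        )
        diff = lo.mean() - hi.mean()
        if pooled == 0.0:
            sep = 0.0 if diff == 0.0 else np.inf * np.sign(diff)
        else:
            sep = diff / pooled
        if sep > best[0]:
            best = (sep, 0.5 * (x_sorted[i - 1] + x_sorted[i]))
    separation, threshold = best
    return ThresholdEstimate(
        threshold_o2=float(threshold),
        separation=float(separation),
        confident=bool(separation >= min_separation),
    )
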