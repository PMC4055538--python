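"""Photic/aphotic global-core marker COGs and the ratio diagnostic.

From the depth-related COG set, the global core is derived by Welch's
unequal-variance t-test between the photic and aphotic dataset groups with
BH FDR control at a strict level (default 1e-4); significant COGs are split
into photic and aphotic members by the direction of their group means.

The diagnostic for a new dataset is the log2 ratio of its mean normalized
abundance over the photic core to that over the aphotic core. Reference
bands (mean ± 2 SD of the log2 ratios of the reference columns' photic and
aphotic datasets) turn the ratio into a three-way zone call: photic,
aphotic, or intermediate (the facultatively-photic, mixed-layer signature).
Values beyond the extreme side of a band count as that zone — the bands
indicate enrichment, they are not intervals of exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .stats import bh_fdr, welch_t_rows

__all__ = [
    "CoreSets",
    "RatioBands",
    "RatioClassification",
    "derive_core_sets",
    "log2_ratio",
    "reference_bands",
    "classify_zone",
]

ZoneCall = Literal["photic", "aphotic", "intermediate"]


@dataclass
class CoreSets:
    """Disjoint photic and aphotic marker COGs with their Welch statistics.

    ``table`` has one row per significant COG: cog_id, statistic, df,
    p_value, p_adjusted, photic_mean, aphotic_mean, direction.
    """

    photic_cogs: list[str]
    aphotic_cogs: list[str]
    table: pd.DataFrame
    alpha: float

    def __post_init__(self) -> None:
        overlap = set(self.photic_cogs) & set(self.aphotic_cogs)
        if overlap:
            raise ValidationError(f"core sets overlap: {sorted(overlap)}")
        if len(self.table):
            sig = self.table[self.table["p_adjusted"] <= self.alpha]
            if set(sig["cog_id"]) != set(self.photic_cogs) | set(self.aphotic_cogs):
                raise ValidationError("core set membership inconsistent with table")


@dataclass(frozen=True)
class RatioBands:
    """Reference log2-ratio bands: (center, halfwidth = 2 SD) per zone."""

    photic_center: float
    photic_halfwidth: float
    aphotic_center: float
    aphotic_halfwidth: float

    def __post_init__(self) -> None:
        if self.photic_halfwidth < 0 or self.aphotic_halfwidth < 0:
            raise ValidationError("band halfwidths must be non-negative")


@dataclass(frozen=True)
class RatioClassification:
    dataset_id: str
    log2_ratio: float
    zone_call: ZoneCall


def derive_core_sets(
    norm: pd.DataFrame,
    labels: Mapping[str, str],
    alpha: float = 1e-4,
) -> CoreSets:
    """Welch-test every COG between photic and aphotic dataset groups.

    ``norm`` holds normalized abundances (rows = COGs, columns = datasets);
    ``labels`` maps every column to "photic" or "aphotic" (each group needs
    >= 2 datasets). COGs with BH-adjusted p <= alpha enter the core;
    direction follows the group means. Constant COGs are never significant
    (their p is 1 by construction).
    """
    if not 0.0 < alpha < 1.0:
        raise ValidationError(f"alpha must lie in (0, 1), got {alpha}")
    unknown = [d for d in norm.columns if d not in labels]
    if unknown:
        raise ValidationError(f"datasets without zone label: {unknown}")
    photic_ds = [d for d in norm.columns if labels[d] == "photic"]
    aphotic_ds = [d for d in norm.columns if labels[d] == "aphotic"]
    if len(photic_ds) < 2 or len(aphotic_ds) < 2:
        raise ValidationError(
            f"each zone needs >= 2 datasets (photic {len(photic_ds)}, "
            f"aphotic {len(aphotic_ds)})"
        )
    X = norm.loc[:, photic_ds].to_numpy(dtype=float)
    Y = norm.loc[:, aphotic_ds].to_numpy(dtype=float)
    t, df, p = welch_t_rows(X, Y)
    q = bh_fdr(p)
    table = pd.DataFrame(
        {
            "cog_id": np.asarray(norm.index, dtype=object),
            "statistic": t,
            "df": df,
            "p_value": p,
            "p_adjusted": q,
            "photic_mean": X.mean(axis=1),
            "aphotic_mean": Y.mean(axis=1),
        }
    )
    table["direction"] = np.where(
        table["photic_mean"] > table["aphotic_mean"], "photic", "aphotic"
    )
    sig = table[table["p_adjusted"] <= alpha]
    photic = sorted(sig.loc[sig["direction"] == "photic", "cog_id"])
    aphotic = sorted(sig.loc[sig["direction"] == "aphotic", "cog_id"])
    return CoreSets(
        photic_cogs=photic,
        aphotic_cogs=aphotic,
        table=sig.reset_index(drop=True),
        alpha=alpha,
    )


def log2_ratio(
    norm_column: pd.Series, core: CoreSets, pseudocount: float = 0.5
) -> float:
    """log2 of (mean photic-core abundance + pc) / (mean aphotic-core + pc).

    The pseudocount (default 0.5 normalized-abundance units) guards against
    zero aphotic means on sparse inputs.
    """
    if not core.photic_cogs or not core.aphotic_cogs:
        raise ValidationError("both core sets must be non-empty")
    if pseudocount < 0:
        raise ValidationError("pseudocount must be non-negative")
    missing = [
        c for c in (*core.photic_cogs, *core.aphotic_cogs)
        if c not in norm_column.index
    ]
    if missing:
        raise ValidationError(f"core COGs absent from profile: {missing[:5]}")
    pm = float(norm_column.loc[core.photic_cogs].mean())
    am = float(norm_column.loc[core.aphotic_cogs].mean())
    num, den = pm + pseudocount, am + pseudocount
    if den == 0.0:
        raise ValidationError("aphotic mean + pseudocount is zero")
    return float(np.log2(num / den))


def reference_bands(
    ratios: Mapping[str, float], labels: Mapping[str, str]
) -> RatioBands:
    """mean ± 2·SD bands of reference log2 ratios per zone label."""
    groups: dict[str, list[float]] = {"photic": [], "aphotic": []}
    for ds, r in ratios.items():
        z = labels.get(ds)
        if z not in groups:
            raise ValidationError(f"dataset {ds!r} lacks a photic/aphotic label")
        groups[z].append(float(r))
    for z, vals in groups.items():
        if len(vals) < 2:
            raise ValidationError(f"need >= 2 reference datasets per zone ({z})")
    p = np.array(groups["photic"])
    a = np.array(groups["aphotic"])
    return RatioBands(
        photic_center=float(p.mean()),
        photic_halfwidth=2.0 * float(p.std(ddof=1)),
        aphotic_center=float(a.mean()),
        aphotic_halfwidth=2.0 * float(a.std(ddof=1)),
    )


def classify_zone(log2_ratio_value: float, bands: RatioBands) -> ZoneCall:
    """Three-way zone call from the reference bands.

    Photic if the value lies within the photic band or above it; aphotic if
    within the aphotic band or below it; intermediate otherwise, including
    the ambiguous case where overlapping bands both contain the value.
    """
    if not bands.photic_center > bands.aphotic_center:
        raise ValidationError(
            "bands are uninformative: photic center must exceed aphotic center"
        )
    in_photic = log2_ratio_value >= bands.photic_center - bands.photic_halfwidth
    in_aphotic = log2_ratio_value <= bands.aphotic_center + bands.aphotic_halfwidth
    if in_photic and in_aphotic:
        return "intermediate"
    if in_photic:
        return "photic"
    if in_aphotic:
        return "aphotic"
    return "intermediate"
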