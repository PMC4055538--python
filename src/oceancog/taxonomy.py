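"""Phylum-level summaries of per-read best-hit taxonomy for core COGs.

Reads are restricted to a COG list and a dataset list, Eukarya and
unidentified assignments are discarded, and the remainder is counted per
(phylum, COG, dataset). Downstream summaries rank phyla by mean per-dataset
total count and report each phylum's share of the retained reads. Counts
are raw, not normalized.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .errors import ValidationError
from .io import validate_read_table

__all__ = ["PhylumCountTable", "summarize_phyla", "top_phyla", "phylum_share"]


@dataclass
class PhylumCountTable:
    """Raw counts on (phylum, cog_id, dataset_id) axes, Eukarya-free.

    ``counts`` is a long-format DataFrame with columns phylum, cog_id,
    dataset_id, count; ``n_retained`` is the number of reads kept after
    discarding Eukarya and unidentified assignments and restricting to the
    requested COGs and datasets.
    """

    counts: pd.DataFrame
    n_retained: int

    def __post_init__(self) -> None:
        required = {"phylum", "cog_id", "dataset_id", "count"}
        if not required <= set(self.counts.columns):
            raise ValidationError(f"phylum table needs columns {sorted(required)}")
        if len(self.counts) and (self.counts["count"] < 0).any():
            raise ValidationError("phylum counts must be non-negative")
        if int(self.counts["count"].sum()) != self.n_retained:
            raise ValidationError("phylum counts do not sum to the retained total")

    def totals_by_phylum(self) -> pd.Series:
        if not len(self.counts):
            return pd.Series(dtype=int)
        return self.counts.groupby("phylum")["count"].sum().sort_index()

    def wide(self, index: str = "phylum", columns: str = "dataset_id") -> pd.DataFrame:
        """Heatmap-ready pivot (summing over the remaining axis)."""
        if not len(self.counts):
            return pd.DataFrame()
        return (
            self.counts.pivot_table(
                index=index, columns=columns, values="count", aggfunc="sum",
                fill_value=0,
            )
            .astype(int)
        )


def summarize_phyla(
    reads: pd.DataFrame,
    core_cogs: Sequence[str],
    datasets: Sequence[str] | None = None,
) -> PhylumCountTable:
    """Count retained reads per (phylum, COG, dataset).

    Reads whose superkingdom is Eukarya or unidentified, or whose phylum is
    empty, are discarded; reads outside ``core_cogs`` (and outside
    ``datasets`` when given) are excluded before counting.
    """
    validate_read_table(reads)
    mask = reads["cog_id"].isin(set(core_cogs))
    if datasets is not None:
        mask &= reads["dataset_id"].isin(set(datasets))
    sub = reads[mask]
    kept = sub[
        ~sub["superkingdom"].isin(["Eukarya", "unidentified"])
        & (sub["phylum"] != "")
    ]
    if not len(kept):
        return PhylumCountTable(
            pd.DataFrame(columns=["phylum", "cog_id", "dataset_id", "count"]), 0
        )
    counts = (
        kept.groupby(["phylum", "cog_id", "dataset_id"])
        .size()
        .rename("count")
        .reset_index()
    )
    return PhylumCountTable(counts, int(len(kept)))


def top_phyla(table: PhylumCountTable, n: int = 10) -> list[str]:
    """Phyla ranked by mean per-dataset total count, descending.

    Ties break lexicographically; at most ``n`` names are returned.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if not len(table.counts):
        return []
    per_dataset = table.counts.pivot_table(
        index="phylum", columns="dataset_id", values="count", aggfunc="sum",
        fill_value=0,
    )
    means = per_dataset.mean(axis=1)
    ranked = means.sort_index().sort_values(ascending=False, kind="stable")
    return ranked.index[:n].tolist()


def phylum_share(table: PhylumCountTable) -> dict[str, float]:
    """Fraction of retained reads contributed by each phylum (sums to 1)."""
    totals = table.totals_by_phylum()
    grand = int(totals.sum()) if len(totals) else 0
    if grand == 0:
        raise ValidationError("phylum table is empty; shares undefined")
    return {ph: float(c) / grand for ph, c in totals.items()}
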