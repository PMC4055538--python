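"""End-to-end orchestration of the depth/oxygen COG profiling analysis.

Stage order mirrors the analysis the package implements:

1. rarefy all datasets to a common depth (the smallest library by default);
2. screen each reference water column for depth-related COGs and intersect;
3. cluster all datasets on the intersected set with bootstrap support;
4. derive the photic/aphotic core marker sets (Welch + BH);
5. compute per-dataset log2 photic:aphotic ratios, reference bands and
   zone calls;
6. identify OMZ-associated COGs and estimate the oxygen threshold;
7. summarize per-read taxonomy at the phylum level for both core sets.

:func:`run_pipeline` works on in-memory objects and returns a
:class:`PipelineResult`; :func:`run_all` adds file I/O around it and writes
result tables, the dendrogram (newick) and a machine-readable JSON summary
into a run directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .core_sets import (
    CoreSets,
    RatioBands,
    classify_zone,
    derive_core_sets,
    log2_ratio,
    reference_bands,
)
from .depth import (
    ColumnDesign,
    Dendrogram,
    DepthCOGSet,
    cluster_datasets,
    column_depth_cogs,
    intersect_depth_cogs,
    photic_label,
)
from .errors import DegenerateDataError, ValidationError
from .hypoxia import (
    DEFAULT_LOW_O2_CUTOFF,
    OMZSet,
    ThresholdEstimate,
    exclude_core,
    omz_candidates,
    omz_cogs,
    oxygen_threshold,
)
from .io import (
    COGCountMatrix,
    DatasetMetadata,
    read_cog_counts,
    read_metadata,
    read_read_assignments,
    write_result,
)
from .normalize import subsample_counts, to_normalized, zscore_rows
from .taxonomy import PhylumCountTable, phylum_share, summarize_phyla

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "run_all"]


@dataclass
class PipelineConfig:
    """All knobs of the analysis, defaulting to the study thresholds.

    Significance levels: 0.01 for the per-column depth screen, 1e-4 for the
    photic/aphotic core derivation, 0.05 for the OMZ rank-sum screen; the
    low-oxygen group is defined by dissolved O2 < 20 µmol·kg⁻¹ and the
    photic zone by PAR >= 1% of its surface value.
    """

    counts_path: str | None = None
    metadata_path: str | None = None
    reads_path: str | None = None
    reference_sites: tuple[str, ...] = ("atlantis", "aloha", "bats")
    omz_site: str = "iquique"
    alpha_depth: float = 0.01
    alpha_core: float = 1e-4
    alpha_omz: float = 0.05
    test: str = "fisher"
    n_boot: int = 1000
    seed: int = 0
    subsample_target: int | None = None  # None = smallest library ("auto")
    low_o2_cutoff: float = DEFAULT_LOW_O2_CUTOFF
    photic_par_fraction: float = 0.01
    pseudocount: float = 0.5
    top_n_phyla: int = 10

    def __post_init__(self) -> None:
        for name in ("alpha_depth", "alpha_core", "alpha_omz"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValidationError(f"{name} must lie in (0, 1), got {v}")
        if not 0.0 < self.photic_par_fraction < 1.0:
            raise ValidationError("photic_par_fraction must lie in (0, 1)")
        if self.n_boot < 1:
            raise ValidationError("n_boot must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "reference_sites" in data:
            data["reference_sites"] = tuple(data["reference_sites"])
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    """Everything the pipeline computes, stage by stage."""

    config: PipelineConfig
    subsampled: COGCountMatrix
    zone_labels: dict[str, str]
    depth_sets: list[DepthCOGSet]
    intersected_cogs: list[str]
    dendrogram: Dendrogram
    core: CoreSets
    ratios: pd.DataFrame  # dataset_id, log2_photic_aphotic, linear_aphotic_photic, zone_call
    bands: RatioBands
    omz: OMZSet
    group1_means: pd.Series
    threshold: ThresholdEstimate | None
    photic_taxa: PhylumCountTable | None = None
    aphotic_taxa: PhylumCountTable | None = None

    def summary(self) -> dict:
        out = {
            "config_hash": self.config.config_hash(),
            "seed": self.config.seed,
            "n_datasets": len(self.subsampled.dataset_ids),
            "subsample_target": int(self.subsampled.library_size.iloc[0]),
            "depth_cogs_per_column": {
                s.site: len(s.cog_ids) for s in self.depth_sets
            },
            "n_intersected_depth_cogs": len(self.intersected_cogs),
            "n_core_photic": len(self.core.photic_cogs),
            "n_core_aphotic": len(self.core.aphotic_cogs),
            "ratio_bands": dataclasses.asdict(self.bands),
            "zone_calls": dict(
                zip(self.ratios["dataset_id"], self.ratios["zone_call"])
            ),
            "n_omz_cogs": len(self.omz.cog_ids),
            "omz_group_sizes": {
                g: int((self.omz.table["group"] == g).sum()) for g in ("I", "II")
            },
        }
        if self.threshold is not None:
            out["o2_threshold_estimate"] = dataclasses.asdict(self.threshold)
        if self.photic_taxa is not None and self.photic_taxa.n_retained:
            out["photic_phylum_share"] = phylum_share(self.photic_taxa)
        if self.aphotic_taxa is not None and self.aphotic_taxa.n_retained:
            out["aphotic_phylum_share"] = phylum_share(self.aphotic_taxa)
        return out


def _column_designs(
    metadata: Sequence[DatasetMetadata], sites: Sequence[str]
) -> list[ColumnDesign]:
    by_site: dict[str, list[DatasetMetadata]] = {}
    for m in metadata:
        by_site.setdefault(m.site, []).append(m)
    designs = []
    for site in sites:
        if site not in by_site:
            raise ValidationError(f"site {site!r} absent from metadata")
        members = sorted(by_site[site], key=lambda m: m.depth_m)
        designs.append(
            ColumnDesign(site=site, dataset_ids=tuple(m.dataset_id for m in members))
        )
    return designs


def run_pipeline(
    matrix: COGCountMatrix,
    metadata: Sequence[DatasetMetadata],
    config: PipelineConfig,
    reads: pd.DataFrame | None = None,
) -> PipelineResult:
    """Execute the full analysis on in-memory inputs."""
    meta_by_id = {m.dataset_id: m for m in metadata}
    missing = [d for d in matrix.dataset_ids if d not in meta_by_id]
    if missing:
        raise ValidationError(f"metadata missing for datasets: {missing}")

    zone_labels = {
        d: (
            meta_by_id[d].zone_label
            if meta_by_id[d].zone_label != "unset"
            else photic_label(meta_by_id[d], config.photic_par_fraction)
        )
        for d in matrix.dataset_ids
    }

    target = config.subsample_target
    if target is None:
        target = int(matrix.counts.sum(axis=0).min())
    sub = subsample_counts(matrix, target, seed=config.seed)
    norm = to_normalized(sub, per_10k=False)

    ref_columns = _column_designs(metadata, config.reference_sites)
    depth_sets = [
        column_depth_cogs(sub, col, alpha=config.alpha_depth, test=config.test)
        for col in ref_columns
    ]
    intersected = intersect_depth_cogs(depth_sets)
    if len(intersected) < 2:
        raise ValidationError(
            "fewer than 2 COGs are depth-related in all reference columns"
        )

    z = zscore_rows(norm.loc[intersected], drop_constant=True)
    dendro = cluster_datasets(z, n_boot=config.n_boot, seed=config.seed)

    core = derive_core_sets(norm.loc[intersected], zone_labels, alpha=config.alpha_core)
    if not core.photic_cogs or not core.aphotic_cogs:
        raise ValidationError(
            "core derivation produced an empty photic or aphotic set; "
            "cannot compute ratio diagnostics"
        )

    ratio_values = {
        d: log2_ratio(norm[d], core, pseudocount=config.pseudocount)
        for d in norm.columns
    }
    ref_datasets = [d for col in ref_columns for d in col.dataset_ids]
    bands = reference_bands(
        {d: ratio_values[d] for d in ref_datasets},
        {d: zone_labels[d] for d in ref_datasets},
    )
    ratios = pd.DataFrame(
        {
            "dataset_id": list(norm.columns),
            "log2_photic_aphotic": [ratio_values[d] for d in norm.columns],
            "linear_aphotic_photic": [
                float(2.0 ** -ratio_values[d]) for d in norm.columns
            ],
            "zone_call": [
                classify_zone(ratio_values[d], bands) for d in norm.columns
            ],
        }
    )

    omz_column = _column_designs(metadata, [config.omz_site])[0]
    candidates = omz_candidates(
        sub, omz_column, alpha=config.alpha_depth, test=config.test
    )
    candidates = exclude_core(candidates, core)
    low_ids = [
        d for d in norm.columns if meta_by_id[d].do_umol_kg < config.low_o2_cutoff
    ]
    omz = omz_cogs(norm, candidates, low_ids, alpha=config.alpha_omz)
    threshold = None
    group1 = omz.group_members("I")
    if group1:
        group1_means = norm.loc[group1].mean(axis=0)
        o2 = pd.Series({d: meta_by_id[d].do_umol_kg for d in norm.columns})
        try:
            threshold = oxygen_threshold(group1_means, o2)
        except (ValidationError, DegenerateDataError):
            threshold = None
    else:
        group1_means = pd.Series(dtype=float)

    photic_taxa = aphotic_taxa = None
    if reads is not None:
        photic_ds = [d for d in norm.columns if zone_labels[d] == "photic"]
        aphotic_ds = [d for d in norm.columns if zone_labels[d] == "aphotic"]
        photic_taxa = summarize_phyla(reads, core.photic_cogs, photic_ds)
        aphotic_taxa = summarize_phyla(reads, core.aphotic_cogs, aphotic_ds)

    return PipelineResult(
        config=config,
        subsampled=sub,
        zone_labels=zone_labels,
        depth_sets=depth_sets,
        intersected_cogs=intersected,
        dendrogram=dendro,
        core=core,
        ratios=ratios,
        bands=bands,
        omz=omz,
        group1_means=group1_means,
        threshold=threshold,
        photic_taxa=photic_taxa,
        aphotic_taxa=aphotic_taxa,
    )


def run_all(config: PipelineConfig, out_dir: str | Path) -> PipelineResult:
    """Load inputs from the configured paths, run the pipeline, write results."""
    if config.counts_path is None or config.metadata_path is None:
        raise ValidationError("run_all requires counts_path and metadata_path")
    matrix = read_cog_counts(config.counts_path, format="matrix_tsv")
    metadata = read_metadata(config.metadata_path)
    reads = (
        read_read_assignments(config.reads_path) if config.reads_path else None
    )
    result = run_pipeline(matrix, metadata, config, reads=reads)
    write_outputs(result, out_dir)
    return result


def write_outputs(result: PipelineResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in result.depth_sets:
        write_result(s.table, out / f"depth_cogs_{s.site}.tsv")
    pd.Series(result.intersected_cogs, name="cog_id").to_frame().to_csv(
        out / "intersected_cogs.tsv", sep="\t", index=False
    )
    (out / "datasets.nwk").write_text(result.dendrogram.to_newick() + "\n")
    write_result(result.core.table, out / "core_sets.tsv")
    write_result(result.ratios, out / "ratio_classification.tsv")
    write_result(result.omz.table, out / "omz_cogs.tsv")
    if len(result.group1_means):
        g = result.group1_means.rename("group1_mean_abundance").to_frame()
        g.insert(0, "dataset_id", g.index)
        write_result(g.reset_index(drop=True), out / "group1_mean_vs_o2.tsv")
    for name, taxa in (
        ("photic", result.photic_taxa), ("aphotic", result.aphotic_taxa)
    ):
        if taxa is not None and len(taxa.counts):
            write_result(taxa.counts, out / f"phylum_counts_{name}.tsv")
            taxa.wide().to_csv(out / f"phylum_matrix_{name}.tsv", sep="\t")
    with open(out / "summary.json", "w") as fh:
        json.dump(result.summary(), fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
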