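"""Synthetic depth- and oxygen-structured metagenomic count data.

The generator emulates the statistical structure of a global ocean survey:
several water columns sampled at multiple depths plus single-depth sites
(24 datasets in the reference configuration, 12 photic / 12 aphotic by the
1%-of-surface-PAR rule), with

* planted photic- and aphotic-enriched marker COGs (fold change applied to a
  Beer–Lambert-derived photic/aphotic zone assignment),
* oxygen-responsive marker COGs switching on below a planted dissolved-O2
  threshold (a hard switch, which makes threshold recovery well-posed),
* mixed-layer datasets formed as convex mixtures of the photic and aphotic
  expected compositions (the facultatively-photic phenomenon),
* Dirichlet site-to-site compositional noise around a lognormal base
  composition, multinomial read sampling, and
* per-read phylum labels drawn from class-specific phylum profiles, with
  photic markers dominated by two phyla and aphotic markers spread over ten.

Everything is driven by a single integer seed; identical configurations and
seeds give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import exp
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import COGCountMatrix, DatasetMetadata

__all__ = [
    "ColumnSpec",
    "SiteSpec",
    "SimulationConfig",
    "SyntheticTruth",
    "par_at_depth",
    "simulate",
    "reference_config",
    "null_config",
]

#: phyla mapped to superkingdom Archaea; everything else in a profile is Bacteria
ARCHAEAL_PHYLA = frozenset({"Euryarchaeota", "Thaumarchaeota", "Crenarchaeota"})


def par_at_depth(par_surface: float, attenuation_k: float, depth: float) -> float:
    """Beer–Lambert light decay: PAR(z) = PAR(0) · exp(-k z).

    ``attenuation_k`` is the diffuse attenuation coefficient (m⁻¹); the
    conventional photic-zone floor, where PAR reaches 1% of its surface
    value, sits at ``ln(100) / k``.
    """
    if not (np.isfinite(attenuation_k) and attenuation_k > 0):
        raise ValidationError(f"attenuation_k must be positive, got {attenuation_k!r}")
    if not (np.isfinite(par_surface) and par_surface >= 0):
        raise ValidationError("par_surface must be finite and non-negative")
    if not (np.isfinite(depth) and depth >= 0):
        raise ValidationError("depth must be finite and non-negative")
    return par_surface * exp(-attenuation_k * depth)


@dataclass(frozen=True)
class ColumnSpec:
    """One multi-depth water column: site name, light field, depths and O2."""

    site: str
    par_surface: float
    attenuation_k: float
    depths_m: tuple[float, ...]
    o2_umol_kg: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.depths_m) < 2:
            raise ValidationError(f"column {self.site}: needs >= 2 depths")
        if len(self.depths_m) != len(self.o2_umol_kg):
            raise ValidationError(f"column {self.site}: depths and O2 differ in length")

    def dataset_ids(self) -> list[str]:
        return [f"{self.site}_{d:g}" for d in self.depths_m]


@dataclass(frozen=True)
class SiteSpec:
    """A single-depth site."""

    site: str
    depth_m: float
    par_surface: float
    attenuation_k: float
    o2_umol_kg: float

    def dataset_id(self) -> str:
        return f"{self.site}_{self.depth_m:g}"


def _reference_columns() -> tuple[ColumnSpec, ...]:
    return (
        ColumnSpec("atlantis", 1500.0, 0.020, (50, 200, 700, 1500), (200, 180, 150, 120)),
        ColumnSpec("aloha", 2000.0, 0.025, (25, 75, 500, 4000), (210, 205, 160, 130)),
        ColumnSpec("bats", 1800.0, 0.023, (20, 100, 500, 1000), (205, 195, 155, 125)),
        # shallow sunlit zone + persistent OMZ: the upwelling column
        ColumnSpec("iquique", 1200.0, 0.120, (50, 85, 110, 200), (25, 11.0, 4.0, 3.2)),
    )


def _reference_singles() -> tuple[SiteSpec, ...]:
    return (
        SiteSpec("gos1", 2, 2000.0, 0.04, 210),
        SiteSpec("gos2", 2, 2000.0, 0.04, 208),
        SiteSpec("gos3", 2, 2000.0, 0.04, 206),
        SiteSpec("gos4", 2, 2000.0, 0.04, 204),
        SiteSpec("med", 50, 1900.0, 0.02, 202),
        SiteSpec("coastal", 5, 1700.0, 0.05, 209),
        SiteSpec("marmara", 1000, 1500.0, 0.05, 30),
        SiteSpec("prt", 6000, 1600.0, 0.02, 50),
    )


def _reference_phylum_profiles() -> dict[str, dict[str, float]]:
    minor = ("Planctomycetes", "Verrucomicrobia", "Chloroflexi",
             "Euryarchaeota", "Thaumarchaeota")
    photic = {
        "Proteobacteria": 0.46,
        "Cyanobacteria": 0.45,
        "Bacteroidetes": 0.04,
        "Firmicutes": 0.02,
        "Actinobacteria": 0.015,
        **{p: 0.003 for p in minor},
    }
    aphotic_minor = (
        "Chloroflexi", "Planctomycetes", "Actinobacteria", "Bacteroidetes",
        "Firmicutes", "Euryarchaeota", "Thaumarchaeota", "Verrucomicrobia",
        "Acidobacteria",
    )
    aphotic = {"Proteobacteria": 0.50, **{p: 0.5 / 9 for p in aphotic_minor}}
    background = {
        "Proteobacteria": 0.40,
        "Cyanobacteria": 0.12,
        "Bacteroidetes": 0.12,
        "Actinobacteria": 0.08,
        "Firmicutes": 0.07,
        "Euryarchaeota": 0.06,
        "Thaumarchaeota": 0.05,
        "Planctomycetes": 0.04,
        "Chloroflexi": 0.03,
        "Verrucomicrobia": 0.02,
        "Acidobacteria": 0.01,
    }
    o2 = {
        "Proteobacteria": 0.55,
        "Planctomycetes": 0.15,
        "Chloroflexi": 0.10,
        "Euryarchaeota": 0.10,
        "Crenarchaeota": 0.10,
    }
    return {"photic": photic, "aphotic": aphotic, "background": background, "o2": o2}


@dataclass
class SimulationConfig:
    """Reference study design for the synthetic survey.

    Defaults mirror the reference configuration: 3 reference water columns
    and 1 OMZ column of 4 depths each plus 8 single-depth sites (24
    datasets, 12 photic / 12 aphotic), 2000 background COGs, 54 photic / 28
    aphotic / 18 oxygen-responsive planted markers at fold change 4, an O2
    switch at 11 µmol·kg⁻¹, mixed-layer datasets at photic weight λ = 0.4,
    libraries of 50,000–60,000 reads and Dirichlet concentration 2×10⁵
    (≈10% per-COG compositional noise between datasets).
    """

    n_background_cogs: int = 2000
    n_photic_markers: int = 54
    n_aphotic_markers: int = 28
    marker_fold_change: float = 4.0
    n_o2_markers: int = 18
    o2_threshold: float = 11.0
    o2_fold_change: float = 4.0
    mixture_weight_lambda: float = 0.4
    columns: tuple[ColumnSpec, ...] = field(default_factory=_reference_columns)
    single_depth_sites: tuple[SiteSpec, ...] = field(default_factory=_reference_singles)
    mixed_datasets: tuple[str, ...] = ("iquique_50", "iquique_85", "marmara_1000")
    library_size_range: tuple[int, int] = (50_000, 60_000)
    dirichlet_concentration: float = 2e5
    base_lognormal_sigma: float = 0.6
    phylum_profiles: Mapping[str, Mapping[str, float]] = field(
        default_factory=_reference_phylum_profiles
    )
    eukarya_fraction: float = 0.05
    unidentified_fraction: float = 0.02
    photic_par_fraction: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_background_cogs",):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        for name in ("n_photic_markers", "n_aphotic_markers", "n_o2_markers"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0 (0 = null simulation)")
        for name in ("marker_fold_change", "o2_fold_change"):
            if not getattr(self, name) > 1.0:
                raise ValidationError(f"{name} must exceed 1")
        if not 0.0 <= self.mixture_weight_lambda <= 1.0:
            raise ValidationError("mixture_weight_lambda must lie in [0, 1]")
        lo, hi = self.library_size_range
        if lo < 1 or hi < lo:
            raise ValidationError("library_size_range must be a positive (lo, hi) pair")
        if not self.dirichlet_concentration > 0:
            raise ValidationError("dirichlet_concentration must be positive")
        if not 0.0 <= self.eukarya_fraction < 1.0:
            raise ValidationError("eukarya_fraction must lie in [0, 1)")
        if not 0.0 <= self.unidentified_fraction < 1.0:
            raise ValidationError("unidentified_fraction must lie in [0, 1)")
        if self.eukarya_fraction + self.unidentified_fraction >= 1.0:
            raise ValidationError("eukarya + unidentified fractions must stay below 1")
        if not 0.0 < self.photic_par_fraction < 1.0:
            raise ValidationError("photic_par_fraction must lie in (0, 1)")
        if not self.o2_threshold > 0:
            raise ValidationError("o2_threshold must be positive")
        ids = self.dataset_ids()
        if len(ids) != len(set(ids)):
            raise ValidationError("dataset ids are not unique across columns/sites")
        for key in ("photic", "aphotic", "background", "o2"):
            if key not in self.phylum_profiles:
                raise ValidationError(f"phylum_profiles missing class {key!r}")
            total = sum(self.phylum_profiles[key].values())
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(f"phylum profile {key!r} sums to {total}, not 1")
        unknown = set(self.mixed_datasets) - set(ids)
        if unknown:
            raise ValidationError(f"mixed_datasets not in design: {sorted(unknown)}")

    def dataset_ids(self) -> list[str]:
        ids: list[str] = []
        for col in self.columns:
            ids.extend(col.dataset_ids())
        ids.extend(s.dataset_id() for s in self.single_depth_sites)
        return ids

    @property
    def n_cogs(self) -> int:
        return (
            self.n_background_cogs
            + self.n_photic_markers
            + self.n_aphotic_markers
            + self.n_o2_markers
        )


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth for recovery tests."""

    photic_marker_ids: tuple[str, ...]
    aphotic_marker_ids: tuple[str, ...]
    o2_marker_ids: tuple[str, ...]
    zone: Mapping[str, str]  # dataset id -> "photic" / "aphotic" (PAR rule)
    mixture_weight: Mapping[str, float]  # photic weight λ per dataset
    o2_threshold: float
    low_o2_dataset_ids: tuple[str, ...]  # datasets at or below the O2 switch

    def __post_init__(self) -> None:
        sets = [set(self.photic_marker_ids), set(self.aphotic_marker_ids),
                set(self.o2_marker_ids)]
        for i in range(3):
            for j in range(i + 1, 3):
                if sets[i] & sets[j]:
                    raise ValidationError("marker id lists must be pairwise disjoint")


def reference_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The reference 24-dataset configuration with an optional seed/overrides."""
    cfg = SimulationConfig(seed=seed, **overrides)
    cfg.validate()
    return cfg


def null_config(seed: int = 0) -> SimulationConfig:
    """Reference design with no true abundance differences between datasets.

    All marker counts are zero and the Dirichlet concentration is pushed so
    high that every dataset shares the same expected composition: the only
    variation left is multinomial counting noise, which is the null the
    exact count tests assume. (Site-to-site compositional noise is a real
    difference between datasets, not a false-positive source, so it has no
    place in a false-positive calibration.)
    """
    return reference_config(
        seed=seed, n_photic_markers=0, n_aphotic_markers=0, n_o2_markers=0,
        mixed_datasets=(), dirichlet_concentration=1e12,
    )


def _dataset_specs(config: SimulationConfig):
    """Yield (dataset_id, site, depth, par_surface, k, o2) for every dataset."""
    for col in config.columns:
        for depth, o2 in zip(col.depths_m, col.o2_umol_kg):
            yield (f"{col.site}_{depth:g}", col.site, float(depth),
                   col.par_surface, col.attenuation_k, float(o2))
    for s in config.single_depth_sites:
        yield (s.dataset_id(), s.site, float(s.depth_m), s.par_surface,
               s.attenuation_k, float(s.o2_umol_kg))


def simulate(
    config: SimulationConfig, include_reads: bool = True
) -> tuple[COGCountMatrix, list[DatasetMetadata], pd.DataFrame | None, SyntheticTruth]:
    """Draw one synthetic survey from the configured design.

    Returns the count matrix, per-dataset metadata, a per-read assignment
    table with phylum labels (or ``None`` when ``include_reads`` is false),
    and the planted :class:`SyntheticTruth`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    photic_ids = tuple(f"COGP{i:04d}" for i in range(config.n_photic_markers))
    aphotic_ids = tuple(f"COGA{i:04d}" for i in range(config.n_aphotic_markers))
    o2_ids = tuple(f"COGO{i:04d}" for i in range(config.n_o2_markers))
    background_ids = tuple(f"COGB{i:04d}" for i in range(config.n_background_cogs))
    cog_ids = list(photic_ids) + list(aphotic_ids) + list(o2_ids) + list(background_ids)
    n_cogs = len(cog_ids)

    cog_class = np.array(
        ["photic"] * len(photic_ids)
        + ["aphotic"] * len(aphotic_ids)
        + ["o2"] * len(o2_ids)
        + ["background"] * len(background_ids)
    )
    is_photic = cog_class == "photic"
    is_aphotic = cog_class == "aphotic"
    is_o2 = cog_class == "o2"

    base = rng.lognormal(mean=0.0, sigma=config.base_lognormal_sigma, size=n_cogs)

    photic_comp = base.copy()
    photic_comp[is_photic] *= config.marker_fold_change
    photic_comp /= photic_comp.sum()
    aphotic_comp = base.copy()
    aphotic_comp[is_aphotic] *= config.marker_fold_change
    aphotic_comp /= aphotic_comp.sum()

    specs = list(_dataset_specs(config))
    zone: dict[str, str] = {}
    mixture: dict[str, float] = {}
    low_o2: list[str] = []
    metadata: list[DatasetMetadata] = []
    counts = np.zeros((n_cogs, len(specs)), dtype=np.int64)
    lib_sizes = np.zeros(len(specs), dtype=np.int64)
    read_frames: list[pd.DataFrame] = []

    lo, hi = config.library_size_range
    for j, (ds, site, depth, par0, k, o2) in enumerate(specs):
        par_z = par_at_depth(par0, k, depth)
        ds_zone = "photic" if par_z >= config.photic_par_fraction * par0 else "aphotic"
        zone[ds] = ds_zone
        if ds in config.mixed_datasets:
            lam = config.mixture_weight_lambda
        else:
            lam = 1.0 if ds_zone == "photic" else 0.0
        mixture[ds] = lam
        expected = lam * photic_comp + (1.0 - lam) * aphotic_comp
        if o2 <= config.o2_threshold:
            low_o2.append(ds)
            expected = expected.copy()
            expected[is_o2] *= config.o2_fold_change
            expected /= expected.sum()
        p = rng.dirichlet(expected * config.dirichlet_concentration)
        n_reads = int(rng.integers(lo, hi + 1))
        col = rng.multinomial(n_reads, p)
        counts[:, j] = col
        lib_sizes[j] = n_reads
        metadata.append(
            DatasetMetadata(
                dataset_id=ds,
                site=site,
                depth_m=depth,
                do_umol_kg=o2,
                par_surface=par0,
                par_at_depth=par_z,
                attenuation_k=k,
            )
        )
        if include_reads:
            read_frames.append(
                _draw_reads(rng, config, ds, col, cog_ids, cog_class)
            )

    matrix = COGCountMatrix(
        pd.DataFrame(counts, index=pd.Index(cog_ids, name="cog_id"),
                     columns=[s[0] for s in specs]),
        pd.Series(lib_sizes, index=[s[0] for s in specs]),
    )
    truth = SyntheticTruth(
        photic_marker_ids=photic_ids,
        aphotic_marker_ids=aphotic_ids,
        o2_marker_ids=o2_ids,
        zone=zone,
        mixture_weight=mixture,
        o2_threshold=config.o2_threshold,
        low_o2_dataset_ids=tuple(low_o2),
    )
    reads = (
        pd.concat(read_frames, ignore_index=True) if include_reads else None
    )
    return matrix, metadata, reads, truth


def _draw_reads(
    rng: np.random.Generator,
    config: SimulationConfig,
    dataset_id: str,
    col_counts: np.ndarray,
    cog_ids: Sequence[str],
    cog_class: np.ndarray,
) -> pd.DataFrame:
    """Per-read taxonomy for one dataset (vectorized by COG class)."""
    n = int(col_counts.sum())
    cog_idx = np.repeat(np.arange(len(cog_ids)), col_counts)
    classes = cog_class[cog_idx]
    phylum = np.empty(n, dtype=object)
    superkingdom = np.empty(n, dtype=object)

    u = rng.random(n)
    is_euk = u < config.eukarya_fraction
    is_unid = (~is_euk) & (u < config.eukarya_fraction + config.unidentified_fraction)
    normal = ~(is_euk | is_unid)
    phylum[is_euk] = "Eukarya_env"
    superkingdom[is_euk] = "Eukarya"
    phylum[is_unid] = ""
    superkingdom[is_unid] = "unidentified"

    for cls, profile in config.phylum_profiles.items():
        mask = normal & (classes == cls)
        m = int(mask.sum())
        if m == 0:
            continue
        names = list(profile.keys())
        probs = np.array(list(profile.values()), dtype=float)
        probs = probs / probs.sum()
        choice = rng.choice(len(names), size=m, p=probs)
        drawn = np.array(names, dtype=object)[choice]
        phylum[mask] = drawn
        superkingdom[mask] = np.where(
            np.isin(drawn, list(ARCHAEAL_PHYLA)), "Archaea", "Bacteria"
        )

    cog_arr = np.array(cog_ids, dtype=object)[cog_idx]
    return pd.DataFrame(
        {
            "read_id": [f"{dataset_id}_r{i}" for i in range(n)],
            "dataset_id": dataset_id,
            "cog_id": cog_arr,
            "superkingdom": superkingdom,
            "phylum": phylum,
        }
    )
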