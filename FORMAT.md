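# File formats

All tables are tab-separated (TSV), UTF-8, with a header row, `.` as the
decimal separator and no quoting. Floats in result tables are written with
12 significant digits; integer counts round-trip bit-exactly. Empty cells
in optional columns mean "absent".

## COG count matrix (`counts.tsv`)

| column | type | meaning |
| --- | --- | --- |
| `cog_id` (first column) | string | COG / NOG identifier, unique, case-sensitive |
| one column per dataset | non-negative integer | reads assigned to that COG in that dataset |

Library size is taken as the column sum. Missing (COG, dataset) pairs are
zeros, not blanks.

## Dataset metadata (`metadata.tsv`)

| column | type | required | meaning |
| --- | --- | --- | --- |
| `dataset_id` | string | yes | unique dataset identifier |
| `site` | string | yes | sampling site; datasets sharing a site form a water column |
| `depth_m` | float ≥ 0 | yes | sampling depth, meters |
| `do_umol_kg` | float ≥ 0 | yes | dissolved oxygen, µmol·kg⁻¹ |
| `par_surface` | float ≥ 0 | no | PAR at the surface, µmol photons m⁻² s⁻¹ |
| `par_at_depth` | float ≥ 0 | no | measured PAR at the sampling depth |
| `attenuation_k` | float > 0 | no | diffuse attenuation coefficient, m⁻¹ (used when `par_at_depth` is absent) |
| `zone_label` | `photic` / `aphotic` / `unset` | no | pre-assigned zone; `unset` triggers the 1%-PAR rule |

## Read assignments (`reads.tsv`)

| column | type | meaning |
| --- | --- | --- |
| `read_id` | string | unique within a dataset |
| `dataset_id` | string | dataset the read belongs to |
| `cog_id` | string | best-hit COG assignment (empty = unassigned) |
| `superkingdom` | `Bacteria` / `Archaea` / `Eukarya` / `unidentified` | best-hit superkingdom |
| `phylum` | string | best-hit phylum (empty for unidentified reads) |

## Result tables

Stage outputs share a common shape: one row per (COG, hypothesis) or per
COG, with columns drawn from `cog_id`, `pair` (the `datasetA|datasetB`
depth pair of a screening test), `statistic`, `df`, `p_value`,
`p_adjusted` (Benjamini–Hochberg; always ≥ `p_value`), `direction`
(`photic`/`aphotic`), `group` (`I`/`II`), `photic_mean`, `aphotic_mean`.

`ratio_classification.tsv` has per-dataset rows: `dataset_id`,
`log2_photic_aphotic` (log2 of the photic:aphotic core mean-abundance
ratio), `linear_aphotic_photic` (the same ratio in the inverse linear
convention), `zone_call` (`photic`/`aphotic`/`intermediate`).

## Other outputs

* `datasets.nwk` — the dataset dendrogram in newick format; internal node
  labels carry bootstrap support percentages.
* `summary.json` — machine-readable run summary (set sizes, band
  parameters, oxygen-threshold estimate, seeds, config hash).
* `truth.json` (simulator) — planted marker ids, per-dataset zone and
  mixture weight, the planted O2 threshold and the low-O2 dataset ids.
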