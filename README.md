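# guildassembly

Community-assembly analysis for soil fungal functional guilds, built around
the abundance-weighted **β-null-deviation** statistic: observed pairwise
Bray–Curtis dissimilarity is compared against null communities resampled
from a fixed regional species-abundance distribution, and the resulting
(signed) deviation matrix is attributed to plant, edaphic, and spatial
drivers with distance-matrix statistics.

The package contains:

| module | role |
| --- | --- |
| `guildassembly.synthetic_data` | synthetic OTU tables, guild annotations, metadata, plant communities and traits under four known assembly regimes (`neutral`, `heterogeneous_selection`, `homogeneous_selection`, `dispersal_limitation`) |
| `guildassembly.tabular_io` | TSV readers/writers for every artifact (OTU table, annotation, metadata, traits, plant community, distance matrix) and YAML run configuration |
| `guildassembly.guild_partition` | split an OTU table into total / mycorrhizal / saprotrophic / pathotrophic sub-tables from annotation confidence rules |
| `guildassembly.preprocess` | rarefaction (without replacement), sqrt/log10 variable transforms, community-weighted trait means |
| `guildassembly.distances` | Bray–Curtis, standardized 1-D Euclidean attribute distances, haversine geographic distances |
| `guildassembly.null_model` | β-null-deviation (ses or raw mode) plus the one-sample mean-deviation t-test |
| `guildassembly.matrix_stats` | Mantel, partial Mantel, MRM with forward selection, variation partitioning, PERMANOVA, NMDS, quantile-bin Wilcoxon contrasts — all with permutation inference and exact-enumeration modes for small n |
| `guildassembly.pipeline` | end-to-end orchestration per depth-layer × guild stratum with a deterministic manifest |

## CLI

```bash
# simulate a dataset under a known regime
guildassembly simulate --regime heterogeneous_selection --n-sites 10 \
    --seed 1 --out-dir sim/

# guild partition, rarefaction, distances
guildassembly partition --table sim/otu_table.tsv --annotation sim/annotation.tsv --out-dir parts/
guildassembly prep --table parts/total.tsv --rarefy-depth auto --seed 1 --out rare.tsv
guildassembly dist --kind bray --table rare.tsv --out bc.tsv

# the core statistic
guildassembly betadev --table rare.tsv --n-null 999 --seed 1 --out-prefix betadev

# attribution statistics
guildassembly mantel --dx betadev.deviation.tsv --dy bc.tsv --n-perm 999 --seed 1
guildassembly mrm --dy betadev.deviation.tsv --predictor SRL=srl.tsv \
    --predictor space=geo.tsv --forward --alpha 0.05 --seed 1

# everything at once from one config
guildassembly run --config examples/config.yml --out-dir run/
```

The config schema (`examples/config.yml`) takes either an `inputs:` block of
TSV paths (`otu_table`, `annotation`, `metadata`, `plant_community`,
`trait_table`) or a `simulate:` block of scenario parameters, plus
`depth_layer`, `guilds`, `n_null` (default 999), `n_perm` (default 999),
`alpha` (default 0.05), `seed`, `rarefy_depth` (`auto` or an integer),
`deviation_mode` (`ses` default, or `raw`), and `transforms` (sqrt / log10
variable lists). Unknown keys are rejected with a suggestion.

Each run writes, per depth × guild stratum: the signed deviation matrix,
observed Bray–Curtis matrix, NMDS coordinates, and a `summary.json` with the
mean-deviation t-test, Mantel/partial-Mantel table, forward-selected MRM,
variation-partitioning fractions, PERMANOVA, and SRL/FRB category
contrasts — plus a top-level `manifest.json` (version, settings, seeds,
input hashes) and `report.md`. Reruns with the same config and seed are
byte-identical.

## Notes on conventions

* **ses vs raw deviation** — the default deviation is the standardized
  effect size `(observed − null mean) / null SD`; the raw difference
  (bounded in [−1, 1]) is available via `mode="raw"`.
* **Null model** — regional probabilities are the column sums of the
  analysed table; each null sample redraws its observed total multinomially.
  Per-sample totals are preserved; richness is not.
* **Permutations** — response-matrix row/column permutation only, p-values
  smoothed as (count+1)/(n\_perm+1); `method="exact"` enumerates all n!
  permutations.
* **Transforms** — SM, SEC, SAP, NH4N, NO3N are square-root transformed and
  LA, SLA, RL, SRL, RNC log10 transformed by default; trait transforms are
  applied before CWM weighting.
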