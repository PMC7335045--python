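# v2gmap

Promoter Capture-C variant-to-gene mapping: from replicate ATAC-seq peaks
and dual-resolution capture interaction calls to an open-chromatin promoter
interactome, GWAS variant-to-gene assignments, and an empirical resampling
test of overlap with eQTL catalogs.

## The problem

Most GWAS risk variants are non-coding and sit in large LD blocks, so the
associated locus rarely identifies the causal gene. One route to effector
genes is physical: profile open chromatin (ATAC-seq) in a disease-relevant
cell type, map which open regions touch which gene promoters in 3D
(promoter-focused Capture-C on DpnII fragments), and ask which genes the
accessible risk variants actually contact. `v2gmap` implements that
integration as a tested, reusable pipeline for anyone with peak calls,
CHiCAGO-style interaction calls (ibed), and sentinel/proxy SNP tables —
exercised end-to-end on a synthetic generator with known ground truth.

## What it computes

- **Reference OCR atlas** — replicate narrowPeak/BED sets are union-merged
  per cell type, merged peaks in < 2 biological replicates are removed,
  cell types are merged into reference open-chromatin regions (OCRs),
  blacklist overlaps are dropped, and an OCR is called *open* in a cell
  type if ≥ 1 replicate peak overlaps it. A CPM filter (≥ 1.5 CPM in ≥ 50%
  of samples) reproduces the pre-filter used before differential testing.
- **Fragment maps** — in-silico DpnII digests (GATC motif) at 1-fragment
  resolution and 4-fragment in-silico concatenations, with promoter windows
  (−1500/+500 bp of TSS, strand-aware) and bait flags.
- **OCR interactome** — significant interactions (score ≥ 5) from both
  resolutions are merged keeping the max score per coordinate-identical
  record and projected onto OCR pairs: a pair is emitted when a significant
  call links fragments overlapping both OCRs, both are open in the cell
  type, and at least one end overlaps a promoter window (prOCR).
- **Variant-to-gene pairs** — proxies filtered by r² (≥ 0.8 strict,
  ≥ 0.4 relaxed) and located in open chromatin are assigned to genes by two
  routes: promoter residency (SNP inside a promoter-window OCR) and
  interaction (the SNP's OCR contacts a promoter OCR). Each variant with
  interaction-route genes is classified against its nearest gene (by TSS
  distance): `nearest_only`, `nearest_plus_distant`, or `skip`.
- **Enrichment statistics** — an empirical resampling test of
  sentinel-gene overlap between the physical map and an eQTL catalog
  (equal-size draws from the ± 5 Mb candidate-gene pool, add-one
  Monte-Carlo p), and a one-sided Fisher exact feature-enrichment statistic
  with sample odds ratios.

## Worked example

Generate a synthetic study at the default (study-scale) configuration and
run every stage:

```bash
v2gmap run-all --workdir demo --seed 1 --simulate
```

or in Python:

```python
from v2gmap.simulate import SimulationConfig, simulate_study, write_study
from v2gmap.pipeline import Pipeline, PipelineParams

study = simulate_study(SimulationConfig(seed=1))
write_study(study, "demo")
pipe = Pipeline("demo", params=PipelineParams(seed=1, empirical_reps=100_000))
pipe.run("run-all")
```

The run logs the filter funnel and writes `demo/results/`. With seed 1 the
category summary and eQTL test report:

```
nearest_only          8.4 %   (21 of 250 categorized variants)
nearest_plus_distant 29.2 %   (73 of 250)
skip                 62.4 %   (156 of 250)
eQTL overlap: observed 19, null mean 1.78, fold 10.7, p ≈ 1e-05
```

Meaning: of 250 accessible proxy SNPs with interaction-derived genes, only
~8% contact exclusively their nearest gene — the majority skip it entirely
— and the physical map shares 19 sentinel-gene pairs with the eQTL list
where random equal-size draws from the 5 Mb pool share ~1.8, a ~10-fold
enrichment. These recovered values match the mix and overlap the generator
planted (8.5/29/62.5% and 19 pairs).

## Layout

| module                | contents |
|-----------------------|----------|
| `v2gmap.genome`       | intervals, DpnII fragment maps, promoter windows, baits |
| `v2gmap.atlas`        | consensus peaks, reference OCRs, openness, CPM filter |
| `v2gmap.interactions` | ibed parsing, resolution merging, OCR projection |
| `v2gmap.variants`     | r² filtering, SNP→gene routes, nearest-gene categories |
| `v2gmap.enrichment`   | resampling overlap test, Fisher feature enrichment |
| `v2gmap.simulate`     | seeded synthetic-study generator with truth tables |
| `v2gmap.pipeline` / `v2gmap.cli` | stage orchestration, manifest, CLI |

File formats are documented in [FORMATS.md](FORMATS.md); the scientific
background and design decisions in [docs/methods.md](docs/methods.md).
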