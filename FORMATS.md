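# File formats

All files are plain text, tab-separated unless noted. Coordinates in BED
and rmap/baitmap files are 0-based half-open; `pos_1based` / `tss_1based`
columns are 1-based and converted on read.

## Inputs (work directory)

| file | format |
|------|--------|
| `digest_1frag.rmap`, `digest_4frag.rmap` | no header: `chrom  start  end  fragment_id` |
| `digest_1frag.baitmap`, `digest_4frag.baitmap` | bait fragments only: rmap columns + `annotation` |
| `transcripts.tsv` | header: `transcript_id  gene_id  gene_symbol  chrom  strand  tss_1based  biotype` |
| `chrom_lengths.tsv` | header: `chrom  length` |
| `peaks_<celltype>_rep<i>.bed` | BED3+; columns beyond 3 ignored (narrowPeak accepted) |
| `blacklist.bed` | BED3; optional |
| `ocr_counts.tsv` | header row of sample ids; first column `ocr_id`; integer counts |
| `library_sizes.tsv` | header: `sample_id  library_size` |
| `interactions_<celltype>_<res>frag.ibed` | 10-column ibed with header: `bait_chr bait_start bait_end bait_name otherEnd_chr otherEnd_start otherEnd_end otherEnd_name N_reads score` |
| `proxies.tsv` | header: `rsid  chrom  pos_1based  sentinel_rsid  r2` (sentinels may appear as their own proxies with r2 = 1) |
| `sentinels.tsv` | header: `rsid  chrom  pos_1based` |
| `eqtl_pairs.tsv` | header: `sentinel_rsid  gene_symbol  source_label` |

## Outputs (`<workdir>/results/` by default)

| file | contents |
|------|----------|
| `atlas.bed` | reference OCRs; name field `ocr_id|open=<cts>|support=<ct=n;...>` |
| `atlas_summary.json` | OCR counts, per-cell-type openness, CPM-filter tally |
| `ocr_interactions.tsv` | `ocr_a ocr_b cell_type score resolutions class_a class_b distance` |
| `interaction_summary.json` | per-cell-type interaction counts and distance quantiles |
| `v2g_pairs.tsv` | `proxy_rsid sentinel_rsid r2 gene_id gene_symbol route cell_type ocr_id partner_ocr_id category` |
| `categories.tsv` | `proxy_rsid nearest_gene category` |
| `category_summary.json` | counts and fractions per category |
| `eqtl_test.json` | observed, reps, null mean, fold enrichment, p, seed, draw size, histogram |
| `eqtl_null_histogram.tsv` | `overlap  count` |
| `manifest.json` | params + config hash, per-stage input SHA-256 checksums, output paths, timestamps |
| `truth.json` | (simulate only) planted proxies/categories/genes, eQTL overlap pairs, OCR openness |
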