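# svmodes

Analysis toolkit for somatic structural variants (SVs) in tumor cohorts:

- **cohort I/O** — VCF (BND + symbolic ALT) and BEDPE ingestion normalized
  to 0-based half-open breakends with junction orientations, BED/TSV/FASTA
  readers and writers, coverage/purity sample QC, and mutational-signature
  presence calls (contribution ≥ 0.06).
- **consensus merging** — multi-caller merging requiring ≥2 callers
  agreeing on type, orientation, and per-end breakpoint distance ≤1 kb;
  connected-component clustering with per-end lower-median coordinates and
  a ≥30 bp size filter (strict-clique mode behind a flag).
- **SV landscape** — per-sample burden tables, Mann-Whitney / KS group
  comparisons with Benjamini-Hochberg adjustment, and log2 size spectra
  with small-event (<10 kb) fractions.
- **chromothripsis context** — event summaries from externally called
  regions and a chromosome-level enrichment test that reshuffles
  breakpoints proportionally to chromosome length.
- **TAD disruption** — boundary-affecting SVs (intrachromosomal, <2 Mb,
  span fully containing a boundary), functional TAD adjacency, boundary
  recurrence with fragile-site distances, oncogene/tumor-suppressor
  adjacency 2×2 tables, and a size-preserving shuffle permutation null.
- **repair mechanisms** — junction microhomology computed from the
  reference for all four junction orientation classes, NHEJ (≤1 bp) /
  MMEJ (2–9 bp) / SSA (≥10 bp) classification, and per-sample
  pseudocounted NHEJ:SSA ratios.
- **subtype enrichment** — exact 2×2 inference (conditional-MLE odds
  ratio, exact conditional confidence intervals by test inversion, and
  the two-sided probability-method p), gene-level SV enrichment with
  non-duplication / complex-only filters, and covariate-adjusted burden
  regression.
- **expression coupling** — geometric-mean complex scores, Fisher-z
  comparison of group correlations, downsampling analysis, and per-gene
  z-score percentiles for SV-bearing samples.
- **synthetic cohorts** — a generator that emits a random genome with a
  TAD/gene scaffold, multi-caller call sets with jitter/dropout/false
  positives, clustered chromothripsis events, physically planted junction
  microhomologies, signature labels with burden/mechanism shifts, and a
  correlated expression matrix — all recorded in a machine-readable truth
  ledger used as the test oracle.

## CLI

All stages are exposed as `svmodes` subcommands and chain through
versioned TSV/BEDPE files:

```sh
svmodes simulate --out demo --seed 3 --scale 0.1      # synthetic cohort
svmodes ingest --vcf demo/calls/acral_000.caller1.vcf \
    --caller caller1 --sample acral_000 --out acral_000.caller1.bedpe
svmodes qc --meta demo/sample_meta.tsv --out meta_qc.tsv
svmodes merge --bedpe acral_000.caller1.bedpe ... --out consensus.bedpe
svmodes landscape --consensus consensus.bedpe --meta meta_qc.tsv --out-prefix land
svmodes tad --consensus consensus.bedpe --boundaries demo/boundaries.bed \
    --tads demo/tads.bed --genes demo/genes.bed --fragile demo/fragile_sites.bed \
    --chrom-sizes demo/genome.chrom.sizes --n-perm 1000 --seed 7 --out-prefix tad
svmodes ct-enrich --consensus consensus.bedpe --regions demo/chromothripsis_regions.tsv \
    --chrom-sizes demo/genome.chrom.sizes --n-perm 1000 --seed 7 --out ct.tsv
svmodes repair --consensus consensus.bedpe --fasta demo/genome.fa --out repair.tsv
svmodes enrich --consensus consensus.bedpe --genes demo/genes.bed \
    --meta meta_qc.tsv --group-by subtype --filter non-duplication --out enrich.tsv
svmodes regress --consensus consensus.bedpe --meta meta_qc.tsv --signatures 3 --out reg.tsv
svmodes express --expr expr.tsv --groups groups.tsv --n-draws 10000 --seed 7 --out express.json
```

## Conventions

Coordinates are 0-based half-open everywhere internally (VCF converted
on read).  Breakend orientation `+` means the junction retains the
sequence left of the position, `-` the sequence right of it; DEL
junctions are `(+,-)`, DUP `(-,+)`, INV `(+,+)`/`(-,-)`, TRA any pair
(including intrachromosomal TRA).
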