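# dgetag

Tag-based digital gene expression (DGE) profiling for organisms without a
sequenced genome. Expression is quantified not by aligning whole reads to a
genome but by counting short restriction-anchored cDNA *tags*: NlaIII cuts
each transcript's cDNA at CATG, MmeI releases the 17 bases downstream, and
sequencing yields millions of 21 bp tags (`CATG` + 17 variable bases) whose
counts proxy transcript abundance. `dgetag` implements the complete analysis
for this protocol, aimed at transcriptomics workflows where one deeply
sequenced tag library per condition must be cleaned, mapped to a de novo
transcript reference, and compared between conditions — plus a
protocol-faithful simulator so every stage can be validated against known
ground truth.

## What it computes

- **Virtual tag database** — all `CATG+17` windows of the reference
  transcripts (sense strand, overlapping sites included), indexed for exact
  and 1-mismatch lookup; tags hitting several genes are classified ambiguous.
- **Cleaning** — 49 bp raw reads are reduced to their 21 bp tag; adaptor-only
  reads (no CATG anchor), empty reads and reads with `N` inside the tag are
  discarded with full accounting (`raw = adaptor + empty + N + clean`).
- **Mapping** — exact matches first; unmatched tags are queried against the
  51 single-substitution neighbours of the 17 variable bases (the anchor is
  enzymatically fixed). Only *unambiguous* tags (gene set of size 1)
  contribute to gene counts.
- **Normalization** — TPM, transcripts per million **clean** tags:
  `tpm = count / N_clean × 10⁶`.
- **Differential expression** — the Audic–Claverie exact test for a count
  observed in two unreplicated libraries of sizes N₁, N₂:

  `P(y|x) = (N₂/N₁)^y (x+y)! / (x! y! (1+N₂/N₁)^(x+y+1))`

  evaluated through its negative-binomial / incomplete-beta representation
  (stable for counts ≫ 10⁵); two-sided p by doubling the smaller tail,
  Benjamini–Hochberg FDR, and the call rule **FDR ≤ 0.001 and
  |log₂ ratio| ≥ 1** (zero counts floored at 1 tag-equivalent for the ratio
  only). Up-regulated genes across a time course are classified by earliest
  significant timepoint (phase 1/2/3).
- **Saturation** — detected genes versus subsampled depth (nested
  hypergeometric subsampling over the tag multiset).
- **Enrichment** — exact upper-tail hypergeometric test of each annotation
  term among DEGs against the annotated background (the k/n vs K/N
  contingency), BH q-values, significance at Q ≤ 0.05; plus
  annotation-coverage arithmetic.
- **Simulator** — synthetic unigene references (configurable CATG-free
  dropout fraction), log-normal heavy-tailed expression with planted
  differential effects, and raw 49 bp reads with substitution errors,
  adaptor-only and N-contaminated reads at configurable rates, with per-read
  provenance recorded for truth-based validation.

## Worked example

A complete synthetic study from one config:

```yaml
# config.yaml
outdir: out
seed: 7
simulate:
  n_genes: 500
  mean_length: 400
  conditions: [control, 1h, 5h, 24h]
  de_fraction: 0.1
  effect_log2: 3.0
  depth: 50000
annotation: annotation.tsv   # two columns: gene_id, term_id
```

```bash
dgetag run config.yaml
```

This simulates four 50,000-read libraries, builds the virtual tag database,
cleans, maps, runs saturation, tests each cold timepoint against the
control, and writes per-stage TSVs plus `out/report.txt`, which begins:

```
## Library accounting
metric	control	1h	5h	24h
total_raw	50000	50000	50000	50000
total_clean	45869	45729	45763	45575
distinct_clean	3231	2891	2891	3072
unambiguous_total	45291	45118	45158	45014
unambiguous_total_pct	98.74	98.66	98.68	98.77
n_detected_genes	365	351	334	351
pct_of_ref_genes	73.0	70.2	66.8	70.2

1h vs control: up=14	down=10
5h vs control: up=14	down=8
24h vs control: up=12	down=6
```

Reading this: ~8.5% of raw reads were discarded as adaptor-only or
N-contaminated (e.g. the control library's accounting JSON shows
2,876 adaptor + 1,255 N of 50,000 raw); 98.7% of clean tags map
unambiguously because the simulated reads all derive from the reference;
365 of 500 reference genes are detected in the control library (the rest
are CATG-free dropouts or expressed below this depth); and at an 8-fold
planted effect on 10% of genes, each timepoint yields a few dozen
significant DEG calls at FDR ≤ 0.001 and |log₂| ≥ 1.

Each stage is also available on its own (`dgetag simulate | buildref |
clean | map | saturation | dge | enrich | report`) and as library functions
(`dgetag.build_virtual_tag_db`, `dgetag.map_tags`, `dgetag.de_table`, ...).

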