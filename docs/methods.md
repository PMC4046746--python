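# Methods

## The measurement model

Tag profiling reduces each cDNA molecule to a single 21 bp tag. The
protocol assumed throughout: oligo-dT-captured cDNA is digested with NlaIII
(cuts at CATG), the bead-bound 3' fragment is retained, and MmeI releases
the 17 bases downstream of the CATG junction. Under complete digestion a
transcript therefore contributes exactly one tag — the **3'-most** CATG+17
window of its sense strand — and a transcript whose last CATG has fewer
than 17 downstream bases contributes nothing (a protocol dropout). The
simulator emits only the 3'-most window per molecule; the virtual tag
database nevertheless indexes *all* windows of every gene, because real
libraries contain internal-site tags from incomplete digestion. Both
structures are sense-strand only (the reference unigenes are assumed
oriented); antisense indexing exists behind a flag, off by default.

## Mapping semantics

Tags are matched exactly first. Only a tag with no exact hit is queried
against its 51 single-substitution neighbours, and mismatches are confined
to the 17 variable bases — the CATG anchor is produced by the enzyme, so an
anchor mismatch means the read is not a tag. Exact-match precedence is a
deliberate choice: without it, error-tolerant lookup would manufacture
ambiguity for tags that match one gene perfectly while sitting one
substitution away from another. A tag resolving to several windows of the
same gene is unambiguous for that gene; a tag resolving to several genes is
ambiguous and excluded from gene counts entirely, which biases counts
downward for gene families but keeps per-gene counts interpretable. The
three statuses (unambiguous / ambiguous / unknown) partition the clean
library exactly; this identity is asserted in the test suite on every
simulated run.

## Cleaning

A read is kept iff its tag region (offset 0 by default; the read layout is
configurable) is 21 bp long, free of `N`, and starts with CATG. Reads
failing these checks are counted as empty/too-short, N-contaminated, or
adaptor-only respectively, so `raw = clean + adaptor + empty + N` always
holds. Low quality is operationalized as `N` in the tag region only; no
quality-score filter is applied by default because base-call qualities are
not informative for the fixed-length tag protocol at this granularity.

## The count test

For one gene with count x in a library of N₁ clean tags and count y in a
library of N₂ clean tags, the Audic–Claverie conditional law is

    P(y | x) = (N₂/N₁)^y (x+y)! / ( x! y! (1+N₂/N₁)^(x+y+1) )

i.e. y | x is negative binomial with x+1 successes and success probability
N₁/(N₁+N₂). Tails are computed through the regularized incomplete beta
function rather than by summing the series: P(Y≤y|x) = I_q(x+1, y+1) with
q = N₁/(N₁+N₂). This is exact to double precision for counts of 10⁵ and
beyond, where naive log-space summation needs tens of thousands of terms.
The two-sided p doubles the smaller tail, caps at 1, and includes the
observed value in both tails. A consequence worth knowing: the p-value is
exchange-symmetric under (x,N₁)↔(y,N₂) only up to the observed value's pmf
mass (exact at x=y, N₁=N₂); the test suite asserts this sharp bound rather
than exact symmetry. An independent exact-rational tail-sum oracle verifies
the implementation to 1e-10 relative error.

The test has no replicate-aware dispersion model, by design: the intended
study design is one library per condition, and at multi-million-tag depths
the test is sensitive to biologically trivial fold changes — which is why
the significance rule combines FDR ≤ 0.001 (Benjamini–Hochberg) with
|log₂ ratio| ≥ 1. For the ratio only, zero counts are floored at one
tag-equivalent (configurable); this floor reproduces the magnitude of the
largest ratios reportable at ~4.4M-tag depth (log₂ of a ~10⁴ count over a
floored 1 is ≈13.5), while a gene with zero in both libraries has no ratio
("-") and is never significant. The floor is not used in the test itself.

Phase classification assigns each up-regulated gene its earliest
significant timepoint against the common control: phase 1 at 1 h, phase 2
first at 5 h, phase 3 first at 24 h.

## Enrichment

Term enrichment among DEGs is the exact upper hypergeometric tail
P(X ≥ k) with population N = genes carrying ≥1 annotation term (not the
whole reference; this matches how annotated-background columns are reported
in this field's pathway tables), successes K = background genes with the
term, draws n = annotated DEGs, observed k. Q-values are BH within one
comparison; Q ≤ 0.05 flags significance. The test is enrichment-only
(upper tail); depletion is not tested.

## The simulator and what it does (not) emulate

`generate_transcriptome` draws gamma-distributed lengths (shape 2, mean
560 bp by default, floor 30 bp) over the ACGT alphabet; a configurable
fraction of genes (default 5%) is guaranteed CATG-free and the rest are
guaranteed ≥1 taggable window. `sample_expression` draws log-normal
transcript shares (log-sd default 2.5, chosen so that at 10⁶ tags over
2×10⁴ genes the majority of detected genes sit below 10 copies — the
heavy-tailed shape characteristic of real tag libraries) and plants
differential effects of ±`effect_log2` (signs split evenly) on a
`de_fraction` subset per non-baseline condition, renormalising afterwards.
`simulate_tag_library` draws each read's category (tag / adaptor-only /
N-contaminated), samples tag reads' source genes proportional to abundance
over taggable genes, applies independent substitution errors to the 17
variable bases (default 1% per base; anchor errors off by default since
they would be unparseable as tags), and pads to 49 bp with a fixed
adaptor constant whose identity is irrelevant downstream. Default
contaminant rates (6% adaptor-only, 2.5% N) give the ~8–9% raw-to-clean
loss typical of these libraries. `simulate_gene_counts` is a documented
distributional shortcut — a multinomial over taggable genes — equivalent to
the noiseless read-level path, used for calibration studies at depth
10⁵–10⁶ where read strings are irrelevant.

Not modelled: PCR amplification bias, cluster formation, quality-score
realism, antisense tags, indels. Passing the recovery tests therefore shows
the analysis chain is correct under multinomial sampling with substitution
noise, not that it is robust to amplification artefacts or mis-oriented
references.

## Numerical and procedural choices

- BH adjustment is the standard step-up with a cumulative minimum; verified
  against statsmodels in the suite.
- Saturation subsampling uses nested multivariate-hypergeometric draws over
  the distinct-tag count vector (equivalent in distribution to removing
  reads one at a time), making each curve monotone by construction with an
  exact full-library endpoint.
- Copy-number bins default to [1], [2–5], [6–10], [11–20], [21–50],
  [51–100], >100.
- Percentages in all emitted tables are rounded to 2 dp at the reporting
  boundary only; internal computation is unrounded.
- Ties, degenerate inputs: empty tag library yields an empty distribution
  (not an error); a term covering the whole background gets p = 1; k = 0
  gets p = 1; an empty DEG∩background yields an empty enrichment table.

## Problem sizes used in validation

The bundled validation runs use desk-scale versions of the study design:
reference sets of 200–5,000 genes, libraries of 2×10⁴–10⁶ tags, 50-seed
null calibrations at 10⁵ tags, and DE recovery at 10⁶ tags per library with
5% of genes at 8-fold effects. At these sizes the whole suite and the
acceptance script each complete in well under a minute.

## Known limitations

- Ambiguity filtering discards shared tags rather than redistributing them;
  families of near-identical paralogues are systematically undercounted.
- One tag per gene under complete digestion means genes without a taggable
  CATG window are invisible; the detected-gene fraction is bounded above by
  the taggable fraction of the reference.
- The Audic–Claverie test conditions on single libraries; its calls reflect
  sampling noise only and overstate certainty relative to designs with
  biological replicates.
- The 1-mismatch neighbourhood can rescue error-bearing tags but also
  reassign a tag whose true source window is absent from the reference;
  with an incomplete reference, "unknown" fractions are optimistic in
  simulation relative to real data.
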