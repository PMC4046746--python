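"""Synthetic references, expression truth and simulated tag libraries.

The generator emulates an NlaIII/MmeI tag-sequencing experiment end to end:
a reference unigene set, a heavy-tailed ground-truth expression profile with
planted differential expression between conditions, and 49 bp raw reads in
which each tag read carries the 3'-most CATG+17 window of its source gene
(possibly with substitution errors) padded with adaptor sequence, alongside
adaptor-only and N-contaminated contaminant reads.  Every read records its
provenance so downstream recovery can be checked against the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reference import ANCHOR, TAG_LEN, VARIABLE_LEN, Transcript, TranscriptSet, tag_windows, three_prime_tag

READ_LEN = 49

# Fixed filler ligated 3' of the tag; its identity is irrelevant downstream,
# it only has to be CATG-free so adaptor-only reads are recognisably empty.
ADAPTOR = "TCGTATGCCGTCTTCTGCTTGAAAAAAAAAAAAAAAAAAAAAAAAAAAA"

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class RawRead:
    read_id: str
    sequence: str
    category: str  # "tag" | "adaptor_only" | "n_contaminated"
    gene_id: str | None = None


@dataclass
class RawReadSet:
    """Simulated 49 bp reads with per-read category and provenance."""

    sample_id: str
    reads: list[RawRead]

    def __len__(self) -> int:
        return len(self.reads)

    def category_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.reads:
            out[r.category] = out.get(r.category, 0) + 1
        return out

    def provenance_counts(self) -> dict[str, int]:
        """Reads per source gene, tag-category reads only."""
        out: dict[str, int] = {}
        for r in self.reads:
            if r.category == "tag" and r.gene_id is not None:
                out[r.gene_id] = out.get(r.gene_id, 0) + 1
        return out

    def to_fastq(self, path) -> None:
        qual = "I" * READ_LEN
        with open(path, "w") as fh:
            for r in self.reads:
                fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")


@dataclass
class ExpressionTruth:
    """Ground-truth transcript abundances per condition, with DE annotations.

    ``abundance[condition]`` is a pandas Series over gene_ids summing to 1.
    ``log2_effect`` is the planted per-gene effect of each non-baseline
    condition relative to baseline (0 for non-DE genes); ``de_flag`` is true
    iff the effect is non-zero.
    """

    conditions: list[str]
    abundance: dict[str, pd.Series]
    log2_effect: dict[str, pd.Series]

    @property
    def baseline(self) -> str:
        return self.conditions[0]

    def de_flags(self, condition: str) -> pd.Series:
        return self.log2_effect[condition] != 0.0

    def to_tsv(self, path) -> None:
        rows = []
        for cond in self.conditions:
            ab = self.abundance[cond]
            eff = self.log2_effect[cond]
            for gene in ab.index:
                rows.append(
                    (gene, cond, ab[gene], bool(eff[gene] != 0.0), eff[gene])
                )
        pd.DataFrame(
            rows, columns=["gene_id", "condition", "abundance", "de_flag", "log2_effect"]
        ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# reference generation
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _strip_anchor(seq: str) -> str:
    """Remove every CATG occurrence by point substitution (C -> T).

    Replacing the leading C with T can never create a new CATG occurrence,
    so a single left-to-right pass terminates with an anchor-free sequence.
    """
    while True:
        i = seq.find(ANCHOR)
        if i == -1:
            return seq
        seq = seq[:i] + "T" + seq[i + 1 :]


def generate_transcriptome(
    n_genes: int,
    mean_length: int = 560,
    seed: int = 0,
    catg_free_fraction: float = 0.05,
    length_shape: float = 2.0,
) -> TranscriptSet:
    """Generate a synthetic oriented unigene reference.

    Lengths are gamma-distributed (shape ``length_shape``, mean
    ``mean_length``) with a floor of 30 bp.  A ``catg_free_fraction`` of the
    genes is guaranteed to contain no taggable CATG window (protocol
    dropouts); every other gene is guaranteed at least one CATG with 17
    bases after it, planting an anchor if the random draw lacks one.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if mean_length < 30:
        raise ValueError("mean_length must be >= 30")
    if not 0.0 <= catg_free_fraction <= 1.0:
        raise ValueError("catg_free_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    lengths = np.maximum(
        30, rng.gamma(length_shape, mean_length / length_shape, size=n_genes).astype(int)
    )
    n_free = round(catg_free_fraction * n_genes)
    free = np.zeros(n_genes, dtype=bool)
    free[rng.choice(n_genes, size=n_free, replace=False)] = True

    width = len(str(n_genes))
    records = []
    for i in range(n_genes):
        seq = _random_seq(rng, int(lengths[i]))
        if free[i]:
            seq = _strip_anchor(seq)
        elif not tag_windows(seq):
            if len(seq) < TAG_LEN:
                seq = seq + _random_seq(rng, TAG_LEN - len(seq))
            pos = int(rng.integers(0, len(seq) - TAG_LEN + 1))
            seq = seq[:pos] + ANCHOR + seq[pos + len(ANCHOR) :]
        records.append(Transcript(f"G{i:0{width}d}", seq))
    return TranscriptSet(records)


# ---------------------------------------------------------------------------
# expression truth
# ---------------------------------------------------------------------------

def sample_expression(
    transcripts: TranscriptSet,
    conditions: list[str],
    de_fraction: float = 0.0,
    effect_log2: float = 2.0,
    dispersion: float = 2.5,
    seed: int = 0,
) -> ExpressionTruth:
    """Draw heavy-tailed baseline abundances and plant differential effects.

    Baseline transcript shares follow a log-normal law with log-sd
    ``dispersion``: a handful of genes dominate the library while the
    majority sit at very low copy numbers, the shape characteristic of real
    tag libraries.  For each non-baseline condition an independent
    ``de_fraction`` subset of genes is multiplied or divided (split evenly)
    by ``2**effect_log2``; abundances are renormalised to sum to 1 and the
    planted effect recorded.
    """
    if not conditions:
        raise ValueError("at least one condition label required")
    if not 0.0 <= de_fraction <= 1.0:
        raise ValueError("de_fraction must lie in [0, 1]")
    if effect_log2 < 0:
        raise ValueError("effect_log2 must be positive")
    rng = np.random.default_rng(seed)
    genes = transcripts.gene_ids
    n = len(genes)
    base = rng.lognormal(0.0, dispersion, size=n)
    base /= base.sum()

    abundance = {conditions[0]: pd.Series(base, index=genes)}
    log2_effect = {conditions[0]: pd.Series(np.zeros(n), index=genes)}
    for cond in conditions[1:]:
        n_de = round(de_fraction * n)
        idx = rng.choice(n, size=n_de, replace=False)
        effects = np.zeros(n)
        half = n_de // 2
        signs = np.array([1.0] * (n_de - half) + [-1.0] * half)
        rng.shuffle(signs)
        effects[idx] = signs * effect_log2
        ab = base * np.exp2(effects)
        ab /= ab.sum()
        abundance[cond] = pd.Series(ab, index=genes)
        log2_effect[cond] = pd.Series(effects, index=genes)
    return ExpressionTruth(list(conditions), abundance, log2_effect)


# ---------------------------------------------------------------------------
# library simulation
# ---------------------------------------------------------------------------

class NoTaggableTranscripts(ValueError):
    """No transcript with positive abundance carries a CATG+17 window."""


def _taggable_profile(
    transcripts: TranscriptSet, truth: ExpressionTruth, condition: str
) -> tuple[list[str], list[str], np.ndarray]:
    """Gene ids, their 3'-most tags, and renormalised sampling weights."""
    ab = truth.abundance[condition]
    genes, tags, weights = [], [], []
    for t in transcripts:
        w = float(ab.get(t.gene_id, 0.0))
        if w <= 0:
            continue
        tag = three_prime_tag(t.sequence)
        if tag is None:
            continue  # protocol dropout: sampled molecules are re-drawn
        genes.append(t.gene_id)
        tags.append(tag)
        weights.append(w)
    if not genes:
        raise NoTaggableTranscripts(
            "no taggable transcripts: no gene with positive abundance has a CATG+17 window"
        )
    w = np.asarray(weights)
    return genes, tags, w / w.sum()


def _mutate_tag(tag: str, positions: np.ndarray, rng: np.random.Generator) -> str:
    chars = list(tag)
    for p in positions:
        current = chars[p]
        choices = [b for b in "ACGT" if b != current]
        chars[p] = choices[int(rng.integers(0, 3))]
    return "".join(chars)


def simulate_tag_library(
    transcripts: TranscriptSet,
    truth: ExpressionTruth,
    condition: str,
    depth: int,
    error_rate: float = 0.01,
    adaptor_only_rate: float = 0.06,
    n_read_rate: float = 0.025,
    seed: int = 0,
    sample_id: str | None = None,
    anchor_errors: bool = False,
) -> RawReadSet:
    """Emit ``depth`` 49 bp raw reads for one condition.

    Tag reads carry the 3'-most CATG+17 window of a gene drawn with
    probability proportional to its true abundance (renormalised over
    taggable genes).  Each of the 17 variable bases is substituted
    independently with probability ``error_rate``; the CATG anchor is left
    intact unless ``anchor_errors`` is set, since anchor errors would be
    unparseable as tags.  Adaptor-only reads and reads with an N inside the
    tag region are injected at their configured rates.  Reads are padded to
    49 bp with the fixed adaptor filler.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    for name, rate in (
        ("error_rate", error_rate),
        ("adaptor_only_rate", adaptor_only_rate),
        ("n_read_rate", n_read_rate),
    ):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    if adaptor_only_rate + n_read_rate >= 1.0:
        raise ValueError("contaminant rates must sum to < 1")

    rng = np.random.default_rng(seed)
    genes, tags, weights = _taggable_profile(transcripts, truth, condition)
    sample_id = sample_id or condition

    # per-read category draw (multinomial over tag/adaptor_only/n_contaminated)
    cat = rng.choice(
        3, size=depth, p=[1.0 - adaptor_only_rate - n_read_rate, adaptor_only_rate, n_read_rate]
    )
    gene_idx = rng.choice(len(genes), size=depth, p=weights)

    err_lo = 0 if anchor_errors else len(ANCHOR)
    n_err_positions = TAG_LEN - err_lo
    n_errors = (
        rng.binomial(n_err_positions, error_rate, size=depth)
        if error_rate > 0
        else np.zeros(depth, dtype=int)
    )

    pad = ADAPTOR[: READ_LEN - TAG_LEN]
    adaptor_read = ADAPTOR[:READ_LEN]
    reads: list[RawRead] = []
    for i in range(depth):
        rid = f"{sample_id}:{i}"
        if cat[i] == 1:
            reads.append(RawRead(rid, adaptor_read, "adaptor_only"))
            continue
        g = int(gene_idx[i])
        tag = tags[g]
        if n_errors[i]:
            pos = rng.choice(np.arange(err_lo, TAG_LEN), size=int(n_errors[i]), replace=False)
            tag = _mutate_tag(tag, pos, rng)
        if cat[i] == 2:
            # N-contaminated: an undetermined base inside the 21 bp tag region
            p = int(rng.integers(0, TAG_LEN))
            tag = tag[:p] + "N" + tag[p + 1 :]
            reads.append(RawRead(rid, tag + pad, "n_contaminated", genes[g]))
        else:
            reads.append(RawRead(rid, tag + pad, "tag", genes[g]))
    return RawReadSet(sample_id, reads)


def simulate_gene_counts(
    transcripts: TranscriptSet,
    truth: ExpressionTruth,
    condition: str,
    depth: int,
    seed: int = 0,
) -> pd.Series:
    """Noiseless per-gene tag counts: a multinomial over taggable genes.

    Distributionally identical to running :func:`simulate_tag_library` with
    zero error and contamination and counting reads by provenance (the
    round-trip equivalence is asserted in the test suite); used for
    calibration studies where read-level detail is irrelevant.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    genes, _, weights = _taggable_profile(transcripts, truth, condition)
    counts = rng.multinomial(depth, weights)
    return pd.Series(counts, index=genes)
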