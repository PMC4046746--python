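"""Tag-to-gene mapping with 1-mismatch tolerance and ambiguity filtering.

Clean tags are matched against the virtual tag database: exact hits first,
and only for tags with no exact hit are the 51 single-substitution
neighbours of the 17 variable bases queried (the CATG anchor is fixed by
the enzyme and never varied).  A tag whose resolved gene set has exactly
one member is *unambiguous* and contributes to gene counts; a tag hitting
several genes is *ambiguous* and filtered out; a tag with no hit within the
mismatch budget is *unknown*.  The three categories partition the clean
library exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .processing import TagLibrary
from .reference import VirtualTagIndex

UNAMBIGUOUS = "unambiguous"
AMBIGUOUS = "ambiguous"
UNKNOWN = "unknown"


@dataclass
class MappingResult:
    """Per-tag mapping status and Table-style aggregate accounting."""

    sample_id: str
    status: dict[str, tuple[str, str | None]]  # tag -> (status, gene_id or None)
    counts: dict[str, int]  # tag -> clean count (from the library)
    n_reference_genes: int
    total_clean: int

    def _agg(self, which: str) -> tuple[int, int]:
        total = distinct = 0
        for tag, (st, _) in self.status.items():
            if st == which:
                total += self.counts[tag]
                distinct += 1
        return total, distinct

    @property
    def unambiguous_total(self) -> int:
        return self._agg(UNAMBIGUOUS)[0]

    @property
    def unambiguous_distinct(self) -> int:
        return self._agg(UNAMBIGUOUS)[1]

    @property
    def ambiguous_total(self) -> int:
        return self._agg(AMBIGUOUS)[0]

    @property
    def unknown_total(self) -> int:
        return self._agg(UNKNOWN)[0]

    @property
    def unknown_distinct(self) -> int:
        return self._agg(UNKNOWN)[1]

    @property
    def all_mapped_total(self) -> int:
        return self.unambiguous_total + self.ambiguous_total

    @property
    def all_mapped_distinct(self) -> int:
        return self.unambiguous_distinct + self._agg(AMBIGUOUS)[1]

    def summary(self) -> dict[str, float]:
        """Library accounting: totals, distinct counts, percentages of clean tags."""
        n, d = self.total_clean, len(self.status)
        def pct(x, denom):
            return round(100.0 * x / denom, 2) if denom else 0.0
        return {
            "total_clean": n,
            "distinct_clean": d,
            "all_mapped_total": self.all_mapped_total,
            "all_mapped_total_pct": pct(self.all_mapped_total, n),
            "all_mapped_distinct": self.all_mapped_distinct,
            "all_mapped_distinct_pct": pct(self.all_mapped_distinct, d),
            "unambiguous_total": self.unambiguous_total,
            "unambiguous_total_pct": pct(self.unambiguous_total, n),
            "unambiguous_distinct": self.unambiguous_distinct,
            "unambiguous_distinct_pct": pct(self.unambiguous_distinct, d),
            "unknown_total": self.unknown_total,
            "unknown_total_pct": pct(self.unknown_total, n),
            "unknown_distinct": self.unknown_distinct,
            "unknown_distinct_pct": pct(self.unknown_distinct, d),
        }

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("tag21\tcount\tstatus\tgene_id\n")
            for tag in sorted(self.status):
                st, gene = self.status[tag]
                fh.write(f"{tag}\t{self.counts[tag]}\t{st}\t{gene or '-'}\n")


def resolve_tag(tag: str, index: VirtualTagIndex, max_mismatch: int = 1) -> set[str]:
    """Gene set a single tag resolves to, with exact-match precedence."""
    genes = index.lookup_exact(tag)
    if not genes and max_mismatch >= 1:
        genes = index.lookup_1mm(tag)
    return genes


def map_tags(
    lib: TagLibrary, index: VirtualTagIndex, max_mismatch: int = 1
) -> MappingResult:
    """Map every distinct clean tag of a library against the reference index.

    Exact matches take precedence: a tag with at least one exact hit never
    consults its 1-mismatch neighbourhood, so error-tolerant matching cannot
    manufacture ambiguity for perfectly matching tags.  A tag hitting
    multiple windows of a single gene is unambiguous for that gene.
    """
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")
    status: dict[str, tuple[str, str | None]] = {}
    for tag in lib.counts:
        genes = resolve_tag(tag, index, max_mismatch)
        if len(genes) == 1:
            status[tag] = (UNAMBIGUOUS, next(iter(genes)))
        elif genes:
            status[tag] = (AMBIGUOUS, None)
        else:
            status[tag] = (UNKNOWN, None)
    return MappingResult(
        lib.sample_id,
        status,
        dict(lib.counts),
        n_reference_genes=index.n_reference_genes,
        total_clean=lib.total_clean,
    )


@dataclass
class GeneCounts:
    """Per-gene unambiguous tag counts for one library."""

    sample_id: str
    counts: pd.Series  # indexed by gene_id, all reference genes, int
    total_clean: int

    @property
    def n_detected_genes(self) -> int:
        return int((self.counts >= 1).sum())

    @property
    def fraction_of_reference(self) -> float:
        return self.n_detected_genes / len(self.counts)

    def to_tsv(self, path) -> None:
        df = self.counts.rename("count").rename_axis("gene_id").reset_index()
        df.to_csv(path, sep="\t", index=False)


def gene_counts(
    mapping: MappingResult, gene_ids: list[str] | None = None
) -> GeneCounts:
    """Sum unambiguous tag counts per gene; detection is count >= 1."""
    acc: dict[str, int] = {}
    for tag, (st, gene) in mapping.status.items():
        if st == UNAMBIGUOUS:
            acc[gene] = acc.get(gene, 0) + mapping.counts[tag]
    if gene_ids is None:
        series = pd.Series(acc, dtype=int).sort_index()
    else:
        series = pd.Series(
            [acc.get(g, 0) for g in gene_ids], index=gene_ids, dtype=int
        )
    return GeneCounts(mapping.sample_id, series, mapping.total_clean)


# ---------------------------------------------------------------------------
# saturation analysis
# ---------------------------------------------------------------------------

@dataclass
class SaturationCurve:
    points: list[tuple[int, int]]  # (subsample_size, n_detected_genes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=["subsample_size", "n_detected_genes"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def saturation_curve(
    lib: TagLibrary,
    index: VirtualTagIndex,
    grid: list[int],
    seed: int = 0,
    max_mismatch: int = 1,
) -> SaturationCurve:
    """Detected-gene count as a function of subsampled sequencing depth.

    The library is mapped once; for each grid size the tag count multiset
    is subsampled without replacement via a multivariate hypergeometric
    draw over distinct tags (equivalent in distribution to drawing reads
    one by one) and the genes with at least one unambiguous tag counted.
    Subsamples are nested (drawn incrementally from largest to smallest),
    making every curve monotone non-decreasing by construction and the
    full-library endpoint exact.
    """
    total = lib.total_clean
    grid = sorted(set(int(g) for g in grid))
    if any(g < 0 for g in grid):
        raise ValueError("subsample sizes must be non-negative")
    if grid and grid[-1] > total:
        raise ValueError(f"subsample size {grid[-1]} exceeds library size {total}")

    mapping = map_tags(lib, index, max_mismatch=max_mismatch)
    tags = sorted(lib.counts)
    counts = np.array([lib.counts[t] for t in tags], dtype=np.int64)
    # gene index per distinct tag; -1 = does not contribute to detection
    gene_of: dict[str, int] = {}
    tag_gene = np.full(len(tags), -1, dtype=np.int64)
    for i, t in enumerate(tags):
        st, gene = mapping.status[t]
        if st == UNAMBIGUOUS:
            tag_gene[i] = gene_of.setdefault(gene, len(gene_of))

    rng = np.random.default_rng(seed)
    points: list[tuple[int, int]] = []
    current = counts.copy()  # nested subsampling, from the full library down
    size = total
    for g in reversed(grid):
        if g < size:
            current = rng.multivariate_hypergeometric(current, g, method="marginals")
            size = g
        mask = (current > 0) & (tag_gene >= 0)
        n_det = len(np.unique(tag_gene[mask]))
        points.append((g, n_det))
    points.reverse()
    return SaturationCurve(points)
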