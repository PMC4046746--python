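"""Reference transcripts and the virtual tag database.

Tag-based expression profiling quantifies transcripts by sequencing a short
restriction-anchored tag per cDNA molecule: NlaIII cuts at CATG and MmeI
releases the 17 bases downstream, so every observable tag is a 21-mer of the
form ``CATG + 17 variable bases``.  The mapping target is therefore not the
transcript sequences themselves but the *virtual tag database*: the set of
all CATG+17 windows extractable from the reference, each window knowing
which gene(s) it came from and where.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ANCHOR = "CATG"
TAG_LEN = 21
VARIABLE_LEN = TAG_LEN - len(ANCHOR)  # 17 bases released by MmeI

_ALPHABET = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class AlphabetError(ValueError):
    """A reference sequence contains characters outside A, C, G, T."""


@dataclass(frozen=True)
class Transcript:
    gene_id: str
    sequence: str
    terms: frozenset[str] = frozenset()

    def __len__(self) -> int:
        return len(self.sequence)


class TranscriptSet:
    """An ordered collection of uniquely named reference transcripts."""

    def __init__(self, records: Iterable[Transcript]):
        self.records: list[Transcript] = list(records)
        self._by_id = {t.gene_id: t for t in self.records}
        if len(self._by_id) != len(self.records):
            raise ValueError("duplicate gene_ids in transcript set")
        for t in self.records:
            if not t.sequence:
                raise ValueError(f"empty sequence for gene {t.gene_id!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[Transcript]:
        return iter(self.records)

    def __getitem__(self, gene_id: str) -> Transcript:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    @property
    def gene_ids(self) -> list[str]:
        return [t.gene_id for t in self.records]

    @classmethod
    def from_fasta(cls, path) -> "TranscriptSet":
        records = [
            Transcript(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fasta")
        ]
        return cls(records)

    def to_fasta(self, path) -> None:
        SeqIO.write(
            (SeqRecord(Seq(t.sequence), id=t.gene_id, description="") for t in self),
            str(path),
            "fasta",
        )


@dataclass(frozen=True)
class VirtualTag:
    """One CATG+17 window of one transcript.

    ``rank_from_3prime`` is 1 for the 3'-most window of the gene; the library
    protocol retains only that window per molecule under complete digestion,
    but incomplete NlaIII digestion can expose internal sites, so all windows
    are indexed.
    """

    tag21: str
    gene_id: str
    offset: int
    rank_from_3prime: int

    def __post_init__(self):
        if not self.tag21.startswith(ANCHOR) or len(self.tag21) != TAG_LEN:
            raise ValueError(f"malformed virtual tag {self.tag21!r}")


def tag_windows(sequence: str) -> list[tuple[int, str]]:
    """All (offset, 21-mer) anchor windows of a sequence, 5' to 3'.

    A window requires a CATG occurrence followed by at least 17 bases.
    Overlapping CATG occurrences each yield their own window.
    """
    out = []
    start = sequence.find(ANCHOR)
    while start != -1:
        if start + TAG_LEN <= len(sequence):
            out.append((start, sequence[start : start + TAG_LEN]))
        start = sequence.find(ANCHOR, start + 1)
    return out


class VirtualTagIndex:
    """Hash index over all virtual tags, queryable exactly or at 1 mismatch.

    ``exact`` maps each distinct 21-mer to ``{gene_id: [VirtualTag, ...]}``.
    Mismatch lookup enumerates the 51 single-substitution neighbours of the
    17 variable bases; the CATG anchor is enzymatically fixed and never
    varied.
    """

    def __init__(self, tags: Iterable[VirtualTag], n_reference_genes: int,
                 genes_with_windows: set[str] | None = None):
        self.exact: dict[str, dict[str, list[VirtualTag]]] = {}
        self.n_reference_genes = n_reference_genes
        genes_seen: set[str] = set()
        for vt in tags:
            self.exact.setdefault(vt.tag21, {}).setdefault(vt.gene_id, []).append(vt)
            genes_seen.add(vt.gene_id)
        self.genes_with_windows = (
            genes_with_windows if genes_with_windows is not None else genes_seen
        )

    # -- queries ---------------------------------------------------------

    def lookup_exact(self, tag21: str) -> set[str]:
        hit = self.exact.get(tag21)
        return set(hit) if hit else set()

    def lookup_1mm(self, tag21: str) -> set[str]:
        """Union of gene sets over all 1-substitution neighbours.

        The exact tag itself is not included; callers give exact matches
        precedence and fall back to this only when there is no exact hit.
        """
        genes: set[str] = set()
        for neighbour in one_mismatch_neighbours(tag21):
            hit = self.exact.get(neighbour)
            if hit:
                genes.update(hit)
        return genes

    # -- summary ---------------------------------------------------------

    @property
    def n_distinct_tags(self) -> int:
        return len(self.exact)

    @property
    def n_tags_multi_gene(self) -> int:
        return sum(1 for genes in self.exact.values() if len(genes) > 1)

    @property
    def n_genes_with_windows(self) -> int:
        return len(self.genes_with_windows)


def one_mismatch_neighbours(tag21: str) -> Iterator[str]:
    """All 51 tags at Hamming distance 1 within the 17 variable bases."""
    for i in range(len(ANCHOR), len(tag21)):
        original = tag21[i]
        for base in "ACGT":
            if base != original:
                yield tag21[:i] + base + tag21[i + 1 :]


def build_virtual_tag_db(
    transcripts: TranscriptSet, include_antisense: bool = False
) -> VirtualTagIndex:
    """Extract every CATG+17 window of every reference gene into an index.

    Windows are taken from the sense strand; reference transcripts are
    assumed oriented (direction fixed upstream by best protein alignment).
    ``include_antisense`` additionally indexes windows of the reverse
    complement (off by default).

    Raises
    ------
    AlphabetError
        If any sequence contains characters outside A, C, G, T, naming the
        offending gene.
    """
    if len(transcripts) == 0:
        raise ValueError("transcript set is empty")
    all_tags: list[VirtualTag] = []
    for t in transcripts:
        bad = set(t.sequence) - _ALPHABET
        if bad:
            raise AlphabetError(
                f"gene {t.gene_id!r} contains non-ACGT characters: {sorted(bad)}"
            )
        strands = [t.sequence]
        if include_antisense:
            strands.append(t.sequence.translate(_COMPLEMENT)[::-1])
        for seq in strands:
            windows = tag_windows(seq)
            n = len(windows)
            for i, (offset, tag) in enumerate(windows):
                all_tags.append(VirtualTag(tag, t.gene_id, offset, n - i))
    return VirtualTagIndex(all_tags, n_reference_genes=len(transcripts))


def three_prime_tag(sequence: str) -> str | None:
    """The tag a complete NlaIII/MmeI digest would release, or None.

    This is the 3'-most CATG window with a full 17 bases after it; genes
    whose last CATG sits closer than 17 bases to the 3' end yield nothing.
    """
    windows = tag_windows(sequence)
    return windows[-1][1] if windows else None


def uniqueness_report(index: VirtualTagIndex) -> dict[str, int]:
    """Tag-to-gene multiplicity summary of a virtual tag database."""
    multi = index.n_tags_multi_gene
    return {
        "n_distinct_tags": index.n_distinct_tags,
        "n_single_gene_tags": index.n_distinct_tags - multi,
        "n_multi_gene_tags": multi,
        "n_genes_with_windows": index.n_genes_with_windows,
        "n_genes_without_windows": index.n_reference_genes
        - index.n_genes_with_windows,
    }


def write_tag_db_tsv(index: VirtualTagIndex, path) -> None:
    with open(path, "w") as fh:
        fh.write("tag21\tgene_id\toffset\trank_from_3prime\n")
        for tag21 in sorted(index.exact):
            for gene_id in sorted(index.exact[tag21]):
                for vt in index.exact[tag21][gene_id]:
                    fh.write(f"{vt.tag21}\t{vt.gene_id}\t{vt.offset}\t{vt.rank_from_3prime}\n")
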