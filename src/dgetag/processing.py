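"""Raw-read cleaning and tag-library accounting.

Raw 49 bp reads are reduced to their 21 bp tag (CATG anchor + 17 variable
bases at a fixed offset) and aggregated into a distinct-tag count table.
Reads are discarded when the tag region is absent (too-short/empty reads),
contains an undetermined base N, or does not begin with the CATG anchor
(adaptor-only reads, which carry no insert); everything surviving is a
"clean tag".  The per-library totals mirror the standard raw/clean
accounting of tag-sequencing studies and supply the library sizes used for
normalization and differential testing.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field

import pandas as pd

from .reference import ANCHOR, TAG_LEN
from .synthetic import RawReadSet


class FastqFormatError(ValueError):
    """Malformed FASTQ record, reported with its record index."""


@dataclass
class TagLibrary:
    """One sample's distinct clean 21 bp tags with counts and accounting."""

    sample_id: str
    counts: dict[str, int]
    total_raw: int
    discarded_empty: int = 0
    discarded_n: int = 0
    discarded_adaptor: int = 0

    @property
    def total_clean(self) -> int:
        return sum(self.counts.values())

    @property
    def distinct_clean(self) -> int:
        return len(self.counts)

    def accounting(self) -> dict[str, int]:
        return {
            "total_raw": self.total_raw,
            "discarded_empty": self.discarded_empty,
            "discarded_n": self.discarded_n,
            "discarded_adaptor": self.discarded_adaptor,
            "total_clean": self.total_clean,
            "distinct_clean": self.distinct_clean,
        }

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("tag21\tcount\n")
            for tag in sorted(self.counts):
                fh.write(f"{tag}\t{self.counts[tag]}\n")

    @classmethod
    def from_tsv(cls, path, sample_id: str | None = None) -> "TagLibrary":
        df = pd.read_csv(path, sep="\t", dtype={"tag21": str, "count": int})
        counts = dict(zip(df["tag21"], df["count"]))
        total = int(df["count"].sum())
        return cls(sample_id or str(path), counts, total_raw=total)

    def write_accounting_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.accounting(), fh, indent=2)
            fh.write("\n")


def _classify_and_extract(seq: str, tag_offset: int) -> tuple[str | None, str]:
    """Return (tag21 or None, discard-category) for one read sequence."""
    tag = seq[tag_offset : tag_offset + TAG_LEN]
    if len(tag) < TAG_LEN or not tag:
        return None, "empty"
    if "N" in tag:
        return None, "n"
    if not tag.startswith(ANCHOR):
        return None, "adaptor"
    return tag, ""


def clean_raw_reads(
    reads, sample_id: str | None = None, tag_offset: int = 0
) -> TagLibrary:
    """Reduce raw reads to a clean distinct-tag library with accounting.

    ``reads`` is a :class:`~dgetag.synthetic.RawReadSet` or any iterable of
    sequence strings.  The 21 bp tag is taken from ``tag_offset`` within the
    read (0 by default: the tag leads the read and the adaptor follows).
    """
    if isinstance(reads, RawReadSet):
        sample_id = sample_id or reads.sample_id
        seqs = (r.sequence for r in reads.reads)
    else:
        seqs = iter(reads)
    counts: dict[str, int] = {}
    n_raw = n_empty = n_n = n_adaptor = 0
    for seq in seqs:
        n_raw += 1
        tag, category = _classify_and_extract(seq, tag_offset)
        if tag is None:
            if category == "empty":
                n_empty += 1
            elif category == "n":
                n_n += 1
            else:
                n_adaptor += 1
            continue
        counts[tag] = counts.get(tag, 0) + 1
    return TagLibrary(
        sample_id or "sample",
        counts,
        total_raw=n_raw,
        discarded_empty=n_empty,
        discarded_n=n_n,
        discarded_adaptor=n_adaptor,
    )


def clean_fastq(path, sample_id: str | None = None, tag_offset: int = 0) -> TagLibrary:
    """Clean a FASTQ file (gzip-tolerant) into a TagLibrary."""
    opener = gzip.open if str(path).endswith(".gz") else open
    seqs = []
    with opener(path, "rt") as fh:
        record = 0
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline()
            if not header.startswith("@") or not plus.startswith("+") or not qual:
                raise FastqFormatError(f"malformed FASTQ record at index {record}")
            seqs.append(seq)
            record += 1
    lib = clean_raw_reads(seqs, sample_id=sample_id or str(path), tag_offset=tag_offset)
    return lib


# ---------------------------------------------------------------------------
# abundance distribution (copy-number binning)
# ---------------------------------------------------------------------------

# Copy-number bin lower edges: [1], [2-5], [6-10], [11-20], [21-50], [51-100], [>100]
DEFAULT_BIN_EDGES = (1, 2, 6, 11, 21, 51, 101)


@dataclass
class AbundanceDistribution:
    """Distinct-tag and total-tag mass per copy-number bin."""

    bins: list[tuple[str, int, int]]  # (label, n_distinct, n_total)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.bins, columns=["copy_range", "n_distinct_tags", "n_total_tags"])

    @property
    def total_distinct(self) -> int:
        return sum(b[1] for b in self.bins)

    @property
    def total_tags(self) -> int:
        return sum(b[2] for b in self.bins)


def abundance_distribution(
    lib: TagLibrary, bin_edges: tuple[int, ...] = DEFAULT_BIN_EDGES
) -> AbundanceDistribution:
    """Bin the library's distinct tags by copy number.

    ``bin_edges`` are strictly increasing lower edges starting at 1; the
    last bin is open-ended.  Every distinct tag falls in exactly one bin, so
    per-bin distinct and total counts sum to the library totals.
    """
    edges = tuple(bin_edges)
    if not edges or edges[0] != 1 or any(b >= a for a, b in zip(edges[1:], edges)):
        raise ValueError("bin edges must be strictly increasing and start at 1")
    labels = []
    for i, lo in enumerate(edges):
        if i + 1 < len(edges):
            hi = edges[i + 1] - 1
            labels.append(f"[{lo}]" if hi == lo else f"[{lo}-{hi}]")
        else:
            labels.append(f">={lo}" if lo > 1 else "all")
    n_distinct = [0] * len(edges)
    n_total = [0] * len(edges)
    for count in lib.counts.values():
        # rightmost edge <= count
        i = 0
        for j, lo in enumerate(edges):
            if count >= lo:
                i = j
            else:
                break
        n_distinct[i] += 1
        n_total[i] += count
    return AbundanceDistribution(list(zip(labels, n_distinct, n_total)))
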