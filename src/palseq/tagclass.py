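"""Tag classification and library statistics.

The downstream analysis of the ditag library proceeds in four steps: sort the
leading 18 bp of each qualified read, count unique prefixes, align the
prefixes against Tag1 (18 bp) and Tag2 (17 bp, taken in the orientation the
instrument actually sequenced — the reverse complement of the printed Tag2),
and count reads carrying an exact or partial tag. Matching is anchored at the
read start with a Hamming-distance budget: reads that acquired extra 5' bases
from digestion jitter do not match, which is the deliberate (and documented)
source of tag fractions below 100%.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, List, Optional, Tuple, Union

from .construct_sim import TAG1, TAG2_AS_READ
from .seqcore import DnaSequence
from .sbl_sim import SblRead

__all__ = [
    "TagPatterns",
    "LibraryStats",
    "sort_and_count_prefixes",
    "classify_read",
    "library_stats",
    "stats_from_counts",
    "render_stats_tsv",
]


@dataclass(frozen=True)
class TagPatterns:
    """The two anchored tag patterns and the mismatch budget.

    ``max_mismatch=0`` reproduces exact matching; the default 1 admits
    "partial" tags with a single mismatched base.
    """

    tag1: DnaSequence = TAG1
    tag2_as_read: DnaSequence = TAG2_AS_READ
    max_mismatch: int = 1


def _bases(read: Union[str, DnaSequence, SblRead]) -> str:
    return str(read.bases) if isinstance(read, SblRead) else str(read)


def sort_and_count_prefixes(
    reads: Iterable[Union[str, DnaSequence, SblRead]], k: int = 18
) -> List[Tuple[str, int]]:
    """Lexicographically sorted unique k-bp read prefixes with multiplicities.

    The counts sum to the number of input reads. A read shorter than ``k``
    is rejected, naming it.
    """
    counter: Counter = Counter()
    for i, read in enumerate(reads):
        bases = _bases(read)
        if len(bases) < k:
            rid = read.template_id if isinstance(read, SblRead) else f"#{i}"
            raise ValueError(f"read {rid} is {len(bases)} bp, shorter than k={k}")
        counter[bases[:k]] += 1
    return sorted(counter.items())


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def classify_read(
    read: Union[str, DnaSequence, SblRead], patterns: Optional[TagPatterns] = None
) -> str:
    """Assign a read to 'tag1', 'tag2' or 'unclassified'.

    Zero-offset anchored comparison: the read prefix is compared against each
    tag over the tag's full length; a tag matches when the Hamming distance
    is <= ``max_mismatch``. If both match, the smaller distance wins and a
    tie is unclassified. Reads with extra 5' bases therefore do not match.
    """
    patterns = patterns or TagPatterns()
    bases = _bases(read)
    if len(bases) < max(len(patterns.tag1), len(patterns.tag2_as_read)):
        raise ValueError(f"read is {len(bases)} bp, shorter than the tag patterns")
    d1 = _hamming(bases[: len(patterns.tag1)], str(patterns.tag1))
    d2 = _hamming(bases[: len(patterns.tag2_as_read)], str(patterns.tag2_as_read))
    m1 = d1 <= patterns.max_mismatch
    m2 = d2 <= patterns.max_mismatch
    if m1 and m2:
        if d1 < d2:
            return "tag1"
        if d2 < d1:
            return "tag2"
        return "unclassified"
    if m1:
        return "tag1"
    if m2:
        return "tag2"
    return "unclassified"


def _pct(count: int, total: int) -> Optional[float]:
    """100 * count / total, rounded half-up to 2 decimals; None if total=0."""
    if total == 0:
        return None
    q = (Decimal(100 * count) / Decimal(total)).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP
    )
    return float(q)


@dataclass(frozen=True)
class LibraryStats:
    """Library-statistics table: raw/qualified/tag counts with percentages
    of qualified reads (half-up, 2 decimals; None when qualified = 0)."""

    raw_reads: int
    qualified_reads: int
    tag1_reads: int
    tag2_reads: int
    tag_total_reads: int
    pct_tag1: Optional[float]
    pct_tag2: Optional[float]
    pct_total: Optional[float]


def stats_from_counts(
    raw_reads: int, qualified_reads: int, tag1_reads: int, tag2_reads: int
) -> LibraryStats:
    """Build the statistics table directly from the four primary counts."""
    total = tag1_reads + tag2_reads
    return LibraryStats(
        raw_reads=raw_reads,
        qualified_reads=qualified_reads,
        tag1_reads=tag1_reads,
        tag2_reads=tag2_reads,
        tag_total_reads=total,
        pct_tag1=_pct(tag1_reads, qualified_reads),
        pct_tag2=_pct(tag2_reads, qualified_reads),
        pct_total=_pct(total, qualified_reads),
    )


def library_stats(
    raw_count: int,
    qualified: Iterable[Union[str, DnaSequence, SblRead]],
    patterns: Optional[TagPatterns] = None,
) -> LibraryStats:
    """Classify a qualified-read stream and assemble the statistics table."""
    patterns = patterns or TagPatterns()
    n_qual = tag1 = tag2 = 0
    for read in qualified:
        n_qual += 1
        cls = classify_read(read, patterns)
        if cls == "tag1":
            tag1 += 1
        elif cls == "tag2":
            tag2 += 1
    return stats_from_counts(raw_count, n_qual, tag1, tag2)


def render_stats_tsv(stats: LibraryStats) -> str:
    """Render the table as TSV (read class, count, percentage of qualified)."""
    def pct(v: Optional[float]) -> str:
        return "NA" if v is None else f"{v:.2f}%"

    lines = [
        "Reads\tRead count\tPercentage (compared with qualified reads)",
        f"Raw reads\t{stats.raw_reads}\t",
        f"Qualified reads\t{stats.qualified_reads}\t",
        f"Tag1-containing reads\t{stats.tag1_reads}\t{pct(stats.pct_tag1)}",
        f"Tag2-containing reads\t{stats.tag2_reads}\t{pct(stats.pct_tag2)}",
        "Total of Tag1/Tag2-containing reads\t"
        f"{stats.tag_total_reads}\t{pct(stats.pct_total)}",
    ]
    return "\n".join(lines) + "\n"
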