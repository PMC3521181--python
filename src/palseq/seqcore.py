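"""DNA sequence primitives: reverse complement, palindrome detection, FASTA/BED I/O.

A *palindromic sequence* here is a DNA segment that equals its own reverse
complement, i.e. it reads identically 5'->3' on both strands. Such segments
can fold back into hairpin stems in single-stranded templates, which is the
failure mode the rest of this package simulates. Only perfect (ungapped,
mismatch-free, zero-loop) palindromes are considered; near-palindromes and
loop-containing inverted repeats are out of scope.

Coordinates are 1-based inclusive throughout the library and converted to
0-based half-open only when writing BED.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, List, Tuple, Union

from Bio import SeqIO

__all__ = [
    "DnaSequence",
    "PalindromeHit",
    "reverse_complement",
    "is_palindrome",
    "find_palindromes",
    "scan_fasta",
    "write_bed",
]

_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class DnaSequence(str):
    """An uppercase DNA string over {A, C, G, T, N}.

    Input is normalized to uppercase on construction; any character outside
    the alphabet raises ``ValueError`` naming the offending 1-based position.
    Instances are plain (immutable) strings and interoperate with all string
    APIs.
    """

    def __new__(cls, bases: str = "") -> "DnaSequence":
        s = str(bases).upper()
        for i, ch in enumerate(s):
            if ch not in _ALPHABET:
                raise ValueError(
                    f"invalid base {ch!r} at position {i + 1}: "
                    "alphabet is A/C/G/T/N"
                )
        return super().__new__(cls, s)

    @property
    def length(self) -> int:
        """Sequence length in bp."""
        return len(self)


@dataclass(frozen=True)
class PalindromeHit:
    """A maximal reverse-complement palindromic interval on a sequence.

    ``start``/``end`` are 1-based inclusive; ``length`` is even and equals
    ``end - start + 1``; ``sequence`` equals its own reverse complement.
    Maximal means extending one base on both sides either breaks the
    palindrome property or leaves the parent sequence.
    """

    start: int
    end: int
    length: int
    sequence: DnaSequence


def reverse_complement(seq: Union[str, DnaSequence]) -> DnaSequence:
    """Return the reverse complement (A<->T, C<->G, N->N).

    An involution: applying it twice returns the input.
    """
    seq = DnaSequence(seq)
    return DnaSequence(str(seq).translate(_COMPLEMENT)[::-1])


def is_palindrome(seq: Union[str, DnaSequence]) -> bool:
    """True iff ``seq`` is non-empty, even-length, N-free and equals its own
    reverse complement. Odd length or N never raises; it is simply False."""
    seq = DnaSequence(seq)
    if len(seq) == 0 or len(seq) % 2 or "N" in seq:
        return False
    return str(seq) == str(reverse_complement(seq))


def find_palindromes(
    seq: Union[str, DnaSequence], min_len: int
) -> List[PalindromeHit]:
    """All maximal perfect palindromic substrings of length >= ``min_len``.

    Uses center expansion around each of the ``n - 1`` inter-base centers
    (a perfect reverse-complement palindrome is necessarily even-length and
    symmetric about one such center), so each center contributes at most one
    maximal hit. Overlapping maximal hits are all reported. N never pairs.

    Parameters
    ----------
    seq : DNA sequence to scan.
    min_len : minimum hit length; must be even and >= 4.

    Returns
    -------
    Hits sorted by start position (1-based inclusive coordinates).
    """
    if min_len < 4 or min_len % 2:
        raise ValueError(f"min_len must be even and >= 4, got {min_len}")
    s = str(DnaSequence(seq))
    comp = s.translate(_COMPLEMENT)
    n = len(s)
    hits: List[PalindromeHit] = []
    for c in range(n - 1):
        i, j = c, c + 1
        while i >= 0 and j < n and s[i] != "N" and s[j] != "N" and s[j] == comp[i]:
            i -= 1
            j += 1
        length = j - i - 1
        if length >= min_len:
            hits.append(
                PalindromeHit(
                    start=i + 2,
                    end=j,
                    length=length,
                    sequence=DnaSequence(s[i + 1 : j]),
                )
            )
    hits.sort(key=lambda h: h.start)
    return hits


#: One BED6 record: (chrom, start 0-based, end exclusive, name, score, strand)
BedRecord = Tuple[str, int, int, str, int, str]


def scan_fasta(
    fasta_in: Union[str, Path, IO[str]], min_len: int
) -> List[BedRecord]:
    """Scan every record of a FASTA file for maximal palindromes.

    Returns BED6 records (0-based half-open), ordered by record then start.
    Hit names are ``PAL<len>`` with the palindrome length as score. Invalid
    residues are rejected with the record id for context.
    """
    records: List[BedRecord] = []
    for rec in SeqIO.parse(fasta_in, "fasta"):
        try:
            seq = DnaSequence(str(rec.seq))
        except ValueError as exc:
            raise ValueError(f"record {rec.id!r}: {exc}") from exc
        for hit in find_palindromes(seq, min_len):
            records.append(
                (rec.id, hit.start - 1, hit.end, f"PAL{hit.length}", hit.length, ".")
            )
    return records


def write_bed(records: Iterable[BedRecord], out: Union[str, Path, IO[str]]) -> None:
    """Write BED6 records as tab-separated lines."""
    own = isinstance(out, (str, Path))
    handle = open(out, "w") if own else out
    try:
        for rec in records:
            handle.write("\t".join(str(x) for x in rec) + "\n")
    finally:
        if own:
            handle.close()
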