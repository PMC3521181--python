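"""Ditag construct assembly and MmeI digestion of the PCR amplicon.

The study library derives from a single 61-bp paired-end ditag construct: an
18-bp Tag1 and a 17-bp Tag2 (both E. coli-derived) flanking a central 26-bp
perfect palindrome whose ends carry the two outward-reading MmeI recognition
sites (TCCGAC, each followed by an extra T/A from sticky-end ligation). PCR
amplification with M13 primers is modeled as exact copying; MmeI digestion of
the amplicon releases a near-homogeneous fragment population equal to the
construct plus 0..+2 bp of end jitter, which becomes the single-stranded
template pool presented to the sequencer.

MmeI is a type IIS enzyme cutting downstream of its site (20 nt on the
recognition strand, 18 nt on the complement). After end repair the canonical
blunt fragment here is exactly the printed construct: the left cut retains
``offset_top - 1`` = 19 nt downstream of the minus-strand site (extra base +
Tag1) and the right cut retains ``offset_bottom`` = 18 nt downstream of the
plus-strand site (extra T + Tag2). Digestion imprecision is additive-only
({0, +1, +2} per end, independently drawn), matching the observed ~62-bp
band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .seqcore import DnaSequence, is_palindrome, reverse_complement

__all__ = [
    "TAG1",
    "TAG2",
    "TAG2_AS_READ",
    "PALINDROME",
    "MMEI_SITE",
    "M13_FORWARD",
    "M13_REVERSE",
    "DEFAULT_JITTER",
    "DitagConstruct",
    "TemplateMolecule",
    "build_construct",
    "default_construct",
    "default_amplicon",
    "find_mmei_sites",
    "canonical_fragment_interval",
    "mmei_digest",
    "write_fragments_fasta",
]

TAG1 = DnaSequence("GGCAATGGCACCATCGCT")  # 18 bp
PALINDROME = DnaSequence("AGTCGGAGTCTGCGCAGACTCCGACT")  # 26 bp, self-revcomp
TAG2 = DnaSequence("CCACGACCGCTGAGGTT")  # 17 bp, as printed (top strand)
#: Tag2 in the orientation actually sequenced (complementary strand).
TAG2_AS_READ = reverse_complement(TAG2)  # AACCTCAGCGGTCGTGG

MMEI_SITE = DnaSequence("TCCGAC")
_MMEI_SITE_RC = reverse_complement(MMEI_SITE)  # GTCGGA

M13_FORWARD = DnaSequence("GTTTTCCCAGTCACGAC")
M13_REVERSE = DnaSequence("TCACACAGGAAACAGCTATGAC")

#: Default end-jitter distribution over {0, +1, +2} extra bp per fragment end.
DEFAULT_JITTER: Dict[int, float] = {0: 0.6, 1: 0.3, 2: 0.1}

# Arbitrary fixed vector filler between the M13 priming regions and the
# insert; chosen once, free of MmeI sites and of palindromic stems >= 16 bp
# so that simulation behaviour is driven only by the construct itself.
_VECTOR_LEFT = DnaSequence("CTAGCTAACGGATTAGCCAT")
_VECTOR_RIGHT = DnaSequence("GATTACCAGATTCGAACTAG")


@dataclass(frozen=True)
class DitagConstruct:
    """The assembled ditag: ``full = tag1 + palindrome + tag2`` (61 bp)."""

    tag1: DnaSequence
    palindrome: DnaSequence
    tag2: DnaSequence
    full: DnaSequence


@dataclass(frozen=True)
class TemplateMolecule:
    """One single-stranded library template presented to the sequencer.

    ``five_prime_offset``/``three_prime_offset`` count extra bases retained
    beyond the canonical fragment boundaries at the template's own 5'/3' ends
    (0..+2). ``origin`` records which amplicon strand the template copies:
    a ``strand_B`` insert is the reverse complement of the corresponding
    ``strand_A`` insert with the two offsets swapped.
    """

    insert: DnaSequence
    five_prime_offset: int
    three_prime_offset: int
    origin: str  # "strand_A" | "strand_B"
    template_id: str = ""


def build_construct(
    tag1: Union[str, DnaSequence] = TAG1,
    palindrome: Union[str, DnaSequence] = PALINDROME,
    tag2: Union[str, DnaSequence] = TAG2,
    *,
    strict_lengths: bool = True,
) -> DitagConstruct:
    """Assemble a ditag construct 5'->3' as tag1 + palindrome + tag2.

    The middle segment must be a perfect palindrome. With
    ``strict_lengths=True`` (default) the printed 18/26/17 bp geometry is
    enforced; pass False to assemble non-canonical constructs.
    """
    tag1, palindrome, tag2 = DnaSequence(tag1), DnaSequence(palindrome), DnaSequence(tag2)
    if not is_palindrome(palindrome):
        raise ValueError("middle segment is not a perfect palindrome")
    if strict_lengths and (len(tag1), len(palindrome), len(tag2)) != (18, 26, 17):
        raise ValueError(
            "expected tag1/palindrome/tag2 lengths 18/26/17, got "
            f"{len(tag1)}/{len(palindrome)}/{len(tag2)} "
            "(pass strict_lengths=False to override)"
        )
    return DitagConstruct(tag1, palindrome, tag2, DnaSequence(tag1 + palindrome + tag2))


def default_construct() -> DitagConstruct:
    """The study's printed 61-bp construct."""
    return build_construct()


def default_amplicon() -> DnaSequence:
    """A deterministic stand-in for the PCR amplicon.

    M13 forward priming site + vector filler + 61-bp construct + vector
    filler + (reverse complement of) the M13 reverse primer. The fillers are
    fixed and inert (no MmeI sites, no long palindromes), so the only cut
    sites and the only hairpin-competent region come from the construct.
    """
    return DnaSequence(
        M13_FORWARD
        + _VECTOR_LEFT
        + default_construct().full
        + _VECTOR_RIGHT
        + reverse_complement(M13_REVERSE)
    )


def find_mmei_sites(seq: Union[str, DnaSequence]) -> List[Tuple[int, str]]:
    """All MmeI recognition sites on both strands.

    Returns ``(position, strand)`` pairs sorted by position, where position
    is the 1-based coordinate of the site's first base on the plus strand:
    TCCGAC occurrences are '+' sites, GTCGGA occurrences (the site read on
    the minus strand) are '-' sites.
    """
    s = str(DnaSequence(seq))
    sites: List[Tuple[int, str]] = []
    for motif, strand in ((str(MMEI_SITE), "+"), (str(_MMEI_SITE_RC), "-")):
        start = s.find(motif)
        while start != -1:
            sites.append((start + 1, strand))
            start = s.find(motif, start + 1)
    sites.sort()
    return sites


def canonical_fragment_interval(
    amplicon: Union[str, DnaSequence],
    offset_top: int = 20,
    offset_bottom: int = 18,
) -> Tuple[int, int]:
    """Zero-jitter blunt fragment boundaries, 1-based inclusive.

    The fragment is delimited by the leftmost minus-strand site (cutting
    upstream/leftward) and the rightmost plus-strand site (cutting
    downstream/rightward). ``offset_top``/``offset_bottom`` are the enzyme's
    20/18 nt cut distances; after end repair the blunt fragment retains
    ``offset_top - 1`` nt left of the minus site start and ``offset_bottom``
    nt right of the plus site end. Boundaries are clipped to the amplicon.
    """
    amplicon = DnaSequence(amplicon)
    sites = find_mmei_sites(amplicon)
    if not sites:
        raise ValueError("amplicon contains no MmeI site")
    minus = [p for p, s in sites if s == "-"]
    plus = [p for p, s in sites if s == "+"]
    start = max(1, minus[0] - (offset_top - 1)) if minus else 1
    end = min(len(amplicon), plus[-1] + 5 + offset_bottom) if plus else len(amplicon)
    if start > end:
        raise ValueError("MmeI sites face each other: no fragment between cuts")
    return start, end


def _jitter_values_probs(jitter_probs: Dict[int, float]) -> Tuple[List[int], List[float]]:
    values = sorted(jitter_probs)
    probs = [jitter_probs[v] for v in values]
    if any(v < 0 for v in values):
        raise ValueError("jitter is additive-only: offsets must be >= 0")
    if abs(sum(probs) - 1.0) > 1e-9:
        raise ValueError(f"jitter probabilities must sum to 1, got {sum(probs)}")
    return values, probs


def mmei_digest(
    amplicon: Union[str, DnaSequence],
    jitter_probs: Optional[Dict[int, float]] = None,
    rng_seed: Union[int, np.random.Generator, None] = 0,
    n: int = 1,
    *,
    offset_top: int = 20,
    offset_bottom: int = 18,
    both_strands: bool = True,
) -> List[TemplateMolecule]:
    """Digest ``n`` copies of the amplicon into template molecules.

    Each molecule's two ends independently draw an additive jitter from
    ``jitter_probs`` (default ``DEFAULT_JITTER`` = {0: 0.6, +1: 0.3,
    +2: 0.1}), extending the canonical fragment outward into the
    flanks, clipped at the amplicon ends. With ``both_strands`` each template
    copies either amplicon strand with equal probability (the sequencer reads
    whichever strand the adaptor ligated to). Reproducible for a fixed
    ``rng_seed``; a ``numpy.random.Generator`` may be passed directly.

    Returns an empty list (with a warning) when no MmeI site is present.
    """
    amplicon = DnaSequence(amplicon)
    if not find_mmei_sites(amplicon):
        warnings.warn("no MmeI site found in amplicon; nothing to digest")
        return []
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    values, probs = _jitter_values_probs(dict(jitter_probs or DEFAULT_JITTER))
    start, end = canonical_fragment_interval(amplicon, offset_top, offset_bottom)

    j5s = rng.choice(values, size=n, p=probs)
    j3s = rng.choice(values, size=n, p=probs)
    strands = rng.random(n) < 0.5 if both_strands else np.zeros(n, dtype=bool)

    out: List[TemplateMolecule] = []
    for i in range(n):
        j5 = int(min(j5s[i], start - 1))  # clip at amplicon boundaries
        j3 = int(min(j3s[i], len(amplicon) - end))
        insert = DnaSequence(amplicon[start - 1 - j5 : end + j3])
        if strands[i]:
            out.append(
                TemplateMolecule(
                    insert=reverse_complement(insert),
                    five_prime_offset=j3,
                    three_prime_offset=j5,
                    origin="strand_B",
                    template_id=f"frag{i}",
                )
            )
        else:
            out.append(
                TemplateMolecule(
                    insert=insert,
                    five_prime_offset=j5,
                    three_prime_offset=j3,
                    origin="strand_A",
                    template_id=f"frag{i}",
                )
            )
    return out


def write_fragments_fasta(templates: Sequence[TemplateMolecule], path) -> None:
    """Write template inserts as FASTA (id = template_id, with offsets in
    the description)."""
    with open(path, "w") as fh:
        for t in templates:
            fh.write(
                f">{t.template_id} origin={t.origin} "
                f"off5={t.five_prime_offset} off3={t.three_prime_offset}\n"
            )
            fh.write(str(t.insert) + "\n")
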