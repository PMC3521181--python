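"""Sequencing-by-ligation read simulator with a hairpin-blocking failure model.

Emulates a SOLiD-style instrument: five sequencing primers, each offset by a
single base, are extended through seven ligation cycles; every cycle a probe
interrogates a dinucleotide and then leaps three bases, so primer ``p`` at
cycle ``c`` reads positions ``(s_p + 5(c-1), s_p + 5(c-1) + 1)`` with start
offsets s = (1, 0, 4, 3, 2) for P1..P5. Over 7 cycles the union covers
template positions 0-35, where position 0 is the final adaptor base
(interrogated once, by P2 cycle 1) and every internal position is
interrogated exactly twice. Reads report template positions 1-35 in base
space (the instrument's exact-call chemistry is modeled as perfect
color-to-base conversion).

The failure model: a template carrying a palindromic stem (>= ``min_stem``
bp, default 16) is assumed to fold into a hairpin that makes the
single-stranded template locally inaccessible to probe hybridization.
Ligation cannot re-initiate past a hairpin, so blocking runs from
``block_lead`` (default 2) bases before the palindrome to the end of the
read. Inside the block the emitted call is an i.i.d. uniform random base at
the instrument's floor quality value (default 7); approaching the block the
quality decays linearly over ``qv_decay_start`` positions. Per-(primer,
cycle) bead status degrades from ``p_bad_base`` to ``p_bad_block`` once both
interrogated positions lie inside the destabilized zone, which opens
``qv_decay_start`` bases before the full block — probe hybridization falters
slightly ahead of where base calls are lost outright.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .construct_sim import TemplateMolecule
from .seqcore import DnaSequence, find_palindromes

__all__ = [
    "PRIMER_OFFSETS",
    "PERIOD",
    "READ_LENGTH",
    "SimParams",
    "SblRead",
    "LibraryResult",
    "primer_positions",
    "coverage_map",
    "encode_colorspace",
    "decode_colorspace",
    "block_window",
    "simulate_read",
    "simulate_library",
    "write_fastq",
    "write_csfasta",
    "write_bead_table",
    "write_truth_table",
]

#: Start offset s_p of each sequencing primer (single-base shifts).
PRIMER_OFFSETS: Dict[int, int] = {1: 1, 2: 0, 3: 4, 4: 3, 5: 2}
#: Cycle period: 2-base read + 3-base leap.
PERIOD = 5
#: Template bases reported per read (positions 1..35; position 0 is adaptor).
READ_LENGTH = 35

_BASES = "ACGT"
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
# Standard rotation-invariant two-base code: color = xor of 2-bit base codes
# (identical pair -> 0; A<->C, G<->T -> 1; A<->G, C<->T -> 2; A<->T, C<->G -> 3).
_DECODE = {
    (prev, color): base
    for prev in _BASES
    for base in _BASES
    for color in [_CODE[prev] ^ _CODE[base]]
}


@dataclass(frozen=True)
class SimParams:
    """Tunable simulation parameters.

    qv_floor is the instrument's baseline quality value (7 on the 5500xl);
    qv_max an instrument ceiling; qv_decay_start the number of positions
    before the block over which mean QV ramps down; p_bad_base /
    p_bad_block the per-(primer, cycle) bead failure probabilities outside /
    inside the destabilized zone; block_lead how many bases before the
    palindrome calls already turn random; min_stem the shortest palindrome
    assumed to form a blocking hairpin.
    """

    n_reads: int = 10_000
    qv_floor: int = 7
    qv_max: int = 34
    qv_decay_start: int = 4
    p_bad_base: float = 0.02
    p_bad_block: float = 0.85
    p_best_given_ok: float = 0.5
    block_lead: int = 2
    min_stem: int = 16
    blocking_enabled: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_bad_base", "p_bad_block", "p_best_given_ok"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.qv_floor >= self.qv_max:
            raise ValueError("qv_floor must be < qv_max")


@dataclass(frozen=True)
class SblRead:
    """One simulated 35-bp read.

    ``bases``/``qvs`` cover template positions 1..35. ``bead_status`` maps
    (primer, cycle) to 'best'/'good'/'bad'. ``truth_block_start`` is the
    first blocked template position (ground truth), or None when the
    template carries no blocking hairpin.
    """

    bases: DnaSequence
    qvs: Tuple[int, ...]
    bead_status: Optional[Dict[Tuple[int, int], str]] = None
    template_id: str = ""
    truth_block_start: Optional[int] = None


def primer_positions(primer: int, cycle: int) -> Tuple[int, int]:
    """Template positions of the dinucleotide read by ``primer`` at ``cycle``.

    1-based cycles; position 0 denotes the final adaptor base.
    """
    if primer not in PRIMER_OFFSETS:
        raise ValueError(f"primer must be in 1..5, got {primer}")
    if cycle < 1:
        raise ValueError(f"cycle must be >= 1, got {cycle}")
    lo = PRIMER_OFFSETS[primer] + PERIOD * (cycle - 1)
    return lo, lo + 1


def coverage_map(n_primers: int = 5, n_cycles: int = 7) -> Dict[int, int]:
    """Per-position interrogation counts over the full schedule.

    With the default 5 primers x 7 cycles this spans positions 0-35 with the
    two boundary positions read once and positions 1-34 read twice.
    """
    if n_cycles < 0:
        raise ValueError("n_cycles must be >= 0")
    counts: Dict[int, int] = {}
    for primer in list(PRIMER_OFFSETS)[:n_primers]:
        for cycle in range(1, n_cycles + 1):
            for pos in primer_positions(primer, cycle):
                counts[pos] = counts.get(pos, 0) + 1
    return counts


def encode_colorspace(seq: Union[str, DnaSequence], primer_base: str) -> str:
    """Encode a base sequence into SOLiD colors given the primer's last base.

    Color i encodes the transition (previous base, current base) under the
    standard rotation-invariant two-base code. N has no defined color.
    """
    seq = DnaSequence(seq)
    prev = str(DnaSequence(primer_base))
    if len(prev) != 1 or prev == "N":
        raise ValueError("primer_base must be a single A/C/G/T base")
    colors = []
    for i, base in enumerate(seq):
        if base == "N":
            raise ValueError(f"color undefined for N at position {i + 1}")
        colors.append(str(_CODE[prev] ^ _CODE[base]))
        prev = base
    return "".join(colors)


def decode_colorspace(colors: str, primer_base: str) -> DnaSequence:
    """Inverse of :func:`encode_colorspace` (exact, given the primer base)."""
    prev = str(DnaSequence(primer_base))
    if len(prev) != 1 or prev == "N":
        raise ValueError("primer_base must be a single A/C/G/T base")
    bases = []
    for ch in colors:
        if ch not in "0123":
            raise ValueError(f"invalid color {ch!r}")
        prev = _DECODE[(prev, int(ch))]
        bases.append(prev)
    return DnaSequence("".join(bases))


def block_window(
    template: TemplateMolecule, params: SimParams
) -> Optional[Tuple[int, int]]:
    """The blocked read interval induced by a hairpin, or None.

    If the template insert contains a palindrome of at least ``min_stem`` bp,
    the block spans from ``block_lead`` bases before the palindrome start
    (template coordinates, floored at 1) to the end of the read — ligation
    cannot re-initiate past a hairpin. Returns None when no qualifying
    palindrome exists, when blocking is disabled, or when the window starts
    beyond the read.
    """
    if not params.blocking_enabled:
        return None
    hits = [
        h
        for h in find_palindromes(template.insert, params.min_stem)
        if h.length >= params.min_stem
    ]
    if not hits:
        return None
    start = max(1, hits[0].start - params.block_lead)
    if start > READ_LENGTH:
        return None
    return start, READ_LENGTH


def _qv_before_block(
    pos: int, block_start: Optional[int], params: SimParams, rng: np.random.Generator
) -> int:
    """QV for a correctly read position: near-ceiling, with a linear ramp
    down over the ``qv_decay_start`` positions preceding the block."""
    if block_start is not None:
        decay_lo = block_start - params.qv_decay_start
        if pos >= decay_lo:
            k = pos - decay_lo + 1  # 1..qv_decay_start
            span = params.qv_max - params.qv_floor
            qv = round(params.qv_max - k * span / (params.qv_decay_start + 1))
            return int(max(params.qv_floor + 1, qv))
    return int(params.qv_max - rng.integers(0, 3))


def simulate_read(
    template: TemplateMolecule,
    params: SimParams,
    rng: np.random.Generator,
) -> SblRead:
    """Simulate one read from a single-stranded template.

    Positions before the block report the true template base at high QV
    (mild linear decay starting ``qv_decay_start`` positions before the
    block); blocked positions report a uniform random base at ``qv_floor``.
    Bead status per (primer, cycle) is drawn bad with ``p_bad_block`` when
    both interrogated positions lie in the destabilized zone (opening
    ``qv_decay_start`` bases before the block), else with ``p_bad_base``.
    """
    insert = template.insert
    if len(insert) < READ_LENGTH:
        raise ValueError(
            f"template {template.template_id!r} insert is {len(insert)} bp; "
            f"need >= {READ_LENGTH}"
        )
    window = block_window(template, params)
    block_start = window[0] if window else None

    bases: List[str] = []
    qvs: List[int] = []
    for pos in range(1, READ_LENGTH + 1):
        if block_start is not None and pos >= block_start:
            bases.append(_BASES[rng.integers(0, 4)])
            qvs.append(params.qv_floor)
        else:
            bases.append(insert[pos - 1])
            qvs.append(_qv_before_block(pos, block_start, params, rng))

    zone_start = None if block_start is None else block_start - params.qv_decay_start
    bead: Dict[Tuple[int, int], str] = {}
    for primer in PRIMER_OFFSETS:
        for cycle in range(1, 8):
            lo, _hi = primer_positions(primer, cycle)
            in_zone = zone_start is not None and lo >= zone_start
            p_bad = params.p_bad_block if in_zone else params.p_bad_base
            if rng.random() < p_bad:
                bead[(primer, cycle)] = "bad"
            elif rng.random() < params.p_best_given_ok:
                bead[(primer, cycle)] = "best"
            else:
                bead[(primer, cycle)] = "good"

    return SblRead(
        bases=DnaSequence("".join(bases)),
        qvs=tuple(qvs),
        bead_status=bead,
        template_id=template.template_id,
        truth_block_start=block_start,
    )


@dataclass
class LibraryResult:
    """Reads plus the aggregated per-(primer, cycle) bead-status counts."""

    reads: List[SblRead]
    bead_table: pd.DataFrame  # columns: primer, cycle, n_best, n_good, n_bad


def simulate_library(
    params: SimParams,
    templates: Sequence[TemplateMolecule],
    rng: Optional[np.random.Generator] = None,
) -> LibraryResult:
    """Simulate one read per template and tally bead statuses.

    Deterministic for a fixed ``params.seed`` (or an explicitly passed
    generator). Raises on an empty template list.
    """
    if not templates:
        raise ValueError("template list is empty")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    reads = [simulate_read(t, params, rng) for t in templates]

    rows = []
    for primer in PRIMER_OFFSETS:
        for cycle in range(1, 8):
            statuses = [r.bead_status[(primer, cycle)] for r in reads]
            rows.append(
                {
                    "primer": primer,
                    "cycle": cycle,
                    "n_best": statuses.count("best"),
                    "n_good": statuses.count("good"),
                    "n_bad": statuses.count("bad"),
                }
            )
    return LibraryResult(reads=reads, bead_table=pd.DataFrame(rows))


def write_fastq(reads: Sequence[SblRead], path: Union[str, Path]) -> None:
    """Write reads as FASTQ with Phred+33 quality encoding (byte-stable for
    identical inputs, so seeded runs produce bit-identical files)."""
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            rid = r.template_id or f"read{i}"
            qual = "".join(chr(q + 33) for q in r.qvs)
            fh.write(f"@{rid}\n{r.bases}\n+\n{qual}\n")


def write_csfasta(
    reads: Sequence[SblRead],
    csfasta_path: Union[str, Path],
    qual_path: Union[str, Path],
    primer_base: str = "T",
) -> None:
    """Optional color-space output: csfasta (leading primer base + colors)
    with a matching .qual file of space-separated QVs."""
    with open(csfasta_path, "w") as cs, open(qual_path, "w") as qu:
        for i, r in enumerate(reads):
            rid = r.template_id or f"read{i}"
            cs.write(f">{rid}\n{primer_base}{encode_colorspace(r.bases, primer_base)}\n")
            qu.write(f">{rid}\n{' '.join(str(q) for q in r.qvs)}\n")


def write_bead_table(bead_table: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write the bead-status count table as TSV."""
    bead_table.to_csv(path, sep="\t", index=False)


def write_truth_table(reads: Sequence[SblRead], path: Union[str, Path]) -> None:
    """Write per-read ground truth (template id, block start) as TSV."""
    with open(path, "w") as fh:
        fh.write("read\ttemplate_id\ttruth_block_start\n")
        for i, r in enumerate(reads):
            bs = "" if r.truth_block_start is None else r.truth_block_start
            fh.write(f"read{i}\t{r.template_id}\t{bs}\n")
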