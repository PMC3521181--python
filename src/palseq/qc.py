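"""Read quality control: N/homopolymer/primer filters and QV-cutoff masking.

Mirrors the library's upstream read QC: reads containing N, long polyA/T/G/C
runs, or PCR (M13) primer sequence are removed before tag classification.
Rules are evaluated in a fixed order (N -> homopolymer -> primer -> QV) and a
rejected read is attributed to the first rule it fails, so the rejection
ledger is deterministic and conserves counts exactly.

QV cutoffs mask rather than reject: positions with QV strictly below the
cutoff become N. Since blocked positions sit at the floor QV of 7, a cutoff
of 8 erases the entire hairpin-affected region while any cutoff <= 7 leaves
it visible — the dichotomy that exposes the random calls as an instrument
artifact rather than real sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Tuple

from .construct_sim import M13_FORWARD, M13_REVERSE
from .seqcore import DnaSequence, reverse_complement
from .sbl_sim import SblRead

__all__ = ["QcConfig", "QcSummary", "filter_read", "run_qc", "apply_qv_cutoff"]

#: Rejection reasons, in evaluation order.
REASONS = ("has_n", "homopolymer", "primer", "qv")


def _default_primer_patterns() -> List[DnaSequence]:
    return [
        M13_FORWARD,
        M13_REVERSE,
        reverse_complement(M13_FORWARD),
        reverse_complement(M13_REVERSE),
    ]


@dataclass(frozen=True)
class QcConfig:
    """QC rule thresholds.

    ``homopolymer_min_run`` is the shortest single-base run that rejects a
    read (within a 35-bp read, 15 marks reads that are mostly one base);
    ``primer_min_match`` the shortest exact substring shared with any primer
    pattern that counts as primer contamination; ``qv_cutoff`` (optional)
    rejects reads whose mean QV falls below it.
    """

    reject_n: bool = True
    homopolymer_min_run: int = 15
    primer_patterns: Tuple[DnaSequence, ...] = tuple(_default_primer_patterns())
    primer_min_match: int = 15
    qv_cutoff: Optional[int] = None

    def __post_init__(self) -> None:
        if self.homopolymer_min_run < 5:
            raise ValueError("homopolymer_min_run must be >= 5")
        if self.primer_patterns and self.primer_min_match > min(
            len(p) for p in self.primer_patterns
        ):
            raise ValueError("primer_min_match exceeds the shortest primer pattern")


@dataclass
class QcSummary:
    """Raw/qualified/rejected accounting; raw = qualified + sum(rejected)."""

    n_raw: int = 0
    n_qualified: int = 0
    n_rejected_by_reason: Dict[str, int] = field(
        default_factory=lambda: {r: 0 for r in REASONS}
    )


def _max_homopolymer_run(bases: str) -> int:
    best = run = 1 if bases else 0
    for a, b in zip(bases, bases[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def _shares_kmer(bases: str, pattern: str, k: int) -> bool:
    if len(bases) < k or len(pattern) < k:
        return False
    kmers = {bases[i : i + k] for i in range(len(bases) - k + 1)}
    return any(pattern[i : i + k] in kmers for i in range(len(pattern) - k + 1))


def filter_read(read: SblRead, config: QcConfig) -> Tuple[bool, str]:
    """Evaluate QC rules on one read; first failing rule wins.

    Returns ``(keep, reason)`` where reason is 'pass' or one of
    'has_n'/'homopolymer'/'primer'/'qv'.
    """
    bases = str(read.bases)
    if config.reject_n and "N" in bases:
        return False, "has_n"
    if _max_homopolymer_run(bases) >= config.homopolymer_min_run:
        return False, "homopolymer"
    for pattern in config.primer_patterns:
        if _shares_kmer(bases, str(pattern), config.primer_min_match):
            return False, "primer"
    if config.qv_cutoff is not None and read.qvs:
        if sum(read.qvs) / len(read.qvs) < config.qv_cutoff:
            return False, "qv"
    return True, "pass"


def run_qc(
    reads: Iterable[SblRead], config: Optional[QcConfig] = None
) -> Tuple[List[SblRead], QcSummary]:
    """Filter a read stream, preserving order of survivors.

    The summary satisfies the conservation invariant
    ``n_raw == n_qualified + sum(n_rejected_by_reason.values())``.
    """
    config = config or QcConfig()
    summary = QcSummary()
    qualified: List[SblRead] = []
    for read in reads:
        summary.n_raw += 1
        keep, reason = filter_read(read, config)
        if keep:
            summary.n_qualified += 1
            qualified.append(read)
        else:
            summary.n_rejected_by_reason[reason] += 1
    return qualified, summary


def apply_qv_cutoff(read: SblRead, cutoff: int) -> SblRead:
    """Mask positions with QV strictly below ``cutoff`` to N.

    QVs and read length are unchanged. With the default simulation (blocked
    positions at floor QV 7), cutoff 8 masks the whole blocked region while
    cutoff <= 7 masks none of it.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    masked = "".join(
        "N" if qv < cutoff else base for base, qv in zip(read.bases, read.qvs)
    )
    return replace(read, bases=DnaSequence(masked))
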