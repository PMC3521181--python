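"""Per-position quality profiling and bead-ratio analysis.

Two instrument-level fingerprints of the hairpin block:

* the per-position mean QV profile, which ramps down just ahead of the
  palindrome and pins at the manufacturer floor (QV 7) from the first fully
  blocked position onward — ``detect_breakpoint`` locates that position as
  the start of the floor *suffix*, robust to the decay ramp; and
* the good/best bead fraction per (primer, cycle), the instrument's own
  library-quality indicator, which collapses once a cycle's interrogated
  dinucleotide enters the destabilized zone around the palindrome.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .sbl_sim import PRIMER_OFFSETS, READ_LENGTH, SblRead, primer_positions

__all__ = [
    "QvProfile",
    "BeadRatioTable",
    "per_position_qv",
    "detect_breakpoint",
    "bead_ratio_table",
    "write_profile_tsv",
    "plot_qv_profile",
    "plot_bead_ratios",
]


@dataclass(frozen=True)
class QvProfile:
    """Arithmetic mean QV per template position 1..35."""

    mean_qv: np.ndarray  # shape (35,), index i -> position i + 1
    n_reads: int
    qv_floor: int = 7

    def at(self, position: int) -> float:
        """Mean QV at a 1-based template position."""
        return float(self.mean_qv[position - 1])


def per_position_qv(reads: Iterable[SblRead], qv_floor: int = 7) -> QvProfile:
    """Column-wise mean QV over a read stream (all reads 35 bp)."""
    qvs = [r.qvs for r in reads]
    if not qvs:
        raise ValueError("cannot profile an empty read stream")
    arr = np.asarray(qvs, dtype=float)
    if arr.shape[1] != READ_LENGTH:
        raise ValueError(f"expected {READ_LENGTH}-bp reads, got {arr.shape[1]}")
    return QvProfile(mean_qv=arr.mean(axis=0), n_reads=arr.shape[0], qv_floor=qv_floor)


def detect_breakpoint(profile: QvProfile, eps: float = 0.25) -> Optional[int]:
    """Smallest position p with mean QV <= floor + eps at every q >= p.

    A suffix condition rather than first touch, so the decay ramp ahead of
    the block cannot trigger a spuriously early breakpoint. Returns None when
    even the final position sits above the floor. Monotone in ``eps``: a
    larger tolerance never yields a later breakpoint.
    """
    at_floor = profile.mean_qv <= profile.qv_floor + eps
    p = None
    for i in range(len(at_floor) - 1, -1, -1):
        if not at_floor[i]:
            break
        p = i + 1
    return p


@dataclass
class BeadRatioTable:
    """Per-(primer, cycle) bead fractions with interrogated positions.

    ``first_decline`` lists every (primer, cycle) of the earliest cycle whose
    good+best fraction falls below the decline threshold (empty when no
    decline occurs).
    """

    table: pd.DataFrame  # primer, cycle, pos_lo, pos_hi, frac_good, frac_best, frac_bad
    first_decline: List[Tuple[int, int]]
    threshold: float


def bead_ratio_table(
    bead_counts: pd.DataFrame,
    n_cycles: int = 7,
    decline_threshold: float = 0.9,
) -> BeadRatioTable:
    """Convert bead-status counts into fractions and locate the first decline.

    ``bead_counts`` must hold columns primer, cycle, n_best, n_good, n_bad
    covering all (primer 1..5) x (cycle 1..n_cycles) pairs; missing pairs are
    rejected, listed. Fractions per row sum to 1.
    """
    required = {
        (p, c) for p in PRIMER_OFFSETS for c in range(1, n_cycles + 1)
    }
    present = {(int(r.primer), int(r.cycle)) for r in bead_counts.itertuples()}
    missing = sorted(required - present)
    if missing:
        raise ValueError(f"bead table is missing (primer, cycle) pairs: {missing}")

    df = bead_counts.copy()
    df = df[[(int(p), int(c)) in required for p, c in zip(df.primer, df.cycle)]]
    totals = df.n_best + df.n_good + df.n_bad
    df["pos_lo"] = [primer_positions(p, c)[0] for p, c in zip(df.primer, df.cycle)]
    df["pos_hi"] = df["pos_lo"] + 1
    df["frac_best"] = df.n_best / totals
    df["frac_good"] = df.n_good / totals
    df["frac_bad"] = df.n_bad / totals
    df = df.sort_values(["cycle", "primer"]).reset_index(drop=True)

    ok = df.frac_best + df.frac_good
    declined = df[ok < decline_threshold]
    first: List[Tuple[int, int]] = []
    if len(declined):
        c0 = int(declined.cycle.min())
        first = [
            (int(r.primer), int(r.cycle))
            for r in declined[declined.cycle == c0].itertuples()
        ]
        first.sort()
    cols = ["primer", "cycle", "pos_lo", "pos_hi", "frac_good", "frac_best", "frac_bad"]
    return BeadRatioTable(table=df[cols], first_decline=first, threshold=decline_threshold)


def write_profile_tsv(profile: QvProfile, path: Union[str, Path]) -> None:
    """Write (position, mean_qv, n) rows as TSV."""
    with open(path, "w") as fh:
        fh.write("position\tmean_qv\tn\n")
        for i, qv in enumerate(profile.mean_qv, start=1):
            fh.write(f"{i}\t{qv:.4f}\t{profile.n_reads}\n")


def plot_qv_profile(profile: QvProfile, path: Union[str, Path]) -> None:
    """Per-position mean QV curve with the floor marked (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 3.5))
    positions = np.arange(1, len(profile.mean_qv) + 1)
    ax.plot(positions, profile.mean_qv, marker="o", ms=3)
    ax.axhline(profile.qv_floor, ls="--", color="grey", label=f"floor QV {profile.qv_floor}")
    ax.set_xlabel("template position (bp)")
    ax.set_ylabel("mean QV")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_bead_ratios(table: BeadRatioTable, path: Union[str, Path]) -> None:
    """Stacked good/best/bad fractions per primer x cycle (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = table.table.sort_values(["primer", "cycle"])
    labels = [f"P{int(p)}c{int(c)}" for p, c in zip(df.primer, df.cycle)]
    x = np.arange(len(df))
    fig, ax = plt.subplots(figsize=(10, 3.5))
    ax.bar(x, df.frac_good, color="tab:blue", label="good")
    ax.bar(x, df.frac_best, bottom=df.frac_good, color="tab:red", label="best")
    ax.bar(x, df.frac_bad, bottom=df.frac_good + df.frac_best, color="tab:green", label="bad")
    ax.set_xticks(x, labels, rotation=90, fontsize=6)
    ax.set_ylabel("fraction of beads")
    ax.legend(frameon=False, ncol=3)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
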