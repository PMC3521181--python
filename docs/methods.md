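# Methods

## The phenomenon being modeled

Sequencing-by-ligation (SBL) chemistry, as used by SOLiD instruments,
requires the single-stranded template to be accessible to short labeled
probes that hybridize and are sealed to the growing strand by ligase. A
perfect DNA palindrome — a segment equal to its own reverse complement — can
fold back on itself within a single-stranded template and form a
double-stranded hairpin stem. Where the stem forms, probes cannot hybridize,
ligation fails, and the instrument emits noise instead of sequence.
Sequencing-by-synthesis chemistries, in which a polymerase actively displaces
or reads through secondary structure, do not share this failure mode.

`palseq` models this end to end for a ditag test library: a 61-bp construct
consisting of an 18-bp Tag1 and a 17-bp Tag2 (both E. coli-derived) flanking
a central 26-bp perfect palindrome that carries two outward-reading MmeI
sites (TCCGAC). The package simulates the library, sequences it in silico
with a 5-primer x 7-cycle ligation schedule, and runs the downstream
analyses — QC, anchored tag classification, per-position QV profiling and
bead-ratio tables — that expose the hairpin block. A generic maximal
palindrome scanner (`seqcore`) applies the same detection to arbitrary FASTA.

## Palindrome scanner

Only perfect, ungapped, even-length palindromes are detected. A perfect
reverse-complement palindrome is symmetric about one of the `n - 1`
inter-base centers, so center expansion finds every maximal hit in
O(n x L) time; an O(n^3) exhaustive enumerator is kept in the test suite as
an independent oracle. N never pairs, so any window containing N is
non-palindromic (conservative and deterministic). Overlapping maximal hits
are all reported. Coordinates are 1-based inclusive in the library and
converted to 0-based half-open only at the BED boundary. Inverted repeats
with spacers (loop-containing hairpins) and thermodynamic stability
(nearest-neighbor free energies) are out of scope: the construct of interest
is a perfect 26-mer and the blocking model is geometric, not energetic.

## Digestion model (`construct_sim`)

PCR amplification is modeled as exact copying; no polymerase error is
simulated because none of the modeled observables depends on it. The
amplicon is the construct embedded between fixed, inert vector filler and the
two M13 priming sequences; the fillers were chosen once and verified to
contain no MmeI site and no palindromic stem >= 16 bp, so all downstream
behaviour is driven by the printed construct.

MmeI is a type IIS enzyme cutting downstream of its recognition site (20 nt
on the recognition strand, 18 nt on the complement, leaving a 2-nt 3'
overhang removed during end repair). Applied literally to this construct,
the 20/18 stagger would trim the first base of Tag1 — inconsistent with the
observed read anatomy, in which the full 18-bp Tag1 occupies read positions
1-18 and the palindrome begins at position 19 (Tag1-led strand) or 18
(Tag2-led strand). The digest model therefore places the zero-jitter blunt
boundaries exactly at the construct: the left cut retains `offset_top - 1` =
19 nt downstream of the minus-strand site (the extra ligation base plus
Tag1), the right cut retains `offset_bottom` = 18 nt downstream of the
plus-strand site (the extra T plus Tag2). Both offsets are config keys.

Digestion imprecision is additive-only: each fragment end independently
gains {0, +1, +2} extra bases with default probabilities (0.6, 0.3, 0.1).
The support {0..+2} reflects the reported <= +2 bp variation per end; the
probability mass is a free modeling choice (no distribution is published)
skewed toward precise cutting, consistent with a dominant ~61-62 bp band.
Fragments are emitted from either strand with equal probability, since the
instrument sequences whichever strand the adaptor ligated to; both Tag1-led
and Tag2-led reads are observed in the modeled experiment. Digestion is
conservative: every fragment is a literal slice of the amplicon, so fragments
plus discarded flanks reconstruct it exactly.

## Ligation schedule and read model (`sbl_sim`)

Each of five primers P1-P5 starts at a single-base offset
(s = 1, 0, 4, 3, 2) and advances five positions per cycle (2-base read +
3-base leap), so primer p at cycle c interrogates dinucleotide
(s_p + 5(c-1), s_p + 5(c-1) + 1). Position 0 is the final adaptor base
(standard convention; it is what P2 cycle 1 reads at (0,1)); reads report
template positions 1-35. Over 7 cycles the union covers positions 0-35 with
each interior position interrogated exactly twice and the two boundary
positions once — 70 interrogations, 10 per cycle in general.

Color space uses the standard rotation-invariant two-base code (color = XOR
of the 2-bit base codes: identical pair -> 0; A<->C, G<->T -> 1; A<->G,
C<->T -> 2; A<->T, C<->G -> 3), overridable in principle but not a modeled
error source: exact-call chemistry is treated as perfect color-to-base
conversion and reads are emitted in base space. A csfasta/.qual writer is
provided for pipelines that want color-space output.

Blocking model. A template containing a palindromic stem of at least
`min_stem` (default 16) bp is assumed to fold into a hairpin. The block
begins `block_lead` (default 2) bases *before* the palindrome — probe
hybridization needs flanking access, so readability is lost slightly ahead
of the stem — and extends to the end of the read, because ligation cannot
re-initiate past a hairpin (neither the sequence reads nor the bead ratios
show any recovery within 35 bp). For the canonical Tag1-led template
(palindrome at 19-44) the block spans positions 17-35.

Within the block each call is an i.i.d. uniform random base — the observed
signature is miscellaneous random sequence with no documented bias — at the
manufacturer floor QV of 7. Ahead of the block, calls are correct with QV
near the ceiling (`qv_max`, default 34 — an arbitrary plausible instrument
ceiling) minus small uniform noise; over the `qv_decay_start` (default 4)
positions preceding the block the QV ramps down linearly (the published
profile shows a gradual decline but prints no values, so the simplest
monotone shape is used), floored at `qv_floor + 1` so that a QV cutoff of
`qv_floor + 1` masks exactly the blocked region.

Bead model. The instrument's per-(primer, cycle) good/best/bad bead status
is drawn independently per cycle: failure probability `p_bad_base` (default
0.02) normally, `p_bad_block` (default 0.85) once **both** interrogated
positions lie in the destabilized zone, which opens `qv_decay_start` bases
before the full block (position 13 by default) — ligation falters slightly
ahead of where base calls are lost outright, and a probe whose dinucleotide
only straddles the zone boundary still ligates at the base rate. With the
default geometry this reproduces the characteristic collapse pattern: first
decline at P3 cycle 3 (14,15) and P4 cycle 3 (13,14), none at P5 cycle 3
(12,13), and a global collapse from cycle 4 onward. Non-bad beads split
best/good with `p_best_given_ok` (default 0.5). Per-bead persistence across
cycles is deliberately not modeled; the analyses consume only per-cycle
fractions. The two failure rates are free parameters (no numeric fractions
are published); they control the depth, not the location, of the collapse.

## QC (`qc`)

Rules run in fixed order — N, homopolymer, primer, optional mean-QV — and a
rejected read is attributed to the first failing rule, so raw = qualified +
sum(rejected) holds exactly and filtering is idempotent. "polyA/T/G/C" is
interpreted as a single-base run of >= `homopolymer_min_run` (default 15
within a 35-bp read), not a whole-read homopolymer; no threshold is
published, so the default marks reads that are mostly one base. Primer
contamination means sharing an exact substring of >= `primer_min_match`
(default 15) bases with either M13 primer or their reverse complements. QV
cutoffs *mask* (QV < cutoff -> N, lengths and QVs unchanged) rather than
reject, which reproduces the observed dichotomy — the blocked region
disappears at cutoff 8 and is fully visible at cutoff <= 7 — while an
optional mean-QV rejection rule (`qv_cutoff`) provides whole-read dropping.

## Tag classification (`tagclass`)

The four-step procedure: sort leading 18-mers, count unique prefixes, align
prefixes against the tags, count exact/partial matches. Tag2 is matched in
the orientation actually sequenced (the reverse complement of the printed
Tag2). "Partial" is operationalized as anchored Hamming distance <=
`max_mismatch` (default 1; 0 reproduces exact matching): reads carrying
extra 5' bases from digestion jitter do not match by design, which is the
documented source of tag fractions below 100% in the modeled experiment.
Under uniform-random 35-mers the false-match probability at one mismatch is
below 1e-7 per read. Percentages are reported against qualified reads,
rounded half-up to two decimals; with zero qualified reads they are
undefined (rendered NA), never a division error.

## Profiling (`profile`)

The per-position profile is the arithmetic mean QV (whether the published
per-position figure shows means or medians is not stated; mean is used and
documented). The floor breakpoint is the smallest position from which the
mean QV stays within `eps` (default 0.25) of the floor for every later
position — a suffix condition robust to the decay ramp, monotone in `eps`.
The bead-ratio table reports per-(primer, cycle) fractions annotated with
interrogated positions; `first_decline` lists all pairs in the earliest
cycle whose good+best fraction drops below a threshold (default 0.9, a free
choice: no numeric fractions are published, only the qualitative pattern).

## Problem sizes and determinism

The simulation analyses use 10,000 reads of 35 bp, enough that every tested
fraction has a standard error well below its tolerance (e.g. the in-block
accuracy of 0.25 is tested within 3 SE ~ 0.003) while the full test suite
runs in seconds. All randomness flows through `numpy.random.default_rng`
seeded from a single integer; seeded runs are bit-identical down to the
FASTQ bytes.

## What the generator does and does not emulate

The synthetic library reproduces: the near-homogeneous MmeI fragment
population with <= +2 bp end jitter; 35-bp base-space reads from 5 primers x
7 cycles; random-base/floor-QV emission from ~2 bp before the palindrome;
and per-primer-per-cycle bead fractions that collapse once interrogated
positions approach the palindrome. It does not emulate: emulsion-PCR bead
population dynamics, color-space basecalling from raw intensities, the
ECC-only sixth primer, PCR/polymerase error, GC bias, chimeras, or partial
hairpin formation (blocking is all-or-none given a qualifying stem, and
near-palindromes never block). Passing tests therefore demonstrate the
internal consistency of the geometric blocking model and the analysis stack,
not instrument-level realism of error rates.

## Known limitations

* The hairpin model is geometric (stem length threshold), not
  thermodynamic; melting conditions, loop penalties and mismatched stems are
  ignored.
* Tag fractions depend on the unpublished jitter distribution and on the
  anchored-matching convention; only their qualitative behaviour (below
  100%, sensitive to 5' jitter) is meaningful.
* Bead-status draws are independent across cycles, so the simulated bead
  fractions have no within-bead autocorrelation.
* The scanner reports perfect palindromes only; biologically relevant
  near-palindromic hairpins require an external structure predictor.
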