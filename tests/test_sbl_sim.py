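"""Ligation schedule, color coding, hairpin blocking and library simulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from palseq.construct_sim import TemplateMolecule, mmei_digest
from palseq.seqcore import DnaSequence
from palseq.sbl_sim import (
    PRIMER_OFFSETS,
    SimParams,
    block_window,
    coverage_map,
    decode_colorspace,
    encode_colorspace,
    primer_positions,
    simulate_library,
    simulate_read,
    write_fastq,
)
from palseq.tagclass import TAG1, TAG2_AS_READ


def _template(insert, **kw):
    defaults = dict(five_prime_offset=0, three_prime_offset=0, origin="strand_A",
                    template_id="t")
    defaults.update(kw)
    return TemplateMolecule(insert=DnaSequence(insert), **defaults)


class TestSchedule:
    @pytest.mark.parametrize(
        "primer,cycle,expected",
        [
            (1, 1, (1, 2)),
            (1, 2, (6, 7)),
            (2, 1, (0, 1)),
            (3, 1, (4, 5)),
            (3, 3, (14, 15)),
            (4, 3, (13, 14)),
            (5, 1, (2, 3)),
        ],
    )
    def test_printed_position_pairs(self, primer, cycle, expected):
        assert primer_positions(primer, cycle) == expected

    @pytest.mark.parametrize("primer,cycle", [(0, 1), (6, 1), (3, 0)])
    def test_out_of_range_rejected(self, primer, cycle):
        with pytest.raises(ValueError):
            primer_positions(primer, cycle)

    def test_full_schedule_coverage(self):
        cov = coverage_map(5, 7)
        assert set(cov) == set(range(36))
        assert cov[0] == 1 and cov[35] == 1
        assert all(cov[p] == 2 for p in range(1, 35))

    def test_single_cycle_coverage(self):
        cov = coverage_map(5, 1)
        assert cov == {0: 1, 1: 2, 2: 2, 3: 2, 4: 2, 5: 1}

    def test_zero_cycles_empty(self):
        assert coverage_map(5, 0) == {}

    @pytest.mark.parametrize("n_cycles", [1, 3, 7, 10])
    def test_total_interrogations_scale(self, n_cycles):
        assert sum(coverage_map(5, n_cycles).values()) == 10 * n_cycles


class TestColorspace:
    def test_identical_transitions_are_color_zero(self):
        assert encode_colorspace("AAAA", "A") == "0000"

    def test_ac_transition_is_color_one(self):
        assert encode_colorspace("AC", "A") == "01"

    @settings(derandomize=True, max_examples=150)
    @given(st.text(alphabet="ACGT", max_size=60), st.sampled_from("ACGT"))
    def test_encode_decode_roundtrip(self, seq, primer_base):
        colors = encode_colorspace(seq, primer_base)
        assert len(colors) == len(seq)
        assert str(decode_colorspace(colors, primer_base)) == seq

    def test_n_has_no_color(self):
        with pytest.raises(ValueError, match="N"):
            encode_colorspace("ANT", "A")


class TestBlockWindow:
    def test_canonical_tag1_template_blocks_from_17(self, tag1_templates_10k):
        assert block_window(tag1_templates_10k[0], SimParams()) == (17, 35)

    def test_non_palindromic_template_is_unblocked(self):
        t = _template(str(TAG1) + "AAACCCAAACCCAAACCCAAACCCAAACCCAAACCC")
        assert block_window(t, SimParams()) is None

    def test_zero_lead_blocks_at_palindrome_start(self, tag1_templates_10k):
        params = SimParams(block_lead=0)
        assert block_window(tag1_templates_10k[0], params) == (19, 35)

    def test_disabled_blocking(self, tag1_templates_10k):
        assert block_window(tag1_templates_10k[0], SimParams(blocking_enabled=False)) is None


class TestSimulateRead:
    def test_blocking_disabled_reads_template_exactly(self, tag1_templates_10k):
        rng = np.random.default_rng(0)
        t = tag1_templates_10k[0]
        read = simulate_read(t, SimParams(blocking_enabled=False), rng)
        assert str(read.bases) == str(t.insert[:35])
        assert read.truth_block_start is None

    def test_blocked_positions_sit_at_floor_qv(self, default_library):
        result, params = default_library
        for read in result.reads[:200]:
            assert all(q == params.qv_floor for q in read.qvs[16:])
            assert read.truth_block_start == 17

    def test_in_block_base_accuracy_is_one_quarter(self, default_library, tag1_templates_10k):
        result, _ = default_library
        truth = str(tag1_templates_10k[0].insert)
        n = len(result.reads)
        acc = np.mean(
            [[r.bases[i] == truth[i] for i in range(16, 35)] for r in result.reads]
        )
        se = np.sqrt(0.25 * 0.75 / (n * 19))
        assert abs(acc - 0.25) < 3 * se

    def test_short_template_rejected(self):
        with pytest.raises(ValueError, match="need >= 35"):
            simulate_read(_template("ACGT" * 5), SimParams(), np.random.default_rng(0))


class TestBeadModel:
    def test_bead_fractions_outside_and_inside_zone(self, default_library):
        """Binomial test at alpha=0.01 on 10^4 beads per (primer, cycle):
        cycles fully before the destabilized zone behave like the base rate,
        cycles inside it like the block rate."""
        result, params = default_library
        n = len(result.reads)
        for row in result.bead_table.itertuples():
            lo = PRIMER_OFFSETS[row.primer] + 5 * (row.cycle - 1)
            ok = row.n_best + row.n_good
            if lo + 1 < 13:  # both positions before the zone
                p = 1 - params.p_bad_base
            elif lo >= 13:  # both positions inside
                p = 1 - params.p_bad_block
            else:
                continue  # straddling pair: intermediate by design
            assert sps.binomtest(ok, n, p).pvalue > 0.01, (row.primer, row.cycle)


class TestSimulateLibrary:
    def test_seeded_runs_are_bit_identical(self, amplicon, tmp_path):
        files = []
        for run in ("a", "b"):
            tpls = mmei_digest(amplicon, {0: 1.0}, rng_seed=33, n=100)
            result = simulate_library(SimParams(seed=44), tpls)
            path = tmp_path / f"{run}.fastq"
            write_fastq(result.reads, path)
            files.append(path.read_bytes())
        assert files[0] == files[1]

    def test_mixed_strands_yield_both_tag_prefixes(self, noblock_library):
        result, _templates = noblock_library
        prefixes = {str(r.bases[:17]) for r in result.reads}
        assert str(TAG1[:17]) in prefixes
        assert str(TAG2_AS_READ) in prefixes

    def test_empty_template_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            simulate_library(SimParams(), [])

    def test_bead_table_counts_sum_to_reads(self, default_library):
        result, _ = default_library
        totals = result.bead_table[["n_best", "n_good", "n_bad"]].sum(axis=1)
        assert (totals == len(result.reads)).all()


class TestSimParams:
    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError, match="p_bad_block"):
            SimParams(p_bad_block=1.5)

    def test_floor_must_be_below_ceiling(self):
        with pytest.raises(ValueError, match="qv_floor"):
            SimParams(qv_floor=40, qv_max=34)
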