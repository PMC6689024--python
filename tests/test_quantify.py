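"""Quantifier: demultiplexing, trimming, placement, tabulation, frequencies."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cbekit.coords import TargetSite, WindowBoundsError, revcomp
from cbekit.quantify import (
    NOT_APPLICABLE,
    AmbiguousSeedError,
    ConversionTable,
    demultiplex,
    place_read,
    quality_trim,
    quantify_reads,
    tabulate,
)
from cbekit.simulate import EditorProfile, FastqRead, ReadBatch, simulate_reads

Q37 = chr(33 + 37)
Q2 = chr(33 + 2)


def _read(seq, qual=None, rid="r1"):
    return FastqRead(rid, seq, qual if qual is not None else Q37 * len(seq))


class TestDemultiplex:
    def test_exact_prefix_assignment_strips_barcode(self):
        reads = [_read("ACGTTTTTGG"), _read("TTTTAAAACC")]
        per_sample, unassigned = demultiplex(reads, {"ACGT": "s1"})
        assert [r.seq for r in per_sample["s1"]] == ["TTTTGG"]
        assert unassigned == 1

    def test_empty_map_passes_through_as_default(self):
        reads = [_read("ACGT"), _read("TTTT")]
        per_sample, unassigned = demultiplex(reads, {})
        assert [r.seq for r in per_sample["default"]] == ["ACGT", "TTTT"]
        assert unassigned == 0

    def test_unequal_barcode_lengths_rejected(self):
        with pytest.raises(ValueError, match="length"):
            demultiplex([], {"ACGT": "s1", "ACG": "s2"})

    def test_counts_conserved(self):
        rng = np.random.default_rng(0)
        reads = [
            _read("".join(rng.choice(list("ACGT"), 30)), rid=f"r{i}") for i in range(200)
        ]
        bmap = {"ACGT": "s1", "TGCA": "s2"}
        per_sample, unassigned = demultiplex(reads, bmap)
        assert sum(len(v) for v in per_sample.values()) + unassigned == 200


class TestQualityTrim:
    def test_high_quality_read_unchanged(self):
        r = _read("ACGTACGT")
        assert quality_trim(r) == r

    def test_low_quality_tail_removed(self):
        r = _read("ACGTACGTAA", Q37 * 5 + Q2 * 5)
        trimmed = quality_trim(r, q_min=15)
        assert trimmed.seq == "ACGTA"
        assert trimmed.qual == Q37 * 5

    def test_interior_low_quality_kept(self):
        # trimming is from the 3' end only; interior dips survive
        r = _read("ACGTACGT", Q37 * 3 + Q2 + Q37 * 4)
        assert quality_trim(r).seq == "ACGTACGT"

    def test_fully_low_quality_read_becomes_empty(self):
        r = _read("ACGT", Q2 * 4)
        assert quality_trim(r).seq == ""

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            quality_trim(FastqRead("r", "ACGT", "III"))


class TestPlaceRead:
    def test_exact_substring_placement(self, plus_site):
        sub = plus_site.amplicon_seq[7:57]
        p = place_read(_read(sub), plus_site)
        assert (p.offset, p.strand, p.mismatches) == (7, "+", 0)

    def test_reverse_complement_placement(self, plus_site):
        sub = plus_site.amplicon_seq[7:57]
        p = place_read(_read(revcomp(sub)), plus_site)
        assert (p.offset, p.strand) == (7, "-")

    def test_random_sequence_unplaced(self, plus_site):
        assert place_read(_read("T" * 40), plus_site) is None

    def test_too_many_mismatches_rejected(self, plus_site):
        sub = list(plus_site.amplicon_seq[7:47])
        # corrupt 30% of the bases after the seed
        for i in range(20, 32):
            sub[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[sub[i]]
        assert place_read(_read("".join(sub)), plus_site, max_mm=0.2) is None

    def test_ambiguous_seed_raises(self):
        amp = "ATCGATTTACGGAGCAGGCTATTCGGAACA" * 2 + "GCTTACGATCAGGATCGGATCGATTACGGATCGGGCTTA"
        site = TargetSite("dup", amp, 40, "+")
        seed = amp[:20]  # occurs twice by construction
        with pytest.raises(AmbiguousSeedError):
            place_read(_read(seed + "AAAA"), site)

    def test_read_running_off_amplicon_discarded(self, plus_site):
        tail = plus_site.amplicon_seq[-25:] + "ACGTACGT"
        assert place_read(_read(tail), plus_site) is None


class TestTabulate:
    def test_uniform_t_at_reference_c(self, plus_site):
        idx4 = 38  # amplicon index of cp 4
        sub = plus_site.amplicon_seq[25:68]
        edited = sub[: idx4 - 25] + "T" + sub[idx4 - 25 + 1 :]
        table = tabulate([(25, edited)] * 100, plus_site)
        assert table.frequency(4, "C", "T") == 1.0

    def test_frequency_is_conversion_over_total(self, plus_site):
        sub = plus_site.amplicon_seq[25:68]
        idx4 = 38
        edited = sub[: idx4 - 25] + "T" + sub[idx4 - 25 + 1 :]
        table = tabulate([(25, sub)] * 80 + [(25, edited)] * 20, plus_site)
        assert table.frequency(4, "C", "T") == pytest.approx(0.2)
        assert table.frequency(4, "C", "C") == pytest.approx(0.8)

    def test_uncovered_position_is_missing_not_zero(self, plus_site):
        # reads covering only the first half of the window
        sub = plus_site.amplicon_seq[25:45]
        table = tabulate([(25, sub)] * 10, plus_site)
        assert table.frequency(33, "G", "A") is None or table.ref_bases[-1] != "G"
        last_cp = table.cps[-1]
        assert table.frequency(last_cp, table.ref_bases[-1], "T") is None

    def test_wrong_reference_base_query_gets_marker(self, plus_site):
        sub = plus_site.amplicon_seq[25:68]
        table = tabulate([(25, sub)] * 5, plus_site)
        assert table.frequency(4, "A", "T") is NOT_APPLICABLE

    def test_out_of_window_query_rejected(self, plus_site):
        table = tabulate([], plus_site)
        with pytest.raises(WindowBoundsError):
            table.frequency(99, "C", "T")

    def test_counts_sum_to_depth(self, plus_site, flat_profile):
        batch, _ = simulate_reads(plus_site, flat_profile, 500, seed=1)
        table = quantify_reads(batch, plus_site).tables["default"]
        assert np.array_equal(table.counts.sum(axis=1), table.depth)


class TestEndToEnd:
    def test_batch_and_per_read_paths_agree(self, plus_site):
        prof = EditorProfile(
            "e", {4: 0.5, 6: 0.2}, seq_error=0.02, low_q_tail_len=4, low_q_score=5
        )
        batch, _ = simulate_reads(plus_site, prof, 300, seed=9, barcode="ACGT")
        bmap = {"ACGT": "s1", "TGCA": "s2"}
        fast = quantify_reads(batch, plus_site, barcode_map=bmap)
        slow = quantify_reads(list(batch), plus_site, barcode_map=bmap)
        assert fast.assigned == slow.assigned
        assert fast.unassigned == slow.unassigned
        for s in bmap.values():
            assert np.array_equal(fast.tables[s].counts, slow.tables[s].counts)

    def test_read_accounting_conserves_total(self, plus_site, flat_profile):
        batch, _ = simulate_reads(plus_site, flat_profile, 1000, seed=2, barcode="ACGT")
        res = quantify_reads(batch, plus_site, barcode_map={"ACGT": "s1", "GGGG": "s2"})
        assert sum(res.assigned.values()) + res.unassigned == 1000

    def test_recovers_expected_frequency(self, plus_site):
        prof = EditorProfile("e", {4: 0.5, 6: 0.1, 8: 0.9})
        batch, truth = simulate_reads(plus_site, prof, 20_000, seed=11)
        table = quantify_reads(batch, plus_site).tables["default"]
        freqs = table.c_to_t_frequencies()
        for cp, exp in truth.expected.items():
            depth = table.depth[table.cps.index(cp)]
            sd = max(np.sqrt(exp * (1 - exp) / depth), 1 / depth)
            assert abs(freqs[cp] - exp) <= 4 * sd, f"cp {cp}"

    def test_strand_invariance(self):
        from cbekit.simulate import make_synthetic_site

        plan = {4: "A", 6: "T", 9: "G"}
        prof = EditorProfile("e", {cp: 0.5 for cp in range(1, 11)}, seq_error=0.0)
        site_p = make_synthetic_site("locus", 77, plan, strand="+")
        site_m = TargetSite(
            "locus_m",
            revcomp(site_p.amplicon_seq),
            len(site_p.amplicon_seq) - 1 - site_p.protospacer_start,
            "-",
        )
        batch, _ = simulate_reads(site_p, prof, 2000, seed=4)
        table_p = quantify_reads(batch, site_p).tables["default"]
        # the same reads quantified against the opposite-strand annotation
        table_m = quantify_reads(batch, site_m).tables["default"]
        assert table_p.ref_bases == table_m.ref_bases
        assert np.array_equal(table_p.counts, table_m.counts)

    def test_low_quality_tail_excluded_from_depth(self, plus_site):
        # tail long enough to push trimmed reads out of the window's 3' end
        prof = EditorProfile("e", {}, seq_error=0.0, low_q_tail_len=10, low_q_score=2)
        batch, _ = simulate_reads(plus_site, prof, 50, seed=6, flank3=0)
        table = quantify_reads(batch, plus_site, q_min=15).tables["default"]
        assert table.depth[-1] == 0  # last window position trimmed away
        assert table.depth[0] == 50

    @settings(max_examples=10, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_batch_engine_matches_per_read_on_random_batches(self, seed):
        from cbekit.simulate import make_synthetic_site

        site = make_synthetic_site("rt", 5, {4: "A", 7: "G"})
        prof = EditorProfile("e", {4: 0.3}, seq_error=0.05)
        batch, _ = simulate_reads(site, prof, 60, seed=seed)
        fast = quantify_reads(batch, site)
        slow = quantify_reads(list(batch), site)
        assert np.array_equal(
            fast.tables["default"].counts, slow.tables["default"].counts
        )
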