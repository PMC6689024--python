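"""Read simulator: closed-form truth, determinism, sampling behavior."""

import io

import numpy as np
import pytest

from cbekit.coords import protospacer_base, quantification_window
from cbekit.simulate import (
    EditorProfile,
    ReadBatch,
    effective_edit_probability,
    expected_t_frequency,
    make_profile_library,
    make_sgrna_panel,
    make_synthetic_site,
    simulate_reads,
)


class TestExpectedTFrequency:
    def test_no_editing_no_error_is_zero(self, plus_site):
        prof = EditorProfile("e", {}, seq_error=0.0)
        assert expected_t_frequency(prof, plus_site, 4) == 0.0

    def test_full_editing_no_error_is_one(self, plus_site):
        prof = EditorProfile("e", {4: 1.0}, seq_error=0.0)
        assert expected_t_frequency(prof, plus_site, 4) == 1.0

    def test_closed_form_value(self, plus_site):
        # q=0.5, e=0.003: 0.5*0.997 + 0.5*0.001 = 0.4990
        prof = EditorProfile("e", {4: 0.5}, seq_error=0.003)
        assert expected_t_frequency(prof, plus_site, 4) == pytest.approx(0.4990, abs=5e-5)

    def test_matches_monte_carlo_oracle(self, plus_site):
        # independent trial-level oracle for the same generative story
        prof = EditorProfile("e", {4: 0.37}, seq_error=0.01)
        rng = np.random.default_rng(99)
        n = 1_000_000
        edited = rng.random(n) < 0.37
        err = rng.random(n) < 0.01
        to = rng.integers(0, 3, n)  # which of the other 3 bases
        base = np.where(edited, 3, 1)  # T=3, C=1 in ACGT order
        other = np.array([[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]])
        final = np.where(err, other[base, to], base)
        mc = (final == 3).mean()
        assert expected_t_frequency(prof, plus_site, 4) == pytest.approx(mc, abs=2e-3)

    def test_context_multiplier_applied_and_clipped(self, plus_site):
        prof = EditorProfile(
            "e", {4: 0.6, 6: 0.6}, {"AC": 2.0, "CC": 1.0, "GC": 1.0, "TC": 0.5}
        )
        q4, clipped4 = effective_edit_probability(prof, plus_site, 4)  # AC context
        q6, clipped6 = effective_edit_probability(prof, plus_site, 6)  # TC context
        assert (q4, clipped4) == (1.0, True)
        assert (q6, clipped6) == (0.3, False)

    def test_non_c_position_rejected(self, plus_site, flat_profile):
        from cbekit.coords import NotACytosineError

        with pytest.raises(NotACytosineError):
            expected_t_frequency(flat_profile, plus_site, 1)


class TestSimulateReads:
    def test_zero_reads(self, plus_site, flat_profile):
        batch, truth = simulate_reads(plus_site, flat_profile, 0, seed=1)
        assert len(batch) == 0
        assert truth.n_reads == 0
        assert set(truth.expected) >= {4, 6, 8}

    def test_negative_reads_rejected(self, plus_site, flat_profile):
        with pytest.raises(ValueError):
            simulate_reads(plus_site, flat_profile, -1, seed=1)

    def test_fixed_seed_is_byte_identical(self, plus_site, flat_profile):
        out = []
        for _ in range(2):
            batch, _ = simulate_reads(plus_site, flat_profile, 500, seed=42, barcode="ACGT")
            buf = io.StringIO()
            batch.to_fastq(buf)
            out.append(buf.getvalue())
        assert out[0] == out[1]

    def test_observed_fraction_within_3_binomial_sd(self, plus_site):
        # q=0.5, e=0 at one C; binomial SD = sqrt(0.25/10000) = 0.005
        prof = EditorProfile("e", {4: 0.5}, seq_error=0.0)
        batch, _ = simulate_reads(plus_site, prof, 10_000, seed=7, flank5=0)
        col = 10 + 3  # window starts at cp -10; cp4 is 13 positions later
        t_frac = (batch.seq[:, col] == ord("T")).mean()
        assert abs(t_frac - 0.5) < 0.015

    def test_non_c_positions_show_error_floor(self, plus_site):
        prof = EditorProfile("e", {}, seq_error=0.03)
        batch, _ = simulate_reads(plus_site, prof, 20_000, seed=3, flank5=0)
        window = quantification_window(plus_site)
        g_cols = [i for i, cp in enumerate(window) if protospacer_base(plus_site, cp) == "G"]
        t_frac = (batch.seq[:, g_cols] == ord("T")).mean()
        assert t_frac == pytest.approx(0.01, abs=0.002)  # e/3

    def test_barcode_prepended_and_qualities_assigned(self, plus_site):
        prof = EditorProfile("e", {}, seq_error=0.0, low_q_tail_len=5, low_q_score=2)
        batch, _ = simulate_reads(plus_site, prof, 3, seed=1, barcode="TTTT")
        rec = next(iter(batch))
        assert rec.seq.startswith("TTTT")
        assert rec.qual[:-5] == chr(33 + 37) * (len(rec.qual) - 5)
        assert rec.qual[-5:] == chr(33 + 2) * 5

    def test_minus_strand_truth_matches_plus_strand(self):
        plan = {4: "A", 7: "T", 10: "G"}
        prof = EditorProfile("e", {cp: 0.4 for cp in range(1, 12)})
        site_p = make_synthetic_site("p", 5, plan, strand="+")
        _, truth_p = simulate_reads(site_p, prof, 0, seed=1)
        site_m = make_synthetic_site("m", 5, plan, strand="-")
        _, truth_m = simulate_reads(site_m, prof, 0, seed=1)
        assert set(truth_p.expected) == set(truth_m.expected)


class TestReadBatch:
    def test_record_round_trip(self, plus_site, flat_profile):
        batch, _ = simulate_reads(plus_site, flat_profile, 20, seed=5)
        rebuilt = ReadBatch.from_records(list(batch))
        assert np.array_equal(batch.seq, rebuilt.seq)
        assert np.array_equal(batch.qual, rebuilt.qual)

    def test_unequal_lengths_rejected(self):
        from cbekit.simulate import FastqRead

        with pytest.raises(ValueError):
            ReadBatch.from_records([FastqRead("a", "ACGT", "IIII"), FastqRead("b", "AC", "II")])


class TestProfileLibrary:
    def test_archetype_supports(self):
        lib = {p.editor_id: p for p in make_profile_library()}
        assert set(lib["forward"].p_edit) <= set(range(1, 9))
        assert set(lib["backward"].p_edit) <= set(range(9, 14))
        assert set(lib["broad"].p_edit) == set(range(1, 15))
        assert lib["gc_averse"].context_mult["GC"] < lib["gc_averse"].context_mult["TC"]

    def test_invalid_profiles_rejected(self):
        with pytest.raises(ValueError):
            EditorProfile("e", {4: 1.5})
        with pytest.raises(ValueError):
            EditorProfile("e", {}, seq_error=0.3)


class TestPanelDesign:
    def test_cover_positions_all_have_cytosines(self):
        panel = make_sgrna_panel(4, seed=11)
        covered = set()
        for site in panel:
            for cp in range(1, 15):
                if protospacer_base(site, cp) == "C":
                    covered.add(cp)
        assert covered >= set(range(1, 15))

    def test_anchors_guarantee_a_c_per_sgrna(self):
        panel = make_sgrna_panel(9, seed=2, anchors=tuple(range(4, 9)))
        for site in panel:
            assert any(protospacer_base(site, cp) == "C" for cp in range(4, 9))

    def test_per_position_places_multiple_sites(self):
        panel = make_sgrna_panel(6, seed=3, cover=tuple(range(2, 15, 2)), per_position=3)
        for cp in range(2, 15, 2):
            n_c = sum(protospacer_base(s, cp) == "C" for s in panel)
            assert n_c >= 3
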