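"""Chi scanning, closed-form cut positions, and the event-driven simulator."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chirace.params import (
    EnzymeParams,
    InvalidParameterError,
    MotorKinetics,
    ReactionConditions,
    SubstrateSpec,
    SwingModel,
    CalibrationEntry,
    CalibrationTable,
)
from chirace.race import (
    CHI_MOTIF,
    SequenceError,
    chi_scan,
    end_stop_probability,
    loop_size,
    predicted_cut_position,
    simulate_molecule,
    simulate_population,
)


def table_enzyme(ratio, advance, cv=0.0, k_sens=75.0, p_chi=1.0, conc=100.0):
    """Single-entry table-mode enzyme for deterministic scenarios."""
    return EnzymeParams(
        recB=MotorKinetics(0.8, 416.7, 9.434),
        recD=MotorKinetics(1.0, 416.7, 68.9),
        swing=SwingModel(cv=cv),
        p_chi_recognition=p_chi,
        k_sens_uM=k_sens,
        calibration=CalibrationTable(
            [CalibrationEntry(inhibitor_uM=conc, ratio=ratio, advance_nt=advance)]
        ),
    )


class TestChiScan:
    def test_motif_equals_sequence_right_entry(self):
        assert len(chi_scan(CHI_MOTIF, "right")) == 1

    def test_orientation_asymmetry_left_entry(self):
        # the same physical site is invisible from the other end
        assert chi_scan(CHI_MOTIF, "left") == []

    def test_cut_distance_hand_computed(self):
        # motif at 0-based 5..12 of a 20-mer; nearest-entry base is index 12,
        # 20-1-12 = 7 from the right entry; minus offset 5 → 2
        seq = "AAAAAGCTGGTGGAAAAAAA"
        assert chi_scan(seq, "right", chi_offset_nt=5) == [2]

    def test_left_entry_sees_reverse_complement_site(self):
        # revcomp of the motif on the top strand is active from the left
        seq = "AAAAACCACCAGCAAAAAAA"
        assert chi_scan(seq, "right") == []
        assert chi_scan(seq, "left") == [0]

    def test_multiple_hits_sorted(self):
        seq = CHI_MOTIF + "TTTT" + CHI_MOTIF + "TT"
        cuts = chi_scan(seq, "right", chi_offset_nt=0)
        assert cuts == sorted(cuts) and len(cuts) == 2

    def test_non_dna_rejected(self):
        with pytest.raises(SequenceError):
            chi_scan("GCTGGTGGN", "right")

    def test_too_short_rejected(self):
        with pytest.raises(SequenceError):
            chi_scan("GCTG", "right")


class TestPredictedCutPosition:
    def test_formula(self):
        assert predicted_cut_position(4350, 0.30, 200) == pytest.approx(1505)

    def test_none_when_past_end(self):
        assert predicted_cut_position(1000, 0.95, 200) is None

    def test_zero_advance_complement(self):
        pos = predicted_cut_position(4350, 0.70, 0)
        assert pos == pytest.approx(3045)
        assert 4350 - pos == pytest.approx(4350 * (1 - 0.70))

    def test_ratio_above_one_rejected(self):
        with pytest.raises(InvalidParameterError):
            predicted_cut_position(1000, 1.2, 0)


class TestEndStopProbability:
    def test_zero_at_zero_inhibitor(self):
        assert end_stop_probability(0.0, 75.0) == 0.0

    def test_half_at_k_sens(self):
        assert end_stop_probability(75.0, 75.0) == pytest.approx(0.5)

    def test_monotone(self):
        ps = [end_stop_probability(i, 75.0) for i in (0, 25, 100, 400)]
        assert ps == sorted(ps)


class TestSimulateMolecule:
    def test_chi_wins_race(self):
        # t_chi = 1300/0.7 ≈ 1857 < t_end = 2270 (v_D = 1): Chi fires
        sub = SubstrateSpec("s", 2270, chi_cut_from_label=970)
        enz = table_enzyme(ratio=0.70, advance=250, conc=100.0)
        cond = ReactionConditions(inhibitor_uM=100.0, mode="table")
        rng = np.random.default_rng(0)
        events = [simulate_molecule(sub, enz, cond, rng) for _ in range(200)]
        assert all(e.trigger == "chi" for e in events)
        assert all(abs(e.position_nt - 1300) <= 1 for e in events)

    def test_end_stop_wins_when_ratio_drops(self):
        # r = 0.5 < 1300/2270: the race flips; sensitized molecules cut at
        # 1135 + advance
        sub = SubstrateSpec("s", 2270, chi_cut_from_label=970)
        enz = table_enzyme(ratio=0.50, advance=250, k_sens=1e-9, conc=100.0)
        cond = ReactionConditions(inhibitor_uM=100.0, mode="table")
        rng = np.random.default_rng(0)
        events = [simulate_molecule(sub, enz, cond, rng) for _ in range(200)]
        assert all(e.trigger == "end_stop" for e in events)
        assert all(e.position_nt == pytest.approx(1135 + 250) for e in events)

    def test_uninhibited_chi_less_substrate_uncut(self, enzyme):
        sub = SubstrateSpec("s", 2270)
        cond = ReactionConditions(inhibitor_uM=0.0, mode="table")
        rng = np.random.default_rng(0)
        events = [simulate_molecule(sub, enzyme, cond, rng) for _ in range(100)]
        assert all(e.trigger == "none" for e in events)

    def test_cut_past_end_yields_no_fragment(self):
        sub = SubstrateSpec("s", 1000)
        enz = table_enzyme(ratio=0.95, advance=200, k_sens=1e-9, conc=100.0)
        cond = ReactionConditions(inhibitor_uM=100.0, mode="table")
        rng = np.random.default_rng(0)
        events = [simulate_molecule(sub, enz, cond, rng) for _ in range(100)]
        assert all(e.trigger == "none" for e in events)

    @settings(derandomize=True, deadline=None, max_examples=60)
    @given(
        length=st.integers(500, 6000),
        ratio=st.floats(0.2, 0.95),
        advance=st.floats(0, 400),
        chi_from_label=st.integers(100, 400),
    )
    def test_cv0_oracle_equivalence(self, length, ratio, advance, chi_from_label):
        """With cv=0 and certain sensitization/recognition the simulator
        agrees exactly with the closed forms and the race inequality."""
        sub = SubstrateSpec("s", length, chi_cut_from_label=chi_from_label)
        enz = table_enzyme(ratio=ratio, advance=advance, k_sens=1e-9, conc=50.0)
        cond = ReactionConditions(inhibitor_uM=50.0, mode="table")
        ev = simulate_molecule(sub, enz, cond, np.random.default_rng(1))
        chi_dist = length - chi_from_label
        chi_wins = chi_dist / ratio < length  # t_chi < t_end at v_D = 1
        if chi_wins:
            assert ev.trigger == "chi"
            assert abs(ev.position_nt - chi_dist) <= 1
        else:
            expected = predicted_cut_position(length, ratio, advance)
            if expected is None:
                assert ev.trigger == "none"
            else:
                assert ev.trigger == "end_stop"
                assert ev.position_nt == pytest.approx(expected)


class TestSimulatePopulation:
    def test_deterministic_for_fixed_seed(self, enzyme):
        sub = SubstrateSpec("s", 4350, chi_cut_from_label=970)
        cond = ReactionConditions(inhibitor_uM=100.0, mode="table")
        a = simulate_population(500, sub, enzyme, cond, 42)
        b = simulate_population(500, sub, enzyme, cond, 42)
        assert a == b

    def test_cv0_end_stop_fragments_identical(self):
        sub = SubstrateSpec("s", 4350)
        enz = table_enzyme(ratio=0.30, advance=200, k_sens=1e-9, conc=400.0)
        cond = ReactionConditions(inhibitor_uM=400.0, mode="table")
        fs = simulate_population(2000, sub, enz, cond, 0)
        assert len(fs.fragments) == 1
        assert fs.fragments[0][0] == 4350 - (4350 * 0.30 + 200)

    def test_mean_fragment_matches_law_of_large_numbers(self):
        # mean end-stop fragment → S(1−r) − advance within 3 SE
        sub = SubstrateSpec("s", 4350)
        enz = table_enzyme(ratio=0.30, advance=200, cv=0.2, k_sens=1e-9, conc=400.0)
        cond = ReactionConditions(inhibitor_uM=400.0, mode="table")
        fs = simulate_population(10000, sub, enz, cond, 7)
        lengths = np.repeat(
            [r.length_nt for r in fs.records], [r.count for r in fs.records]
        )
        se = lengths.std(ddof=1) / math.sqrt(lengths.size)
        assert abs(lengths.mean() - (4350 * 0.70 - 200)) < 3 * se

    def test_fragment_plus_position_is_substrate_length(self, enzyme):
        sub = SubstrateSpec("s", 2270, chi_cut_from_label=970)
        cond = ReactionConditions(inhibitor_uM=200.0, mode="table")
        rng = np.random.default_rng(3)
        for _ in range(300):
            ev = simulate_molecule(sub, enzyme, cond, rng)
            if ev.trigger != "none":
                frag = 2270 - ev.position_nt
                assert 0 < frag <= 2270

    def test_counts_sum_to_n(self, enzyme):
        sub = SubstrateSpec("s", 1340)
        cond = ReactionConditions(inhibitor_uM=50.0, mode="table")
        fs = simulate_population(1000, sub, enzyme, cond, 5)
        assert (
            sum(r.count for r in fs.records) + fs.full_length_count == 1000
        )

    def test_mean_end_stop_length_increases_with_inhibitor(self, enzyme):
        """The packaged calibration makes the labeled end-stop product longer
        at higher inhibitor concentration."""
        sub = SubstrateSpec("s", 4350)
        means = []
        for conc in (25, 50, 100, 200, 400):
            cond = ReactionConditions(inhibitor_uM=conc, mode="table")
            fs = simulate_population(4000, sub, enzyme, cond, 11)
            means.append(fs.mean_length(trigger="end_stop"))
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_chi_fragment_span_at_most_3nt(self, enzyme):
        sub = SubstrateSpec("s", 4350, chi_cut_from_label=970)
        cond = ReactionConditions(inhibitor_uM=0.0, mode="table")
        fs = simulate_population(5000, sub, enzyme, cond, 2)
        chi_lengths = [r.length_nt for r in fs.records if r.trigger == "chi"]
        assert max(chi_lengths) - min(chi_lengths) <= 3


class TestLoopSize:
    def test_zero_at_equal_speeds(self):
        enz = table_enzyme(ratio=1.0, advance=0, conc=0.0)
        cond = ReactionConditions(inhibitor_uM=0.0, mode="table")
        assert loop_size(enz, cond, 500.0) == 0.0

    def test_grows_linearly(self):
        enz = table_enzyme(ratio=0.7, advance=0, conc=0.0)
        cond = ReactionConditions(inhibitor_uM=0.0, mode="table")
        assert loop_size(enz, cond, 1000.0) == pytest.approx(300.0)

    def test_monotone_in_time(self):
        enz = table_enzyme(ratio=0.5, advance=0, conc=0.0)
        cond = ReactionConditions(inhibitor_uM=0.0, mode="table")
        sizes = [loop_size(enz, cond, t) for t in (0, 100, 500, 1000)]
        assert sizes == sorted(sizes)
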