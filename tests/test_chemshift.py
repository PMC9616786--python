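"""Secondary-shift arithmetic, helix calling and population estimation."""

import io as stdio
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from camsite.chemshift import (
    DeltaEntry,
    DeltaProfile,
    RandomCoilTable,
    ShiftEntry,
    ShiftTable,
    SSThresholds,
    call_segments,
    compute_delta,
    helix_population,
    is_helical,
    population_error,
)
from camsite.errors import ParseError, ValidationError
from camsite.io import load_shift_table
from camsite.sequences import INF2_2_19

TSV_FIXTURE = """residue\taa\tatom\tshift_ppm
3\tV\tHA\t4.02
3\tV\tCA\t63.1
11\tW\tHA\t4.50
"""

NMRSTAR_FIXTURE = """data_synthetic_shifts

save_assigned_chemical_shifts
   _Assigned_chem_shift_list.Sf_category  assigned_chemical_shifts

   loop_
      _Atom_chem_shift.ID
      _Atom_chem_shift.Seq_ID
      _Atom_chem_shift.Comp_ID
      _Atom_chem_shift.Atom_ID
      _Atom_chem_shift.Atom_type
      _Atom_chem_shift.Val
      _Atom_chem_shift.Val_err

      1  2  SER  HA  H  4.471  0.01
      2  3  VAL  HA  H  4.021  0.01
      3  3  VAL  HB  H  2.105  0.01

   stop_
save_
"""


class TestLoadShiftTable:
    def test_tsv_fixture_transcribed(self):
        table = load_shift_table(stdio.StringIO(TSV_FIXTURE), "tsv")
        assert len(table.entries) == 3
        assert table.shifts_for("HA") == {3: 4.02, 11: 4.50}
        assert table.shifts_for("CA") == {3: 63.1}

    def test_empty_stream_is_a_parse_error(self):
        with pytest.raises(ParseError):
            load_shift_table(stdio.StringIO(""), "tsv")

    def test_minimal_nmrstar_loop(self):
        """Hand-parsed oracle: two HA rows at the written ppm values."""
        table = load_shift_table(stdio.StringIO(NMRSTAR_FIXTURE), "nmrstar")
        ha = table.shifts_for("HA")
        assert ha == {2: 4.471, 3: 4.021}
        assert table.residue_types()[2] == "S"

    def test_unknown_atom_skipped_not_fatal(self, caplog):
        text = TSV_FIXTURE + "4\tK\tHB\t1.80\n"
        table = load_shift_table(stdio.StringIO(text), "tsv")
        assert len(table.entries) == 3

    def test_duplicate_residue_atom_rejected(self):
        text = TSV_FIXTURE + "3\tV\tHA\t4.10\n"
        with pytest.raises(ValidationError, match="duplicate"):
            load_shift_table(stdio.StringIO(text), "tsv")

    def test_malformed_line_names_line_number(self):
        with pytest.raises(ParseError, match="line 2"):
            load_shift_table(stdio.StringIO("residue\taa\tatom\tshift_ppm\nnot-a-row\n"), "tsv")


class TestComputeDelta:
    def test_observed_equal_to_rc_gives_zero(self, rc):
        entries = [
            ShiftEntry(r, aa, "HA", rc.halpha(aa))
            for r, aa in [(2, "S"), (3, "V"), (4, "K")]
        ]
        profile = compute_delta(ShiftTable("pep", entries=entries), rc)
        assert all(e.delta_halpha == pytest.approx(0.0) for e in profile.entries)

    def test_single_alanine_offset(self, rc):
        table = ShiftTable("a", entries=[ShiftEntry(5, "A", "HA", rc.halpha("A") - 0.10)])
        profile = compute_delta(table, rc)
        assert profile.entries[0].delta_halpha == pytest.approx(-0.10)

    def test_full_peptide_against_subtraction_oracle(self, rc):
        """Element-wise subtraction oracle over the 2-19 peptide."""
        observed = {
            res: (4.0 + 0.01 * res, 55.0 + 0.1 * res)
            for res in range(2, 20)
        }
        entries = []
        for i, aa in enumerate(INF2_2_19.sequence):
            res = i + 2
            entries.append(ShiftEntry(res, aa, "HA", observed[res][0]))
            entries.append(ShiftEntry(res, aa, "CA", observed[res][1]))
        profile = compute_delta(ShiftTable("2-19", entries=entries), rc)
        by_res = profile.by_residue()
        for i, aa in enumerate(INF2_2_19.sequence):
            res = i + 2
            assert by_res[res].delta_halpha == pytest.approx(observed[res][0] - rc.halpha(aa))
            assert by_res[res].delta_calpha == pytest.approx(observed[res][1] - rc.calpha(aa))

    def test_missing_atom_leaves_delta_absent(self, rc):
        table = ShiftTable("a", entries=[ShiftEntry(5, "A", "CA", 54.0)])
        e = compute_delta(table, rc).entries[0]
        assert e.delta_halpha is None and e.delta_calpha is not None

    def test_unknown_residue_type_raises(self):
        table = ShiftTable("a", entries=[ShiftEntry(5, "A", "HA", 4.2)])
        bare = RandomCoilTable({aa: (4.3, 55.0) for aa in "CDEFGHIKLMNPQRSTVWY"})
        with pytest.raises(ValidationError, match="A"):
            compute_delta(table, bare)

    @given(
        shifts=st.lists(
            st.tuples(st.integers(1, 50), st.sampled_from("ACDEFGHIKLMNPQRSTVWY"),
                      st.floats(-1, 1, allow_nan=False)),
            min_size=1, max_size=20, unique_by=lambda t: t[0],
        )
    )
    @settings(deadline=None, max_examples=50)
    def test_round_trip_reconstructs_observed(self, shifts):
        """Adding the random-coil value back recovers observed shifts exactly."""
        rc = RandomCoilTable.wishart()
        entries = [ShiftEntry(r, aa, "HA", rc.halpha(aa) + d) for r, aa, d in shifts]
        table = ShiftTable("rt", entries=entries)
        profile = compute_delta(table, rc)
        types = table.residue_types()
        ha = table.shifts_for("HA")
        for e in profile.entries:
            assert e.delta_halpha + rc.halpha(types[e.residue]) == pytest.approx(
                ha[e.residue], abs=1e-12
            )


def make_profile(deltas: dict[int, float]) -> DeltaProfile:
    return DeltaProfile(
        "p", entries=[DeltaEntry(r, delta_halpha=d) for r, d in deltas.items()]
    )


class TestCallSegments:
    def test_all_coil_gives_no_segments(self):
        profile = make_profile({r: 0.01 for r in range(1, 20)})
        assert call_segments(profile) == []

    def test_single_clean_helix(self):
        """Run-finding on an exact synthetic profile: −0.10 on 3-17 only."""
        deltas = {r: (-0.10 if 3 <= r <= 17 else 0.0) for r in range(2, 20)}
        segments = call_segments(make_profile(deltas))
        assert [s.span for s in segments] == [(3, 17)]
        assert segments[0].population_percent == pytest.approx(100 * 0.10 / 0.39)

    def test_interior_gap_of_one_is_bridged(self):
        deltas = {r: (-0.10 if 3 <= r <= 17 and r != 10 else 0.0) for r in range(2, 20)}
        assert [s.span for s in call_segments(make_profile(deltas))] == [(3, 17)]

    def test_gap_of_two_splits_the_run(self):
        deltas = {r: -0.10 for r in range(3, 18)}
        deltas[10] = deltas[11] = 0.0
        spans = [s.span for s in call_segments(make_profile(deltas))]
        assert spans == [(3, 9), (12, 17)]

    def test_short_runs_dropped(self):
        deltas = {r: 0.0 for r in range(1, 20)}
        deltas[5] = deltas[6] = -0.2
        assert call_segments(make_profile(deltas)) == []

    def test_calpha_alone_marks_helix(self):
        entries = [DeltaEntry(r, delta_calpha=1.0) for r in range(3, 10)]
        segments = call_segments(DeltaProfile("ca_only", entries=entries))
        assert [s.span for s in segments] == [(3, 9)]
        assert math.isnan(segments[0].population_percent)

    def test_entry_order_does_not_matter(self):
        deltas = {r: (-0.10 if 3 <= r <= 17 else 0.0) for r in range(2, 20)}
        forward = make_profile(deltas)
        reverse = DeltaProfile("p", entries=list(reversed(forward.entries)))
        assert [s.span for s in call_segments(forward)] == [
            s.span for s in call_segments(reverse)
        ]

    def test_empty_profile_rejected(self):
        with pytest.raises(ValidationError):
            call_segments(DeltaProfile("empty", entries=[]))

    def test_coil_band_is_exclusive_of_boundary(self):
        assert is_helical(DeltaEntry(1, delta_halpha=-0.04))
        assert not is_helical(DeltaEntry(1, delta_halpha=-0.039))
        assert is_helical(DeltaEntry(1, delta_calpha=0.4))
        assert not is_helical(DeltaEntry(1, delta_calpha=0.399))


class TestHelixPopulation:
    def test_full_helix_value_gives_100(self):
        profile = make_profile({r: -0.39 for r in range(3, 18)})
        assert helix_population(profile, (3, 17)).percent == pytest.approx(100.0)

    def test_zero_deltas_give_0(self):
        profile = make_profile({r: 0.0 for r in range(3, 18)})
        assert helix_population(profile, (3, 17)).percent == pytest.approx(0.0)

    def test_range_restricts_the_average(self):
        deltas = {r: -0.39 for r in range(3, 18)}
        deltas.update({r: 0.0 for r in range(18, 25)})
        assert helix_population(make_profile(deltas), (3, 17)).percent == pytest.approx(100.0)

    def test_clamping_keeps_raw_value(self):
        over = helix_population(make_profile({3: -0.5, 4: -0.5, 5: -0.5}), (3, 5))
        assert over.percent == 100.0
        assert over.raw_percent == pytest.approx(100 * 0.5 / 0.39)
        under = helix_population(make_profile({3: 0.1, 4: 0.1}), (3, 4))
        assert under.percent == 0.0
        assert under.raw_percent < 0

    def test_no_halpha_in_range_raises(self):
        with pytest.raises(ValidationError):
            helix_population(make_profile({3: -0.1}), (10, 12))

    @given(scale=st.floats(0.05, 1.0), base=st.floats(-0.3, -0.05))
    @settings(deadline=None, max_examples=50)
    def test_linear_in_uniform_scaling_before_clamp(self, scale, base):
        profile = make_profile({r: base for r in range(1, 6)})
        scaled = make_profile({r: base * scale for r in range(1, 6)})
        raw = helix_population(profile, (1, 5)).raw_percent
        assert helix_population(scaled, (1, 5)).raw_percent == pytest.approx(raw * scale)


class TestPopulationError:
    @pytest.mark.parametrize(
        "shift_error,expected",
        [(0.0, 0.0), (0.39, 100.0), (0.01, 100 * 0.01 / 0.39)],
    )
    def test_linear_propagation(self, shift_error, expected):
        assert population_error(shift_error) == pytest.approx(expected)

    def test_measurement_error_rounds_to_three_percent(self):
        assert round(population_error(0.01)) == 3

    def test_negative_error_rejected(self):
        with pytest.raises(ValidationError):
            population_error(-0.01)


class TestThresholdValidation:
    def test_defaults_match_coil_band_convention(self):
        thr = SSThresholds()
        assert (thr.halpha_coil_band, thr.calpha_coil_band) == (0.04, 0.4)
        assert thr.full_helix_halpha == -0.39

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValidationError):
            SSThresholds(halpha_coil_band=0)
        with pytest.raises(ValidationError):
            SSThresholds(full_helix_halpha=0.39)
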