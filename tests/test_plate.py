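"""Plate model: addressing, layouts, reads I/O, and 384->96 reformatting."""

import numpy as np
import pandas as pd
import pytest

from pparscreen.plate import (
    Role,
    ScreeningPlate,
    WellAddress,
    WellRecord,
    default_screen_layout,
    load_plate_reads,
    parse_layout,
    plan_reformat,
    sample_positions,
    write_plate,
)


class TestWellAddress:
    @pytest.mark.parametrize(
        "text,row,col", [("A1", "A", 1), ("h12", "H", 12), ("P24", "P", 24)]
    )
    def test_parse_and_canonical_form(self, text, row, col):
        addr = WellAddress.parse(text)
        assert (addr.row, addr.column) == (row, col)
        assert str(addr) == f"{row}{col}"

    @pytest.mark.parametrize("text,fmt", [("I1", 96), ("A13", 96), ("Q1", 384), ("A25", 384)])
    def test_out_of_bounds_rejected(self, text, fmt):
        with pytest.raises(ValueError):
            WellAddress.parse(text, fmt)

    @pytest.mark.parametrize("text", ["", "1A", "A0", "AA1", "A1.5"])
    def test_malformed_rejected(self, text):
        with pytest.raises(ValueError):
            WellAddress.parse(text)


class TestParseLayout:
    def test_default_screen_layout_counts(self):
        layout = default_screen_layout(96)
        roles = pd.Series([r for r, _ in layout.values()]).value_counts()
        assert roles[Role.negative_control] == 8
        assert roles[Role.positive_control] == 8
        assert roles[Role.sample] == 80
        # control columns are exactly columns 1 and 12
        for r in "ABCDEFGH":
            assert layout[f"{r}1"][0] is Role.negative_control
            assert layout[f"{r}12"][0] is Role.positive_control

    def test_empty_table_gives_all_empty(self):
        layout = parse_layout(pd.DataFrame(columns=["well", "role"]), 96)
        assert len(layout) == 96
        assert all(role is Role.empty for role, _ in layout.values())

    def test_duplicate_address_rejected_with_both_rows(self):
        table = pd.DataFrame(
            {"well": ["A1", "B2", "A1"], "role": ["neg", "sample", "pos"]}
        )
        with pytest.raises(ValueError, match=r"A1.*rows 0 and 2"):
            parse_layout(table, 96)

    def test_role_aliases_and_sample_ids(self):
        table = pd.DataFrame(
            {
                "well": ["A1", "A2", "A12"],
                "role": ["neg", "sample", "pos"],
                "sample_id": [None, "X7", None],
            }
        )
        layout = parse_layout(table, 96)
        assert layout["A1"] == (Role.negative_control, None)
        assert layout["A2"] == (Role.sample, "X7")
        assert layout["A12"] == (Role.positive_control, None)


class TestLoadPlateReads:
    def test_ratio_derivation(self):
        layout = parse_layout(
            pd.DataFrame({"well": ["A1"], "role": ["sample"]}), 96
        )
        plate = load_plate_reads(
            pd.DataFrame({"well": ["A1"], "firefly": [500], "renilla": [1000]}),
            layout,
        )
        assert plate["A1"].ratio == pytest.approx(0.5)

    def test_zero_renilla_is_unusable_not_error(self):
        layout = parse_layout(pd.DataFrame({"well": ["A1"], "role": ["sample"]}), 96)
        plate = load_plate_reads(
            pd.DataFrame({"well": ["A1"], "firefly": [500], "renilla": [0]}),
            layout,
        )
        assert plate["A1"].ratio is None
        assert not plate["A1"].usable

    def test_negative_luminescence_rejected(self):
        layout = parse_layout(pd.DataFrame({"well": ["A1"], "role": ["sample"]}), 96)
        with pytest.raises(ValueError, match="negative"):
            load_plate_reads(
                pd.DataFrame({"well": ["A1"], "firefly": [-5], "renilla": [100]}),
                layout,
            )

    def test_non_numeric_rejected_with_position(self):
        layout = parse_layout(pd.DataFrame({"well": ["B3"], "role": ["sample"]}), 96)
        with pytest.raises(ValueError, match="B3"):
            load_plate_reads(
                pd.DataFrame({"well": ["B3"], "firefly": ["oops"], "renilla": [100]}),
                layout,
            )

    def test_reads_on_empty_well_warn(self):
        layout = parse_layout(pd.DataFrame(columns=["well", "role"]), 96)
        with pytest.warns(UserWarning, match="empty"):
            load_plate_reads(
                pd.DataFrame({"well": ["A1"], "firefly": [1], "renilla": [1]}),
                layout,
            )

    def test_full_default_plate_role_counts(self, rng):
        layout = default_screen_layout(96)
        wells = sorted(layout, key=lambda k: WellAddress.parse(k))
        reads = pd.DataFrame(
            {
                "well": wells,
                "firefly": rng.uniform(100, 1000, 96),
                "renilla": rng.uniform(5000, 15000, 96),
            }
        )
        plate = load_plate_reads(reads, layout)
        assert len(plate.by_role(Role.negative_control)) == 8
        assert len(plate.by_role(Role.positive_control)) == 8
        assert len(plate.samples()) == 80

    def test_write_load_round_trip(self, rng):
        layout = default_screen_layout(96)
        wells = sorted(layout, key=lambda k: WellAddress.parse(k))
        reads = pd.DataFrame(
            {
                "well": wells,
                "firefly": rng.uniform(100, 1000, 96).round(3),
                "renilla": rng.uniform(5000, 15000, 96).round(3),
            }
        )
        plate = load_plate_reads(reads, layout)
        out = write_plate(plate)
        merged = reads.merge(out, on="well", suffixes=("_in", "_out"))
        assert len(merged) == 96
        np.testing.assert_allclose(merged.firefly_in, merged.firefly_out)
        np.testing.assert_allclose(merged.renilla_in, merged.renilla_out)


def _library_plate(plate_id, n_samples, start=0):
    """384-well plate with samples row-major in the non-reserved columns."""
    plate = ScreeningPlate(plate_id, 384)
    k = 0
    for row in "ABCDEFGHIJKLMNOP":
        for col in range(3, 23):
            if k >= n_samples:
                return plate
            plate.add(
                WellRecord(
                    address=WellAddress(row, col),
                    role=Role.sample,
                    sample_id=f"L{start + k:04d}",
                )
            )
            k += 1
    return plate


class TestPlanReformat:
    def test_560_samples_need_7_target_plates(self):
        plates = [_library_plate("SRC1", 320), _library_plate("SRC2", 240, start=320)]
        transfers = plan_reformat(plates)
        assert len(transfers) == 560
        assert max(t.target_plate for t in transfers) == 7
        # each target plate carries exactly 80
        counts = pd.Series([t.target_plate for t in transfers]).value_counts()
        assert set(counts) == {80}

    def test_single_sample_lands_at_A2(self):
        transfers = plan_reformat([_library_plate("SRC", 1)])
        assert len(transfers) == 1
        assert transfers[0].target_plate == 1
        assert transfers[0].target_well == "A2"

    def test_sample_in_reserved_column_rejected(self):
        plate = ScreeningPlate("SRC", 384)
        plate.add(
            WellRecord(address=WellAddress("A", 1), role=Role.sample, sample_id="X")
        )
        with pytest.raises(ValueError, match="reserved"):
            plan_reformat([plate])

    def test_bijection_onto_sample_wells(self):
        transfers = plan_reformat([_library_plate("SRC", 137)])
        sources = {(t.source_plate, t.source_well) for t in transfers}
        targets = {(t.target_plate, t.target_well) for t in transfers}
        assert len(sources) == len(targets) == 137
        valid = set(sample_positions(96))
        assert all(t.target_well in valid for t in transfers)
        # target control columns never receive a sample
        assert not any(
            t.target_well.endswith("1") and len(t.target_well) == 2
            for t in transfers
        )
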