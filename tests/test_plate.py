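import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pairscreen as ps
from pairscreen.plate import PLATE_GEOMETRIES, write_specification


class TestWellAddress:
    @pytest.mark.parametrize("well", ["A01", "B07", "P24", "H12"])
    def test_id_round_trips(self, well):
        assert ps.WellAddress.parse(well).id == well

    def test_lowercase_and_bounds(self):
        addr = ps.WellAddress.parse("b07")
        assert addr.id == "B07"
        assert addr.in_bounds(384)
        assert not ps.WellAddress.parse("Q01").in_bounds(384)  # row 17 of 16

    @pytest.mark.parametrize("bad", ["7B", "B", "07", "B0x"])
    def test_malformed_ids_rejected(self, bad):
        with pytest.raises(ps.LayoutError):
            ps.WellAddress.parse(bad)


class TestSpecificationParsing:
    def test_csv_json_round_trip(self, tmp_path):
        layout = ps.demo_layout(n_pairs=2, n_conc=3, plate_format=96, n_blanks=4)
        csv_path = tmp_path / "spec.csv"
        write_specification(layout, csv_path)
        parsed = ps.parse_specification(csv_path)
        assert parsed.plate_format == 96
        assert parsed.wells == layout.wells

        json_path = tmp_path / "spec.json"
        records = [
            {
                "well": w,
                "role": e.role,
                "drug1": e.drug1,
                "conc1": e.conc1,
                "drug2": e.drug2,
                "conc2": e.conc2,
                "replicate": e.replicate,
            }
            for w, e in layout.wells.items()
        ]
        json_path.write_text(json.dumps({"plate_format": 96, "wells": records}))
        assert ps.parse_specification(json_path).wells == layout.wells

    def test_checkerboard_8_pairs_6x6_fills_288_wells(self):
        """8 pairs × 6×6 dose grids assign 288 patches on a 384-well plate."""
        layout = ps.demo_layout(
            n_pairs=8, n_conc=6, plate_format=384, n_blanks=8, n_extra_controls=0
        )
        assigned = len(layout.treated_wells) + len(layout.control_wells)
        assert assigned == 8 * 36
        # every treated well maps to exactly one (pair, c1, c2)
        for w in layout.treated_wells:
            assert layout.wells[w].patch is not None

    def test_duplicate_well_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text(
            "well,drug1,conc1,drug2,conc2,role,replicate\n"
            "A01,d1,1,d2,1,treated,r1\n"
            "A01,d1,2,d2,1,treated,r2\n"
        )
        with pytest.raises(ps.LayoutError, match="more than once"):
            ps.parse_specification(path)

    def test_missing_controls_blocks_viability(self):
        wells = {
            "A01": ps.WellEntry(well="A01", role="treated", drug1="d1", conc1=1.0,
                                drug2="d2", conc2=1.0, replicate="r"),
        }
        layout = ps.PlateLayout(plate_format=96, wells=wells)
        with pytest.raises(ps.LayoutError, match="growth-control"):
            ps.survival_table({"A01": 5.0}, layout)

    def test_well_partition_covers_plate(self):
        layout = ps.demo_layout(n_pairs=2, n_conc=3, plate_format=96, n_blanks=4)
        n_rows, n_cols = PLATE_GEOMETRIES[96]
        assigned = (
            set(layout.treated_wells) | set(layout.control_wells) | set(layout.blank_wells)
        )
        assert len(assigned) == len(layout.wells)
        unused = n_rows * n_cols - len(assigned)
        assert unused >= 0
        assert len(layout.treated_wells) + len(layout.control_wells) + len(
            layout.blank_wells
        ) + unused == n_rows * n_cols


class TestMergeReplicates:
    def test_zero_sd_pair_kept(self):
        res = ps.merge_replicates([50, 50], threshold=30)
        assert res.merged_value == 50
        assert not res.excluded

    def test_overdispersed_pair_excluded(self):
        # sample SD of {0, 60} is sqrt(1800) ≈ 42.43 ≥ 30
        res = ps.merge_replicates([0, 60], threshold=30)
        assert res.sd == pytest.approx(42.426406871, abs=1e-6)
        assert res.excluded
        assert res.merged_value is None

    def test_singleton_kept_with_zero_sd(self):
        res = ps.merge_replicates([70])
        assert (res.merged_value, res.sd, res.excluded) == (70, 0.0, False)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            ps.merge_replicates([])

    def test_threshold_boundary_is_exclusive(self):
        # values with SD exactly at the threshold are excluded ("smaller than" kept)
        vals = [0.0, 2.0]  # sample SD = sqrt(2)
        sd = float(np.std(vals, ddof=1))
        assert ps.merge_replicates(vals, threshold=sd).excluded
        assert not ps.merge_replicates(vals, threshold=sd + 1e-9).excluded

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(min_value=-100, max_value=200), min_size=1, max_size=8),
        st.randoms(use_true_random=False),
    )
    def test_permutation_invariance(self, values, rnd):
        shuffled = list(values)
        rnd.shuffle(shuffled)
        a = ps.merge_replicates(values)
        b = ps.merge_replicates(shuffled)
        assert a.excluded == b.excluded
        assert a.sd == pytest.approx(b.sd, rel=1e-12, abs=1e-12)
        if not a.excluded:
            assert a.merged_value == pytest.approx(b.merged_value, rel=1e-12, abs=1e-12)
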