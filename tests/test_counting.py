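import numpy as np
import pandas as pd
import pytest

from ovicount.counting import (
    FilterConfig,
    WellCountRecord,
    count_plate,
    count_well,
    export_counts,
    filter_detections,
    read_counts,
    save_overlay,
)
from ovicount.plate import PlateGrid, WellAddress
from ovicount.segment import run_backend
from ovicount.synth import random_well_spec, render_plate, render_well
from ovicount.wells import WellBoundary, detect_well, preprocess
from test_segment import make_instance


def square_mask(shape, r0, c0, side):
    m = np.zeros(shape, dtype=bool)
    m[r0:r0 + side, c0:c0 + side] = True
    return m


def detection_set_with_areas(areas, inside=True, shape=(200, 200)):
    from ovicount.segment import DetectionSet

    insts = []
    c0 = 80 if inside else 2
    for i, a in enumerate(areas):
        side = int(round(np.sqrt(a)))
        insts.append(make_instance(square_mask(shape, c0, c0, side), 0.9 - i * 0.01))
    return DetectionSet(tuple(insts), shape)


BOUNDARY = WellBoundary((100.0, 100.0), 60.0, 1.0)


class TestFilterDetections:
    def test_area_window_inclusive(self):
        dets = detection_set_with_areas([1000, 3000, 5000])
        kept = filter_detections(dets, BOUNDARY)
        assert len(kept) == 1
        # exact bounds are kept: the window is [2500, 4000] inclusive
        exact = detection_set_with_areas([2500, 4000])
        assert len(filter_detections(exact, BOUNDARY)) == 2

    def test_outside_boundary_excluded(self):
        dets = detection_set_with_areas([3000], inside=False)
        assert len(filter_detections(dets, BOUNDARY)) == 0
        assert len(filter_detections(dets, None, FilterConfig(require_inside_well=False))) == 1

    def test_reflections_masked_out(self):
        spec = random_well_spec(41, n_eggs=6, n_reflections=2)
        img, truth = render_well(spec)
        pre = preprocess(img)
        boundary = detect_well(pre, 520)
        dets = run_backend(pre)
        masked = filter_detections(dets, boundary)
        unmasked = filter_detections(dets, None, FilterConfig(require_inside_well=False))
        assert len(masked) == truth.count == 6
        assert len(unmasked) == truth.count + 2

    @pytest.mark.parametrize("seed", range(8))
    def test_filter_monotonicity(self, seed):
        """Shrinking the area window or the boundary never increases the count."""
        rng = np.random.default_rng(seed)
        areas = rng.integers(500, 6000, size=12).tolist()
        dets = detection_set_with_areas(areas)
        wide = len(filter_detections(dets, BOUNDARY, FilterConfig(area_min=1, area_max=10000)))
        mid = len(filter_detections(dets, BOUNDARY))
        narrow = len(filter_detections(dets, BOUNDARY, FilterConfig(area_min=2800, area_max=3500)))
        assert wide >= mid >= narrow
        smaller = WellBoundary(BOUNDARY.center, 30.0, 1.0)
        assert len(filter_detections(dets, smaller)) <= len(filter_detections(dets, BOUNDARY))


class TestCountWell:
    def test_blank_well_counts_zero(self, tmp_path):
        from ovicount.synth import SyntheticWellSpec
        import imageio.v3 as iio

        img, _ = render_well(SyntheticWellSpec())
        p = tmp_path / "plate01_A1.png"
        iio.imwrite(p, img)
        rec = count_well(p, est_diameter=520)
        assert rec.count == 0
        assert rec.well == WellAddress(0, 0)

    def test_planted_eggs_counted(self, tmp_path):
        import imageio.v3 as iio

        spec = random_well_spec(43, n_eggs=5)
        img, _ = render_well(spec)
        p = tmp_path / "plate01_B2.png"
        iio.imwrite(p, img)
        rec = count_well(p, est_diameter=520)
        assert rec.count == 5 and rec.count <= rec.n_prefilter

    def test_area_window_below_planted_sizes_zeroes_count(self, tmp_path):
        import imageio.v3 as iio

        spec = random_well_spec(43, n_eggs=5)
        img, _ = render_well(spec)
        p = tmp_path / "plate01_B2.png"
        iio.imwrite(p, img)
        rec = count_well(
            p, est_diameter=520, filter_cfg=FilterConfig(area_min=100, area_max=200)
        )
        assert rec.count == 0

    def test_record_invariant(self):
        with pytest.raises(ValueError):
            WellCountRecord(WellAddress(0, 0), "p", count=3, n_prefilter=2)


@pytest.fixture(scope="module")
def small_plate(tmp_path_factory):
    out = tmp_path_factory.mktemp("plate")
    grid = PlateGrid(2, 2)
    specs = [random_well_spec(50 + i, n_eggs=n) for i, n in enumerate([2, 3, 4, 5])]
    truth = render_plate(grid, specs, out)
    return out, grid, truth


class TestCountPlate:
    def test_counts_match_truth(self, small_plate):
        out, grid, truth = small_plate
        table = count_plate(out, grid=grid)
        merged = table.merge(truth, on="well_label")
        assert (merged["count"] == merged["true_count"]).all()

    def test_propagation_matches_per_image_detection(self, small_plate):
        out, grid, _ = small_plate
        a = count_plate(out, grid=grid, propagate=True)
        b = count_plate(out, grid=grid, propagate=False)
        assert a["count"].tolist() == b["count"].tolist()

    def test_total_equals_sum_of_independent_wells(self, small_plate):
        out, grid, _ = small_plate
        table = count_plate(out, grid=grid)
        singles = sum(
            count_well(p, est_diameter=520).count for p in sorted(out.glob("*.png"))
        )
        assert table["count"].sum() == singles

    def test_layout_metadata_attached(self, small_plate):
        out, grid, _ = small_plate
        layout = pd.DataFrame(
            {
                "plate_id": ["plate01"] * 4,
                "well_label": ["A1", "A2", "B1", "B2"],
                "condition": ["dmso", "dmso", "rapa25", "rapa25"],
                "day": [1, 1, 1, 1],
            }
        )
        table = count_plate(out, layout=layout, grid=grid)
        assert set(table["condition"]) == {"dmso", "rapa25"}

    def test_empty_directory_warns(self, tmp_path):
        with pytest.warns(UserWarning, match="no well images"):
            table = count_plate(tmp_path)
        assert table.empty

    def test_duplicate_label_is_hard_error(self, tmp_path):
        import imageio.v3 as iio

        img, _ = render_well(random_well_spec(1, n_eggs=1))
        iio.imwrite(tmp_path / "plateA_A1.png", img)
        iio.imwrite(tmp_path / "plateB_A1.png", img)
        with pytest.raises(ValueError, match="duplicate well label"):
            count_plate(tmp_path)


class TestExport:
    def make_table(self):
        return pd.DataFrame(
            {
                "plate_id": ["p"] * 3,
                "well_label": ["A1", "A2", "A3"],
                "condition": ["c"] * 3,
                "day": [1, 1, 1],
                "count": [4, 5, 6],
                "n_prefilter": [4, 6, 6],
                "flags": ["", "", "well_detection_fallback"],
            }
        )

    def test_csv_round_trip(self, tmp_path):
        table = self.make_table()
        path = export_counts(table, tmp_path / "counts.csv")
        back = read_counts(path)
        pd.testing.assert_frame_equal(back, table)

    def test_xlsx_round_trip(self, tmp_path):
        table = self.make_table()
        path = export_counts(table, tmp_path / "counts.xlsx")
        back = read_counts(path)
        assert back["count"].tolist() == [4, 5, 6]

    def test_overlay_written_and_side_effect_free(self, tmp_path):
        spec = random_well_spec(47, n_eggs=5)
        img, _ = render_well(spec)
        pre = preprocess(img)
        boundary = detect_well(pre, 520)
        dets = run_backend(pre)
        before = dets.instances
        out = save_overlay(img, dets, boundary, tmp_path / "overlay.png")
        assert out.exists() and out.stat().st_size > 0
        assert dets.instances == before
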