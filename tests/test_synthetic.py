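"""Synthetic histology generator: tiles, slides, cohorts, ground truth."""

import numpy as np
import pandas as pd
import pytest
from skimage.measure import label as cc_label

from nashscore.features import TILE_PX
from nashscore.synthetic import (
    SyntheticSlideSpec,
    generate_cohort,
    generate_slide,
    generate_tile,
    render_slide,
    render_tile,
)


class TestTiles:
    def test_steatosis_tile_vacuole_fraction_inside_bin(self):
        # bin 4 covers [20, 25)% vacuole area
        tr = render_tile("steatosis", 4, tile_px=299, mpp=0.44, seed=7)
        frac = tr.vacuole_mask.mean()
        assert 0.20 <= frac < 0.25

    @pytest.mark.parametrize("bin_index", [0, 2, 8, 14])
    def test_steatosis_bins_are_rendered_in_range(self, bin_index):
        from nashscore.features import STEATOSIS_BIN_EDGES

        tr = render_tile("steatosis", bin_index, seed=bin_index + 1)
        lo, hi = STEATOSIS_BIN_EDGES[bin_index] / 100, STEATOSIS_BIN_EDGES[bin_index + 1] / 100
        assert lo <= tr.vacuole_mask.mean() < hi

    def test_ballooning_absence_class_has_no_balloon_primitives(self):
        tr = render_tile("ballooning", 0, tile_px=299, mpp=0.44, seed=1)
        assert not any(p["kind"] == "balloon" for p in tr.primitives)
        tr1 = render_tile("ballooning", 1, seed=2)
        assert any(p["kind"] == "balloon" for p in tr1.primitives)

    def test_fibrosis_bridging_tile_connects_two_rims(self):
        tr = render_tile("fibrosis", 3, tile_px=299, mpp=1.32, seed=3)
        rims = [p["center"] for p in tr.primitives if p["kind"] == "portal_rim"]
        bridges = [p for p in tr.primitives if p["kind"] == "bridge"]
        assert len(rims) >= 2 and len(bridges) >= 1
        # the two bridged rims belong to one connected collagen component
        labelled = cc_label(tr.collagen_mask, connectivity=2)
        br = bridges[0]
        comp_a = labelled[int(round(br["from"][0])) % 299, int(round(br["from"][1])) % 299]
        comp_b = labelled[int(round(br["to"][0])) % 299, int(round(br["to"][1])) % 299]
        assert comp_a == comp_b and comp_a > 0

    def test_inflammation_tile_class_counts(self):
        assert not any(p["kind"] == "focus" for p in render_tile("inflammation", 0, seed=4).primitives)
        n1 = sum(p["kind"] == "focus" for p in render_tile("inflammation", 1, seed=4).primitives)
        n2 = sum(p["kind"] == "focus" for p in render_tile("inflammation", 2, seed=4).primitives)
        assert 1 <= n1 <= 2 and n2 >= 3

    def test_invalid_class_rejected_with_message(self):
        with pytest.raises(ValueError, match="invalid class"):
            generate_tile("ballooning", 2)
        with pytest.raises(ValueError, match="unknown feature"):
            generate_tile("cholestasis", 0)

    def test_tiles_are_uint8_rgb_and_deterministic(self):
        img1, label = generate_tile("fibrosis", 2, seed=9)
        img2, _ = generate_tile("fibrosis", 2, seed=9)
        assert img1.dtype == np.uint8 and img1.shape == (299, 299, 3)
        assert label == 2
        np.testing.assert_array_equal(img1, img2)
        img3, _ = generate_tile("fibrosis", 2, seed=10)
        assert not np.array_equal(img1, img3)

    def test_ignore_tiles_render_artifacts(self):
        kinds = {render_tile("steatosis", "ignore", seed=s).primitives[-1]["kind"] for s in range(8)}
        assert kinds <= {"ignore_blank", "ignore_edge", "ignore_pen"}
        assert len(kinds) >= 2


class TestSlides:
    def test_spec_validation(self):
        with pytest.raises(ValueError, match="at least one tile"):
            SyntheticSlideSpec(slide_id="x", width_px=100, height_px=100)
        with pytest.raises(ValueError, match="steatosis_area_frac"):
            SyntheticSlideSpec(slide_id="x", steatosis_area_frac=1.2)
        with pytest.raises(ValueError, match="fibrosis_class"):
            SyntheticSlideSpec(slide_id="x", fibrosis_class=5)

    def test_slide_scores_follow_kleiner_rules(self):
        spec = SyntheticSlideSpec(slide_id="s", steatosis_area_frac=0.20, inflam_foci_per_field=3.0,
                                  ballooning_burden="few", fibrosis_class=2)
        assert spec.slide_scores() == {"ballooning": 1, "inflammation": 2, "steatosis": 1, "fibrosis": 2}

    def test_null_pathology_scores_all_zero(self):
        spec = SyntheticSlideSpec(slide_id="s", width_px=897, height_px=897)
        assert set(spec.slide_scores().values()) == {0}

    def test_tile_label_grid_shapes(self, tmp_path):
        spec = SyntheticSlideSpec(slide_id="s", width_px=897, height_px=598, seed=1)
        path, gt = generate_slide(spec, tmp_path)
        assert gt.per_tile_labels["steatosis"].shape == (598 // TILE_PX, 897 // TILE_PX) == (2, 3)
        assert gt.per_tile_labels["ballooning"].shape == (2, 3)
        # at 1:3 downscale a 897x598 slide holds no complete low-res tile rows
        assert gt.per_tile_labels["fibrosis"].shape == (0, 1)
        assert path.exists()

    def test_rendered_steatosis_area_matches_spec_within_2_points(self):
        for frac, seed in [(0.10, 1), (0.40, 2), (0.65, 3)]:
            spec = SyntheticSlideSpec(slide_id="s", width_px=897, height_px=897, steatosis_area_frac=frac, seed=seed)
            sr = render_slide(spec)  # 3x3 = 9 high-res tiles
            assert abs(sr.vacuole_mask.mean() - frac) < 0.02

    def test_slide_tiff_round_trip(self, tmp_path):
        from nashscore.tiling import load_slide

        spec = SyntheticSlideSpec(slide_id="rt", width_px=897, height_px=897, steatosis_area_frac=0.1, seed=4)
        path, _ = generate_slide(spec, tmp_path)
        slide = load_slide(path)
        assert slide.mpp == pytest.approx(0.44, rel=1e-6)
        assert slide.pixels.shape == (897, 897, 3)

    def test_per_tile_steatosis_labels_consistent_with_mask(self):
        from nashscore.features import steatosis_bin_index

        spec = SyntheticSlideSpec(slide_id="s", width_px=897, height_px=897, steatosis_area_frac=0.3, seed=8)
        sr = render_slide(spec)
        vac = sr.vacuole_mask
        for (r, c), lbl in np.ndenumerate(sr.ground_truth.per_tile_labels["steatosis"]):
            frac = vac[r * TILE_PX : (r + 1) * TILE_PX, c * TILE_PX : (c + 1) * TILE_PX].mean()
            assert lbl == steatosis_bin_index(100 * frac)


class TestCohorts:
    def test_determinism(self, tmp_path):
        m1 = generate_cohort(6, tmp_path / "a", seed=0, width_px=299, height_px=299, write_tile_labels=False)
        m2 = generate_cohort(6, tmp_path / "b", seed=0, width_px=299, height_px=299, write_tile_labels=False)
        pd.testing.assert_frame_equal(m1.drop(columns="path"), m2.drop(columns="path"))

    def test_noiseless_manifest_round_trips_truth(self, tmp_path):
        m = generate_cohort(10, tmp_path, seed=3, width_px=299, height_px=299, write_tile_labels=False)
        for feat in ["ballooning", "inflammation", "steatosis", "fibrosis"]:
            np.testing.assert_array_equal(m[feat], m[f"true_{feat}"])

    def test_uniform_fibrosis_counts_within_binomial_bounds(self, tmp_path):
        mix = {
            "ballooning": [1, 0, 0],
            "inflammation": [1, 0, 0, 0],
            "steatosis": [1, 0, 0, 0],
            "fibrosis": [0.2] * 5,
        }
        m = generate_cohort(200, tmp_path, score_mix=mix, seed=5, width_px=299, height_px=299,
                            write_tile_labels=False)
        counts = m["fibrosis"].value_counts()
        for k in range(5):
            assert 20 <= counts.get(k, 0) <= 60

    def test_observer_noise_shifts_by_at_most_one(self, tmp_path):
        m = generate_cohort(40, tmp_path, observer_noise_sd=0.6, seed=6, width_px=299, height_px=299,
                            write_tile_labels=False)
        diffs = (m["fibrosis"] - m["true_fibrosis"]).abs()
        assert diffs.max() <= 1
        assert (m[["ballooning", "inflammation", "steatosis", "fibrosis"]].to_numpy() >= 0).all()
        # some perturbation should actually occur at this noise level
        all_feats = ["ballooning", "inflammation", "steatosis", "fibrosis"]
        assert sum((m[f] != m[f"true_{f}"]).sum() for f in all_feats) > 0

    def test_manifest_columns_and_split(self, tmp_path):
        m = generate_cohort(8, tmp_path, seed=7, width_px=299, height_px=299, write_tile_labels=False)
        for col in ["slide_id", "path", "ballooning", "inflammation", "steatosis", "fibrosis", "split"]:
            assert col in m.columns
        assert set(m["split"]) == {"train", "test"}
        assert (m["split"] == "train").sum() == 6  # 75% of 8

    def test_invalid_mix_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="distribution"):
            generate_cohort(2, tmp_path, score_mix={"fibrosis": [0.5, 0.5]}, width_px=299, height_px=299)
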