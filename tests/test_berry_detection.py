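"""Detection-stage tests: Hough candidates, one-class model, color extraction."""

import dataclasses

import numpy as np
import pytest
from scipy.signal import fftconvolve
from skimage.color import rgb2gray
from skimage.draw import circle_perimeter
from skimage.feature import canny

from berrypheno import (
    SceneSpec,
    detect_circles,
    extract_berry_color,
    extract_patch,
    featurize_patch,
    filter_candidates,
    fit_one_class_model,
    render_scene,
)
from berrypheno.benchmark import match_detections, training_patches
from berrypheno.berry_detection import (
    CANNY_SIGMA,
    OneClassModel,
    write_detections_tsv,
)
from berrypheno.synthetic_scene import SHADING, disk_mask


def draw_shaded_circle(img, cx, cy, r, base=(120.0, 90.0, 70.0)):
    yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    d2 = (xx - cx) ** 2 + (yy - cy) ** 2
    mask = d2 <= r**2
    shade = 1.0 - SHADING * d2[mask] / r**2
    img[mask] = np.asarray(base)[None, :] * shade[:, None]
    return img


class TestDetectCircles:
    def test_uniform_image_yields_nothing(self):
        img = np.zeros((120, 120, 3), dtype=np.uint8)
        assert detect_circles(img, 5, 20) == []

    @pytest.mark.parametrize("rmin,rmax", [(0, 10), (12, 10), (5, 80)])
    def test_invalid_radius_range(self, rmin, rmax):
        img = np.zeros((100, 100, 3), dtype=np.uint8)
        with pytest.raises(ValueError):
            detect_circles(img, rmin, rmax)

    def test_single_circle_recovered_subpixel(self):
        img = np.full((140, 140, 3), 15.0)
        draw_shaded_circle(img, 67.0, 71.0, 18.0)
        cands = detect_circles(np.clip(img, 0, 255).astype(np.uint8), 12, 24)
        assert cands
        cx, cy, r, _ = cands[0]
        assert abs(r - 18.0) <= 1.0
        assert np.hypot(cx - 67.0, cy - 71.0) <= 1.0

    def test_ten_separated_berries_recovered(self):
        """At least 9 of 10 non-overlapping berries of radius 15-25 px are
        found with center and radius errors of at most 2 px."""
        spec = SceneSpec(
            n_berries=10,
            radius_range_px=(15, 25),
            image_size=(640, 480),
            max_overlap=0.0,
            seed=8,
        )
        image, truth = render_scene(spec)
        cands = detect_circles(image, 12, 28)
        matched = 0
        for b in truth.berries:
            for cx, cy, r, _ in cands:
                if np.hypot(cx - b["cx"], cy - b["cy"]) <= 2 and abs(r - b["r"]) <= 2:
                    matched += 1
                    break
        assert matched >= 9

    def test_nms_spacing_contract(self, default_scene):
        image, _ = default_scene
        cands = detect_circles(image, 9, 20)
        scores = [c[3] for c in cands]
        assert scores == sorted(scores, reverse=True)
        for i in range(len(cands)):
            for j in range(i + 1, len(cands)):
                d = np.hypot(cands[i][0] - cands[j][0], cands[i][1] - cands[j][1])
                # NMS operated on the unrefined integer candidates; refinement
                # moves circles by at most ~1 px each
                assert d >= 0.8 * (cands[i][2] + cands[j][2]) / 2.0 - 2.0

    def test_matches_brute_force_template_search(self):
        """On a few perfect circles, the detector agrees with an exhaustive
        perimeter-coverage search over all (x, y, r) within quantization."""
        img = np.full((150, 150, 3), 12.0)
        circles = [(40.0, 45.0, 13.0), (105.0, 50.0, 17.0), (60.0, 110.0, 11.0)]
        for cx, cy, r in circles:
            draw_shaded_circle(img, cx, cy, r)
        img = np.clip(img, 0, 255).astype(np.uint8)

        edges = canny(rgb2gray(img / 255.0), sigma=CANNY_SIGMA).astype(float)
        best = {}  # oracle: for each radius, full coverage map via convolution
        for r in range(9, 20):
            rr, cc = circle_perimeter(0, 0, r)
            kern = np.zeros((2 * r + 1, 2 * r + 1))
            kern[rr + r, cc + r] = 1.0
            cov = fftconvolve(edges, kern, mode="same") / len(rr)
            best[r] = cov
        oracle = []
        for cx, cy, r in circles:  # argmax in the neighbourhood of each circle
            cands = []
            for rr in best:
                win = best[rr][int(cy) - 4 : int(cy) + 5, int(cx) - 4 : int(cx) + 5]
                k = np.unravel_index(np.argmax(win), win.shape)
                cands.append((win[k], int(cy) - 4 + k[0], int(cx) - 4 + k[1], rr))
            s, oy, ox, orr = max(cands)
            oracle.append((ox, oy, orr))

        detected = detect_circles(img, 9, 19)
        assert len(detected) == len(circles)
        for ox, oy, orr in oracle:
            assert any(
                np.hypot(cx - ox, cy - oy) <= 2 and abs(r - orr) <= 2
                for cx, cy, r, _ in detected
            )


class TestOneClassModel:
    def test_too_few_patches(self):
        with pytest.raises(ValueError):
            fit_one_class_model([np.ones((9, 9, 3))] * 9)

    def test_identical_patches_handled_by_ridge(self):
        patches = [np.full((11, 11, 3), 80.0)] * 12
        model = fit_one_class_model(patches)
        assert np.isfinite(model.feature_covariance).all()
        # every training patch accepted despite zero variance
        d = model.mahalanobis(featurize_patch(patches[0]))
        assert d <= model.acceptance_threshold + 1e-9

    def test_quantile_one_accepts_all_training(self, rng):
        patches = [rng.uniform(0, 255, size=(13, 13, 3)) for _ in range(25)]
        model = fit_one_class_model(patches, quantile=1.0)
        for p in patches:
            assert model.mahalanobis(featurize_patch(p)) <= model.acceptance_threshold + 1e-9

    def test_berry_acceptance_and_background_rejection(self, trained_one_class_model):
        """Held-out berries are accepted >= 95% of the time, background
        patches <= 10%."""
        model = trained_one_class_model
        n_pos = acc_pos = n_neg = acc_neg = 0
        rng = np.random.default_rng(99)
        for i in range(6):
            image, truth = render_scene(SceneSpec(seed=900 + i))
            h, w = image.shape[:2]
            for b in truth.berries:
                d = model.mahalanobis(
                    featurize_patch(extract_patch(image, b["cx"], b["cy"], b["r"]))
                )
                n_pos += 1
                acc_pos += d <= model.acceptance_threshold
            tries = 0
            while n_neg < (i + 1) * 20 and tries < 500:
                tries += 1
                r = rng.uniform(10, 16)
                cx = rng.uniform(r + 1, w - r - 2)
                cy = rng.uniform(r + 1, h - r - 2)
                if any(
                    np.hypot(cx - b["cx"], cy - b["cy"]) < r + b["r"] + 2
                    for b in truth.berries
                ):
                    continue
                d = model.mahalanobis(
                    featurize_patch(extract_patch(image, cx, cy, r))
                )
                n_neg += 1
                acc_neg += d <= model.acceptance_threshold
        assert acc_pos / n_pos >= 0.95
        assert acc_neg / n_neg <= 0.10

    def test_threshold_monotonicity(self, trained_one_class_model, default_scene):
        """Raising the acceptance threshold never loses detections."""
        image, _ = default_scene
        cands = detect_circles(image, 9, 20)
        base = trained_one_class_model
        counts = [
            len(filter_candidates(image, cands, dataclasses.replace(base, acceptance_threshold=t)))
            for t in (0.5, 1.0, 2.0, base.acceptance_threshold, 50.0)
        ]
        assert counts == sorted(counts)


class TestFilterCandidates:
    def test_empty_candidates(self, trained_one_class_model, default_scene):
        image, _ = default_scene
        assert filter_candidates(image, [], trained_one_class_model) == []

    def test_training_patch_is_accepted(self, trained_one_class_model):
        image, truth = render_scene(SceneSpec(seed=500))  # part of the training set
        b = truth.berries[0]
        dets = filter_candidates(
            image, [(b["cx"], b["cy"], b["r"], 1.0)], trained_one_class_model
        )
        assert len(dets) == 1
        assert dets[0].score > 0.0

    def test_spurious_circles_rejected(self, trained_one_class_model):
        """Injected background circles pass the filter at most 10% of the time."""
        rng = np.random.default_rng(5)
        n = kept = 0
        for i in range(5):
            image, truth = render_scene(SceneSpec(seed=700 + i))
            h, w = image.shape[:2]
            spurious = []
            while len(spurious) < 15:
                r = rng.uniform(10, 16)
                cx = rng.uniform(r + 1, w - r - 2)
                cy = rng.uniform(r + 1, h - r - 2)
                if all(
                    np.hypot(cx - b["cx"], cy - b["cy"]) > r + b["r"] + 2
                    for b in truth.berries
                ):
                    spurious.append((cx, cy, r, 0.5))
            dets = filter_candidates(image, spurious, trained_one_class_model)
            n += len(spurious)
            kept += len(dets)
        assert kept / n <= 0.10


class TestExtractBerryColor:
    def test_uniform_disk_exact(self):
        img = np.zeros((60, 60, 3))
        img[disk_mask((60, 60), 30, 30, 12)] = (10.0, 20.0, 30.0)
        assert extract_berry_color(img, (30, 30), 12) == pytest.approx((10, 20, 30))

    def test_painted_mean_recovered(self, nonoverlap_scene):
        """Rendered berries' inner-disk means match the generator's analytic
        expectation within +/- 3 per channel."""
        image, truth = nonoverlap_scene
        for b in truth.berries:
            got = extract_berry_color(image, (b["cx"], b["cy"]), b["r"])
            assert got == pytest.approx(tuple(b["mean_rgb"]), abs=3.0)

    def test_single_pixel_fallback(self):
        img = np.zeros((20, 20, 3))
        img[10, 10] = (5.0, 6.0, 7.0)
        # inner disk of 0.8*0.6 px contains no pixel center away from (10,10)
        assert extract_berry_color(img, (10.3, 10.3), 0.6) == pytest.approx(
            (5, 6, 7), abs=1e-9
        )

    def test_out_of_bounds_rejected(self):
        img = np.zeros((30, 30, 3))
        with pytest.raises(ValueError):
            extract_berry_color(img, (2, 2), 10)


class TestDetectionTsv:
    def test_tsv_layout_and_calibration_comment(self, tmp_path, default_scene,
                                                trained_one_class_model):
        image, _ = default_scene
        dets = filter_candidates(
            image, detect_circles(image, 9, 20), trained_one_class_model
        )
        path = tmp_path / "out.tsv"
        write_detections_tsv(path, "scene.png", dets, mm_per_pixel=0.4)
        lines = path.read_text().splitlines()
        assert lines[0] == "# mm_per_pixel=0.4"
        assert lines[1].split("\t")[:3] == ["image", "berry_index", "center_x"]
        assert len(lines) == 2 + len(dets)
        dia = float(lines[2].split("\t")[5])
        r = float(lines[2].split("\t")[4])
        assert dia == pytest.approx(2 * r * 0.4, abs=0.01)

        write_detections_tsv(path, "scene.png", dets, mm_per_pixel=None)
        lines = path.read_text().splitlines()
        assert not lines[0].startswith("#")
        assert lines[1].split("\t")[5] == ""  # diameter blank if uncalibrated
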