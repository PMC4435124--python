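"""Standard synthetic detection/size benchmark.

Trains the one-class model on ground-truth berry patches from a set of
training scenes, runs the full detection pipeline (Hough candidates,
one-class filtering, label calibration, mm conversion) on disjoint
evaluation scenes, and scores recall, precision and diameter error
against generator truth by greedy matching.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .berry_detection import (
    BerryDetection,
    detect_berries,
    extract_patch,
    fit_one_class_model,
)
from .size_calibration import LabelNotFoundError, calibrate_image
from .synthetic_scene import SceneSpec, render_scene

# matching tolerances: a detection claims a truth berry when the center is
# within half a radius and the radius within 35%
MATCH_CENTER_FACTOR = 0.5
MATCH_RADIUS_FACTOR = 0.35


@dataclass(frozen=True)
class BenchmarkResult:
    n_scenes: int
    n_true: int
    n_detected: int
    n_matched: int
    recall: float
    precision: float
    diameter_rmse_pct: float  # RMS relative diameter error, percent
    mean_abs_diameter_err_mm: float


def match_detections(
    truth_berries: list[dict], detections: list[BerryDetection]
) -> list[tuple[int, int]]:
    """Greedy one-to-one matching of detections (score-descending) to the
    nearest unclaimed truth circle within tolerance. Returns index pairs
    (truth_idx, det_idx)."""
    order = sorted(range(len(detections)), key=lambda i: -detections[i].score)
    claimed: set[int] = set()
    pairs = []
    for di in order:
        det = detections[di]
        best, best_d = None, np.inf
        for ti, tb in enumerate(truth_berries):
            if ti in claimed:
                continue
            d = float(np.hypot(det.center_x - tb["cx"], det.center_y - tb["cy"]))
            if (
                d <= MATCH_CENTER_FACTOR * tb["r"]
                and abs(det.radius - tb["r"]) <= MATCH_RADIUS_FACTOR * tb["r"]
                and d < best_d
            ):
                best, best_d = ti, d
        if best is not None:
            claimed.add(best)
            pairs.append((best, di))
    return pairs


def training_patches(specs: list[SceneSpec]) -> list[np.ndarray]:
    """Ground-truth berry patches from rendered training scenes."""
    patches = []
    for spec in specs:
        image, truth = render_scene(spec)
        for b in truth.berries:
            try:
                patches.append(extract_patch(image, b["cx"], b["cy"], b["r"]))
            except ValueError:
                continue
    return patches


def run_detection_benchmark(
    n_scenes: int = 50,
    n_train_scenes: int = 20,
    base_spec: SceneSpec | None = None,
    seed: int = 0,
    quantile: float = 0.99,
) -> BenchmarkResult:
    """Run the standard synthetic benchmark and score it against truth."""
    base = base_spec or SceneSpec()
    train_specs = [replace(base, seed=seed * 100003 + 1000 + i) for i in range(n_train_scenes)]
    model = fit_one_class_model(training_patches(train_specs), quantile=quantile)

    rmin = max(2, int(np.floor(base.radius_range_px[0] - 3)))
    rmax = int(np.ceil(base.radius_range_px[1] + 3))

    n_true = n_det = n_matched = 0
    sq_rel_err = []
    abs_err_mm = []
    for i in range(n_scenes):
        spec = replace(base, seed=seed * 100003 + i)
        image, truth = render_scene(spec)
        detections = detect_berries(image, rmin, rmax, model)
        try:
            cal = calibrate_image(image, spec.label_length_mm)
            mmpp = cal.mm_per_pixel
        except LabelNotFoundError:
            mmpp = None
        n_true += len(truth.berries)
        n_det += len(detections)
        pairs = match_detections(truth.berries, detections)
        n_matched += len(pairs)
        for ti, di in pairs:
            d_true_mm = 2.0 * truth.berries[ti]["r"] * truth.mm_per_pixel
            if mmpp is None:
                continue
            d_est_mm = 2.0 * detections[di].radius * mmpp
            sq_rel_err.append(((d_est_mm - d_true_mm) / d_true_mm) ** 2)
            abs_err_mm.append(abs(d_est_mm - d_true_mm))
    return BenchmarkResult(
        n_scenes=n_scenes,
        n_true=n_true,
        n_detected=n_det,
        n_matched=n_matched,
        recall=n_matched / n_true if n_true else 1.0,
        precision=n_matched / n_det if n_det else 1.0,
        diameter_rmse_pct=100.0 * float(np.sqrt(np.mean(sq_rel_err))) if sq_rel_err else 0.0,
        mean_abs_diameter_err_mm=float(np.mean(abs_err_mm)) if abs_err_mm else 0.0,
    )
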