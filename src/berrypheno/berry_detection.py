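"""Berry detection: circular Hough candidates vetted by a one-class model.

The detector runs in three stages:

1. :func:`detect_circles` — Canny edge map, circular Hough transform over
   the requested radius range, greedy non-maximum suppression, then
   sub-pixel refinement of each surviving circle by an algebraic
   least-squares fit to nearby edge points.
2. :func:`fit_one_class_model` — a Gaussian one-class model over a
   7-dimensional patch feature vector (per-channel mean, per-channel
   standard deviation, radial intensity-falloff slope), trained on
   positive berry patches only; candidates are accepted when their
   Mahalanobis distance is below a quantile threshold of the training
   distances.
3. :func:`filter_candidates` — applies the model and attaches each kept
   berry's mean RGB (:func:`extract_berry_color`, rim excluded).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.color import rgb2gray
from skimage.feature import canny, peak_local_max
from skimage.transform import hough_circle

from .synthetic_scene import RIM_FRACTION, disk_mask

# Hough accumulator is normalised by circumference: a peak value is roughly
# the fraction of the circle perimeter supported by edge pixels.
HOUGH_PEAK_THRESHOLD = 0.35
NMS_CENTER_FACTOR = 0.8  # two accepted circles must be >= 0.8*(r1+r2)/2 apart
CANNY_SIGMA = 1.6
DEFAULT_QUANTILE = 0.99
RIDGE_SCALE = 1e-6
COND_LIMIT = 1e10


@dataclass(frozen=True)
class BerryDetection:
    """One segmented berry: position, size, color, acceptance score."""

    center_x: float
    center_y: float
    radius: float
    mean_rgb: tuple[float, float, float]
    score: float


@dataclass(frozen=True)
class OneClassModel:
    """Gaussian one-class acceptance model over patch features."""

    feature_mean: np.ndarray
    feature_covariance: np.ndarray
    acceptance_threshold: float

    def mahalanobis(self, features: np.ndarray) -> float:
        d = np.asarray(features, float) - self.feature_mean
        return float(np.sqrt(d @ np.linalg.solve(self.feature_covariance, d)))


def _as_float_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    if image.size == 0:
        raise ValueError("empty image")
    return image.astype(float)


# --------------------------------------------------------------------------
# Stage 1: circle candidates
# --------------------------------------------------------------------------


def _refine_circle(
    edges: np.ndarray, cx: float, cy: float, r: float, band: float = 2.5
) -> tuple[float, float, float]:
    """Sub-pixel circle refinement: Kasa algebraic fit to edge points in an
    annulus around the Hough candidate. Falls back to the input on failure."""
    ys, xs = np.nonzero(edges)
    d = np.hypot(xs - cx, ys - cy)
    sel = np.abs(d - r) <= band
    if sel.sum() < 8:
        return cx, cy, r
    x, y = xs[sel].astype(float), ys[sel].astype(float)
    A = np.column_stack([x, y, np.ones_like(x)])
    b = x**2 + y**2
    try:
        sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    except np.linalg.LinAlgError:
        return cx, cy, r
    rcx, rcy = sol[0] / 2.0, sol[1] / 2.0
    rr2 = sol[2] + rcx**2 + rcy**2
    if rr2 <= 0:
        return cx, cy, r
    rr = float(np.sqrt(rr2))
    # reject wild refinements (fit captured by a neighbouring structure)
    if np.hypot(rcx - cx, rcy - cy) > band + 1 or abs(rr - r) > band + 1:
        return cx, cy, r
    return float(rcx), float(rcy), rr


def detect_circles(
    image: np.ndarray,
    rmin: int,
    rmax: int,
    peak_threshold: float = HOUGH_PEAK_THRESHOLD,
) -> list[tuple[float, float, float, float]]:
    """Detect circle candidates by circular Hough transform.

    Returns ``(center_x, center_y, radius, accumulator_score)`` tuples
    sorted by score descending. Candidates are non-maximum suppressed so no
    two accepted circles have center distance below
    ``0.8 * (r1 + r2) / 2``; ties in score break toward smaller
    ``(y, x, r)``. Accepted circles are refined to sub-pixel precision
    against the edge map.
    """
    image = _as_float_image(image)
    h, w = image.shape[:2]
    if not (0 < rmin <= rmax < min(h, w) / 2):
        raise ValueError(f"invalid radius range ({rmin}, {rmax}) for {w}x{h} image")

    grey = rgb2gray(image / 255.0)
    edges = canny(grey, sigma=CANNY_SIGMA)
    if not edges.any():
        return []

    radii = np.arange(int(rmin), int(rmax) + 1)
    spaces = hough_circle(edges, radii, normalize=True)

    raw: list[tuple[float, int, int, int]] = []  # (score, y, x, r)
    for r, space in zip(radii, spaces):
        peaks = peak_local_max(space, min_distance=3, threshold_abs=peak_threshold)
        for py, px in peaks:
            raw.append((float(space[py, px]), int(py), int(px), int(r)))
    # score descending; equal scores break toward smaller (y, x, r)
    raw.sort(key=lambda t: (-t[0], t[1], t[2], t[3]))

    accepted: list[tuple[float, float, float, float]] = []  # cx, cy, r, score
    for score, py, px, r in raw:
        close = any(
            np.hypot(px - acx, py - acy) < NMS_CENTER_FACTOR * (r + ar) / 2.0
            for acx, acy, ar, _ in accepted
        )
        if close:
            continue
        cx, cy, rr = _refine_circle(edges, float(px), float(py), float(r))
        if not (rr <= cx <= w - 1 - rr and rr <= cy <= h - 1 - rr):
            continue
        accepted.append((cx, cy, rr, score))
    return accepted


# --------------------------------------------------------------------------
# Stage 2: one-class patch model
# --------------------------------------------------------------------------


def extract_patch(image: np.ndarray, cx: float, cy: float, r: float) -> np.ndarray:
    """Square RGB patch whose inscribed circle is the berry candidate."""
    image = _as_float_image(image)
    h, w = image.shape[:2]
    half = int(np.ceil(r))
    x0, x1 = int(round(cx)) - half, int(round(cx)) + half + 1
    y0, y1 = int(round(cy)) - half, int(round(cy)) + half + 1
    if x0 < 0 or y0 < 0 or x1 > w or y1 > h:
        raise ValueError(f"patch for circle ({cx}, {cy}, r={r}) exceeds image bounds")
    return image[y0:y1, x0:x1]


def featurize_patch(patch: np.ndarray) -> np.ndarray:
    """7-vector: per-channel mean, per-channel SD, radial falloff slope.

    The slope is the least-squares coefficient of grey intensity against
    normalised radial distance d/r over the inscribed disk; shaded convex
    berries give a clearly negative slope, flat clutter does not.
    """
    patch = np.asarray(patch, float)
    h, w = patch.shape[:2]
    r = (min(h, w) - 1) / 2.0
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    d = np.hypot(xx - cx, yy - cy)
    mask = d <= r
    pix = patch[mask]
    means = pix.mean(axis=0)
    sds = pix.std(axis=0)
    grey = pix.mean(axis=1)
    rho = d[mask] / max(r, 1e-9)
    rho_c = rho - rho.mean()
    denom = float(rho_c @ rho_c)
    slope = float(rho_c @ (grey - grey.mean()) / denom) if denom > 0 else 0.0
    return np.concatenate([means, sds, [slope]])


def fit_one_class_model(
    positive_patches: list[np.ndarray], quantile: float = DEFAULT_QUANTILE
) -> OneClassModel:
    """Fit the Gaussian one-class model on positive berry patches only.

    The acceptance threshold is the ``quantile``-quantile of the training
    Mahalanobis distances (default 0.99). A near-singular covariance is
    ridge-regularised by ``1e-6 * trace / dim`` on the diagonal.
    """
    if len(positive_patches) < 10:
        raise ValueError(f"need >= 10 positive patches, got {len(positive_patches)}")
    feats = np.array([featurize_patch(p) for p in positive_patches])
    mean = feats.mean(axis=0)
    cov = np.cov(feats, rowvar=False)
    tr = float(np.trace(cov))
    ridge = RIDGE_SCALE * (tr / cov.shape[0] if tr > 0 else 1.0)
    if tr <= 0 or np.linalg.cond(cov) > COND_LIMIT:
        cov = cov + ridge * np.eye(cov.shape[0])
    model = OneClassModel(mean, cov, acceptance_threshold=np.inf)
    dists = np.array(
        [OneClassModel.mahalanobis(model, f) for f in feats]
    )
    thr = float(np.quantile(dists, quantile))
    return OneClassModel(mean, cov, acceptance_threshold=thr)


# --------------------------------------------------------------------------
# Stage 3: filtering and color extraction
# --------------------------------------------------------------------------


def extract_berry_color(
    image: np.ndarray, center: tuple[float, float], radius: float
) -> tuple[float, float, float]:
    """Channel-wise mean over the inner disk of radius ``0.8 * radius``.

    The rim is excluded to avoid background bleed at the berry edge. A
    degenerate inner disk falls back to the single pixel at the center.
    """
    image = _as_float_image(image)
    h, w = image.shape[:2]
    cx, cy = center
    if not (radius <= cx <= w - 1 - radius and radius <= cy <= h - 1 - radius):
        raise ValueError(f"circle ({cx}, {cy}, r={radius}) exceeds image bounds")
    mask = disk_mask((h, w), cx, cy, RIM_FRACTION * radius)
    if not mask.any():
        px = image[int(round(cy)), int(round(cx))]
        return tuple(float(v) for v in px)
    return tuple(float(v) for v in image[mask].mean(axis=0))


def filter_candidates(
    image: np.ndarray,
    candidates: list[tuple[float, float, float, float]],
    model: OneClassModel,
) -> list[BerryDetection]:
    """Vet Hough candidates with the one-class model.

    A candidate is kept iff its patch's Mahalanobis distance is within the
    model threshold; its score is ``exp(-d^2 / 2)`` (already in [0, 1]).
    """
    image = _as_float_image(image)
    out = []
    for cx, cy, r, _acc in candidates:
        try:
            feats = featurize_patch(extract_patch(image, cx, cy, r))
        except ValueError:
            continue
        d = model.mahalanobis(feats)
        if d <= model.acceptance_threshold:
            out.append(
                BerryDetection(
                    center_x=cx,
                    center_y=cy,
                    radius=r,
                    mean_rgb=extract_berry_color(image, (cx, cy), r),
                    score=float(np.exp(-(d**2) / 2.0)),
                )
            )
    return out


def detect_berries(
    image: np.ndarray, rmin: int, rmax: int, model: OneClassModel
) -> list[BerryDetection]:
    """Full detection pass: Hough candidates then one-class filtering."""
    return filter_candidates(image, detect_circles(image, rmin, rmax), model)


# --------------------------------------------------------------------------
# TSV output (one row per berry, loop-wise per analysed image)
# --------------------------------------------------------------------------

DETECTION_COLUMNS = [
    "image",
    "berry_index",
    "center_x",
    "center_y",
    "radius_px",
    "diameter_mm",
    "mean_R",
    "mean_G",
    "mean_B",
    "score",
]


def write_detections_tsv(
    path: str | Path,
    image_name: str,
    detections: list[BerryDetection],
    mm_per_pixel: float | None = None,
) -> None:
    """Write per-berry rows as tab-separated values.

    The calibration, when present, is recorded as a ``# mm_per_pixel=``
    header comment; ``diameter_mm`` stays blank for uncalibrated images.
    """
    lines = []
    if mm_per_pixel is not None:
        lines.append(f"# mm_per_pixel={mm_per_pixel:.6g}")
    lines.append("\t".join(DETECTION_COLUMNS))
    for i, det in enumerate(detections):
        dia = f"{2.0 * det.radius * mm_per_pixel:.3f}" if mm_per_pixel else ""
        lines.append(
            "\t".join(
                [
                    image_name,
                    str(i),
                    f"{det.center_x:.2f}",
                    f"{det.center_y:.2f}",
                    f"{det.radius:.2f}",
                    dia,
                    f"{det.mean_rgb[0]:.2f}",
                    f"{det.mean_rgb[1]:.2f}",
                    f"{det.mean_rgb[2]:.2f}",
                    f"{det.score:.4f}",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")
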