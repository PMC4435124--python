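"""Synthetic vineyard scenes with full ground truth.

Generates the two kinds of inputs the rest of the pipeline consumes:

* regular plant grids (2.0 m interrow, 1.0 m vine spacing, rows running
  north-south, RTK-GPS survey jitter within +/- 2 cm), and
* bunch-zone images: clustered, shaded circular berries of one of five
  color classes (1=black, 2=red, 3=rose, 4=grey, 5=green) on a dark
  night-acquisition background, plus a magenta size-reference label of
  known physical length fixed at a wire position.

Every rendered scene carries a :class:`SceneGroundTruth` sidecar (berry
centers, radii, classes, per-berry expected mean RGB, the label bounding
box and the true mm-per-pixel scale), so detection, calibration and
classification can all be scored without field data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter

# --------------------------------------------------------------------------
# Color-class model
# --------------------------------------------------------------------------

CLASS_NAMES = {1: "black", 2: "red", 3: "rose", 4: "grey", 5: "green"}
CLASS_CODES = {v: k for k, v in CLASS_NAMES.items()}

# Per-class trivariate Gaussian RGB distributions (0..255). Means and
# spreads are chosen so that red (2) and rose (3) overlap substantially
# (about one standard deviation apart per channel) while black (1) and
# green (5) are far separated; grey (4) sits moderately close to green.
# Channels are positively correlated (common illumination factor).
CLASS_RGB_MEANS = {
    1: np.array([35.0, 25.0, 32.0]),
    2: np.array([96.0, 44.0, 50.0]),
    3: np.array([108.0, 56.0, 62.0]),
    4: np.array([118.0, 112.0, 106.0]),
    5: np.array([92.0, 132.0, 74.0]),
}
CLASS_RGB_SDS = {
    1: np.array([8.0, 7.0, 8.0]),
    2: np.array([13.0, 10.0, 11.0]),
    3: np.array([13.0, 11.0, 12.0]),
    4: np.array([11.0, 10.0, 10.0]),
    5: np.array([10.0, 11.0, 9.0]),
}
_CHANNEL_CORR = 0.5  # off-diagonal correlation between RGB channels


def class_rgb_cov(color_class: int) -> np.ndarray:
    """Full 3x3 covariance of a class RGB distribution."""
    sd = CLASS_RGB_SDS[int(color_class)]
    corr = np.full((3, 3), _CHANNEL_CORR)
    np.fill_diagonal(corr, 1.0)
    return corr * np.outer(sd, sd)


def _check_class(color_class: int) -> int:
    c = int(color_class)
    if c not in CLASS_NAMES:
        raise ValueError(f"color class must be in 1..5, got {color_class!r}")
    return c


def class_rgb_sampler(
    color_class: int,
    seed: int | None = None,
    size: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw berry RGB triples from the class color distribution.

    Returns a single (R, G, B) array for ``size=None`` or a ``(size, 3)``
    array otherwise, clipped to 0..255. A fixed ``seed`` gives a
    reproducible draw.
    """
    c = _check_class(color_class)
    if rng is None:
        rng = np.random.default_rng(seed)
    n = 1 if size is None else int(size)
    x = rng.multivariate_normal(CLASS_RGB_MEANS[c], class_rgb_cov(c), size=n)
    x = np.clip(x, 0.0, 255.0)
    return x[0] if size is None else x


def sample_color_dataset(
    class_counts: dict[int, int], seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Sample a labelled image-level color dataset.

    One draw per image from the class distribution (image-to-image color
    variation is dominated by genotype, not by per-berry noise, which the
    per-image mean averages away). Returns ``(X, y)`` with X an ``(n, 3)``
    RGB array and y the integer class codes.
    """
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for c in sorted(class_counts):
        n = int(class_counts[c])
        if n:
            xs.append(class_rgb_sampler(c, size=n, rng=rng))
            ys.append(np.full(n, _check_class(c)))
    return np.vstack(xs), np.concatenate(ys)


# --------------------------------------------------------------------------
# Plant grid
# --------------------------------------------------------------------------

GPS_JITTER_M = 0.02  # RTK-GPS survey accuracy, metres per axis


@dataclass(frozen=True)
class PlantRecord:
    """One surveyed grapevine."""

    plant_id: str
    easting: float
    northing: float
    row_index: int
    training_direction: str  # "north" or "south"

    def __post_init__(self):
        if self.training_direction not in ("north", "south"):
            raise ValueError(
                f"training_direction must be north/south, got {self.training_direction!r}"
            )
        if "_" in self.plant_id:
            raise ValueError("plant_id may not contain '_' (reserved separator)")


def generate_plant_grid(
    n_rows: int,
    vines_per_row: int,
    origin: tuple[float, float] = (0.0, 0.0),
    interrow_m: float = 2.0,
    spacing_m: float = 1.0,
    seed: int = 0,
    jitter_m: float = GPS_JITTER_M,
) -> list[PlantRecord]:
    """Lay out a rectangular vineyard grid in UTM coordinates.

    Rows run north-south: consecutive vines within a row differ by
    ``spacing_m`` in northing and consecutive rows by ``interrow_m`` in
    easting. Positions get zero-mean uniform survey jitter within
    ``+/- jitter_m`` per axis, and each vine's training direction is drawn
    deterministically from ``seed``.
    """
    if n_rows < 1 or vines_per_row < 1:
        raise ValueError("n_rows and vines_per_row must be >= 1")
    if interrow_m <= 0 or spacing_m <= 0:
        raise ValueError("interrow_m and spacing_m must be positive")
    rng = np.random.default_rng(seed)
    e0, n0 = origin
    plants = []
    idx = 0
    for r in range(n_rows):
        for v in range(vines_per_row):
            je, jn = rng.uniform(-jitter_m, jitter_m, size=2)
            plants.append(
                PlantRecord(
                    plant_id=f"GF{idx:04d}",
                    easting=e0 + r * interrow_m + je,
                    northing=n0 + v * spacing_m + jn,
                    row_index=r,
                    training_direction="south" if rng.integers(2) else "north",
                )
            )
            idx += 1
    return plants


def write_plant_grid(path: str | Path, plants: Sequence[PlantRecord]) -> None:
    pd.DataFrame([dataclasses.asdict(p) for p in plants])[
        ["plant_id", "easting", "northing", "row_index", "training_direction"]
    ].to_csv(path, index=False)


def read_plant_grid(path: str | Path) -> list[PlantRecord]:
    df = pd.read_csv(path, dtype={"plant_id": str})
    return [
        PlantRecord(
            plant_id=row.plant_id,
            easting=float(row.easting),
            northing=float(row.northing),
            row_index=int(row.row_index),
            training_direction=str(row.training_direction),
        )
        for row in df.itertuples()
    ]


# --------------------------------------------------------------------------
# Scene specification and ground truth
# --------------------------------------------------------------------------

LABEL_RGB = np.array([225.0, 40.0, 220.0])  # magenta: outside all berry chroma
BACKGROUND_RGB = np.array([16.0, 15.0, 18.0])
WIRE_GREY = 55.0
# Radial shading: pixel value = base * (1 - SHADING * (d/r)^2); mimics the
# intensity falloff of a curved berry surface under frontal LED light.
SHADING = 0.35
RIM_FRACTION = 0.8  # inner-disk fraction used for "true" mean color
PIXEL_NOISE_SD = 2.0


class PackingError(RuntimeError):
    """Raised when a scene spec cannot be packed within bounded retries."""


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic bunch-zone image."""

    n_berries: int = 12
    radius_range_px: tuple[float, float] = (12.0, 17.0)
    color_class: int = 5
    cluster_count: int = 2
    label_length_mm: float = 50.0
    mm_per_pixel: float = 0.4
    image_size: tuple[int, int] = (400, 300)  # (width, height)
    seed: int = 0
    max_overlap: float = 0.3  # max pairwise overlap area / smaller circle area
    daylight_gradient: bool = False  # demonstration-only degradation mode

    def __post_init__(self):
        rmin, rmax = self.radius_range_px
        if not (0 < rmin <= rmax):
            raise ValueError("radius range must satisfy 0 < min <= max")
        if self.mm_per_pixel <= 0:
            raise ValueError("mm_per_pixel must be positive")
        _check_class(self.color_class)
        if self.n_berries < 0:
            raise ValueError("n_berries must be >= 0")


@dataclass
class SceneGroundTruth:
    """Generator truth for one rendered scene."""

    berries: list[dict] = field(default_factory=list)
    label_bbox: tuple[int, int, int, int] = (0, 0, 0, 0)  # x0, y0, x1, y1 (exclusive)
    mm_per_pixel: float = 1.0

    def to_json(self) -> str:
        return json.dumps(
            {
                "berries": self.berries,
                "label_bbox": list(self.label_bbox),
                "mm_per_pixel": self.mm_per_pixel,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "SceneGroundTruth":
        d = json.loads(text)
        return cls(
            berries=d["berries"],
            label_bbox=tuple(d["label_bbox"]),
            mm_per_pixel=d["mm_per_pixel"],
        )


def disk_mask(
    shape: tuple[int, int], cx: float, cy: float, radius: float
) -> np.ndarray:
    """Boolean mask of pixels whose center lies within ``radius`` of (cx, cy).

    Shared membership rule for rendering and color extraction: strict
    Euclidean test on pixel centers, origin top-left, x = column, y = row.
    """
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2


def _circle_overlap_area(d: float, r1: float, r2: float) -> float:
    """Area of intersection of two circles with center distance d."""
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        return np.pi * min(r1, r2) ** 2
    a1 = r1**2 * np.arccos((d**2 + r1**2 - r2**2) / (2 * d * r1))
    a2 = r2**2 * np.arccos((d**2 + r2**2 - r1**2) / (2 * d * r2))
    tri = 0.5 * np.sqrt(
        max(0.0, (-d + r1 + r2) * (d + r1 - r2) * (d - r1 + r2) * (d + r1 + r2))
    )
    return a1 + a2 - tri


def expected_inner_mean_rgb(base_rgb: np.ndarray) -> np.ndarray:
    """Expected mean RGB over the inner disk (rim excluded) of a shaded berry.

    With shading factor 1 - SHADING*(d/r)^2 the mean of (d/r)^2 over a disk
    of radius RIM_FRACTION*r is RIM_FRACTION^2 / 2, so the closed form is
    base * (1 - SHADING * RIM_FRACTION^2 / 2).
    """
    return np.asarray(base_rgb, float) * (1.0 - SHADING * RIM_FRACTION**2 / 2.0)


def _place_label(spec: SceneSpec) -> tuple[int, int, int, int]:
    w, h = spec.image_size
    length_px = int(round(spec.label_length_mm / spec.mm_per_pixel))
    height_px = max(6, int(round(length_px * 0.35)))
    if length_px + 10 > w or height_px + 10 > h:
        raise PackingError(f"label does not fit in image for spec {spec}")
    x0 = (w - length_px) // 3
    y0 = max(4, h // 10)
    return (x0, y0, x0 + length_px, y0 + height_px)


def _place_berries(spec: SceneSpec, label_bbox, rng) -> list[tuple[float, float, float]]:
    w, h = spec.image_size
    rmin, rmax = spec.radius_range_px
    lx0, ly0, lx1, ly1 = label_bbox
    n_clusters = max(1, int(spec.cluster_count))
    y_top = ly1 + rmax + 4  # berries hang below the wire/label zone
    if y_top >= h - rmax - 2:
        raise PackingError(f"no vertical room for berries in spec {spec}")
    centers = np.column_stack(
        [
            rng.uniform(rmax + 2, w - rmax - 2, n_clusters),
            rng.uniform(y_top, h - rmax - 2, n_clusters),
        ]
    )
    placed: list[tuple[float, float, float]] = []
    attempts = 0
    max_attempts = 4000 + 400 * spec.n_berries
    while len(placed) < spec.n_berries:
        attempts += 1
        if attempts > max_attempts:
            raise PackingError(
                f"could not pack {spec.n_berries} berries after {max_attempts} "
                f"attempts for spec {spec}"
            )
        k = int(rng.integers(n_clusters))
        r = float(rng.uniform(rmin, rmax))
        cx = float(rng.normal(centers[k, 0], 2.2 * rmax))
        cy = float(rng.normal(centers[k, 1], 2.2 * rmax))
        if not (r + 1 <= cx <= w - r - 2 and r + 1 <= cy <= h - r - 2):
            continue
        if cy - r < ly1 + 2 and cx + r > lx0 - 2 and cx - r < lx1 + 2:
            continue  # keep label unoccluded
        ok = True
        for px, py, pr in placed:
            d = float(np.hypot(cx - px, cy - py))
            ov = _circle_overlap_area(d, r, pr) / (np.pi * min(r, pr) ** 2)
            if ov > spec.max_overlap:
                ok = False
                break
        if ok:
            placed.append((cx, cy, r))
    return placed


def render_scene(spec: SceneSpec) -> tuple[np.ndarray, SceneGroundTruth]:
    """Render one bunch-zone image and its ground truth.

    The image is an ``(H, W, 3)`` uint8 array; rendering is fully
    deterministic in the spec (including its seed).
    """
    w, h = spec.image_size
    rng = np.random.default_rng(spec.seed)

    img = np.empty((h, w, 3), dtype=float)
    img[:] = BACKGROUND_RGB
    # low-frequency clutter: blurred noise, mimicking out-of-focus canopy
    clutter = gaussian_filter(rng.normal(0.0, 14.0, size=(h, w)), sigma=6)
    img += clutter[:, :, None]
    if spec.daylight_gradient:
        # demonstration-only: strong horizontal illumination gradient
        img += np.linspace(0.0, 120.0, w)[None, :, None]

    label_bbox = _place_label(spec)
    lx0, ly0, lx1, ly1 = label_bbox
    # trellis wire through the label zone
    wire_y = (ly0 + ly1) // 2
    img[wire_y - 1 : wire_y + 1, :, :] = WIRE_GREY
    img[ly0:ly1, lx0:lx1, :] = LABEL_RGB + rng.normal(0, 2.0, size=(ly1 - ly0, lx1 - lx0, 3))

    berries = _place_berries(spec, label_bbox, rng)
    truth = SceneGroundTruth(mm_per_pixel=spec.mm_per_pixel, label_bbox=label_bbox)
    yy, xx = np.mgrid[0:h, 0:w]
    for cx, cy, r in berries:
        base = class_rgb_sampler(spec.color_class, rng=rng)
        d2 = (xx - cx) ** 2 + (yy - cy) ** 2
        mask = d2 <= r**2
        shade = 1.0 - SHADING * d2[mask] / r**2
        img[mask] = base[None, :] * shade[:, None]
        truth.berries.append(
            {
                "cx": cx,
                "cy": cy,
                "r": r,
                "class": spec.color_class,
                "mean_rgb": [float(v) for v in expected_inner_mean_rgb(base)],
            }
        )

    img += rng.normal(0.0, PIXEL_NOISE_SD, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return img, truth


# --------------------------------------------------------------------------
# Scene I/O: PNG image plus .truth.json sidecar
# --------------------------------------------------------------------------


def save_scene(path: str | Path, image: np.ndarray, truth: SceneGroundTruth) -> None:
    """Write the image as 8-bit RGB PNG and the truth as a JSON sidecar."""
    path = Path(path)
    Image.fromarray(image, mode="RGB").save(path, format="PNG")
    path.with_suffix(".truth.json").write_text(truth.to_json())


def load_scene(path: str | Path) -> tuple[np.ndarray, SceneGroundTruth | None]:
    path = Path(path)
    image = np.asarray(Image.open(path).convert("RGB"))
    sidecar = path.with_suffix(".truth.json")
    truth = SceneGroundTruth.from_json(sidecar.read_text()) if sidecar.exists() else None
    return image, truth
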