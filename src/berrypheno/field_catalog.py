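"""Acquisition-side data management for the field phenotyping platform.

Covers everything between the rover stopping at a vine and an analysed
image: the ``plantID_camera_cameraID_datetime`` filename convention,
geotag embedding (UTM position + heading, JSON sidecar authoritative with
a convenience copy in the PNG text header), per-vine camera stop
positions offset 25 cm along the row by training direction, image-to-plant
assignment with a positional consistency check, a simulator of the
message -> trigger -> store -> acknowledge acquisition handshake, and an
embedded relational catalog for exact, spatial and temporal queries.
"""

from __future__ import annotations

import json
import sqlite3
import warnings
from dataclasses import dataclass
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
from PIL import Image
from PIL.PngImagePlugin import PngInfo

from .synthetic_scene import PlantRecord

CAMERA_ROLES = ("rgb", "mono1", "mono2", "mono3", "nir")
STOP_OFFSET_M = 0.25  # along-row shift of the camera stop point
POSITION_MISMATCH_M = 0.5  # half the vine spacing: never points at a neighbour
ACQUISITION_SECONDS_PER_PLANT = 15
POSITION_JITTER_M = 0.02  # repeat-approach GPS scatter

_TS_FORMAT = "%Y%m%dT%H%M%S"
_EXTENSIONS = (".png", ".tif", ".tiff")


class FilenameError(ValueError):
    """Invalid ID or malformed image filename."""


class MissingGeotagError(RuntimeError):
    pass


class UnassignedError(RuntimeError):
    """Image's plant ID is not in the plant table."""


class TableIntegrityError(RuntimeError):
    """Duplicate plant ID in the plant table."""


class AlreadyOffsetError(RuntimeError):
    """Stop-position offset applied to an already-offset position."""


class PositionMismatchWarning(UserWarning):
    """Recorded image position is far from the plant's stop position."""


@dataclass(frozen=True)
class ImageRecord:
    """One captured image with its acquisition metadata."""

    plant_id: str
    camera_role: str
    camera_id: str
    timestamp: datetime
    easting: float
    northing: float
    orientation: float  # degrees clockwise from north, [0, 360)
    path: str

    def __post_init__(self):
        if self.camera_role not in CAMERA_ROLES:
            raise ValueError(f"camera_role must be one of {CAMERA_ROLES}")
        if not (0.0 <= self.orientation < 360.0):
            raise ValueError("orientation must be in [0, 360)")


# --------------------------------------------------------------------------
# Filename convention: plantID_camera_cameraID_datetime
# --------------------------------------------------------------------------


def make_filename(
    plant_id: str,
    camera_role: str,
    camera_id: str,
    timestamp: datetime,
    extension: str = ".png",
) -> str:
    if "_" in plant_id or "_" in camera_id:
        raise FilenameError("plant_id and camera_id may not contain '_' (separator)")
    if not plant_id or not camera_id:
        raise FilenameError("plant_id and camera_id must be non-empty")
    if camera_role not in CAMERA_ROLES:
        raise FilenameError(f"camera_role must be one of {CAMERA_ROLES}")
    if extension not in _EXTENSIONS:
        raise FilenameError(f"extension must be one of {_EXTENSIONS}")
    return f"{plant_id}_{camera_role}_{camera_id}_{timestamp.strftime(_TS_FORMAT)}{extension}"


def parse_filename(name: str) -> dict:
    """Inverse of :func:`make_filename`; names the failing field on error."""
    stem = Path(name).name
    ext = Path(stem).suffix.lower()
    if ext not in _EXTENSIONS:
        raise FilenameError(f"extension: {ext!r} not one of {_EXTENSIONS}")
    parts = Path(stem).stem.split("_")
    if len(parts) != 4:
        raise FilenameError(f"structure: expected 4 '_'-separated fields, got {len(parts)}")
    plant_id, camera_role, camera_id, ts = parts
    if not plant_id:
        raise FilenameError("plant_id: empty")
    if camera_role not in CAMERA_ROLES:
        raise FilenameError(f"camera_role: {camera_role!r} not one of {CAMERA_ROLES}")
    if not camera_id:
        raise FilenameError("camera_id: empty")
    try:
        timestamp = datetime.strptime(ts, _TS_FORMAT)
    except ValueError:
        raise FilenameError(f"datetime: {ts!r} is not YYYYMMDDThhmmss") from None
    return {
        "plant_id": plant_id,
        "camera_role": camera_role,
        "camera_id": camera_id,
        "timestamp": timestamp,
        "extension": ext,
    }


# --------------------------------------------------------------------------
# Geotags: JSON sidecar authoritative, PNG text header as convenience copy
# --------------------------------------------------------------------------


def _sidecar(image_path: Path) -> Path:
    return image_path.with_suffix(image_path.suffix + ".geo.json")


def embed_geotag(
    image_path: str | Path,
    position: tuple[float, float],
    orientation: float,
) -> None:
    """Attach UTM position and heading to an image file.

    The JSON sidecar is authoritative; a text copy goes into the PNG
    header when the container supports it, otherwise sidecar-only with a
    warning. Round trip is lossless to 1 mm / 0.01 degrees.
    """
    image_path = Path(image_path)
    payload = {
        "easting": round(float(position[0]), 4),
        "northing": round(float(position[1]), 4),
        "orientation": round(float(orientation), 3),
    }
    _sidecar(image_path).write_text(json.dumps(payload))
    try:
        with Image.open(image_path) as im:
            if im.format != "PNG":
                raise OSError(f"cannot write text header to {im.format} container")
            info = PngInfo()
            for k, v in payload.items():
                info.add_text(f"berrypheno:{k}", repr(v))
            im.save(image_path, format="PNG", pnginfo=info)
    except OSError as exc:
        warnings.warn(f"geotag stored in sidecar only: {exc}", stacklevel=2)


def read_geotag(image_path: str | Path) -> tuple[tuple[float, float], float]:
    """Read (position, orientation); sidecar first, then PNG header."""
    image_path = Path(image_path)
    sidecar = _sidecar(image_path)
    if sidecar.exists():
        d = json.loads(sidecar.read_text())
    else:
        try:
            with Image.open(image_path) as im:
                text = getattr(im, "text", {})
            d = {
                k: float(text[f"berrypheno:{k}"])
                for k in ("easting", "northing", "orientation")
            }
        except (OSError, KeyError):
            raise MissingGeotagError(f"no geotag for {image_path}") from None
    return (d["easting"], d["northing"]), d["orientation"]


# --------------------------------------------------------------------------
# Stop positions and plant assignment
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class StopPosition:
    """Camera stop point: already offset along the row; do not offset again."""

    easting: float
    northing: float


def stop_position(plant: PlantRecord | StopPosition) -> StopPosition:
    """Stop point of a vine: 25 cm along the row toward the training side.

    Rows run north-south, so the shift acts on the northing. The offset is
    not idempotent; re-applying it to a :class:`StopPosition` raises.
    """
    if isinstance(plant, StopPosition):
        raise AlreadyOffsetError("stop-position offset already applied")
    sign = 1.0 if plant.training_direction == "north" else -1.0
    return StopPosition(plant.easting, plant.northing + sign * STOP_OFFSET_M)


def assign_image_to_plant(
    record: ImageRecord, plants: list[PlantRecord]
) -> str:
    """Assign an image to its vine by the plant ID in the filename.

    The plant table is the authority; the recorded GPS position is only a
    consistency check — beyond 0.5 m from the stop point it emits a
    :class:`PositionMismatchWarning`, never a failure.
    """
    ids = [p.plant_id for p in plants]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise TableIntegrityError(f"duplicate plant_id(s) in table: {dup}")
    table = {p.plant_id: p for p in plants}
    parsed = parse_filename(record.path)
    pid = parsed["plant_id"]
    if pid not in table:
        raise UnassignedError(f"plant_id {pid!r} not in plant table")
    stop = stop_position(table[pid])
    dist = float(np.hypot(record.easting - stop.easting, record.northing - stop.northing))
    if dist > POSITION_MISMATCH_M:
        warnings.warn(
            PositionMismatchWarning(
                f"image {record.path}: recorded position {dist:.2f} m from "
                f"stop point of {pid}"
            ),
            stacklevel=2,
        )
    return pid


# --------------------------------------------------------------------------
# Acquisition protocol simulator (message -> trigger -> store -> acknowledge)
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ProtocolEvent:
    kind: str  # message | trigger | record | incomplete | ack
    plant_id: str
    timestamp: datetime
    detail: str = ""


def run_acquisition(
    route: list[PlantRecord],
    camera_set: dict[str, str],  # camera_role -> camera_id
    start_time: datetime | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
    failing: set[tuple[str, str]] | None = None,
) -> tuple[list[ImageRecord], list[ProtocolEvent]]:
    """Simulate one acquisition drive over an ordered route of vines.

    Per plant, in strict sequence: the rover's position message, one
    synchronized trigger of all cameras (all records share a timestamp
    and jittered GPS fix, within +/- 2 cm of the stop point), filename
    generation and geotag embedding, then the acknowledgment that releases
    the rover toward the next vine — never before the previous plant's
    acknowledgment. ``failing`` injects per-(plant, camera) faults: the
    plant is logged incomplete but still acknowledged.

    With ``out_dir`` set, a tiny placeholder PNG is written and geotagged
    for every record; otherwise records carry bare filenames.
    """
    if not route:
        raise ValueError("route must be non-empty")
    if not camera_set:
        raise ValueError("camera set must be non-empty")
    for role in camera_set:
        if role not in CAMERA_ROLES:
            raise ValueError(f"unknown camera role {role!r}")
    failing = failing or set()
    rng = np.random.default_rng(seed)
    clock = start_time or datetime(2014, 8, 20, 23, 0, 0)
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    records: list[ImageRecord] = []
    events: list[ProtocolEvent] = []
    for plant in route:
        stop = stop_position(plant)
        je, jn = rng.uniform(-POSITION_JITTER_M, POSITION_JITTER_M, size=2)
        easting, northing = stop.easting + je, stop.northing + jn
        orientation = 90.0 if plant.training_direction == "north" else 270.0
        events.append(ProtocolEvent("message", plant.plant_id, clock))
        events.append(ProtocolEvent("trigger", plant.plant_id, clock))
        incomplete = False
        for role in sorted(camera_set):
            if (plant.plant_id, role) in failing:
                incomplete = True
                continue
            name = make_filename(plant.plant_id, role, camera_set[role], clock)
            path = str(out_dir / name) if out_dir is not None else name
            if out_dir is not None:
                Image.new("RGB", (4, 4)).save(path, format="PNG")
                embed_geotag(path, (easting, northing), orientation)
            records.append(
                ImageRecord(
                    plant_id=plant.plant_id,
                    camera_role=role,
                    camera_id=camera_set[role],
                    timestamp=clock,
                    easting=easting,
                    northing=northing,
                    orientation=orientation,
                    path=path,
                )
            )
            events.append(ProtocolEvent("record", plant.plant_id, clock, detail=role))
        if incomplete:
            events.append(ProtocolEvent("incomplete", plant.plant_id, clock))
        events.append(ProtocolEvent("ack", plant.plant_id, clock))
        clock = clock + timedelta(seconds=ACQUISITION_SECONDS_PER_PLANT)
    return records, events


# --------------------------------------------------------------------------
# Embedded relational catalog
# --------------------------------------------------------------------------

_SCHEMA = """
CREATE TABLE IF NOT EXISTS images (
    plant_id TEXT NOT NULL,
    camera_role TEXT NOT NULL,
    camera_id TEXT NOT NULL,
    timestamp TEXT NOT NULL,
    easting REAL NOT NULL,
    northing REAL NOT NULL,
    orientation REAL NOT NULL,
    path TEXT NOT NULL UNIQUE
);
"""


class ImageCatalog:
    """Single-file relational store of :class:`ImageRecord` rows.

    Queries return records stable-ordered by (plant_id, timestamp,
    camera_role); an empty catalog yields empty results, not errors.
    """

    def __init__(self, path: str | Path = ":memory:"):
        self._con = sqlite3.connect(str(path))
        self._con.execute(_SCHEMA)
        self._con.commit()

    def close(self) -> None:
        self._con.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()

    def add(self, records: list[ImageRecord]) -> int:
        rows = [
            (
                r.plant_id,
                r.camera_role,
                r.camera_id,
                r.timestamp.isoformat(),
                r.easting,
                r.northing,
                r.orientation,
                r.path,
            )
            for r in records
        ]
        self._con.executemany(
            "INSERT OR REPLACE INTO images VALUES (?,?,?,?,?,?,?,?)", rows
        )
        self._con.commit()
        return len(rows)

    def query(
        self,
        plant_id: str | None = None,
        rectangle: tuple[float, float, float, float] | None = None,
        date_range: tuple[datetime, datetime] | None = None,
    ) -> list[ImageRecord]:
        """Exact plant-ID, spatial-rectangle and/or date-range query.

        ``rectangle`` is (easting_min, northing_min, easting_max,
        northing_max), inclusive.
        """
        clauses, args = [], []
        if plant_id is not None:
            clauses.append("plant_id = ?")
            args.append(plant_id)
        if rectangle is not None:
            e0, n0, e1, n1 = rectangle
            clauses.append("easting BETWEEN ? AND ? AND northing BETWEEN ? AND ?")
            args += [min(e0, e1), max(e0, e1), min(n0, n1), max(n0, n1)]
        if date_range is not None:
            clauses.append("timestamp BETWEEN ? AND ?")
            args += [date_range[0].isoformat(), date_range[1].isoformat()]
        sql = "SELECT * FROM images"
        if clauses:
            sql += " WHERE " + " AND ".join(clauses)
        sql += " ORDER BY plant_id, timestamp, camera_role"
        out = []
        for row in self._con.execute(sql, args):
            out.append(
                ImageRecord(
                    plant_id=row[0],
                    camera_role=row[1],
                    camera_id=row[2],
                    timestamp=datetime.fromisoformat(row[3]),
                    easting=row[4],
                    northing=row[5],
                    orientation=row[6],
                    path=row[7],
                )
            )
        return out
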