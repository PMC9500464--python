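"""Reading, validation and assembly of VPC eye-tracking recordings.

The on-disk dialects are deliberately plain text:

* gaze CSV — columns ``subject_id, group, image_id, viewing, t_ms, x_px,
  y_px, valid`` (UTF-8, header mandatory); one row per 120 Hz gaze sample on
  a 1920x1080 screen.
* scene JSON — a list of ``{image_id, objects: [{cx, cy, r}], roi: {x0, y0,
  x1, y1}}`` describing each test image's 4-8 objects and the single
  region of interest (RoI) where an object is added or removed between the
  two viewings.
* labels CSV — ``subject_id, group`` with group in {PwAD, HC}; PwAD is the
  positive class throughout the package.

Coordinates use the raster convention: origin top-left, x rightward,
y downward, half-open screen bounds [0, 1920) x [0, 1080). Rows flagged
invalid or falling off screen are dropped (with a logged count) rather than
imputed, and a subject missing any (image, viewing) recording is excluded
outright: the outer autoencoder requires all V views.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SCREEN_W = 1920
SCREEN_H = 1080
GROUPS = ("PwAD", "HC")
POSITIVE_GROUP = "PwAD"

GAZE_COLUMNS = [
    "subject_id",
    "group",
    "image_id",
    "viewing",
    "t_ms",
    "x_px",
    "y_px",
    "valid",
]


class GazeIOError(ValueError):
    """Base class for ingestion failures."""


class FormatError(GazeIOError):
    """A file is structurally malformed (missing columns, bad JSON...)."""


class EmptyInputError(GazeIOError):
    """A file contains no data rows."""


class ValidationError(GazeIOError):
    """Data violates a domain invariant."""


class ClassDegeneracyError(ValidationError):
    """A class ended up with no usable subjects."""


@dataclass(frozen=True)
class SceneSpec:
    """Geometry of one test image: its objects and the changed-object RoI."""

    image_id: int
    objects: tuple[tuple[float, float, float], ...]  # (cx, cy, radius) px
    roi: tuple[float, float, float, float]  # (x0, y0, x1, y1) px, half-open

    def validate(self) -> None:
        if not 4 <= len(self.objects) <= 8:
            raise ValidationError(
                f"image {self.image_id}: {len(self.objects)} objects, expected 4..8"
            )
        x0, y0, x1, y1 = self.roi
        if not (0 <= x0 < x1 <= SCREEN_W and 0 <= y0 < y1 <= SCREEN_H):
            raise ValidationError(f"image {self.image_id}: roi {self.roi} off screen")


@dataclass
class GazeRecords:
    """Cleaned gaze samples grouped by (subject_id, image_id, viewing).

    Each group maps to an (n, 3) float array of columns (t_ms, x_px, y_px),
    sorted by time. ``n_rows_in = n_rows_retained + n_rows_dropped`` always
    holds.
    """

    groups: dict[tuple[str, int, int], np.ndarray]
    subject_group: dict[str, str]
    n_rows_in: int = 0
    n_rows_retained: int = 0
    n_rows_dropped: int = 0


@dataclass
class CohortTable:
    """Subject ids and binary labels (PwAD = 1, HC = 0)."""

    subjects: list[tuple[str, str]]

    def __post_init__(self) -> None:
        ids = [s for s, _ in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate subject_id in labels")
        for sid, grp in self.subjects:
            if grp not in GROUPS:
                raise ValidationError(f"subject {sid}: unknown group {grp!r}")
        present = {g for _, g in self.subjects}
        if present != set(GROUPS):
            raise ClassDegeneracyError(f"labels cover only groups {sorted(present)}")

    def label(self, subject_id: str) -> int:
        grp = dict(self.subjects)[subject_id]
        return 1 if grp == POSITIVE_GROUP else 0


@dataclass
class Cohort:
    """Assembled per-subject sample streams, complete in all V x 2 views."""

    scenes: list[SceneSpec]
    samples: dict[str, dict[tuple[int, int], np.ndarray]]  # sid -> (img, view) -> (n,2) xy
    labels: dict[str, int]
    excluded: list[str] = field(default_factory=list)

    @property
    def n_views(self) -> int:
        return len(self.scenes)

    @property
    def subject_ids(self) -> list[str]:
        return sorted(self.samples)


# -- readers ----------------------------------------------------------------


def read_gaze(path: str | Path) -> GazeRecords:
    """Read and clean a gaze CSV into per-(subject, image, viewing) streams.

    Rows with ``valid == False`` or off-screen coordinates are dropped and
    counted; remaining samples are sorted by time within each group and must
    then be strictly increasing in ``t_ms``.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: empty gaze file") from None
    for col in GAZE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    if len(df) == 0:
        raise EmptyInputError(f"{path}: no gaze rows")

    n_in = len(df)
    valid = df["valid"].astype(bool).to_numpy()
    x = df["x_px"].to_numpy(dtype=float)
    y = df["y_px"].to_numpy(dtype=float)
    keep = valid & (x >= 0) & (x < SCREEN_W) & (y >= 0) & (y < SCREEN_H)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("read_gaze: dropped %d/%d invalid or off-screen rows", n_dropped, n_in)
    df = df.loc[keep]

    groups: dict[tuple[str, int, int], np.ndarray] = {}
    subject_group: dict[str, str] = {}
    for (sid, img, view), sub in df.groupby(["subject_id", "image_id", "viewing"], sort=True):
        sid = str(sid)
        img, view = int(img), int(view)
        if view not in (1, 2):
            raise ValidationError(f"subject {sid} image {img}: viewing {view} not in {{1,2}}")
        grp = str(sub["group"].iloc[0])
        if grp not in GROUPS:
            raise ValidationError(f"subject {sid}: unknown group {grp!r}")
        prev = subject_group.setdefault(sid, grp)
        if prev != grp:
            raise ValidationError(f"subject {sid}: inconsistent group labels")
        arr = sub[["t_ms", "x_px", "y_px"]].to_numpy(dtype=float)
        arr = arr[np.argsort(arr[:, 0], kind="stable")]
        if len(arr) > 1 and not np.all(np.diff(arr[:, 0]) > 0):
            raise ValidationError(
                f"non-monotone timestamps in (subject={sid}, image={img}, viewing={view})"
            )
        groups[(sid, img, view)] = arr

    return GazeRecords(
        groups=groups,
        subject_group=subject_group,
        n_rows_in=n_in,
        n_rows_retained=n_in - n_dropped,
        n_rows_dropped=n_dropped,
    )


def read_scenes(path: str | Path) -> list[SceneSpec]:
    """Read and validate a scene JSON; entries returned sorted by image_id."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise FormatError(f"{path}: invalid JSON ({e})") from None
    if not isinstance(doc, list) or not doc:
        raise EmptyInputError(f"{path}: expected a non-empty list of scenes")
    scenes = []
    seen: set[int] = set()
    for entry in doc:
        try:
            img = int(entry["image_id"])
            objs = tuple(
                (float(o["cx"]), float(o["cy"]), float(o["r"])) for o in entry["objects"]
            )
            r = entry["roi"]
            roi = (float(r["x0"]), float(r["y0"]), float(r["x1"]), float(r["y1"]))
        except (KeyError, TypeError) as e:
            raise FormatError(f"{path}: malformed scene entry ({e})") from None
        if img in seen:
            raise ValidationError(f"{path}: duplicate image_id {img}")
        seen.add(img)
        spec = SceneSpec(image_id=img, objects=objs, roi=roi)
        spec.validate()
        scenes.append(spec)
    return sorted(scenes, key=lambda s: s.image_id)


def write_scenes(scenes: list[SceneSpec], path: str | Path) -> None:
    doc = [
        {
            "image_id": s.image_id,
            "objects": [{"cx": cx, "cy": cy, "r": r} for cx, cy, r in s.objects],
            "roi": dict(zip(("x0", "y0", "x1", "y1"), s.roi)),
        }
        for s in scenes
    ]
    Path(path).write_text(json.dumps(doc, indent=1))


def read_labels(path: str | Path) -> CohortTable:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: empty labels file") from None
    for col in ("subject_id", "group"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return CohortTable(subjects=[(str(s), str(g)) for s, g in df.itertuples(index=False)])


def assemble_cohort(
    records: GazeRecords, scenes: list[SceneSpec], labels: CohortTable
) -> Cohort:
    """Organize cleaned records into a complete-case cohort.

    A subject is retained only when all V x 2 (image, viewing) groups are
    present and non-empty; anything less and the subject is excluded (and
    reported), never zero-filled.
    """
    label_map = dict(labels.subjects)
    image_ids = [s.image_id for s in scenes]
    required = [(img, v) for img in image_ids for v in (1, 2)]

    subjects = sorted({sid for sid, _, _ in records.groups})
    for sid in subjects:
        if sid not in label_map:
            raise ValidationError(f"subject {sid} has gaze data but no label")

    samples: dict[str, dict[tuple[int, int], np.ndarray]] = {}
    excluded: list[str] = []
    for sid in subjects:
        views = {}
        complete = True
        for img, v in required:
            arr = records.groups.get((sid, img, v))
            if arr is None or len(arr) == 0:
                complete = False
                break
            views[(img, v)] = arr[:, 1:3]  # xy only
        if complete:
            samples[sid] = views
        else:
            excluded.append(sid)
    if excluded:
        logger.info("assemble_cohort: excluded %d incomplete subjects: %s", len(excluded), excluded)

    lab = {sid: (1 if label_map[sid] == POSITIVE_GROUP else 0) for sid in samples}
    for cls, name in ((1, "PwAD"), (0, "HC")):
        if not any(v == cls for v in lab.values()):
            raise ClassDegeneracyError(f"no retained subjects in class {name}")
    return Cohort(scenes=scenes, samples=samples, labels=lab, excluded=excluded)


def load_cohort(
    gaze_path: str | Path, scenes_path: str | Path, labels_path: str | Path
) -> Cohort:
    """Convenience: read all three files and assemble the cohort."""
    return assemble_cohort(
        read_gaze(gaze_path), read_scenes(scenes_path), read_labels(labels_path)
    )
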