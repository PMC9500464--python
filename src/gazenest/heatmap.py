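"""Fixation maps, Gaussian-smoothed heatmaps and RoI dwell statistics.

Gaze samples on the 1920x1080 screen are binned onto a 24-row x 32-column
grid (each cell covers 60 x 45 px -- the anisotropy is implied by the
resolutions), smoothed with a truncated Gaussian kernel under reflective
boundary conditions, and normalized to peak 1. The resulting 768-cell
heatmap pair per image (viewing 1, viewing 2) is the network's sole input.

Fixation identification: by default every valid 120 Hz gaze sample counts
as a fixation point (the density a raw-sample overlay produces); an optional
dispersion-threshold (I-DT) mode collapses samples to fixation centroids
first, for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
from scipy.ndimage import gaussian_filter

from .gaze_io import SCREEN_H, SCREEN_W, Cohort

GRID_ROWS = 24
GRID_COLS = 32
CELL_W = SCREEN_W // GRID_COLS  # 60 px
CELL_H = SCREEN_H // GRID_ROWS  # 45 px

__all__ = [
    "GRID_ROWS",
    "GRID_COLS",
    "SubjectViews",
    "bin_samples",
    "smooth",
    "smooth_and_normalize",
    "build_subject_views",
    "roi_dwell_fraction",
    "identify_fixations_idt",
    "save_views",
    "load_views",
]


@dataclass
class SubjectViews:
    """All V heatmap pairs for one subject plus the binary label.

    ``maps`` has shape (V, 2, 24, 32): image index (ascending image_id),
    viewing (first, second), grid rows, grid columns.
    """

    subject_id: str
    label: int
    maps: np.ndarray

    def __post_init__(self) -> None:
        if self.maps.ndim != 4 or self.maps.shape[1:] != (2, GRID_ROWS, GRID_COLS):
            raise ValueError(f"maps shape {self.maps.shape} != (V, 2, 24, 32)")


def bin_samples(xy: np.ndarray) -> np.ndarray:
    """Count gaze positions into the 24x32 grid (a fixation map).

    Sample (x, y) lands in cell (floor(y/45), floor(x/60)). All samples must
    be on screen -- ingestion is responsible for filtering.
    """
    grid = np.zeros((GRID_ROWS, GRID_COLS))
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    if len(xy) == 0:
        return grid
    x, y = xy[:, 0], xy[:, 1]
    if np.any((x < 0) | (x >= SCREEN_W) | (y < 0) | (y >= SCREEN_H)):
        raise ValueError("off-screen sample reached bin_samples")
    rows = (y // CELL_H).astype(int)
    cols = (x // CELL_W).astype(int)
    np.add.at(grid, (rows, cols), 1.0)
    return grid


def smooth(fixation_map: np.ndarray, sigma_cells: float = 1.0) -> np.ndarray:
    """Gaussian smoothing (truncated at 4 sigma, reflective boundary).

    Preserves total mass: the sampled kernel is normalized and reflection
    loses nothing over the edges.
    """
    if sigma_cells <= 0:
        raise ValueError("sigma_cells must be > 0")
    return gaussian_filter(
        np.asarray(fixation_map, dtype=float), sigma=sigma_cells, mode="reflect", truncate=4.0
    )


def smooth_and_normalize(
    fixation_map: np.ndarray, sigma_cells: float = 1.0, norm: str = "max"
) -> np.ndarray:
    """Smooth a fixation map and normalize it into a fixation heatmap.

    ``norm="max"`` (default) scales the peak to 1, suiting a bounded decoder
    output; ``norm="sum"`` produces a probability surface instead. An
    all-zero map stays all-zero.
    """
    out = smooth(fixation_map, sigma_cells)
    if norm == "max":
        m = out.max()
        return out / m if m > 0 else out
    if norm == "sum":
        s = out.sum()
        return out / s if s > 0 else out
    raise ValueError(f"unknown norm {norm!r}")


def identify_fixations_idt(
    t_ms: np.ndarray,
    xy: np.ndarray,
    dispersion_px: float = 50.0,
    min_duration_ms: float = 100.0,
) -> np.ndarray:
    """Dispersion-threshold (I-DT) fixation detection; returns centroids.

    A window grows while (max-min x) + (max-min y) stays within
    ``dispersion_px``; windows lasting at least ``min_duration_ms`` emit
    their centroid as one fixation point.
    """
    t = np.asarray(t_ms, dtype=float)
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    fixations = []
    i, n = 0, len(t)
    while i < n:
        j = i + 1
        while j < n:
            win = xy[i : j + 1]
            if (np.ptp(win[:, 0]) + np.ptp(win[:, 1])) > dispersion_px:
                break
            j += 1
        if j - i >= 2 and t[j - 1] - t[i] >= min_duration_ms:
            fixations.append(xy[i:j].mean(axis=0))
            i = j
        else:
            i += 1
    return np.array(fixations).reshape(-1, 2)


def roi_dwell_fraction(xy: np.ndarray, roi: tuple[float, float, float, float]) -> float:
    """Fraction of samples inside the half-open RoI rectangle.

    The relative fixation time on the changed region is the behavioral
    novelty-preference readout; PwAD show less of it than HC.
    """
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    if len(xy) == 0:
        raise ValueError("roi_dwell_fraction undefined for an empty sample list")
    x0, y0, x1, y1 = roi
    inside = (xy[:, 0] >= x0) & (xy[:, 0] < x1) & (xy[:, 1] >= y0) & (xy[:, 1] < y1)
    return float(inside.mean())


def build_subject_views(
    cohort: Cohort,
    sigma_cells: float = 1.0,
    norm: str = "max",
    fixation_mode: str = "samples",
    idt_dispersion_px: float = 50.0,
    idt_min_duration_ms: float = 100.0,
    timestamps: dict | None = None,
) -> list[SubjectViews]:
    """Turn an assembled cohort into per-subject heatmap stacks.

    ``fixation_mode="samples"`` uses every gaze sample; ``"idt"`` first
    collapses samples to I-DT fixation centroids (requires ``timestamps``
    mapping the same (subject, (image, viewing)) keys to time arrays, as
    produced by ingestion).
    """
    views = []
    image_ids = [s.image_id for s in cohort.scenes]
    for sid in cohort.subject_ids:
        maps = np.zeros((len(image_ids), 2, GRID_ROWS, GRID_COLS))
        for vi, img in enumerate(image_ids):
            for wi, viewing in enumerate((1, 2)):
                xy = cohort.samples[sid][(img, viewing)]
                if fixation_mode == "idt":
                    if timestamps is None:
                        raise ValueError("idt mode needs per-group timestamps")
                    xy = identify_fixations_idt(
                        timestamps[sid][(img, viewing)],
                        xy,
                        dispersion_px=idt_dispersion_px,
                        min_duration_ms=idt_min_duration_ms,
                    )
                elif fixation_mode != "samples":
                    raise ValueError(f"unknown fixation_mode {fixation_mode!r}")
                maps[vi, wi] = smooth_and_normalize(bin_samples(xy), sigma_cells, norm)
        views.append(SubjectViews(subject_id=sid, label=cohort.labels[sid], maps=maps))
    return views


# -- persistence ------------------------------------------------------------


def save_views(views: list[SubjectViews], path: str | Path) -> None:
    """Persist heatmaps as one HDF5 dataset [subjects, V, 2, 24, 32]."""
    with h5py.File(path, "w") as f:
        f.create_dataset("heatmaps", data=np.stack([v.maps for v in views]))
        f.attrs["subject_ids"] = [v.subject_id for v in views]
        f.attrs["labels"] = [v.label for v in views]


def load_views(path: str | Path) -> list[SubjectViews]:
    with h5py.File(path, "r") as f:
        maps = f["heatmaps"][()]
        sids = [s.decode() if isinstance(s, bytes) else str(s) for s in f.attrs["subject_ids"]]
        labels = [int(x) for x in f.attrs["labels"]]
    return [
        SubjectViews(subject_id=s, label=y, maps=m) for s, y, m in zip(sids, labels, maps)
    ]
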