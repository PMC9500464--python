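"""Seeded synthetic VPC cohorts with the qualitative PwAD/HC gaze contrast.

The clinical cohort behind this method is not publicly deposited, so this
module simulates the study conditions: 12 stereo test images, each freely
viewed twice for 5 s at 120 Hz on a 1920x1080 screen, with one object added
or removed between viewings (the RoI). Group structure follows the reported
phenomenology: patients (PwAD) concentrate gaze centrally and largely ignore
the RoI on the second viewing (diminished novelty preference), while healthy
controls (HC) explore the objects globally and seek out the RoI.

Gaze is modeled as i.i.d. draws from a spatial mixture of Gaussians -- a
central-bias component, per-object components, and (second viewing only) an
RoI component -- because everything downstream consumes only spatial density
(fixation heatmaps); no saccade sequencing, blinks or pupil dynamics are
simulated. Draws falling off screen are rejected and redrawn so no mass
piles up on the borders. Per-subject heterogeneity enters as Dirichlet
jitter on the mixture weights. The effect size ``delta`` interpolates both
group profiles linearly between a shared neutral profile (delta = 0, no
group signal) and the maximally separated defaults (delta = 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .gaze_io import GAZE_COLUMNS, SCREEN_H, SCREEN_W, Cohort, SceneSpec, write_scenes

__all__ = [
    "GroupGazeProfile",
    "CohortConfig",
    "GenerationError",
    "generate_scenes",
    "simulate_viewing",
    "generate_cohort",
    "generate_views",
    "write_cohort",
    "DEFAULT_PWAD_PROFILE",
    "DEFAULT_HC_PROFILE",
]

SCREEN_CENTER = (SCREEN_W / 2.0, SCREEN_H / 2.0)


class GenerationError(RuntimeError):
    """Scene placement failed within the retry budget."""


@dataclass(frozen=True)
class GroupGazeProfile:
    """Spatial-mixture weights and dispersions for one diagnostic group.

    ``w_roi_second_viewing`` is active only on the second viewing; on the
    first viewing the center/object weights are renormalized without it.
    """

    w_center: float
    w_objects: float
    w_roi_second_viewing: float
    sigma_center_px: float = 150.0
    sigma_object_px: float = 60.0
    subject_variability: float = 50.0  # Dirichlet concentration

    def __post_init__(self) -> None:
        w = np.array([self.w_center, self.w_objects, self.w_roi_second_viewing])
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("mixture weights must be non-negative and not all zero")
        if self.sigma_center_px <= 0 or self.sigma_object_px <= 0:
            raise ValueError("dispersions must be positive")

    @property
    def weights(self) -> np.ndarray:
        w = np.array([self.w_center, self.w_objects, self.w_roi_second_viewing])
        return w / w.sum()


# Second-viewing defaults encoding the reported group contrast: PwAD central
# bias with scant RoI attention vs HC object exploration plus RoI seeking.
DEFAULT_PWAD_PROFILE = GroupGazeProfile(0.70, 0.25, 0.05)
DEFAULT_HC_PROFILE = GroupGazeProfile(0.25, 0.45, 0.30)


@dataclass(frozen=True)
class CohortConfig:
    """Simulation parameters; defaults reproduce the study task geometry."""

    n_per_group: int = 30
    n_images: int = 12
    viewing_s: float = 5.0
    rate_hz: float = 120.0
    delta: float = 1.0  # PwAD-HC profile gap in [0, 1]
    seed: int = 0
    pwad_profile: GroupGazeProfile = field(default=DEFAULT_PWAD_PROFILE)
    hc_profile: GroupGazeProfile = field(default=DEFAULT_HC_PROFILE)

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError("delta must lie in [0, 1]")

    @property
    def samples_per_viewing(self) -> int:
        return int(round(self.rate_hz * self.viewing_s))


@dataclass
class SyntheticCohort:
    """In-memory result of a simulation run (files are optional)."""

    scenes: list[SceneSpec]
    samples: dict[str, dict[tuple[int, int], np.ndarray]]  # sid -> (img, view) -> xy
    labels: dict[str, int]
    config: CohortConfig

    def as_cohort(self) -> Cohort:
        """View this simulation as an assembled cohort (no file round trip)."""
        return Cohort(scenes=self.scenes, samples=self.samples, labels=self.labels)


# -- scenes -----------------------------------------------------------------


def generate_scenes(n_images: int, seed: int | np.random.Generator) -> list[SceneSpec]:
    """Place 4-8 non-overlapping circular objects per image; one is marked
    changed and its bounding square becomes the RoI."""
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scenes = []
    for img in range(1, n_images + 1):
        for _attempt in range(50):
            n_obj = int(rng.integers(4, 9))
            placed: list[tuple[float, float, float]] = []
            ok = True
            for _ in range(n_obj):
                for _retry in range(200):
                    r = float(rng.uniform(40.0, 80.0))
                    cx = float(rng.uniform(r + 10.0, SCREEN_W - r - 10.0))
                    cy = float(rng.uniform(r + 10.0, SCREEN_H - r - 10.0))
                    if all(
                        np.hypot(cx - ox, cy - oy) > r + orr + 10.0
                        for ox, oy, orr in placed
                    ):
                        placed.append((cx, cy, r))
                        break
                else:
                    ok = False
                    break
            if ok:
                break
        else:
            raise GenerationError(f"could not place objects for image {img}")
        changed = int(rng.integers(len(placed)))
        cx, cy, r = placed[changed]
        roi = (
            max(0.0, cx - r),
            max(0.0, cy - r),
            min(float(SCREEN_W), cx + r),
            min(float(SCREEN_H), cy + r),
        )
        scenes.append(SceneSpec(image_id=img, objects=tuple(placed), roi=roi))
    return scenes


# -- gaze -------------------------------------------------------------------


def _viewing_weights(weights: np.ndarray, viewing: int) -> np.ndarray:
    """RoI weight is inert on viewing 1: renormalize the other two."""
    if viewing == 2:
        return weights
    w = np.array([weights[0], weights[1], 0.0])
    return w / w.sum()


def simulate_viewing(
    profile: GroupGazeProfile,
    scene: SceneSpec,
    viewing: int,
    n_samples: int,
    rng: np.random.Generator,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Draw ``n_samples`` on-screen gaze positions from the spatial mixture.

    ``weights`` overrides the profile's (already jittered, e.g. per-subject)
    center/objects/RoI mixture weights. Off-screen draws are rejected and
    redrawn, so exactly ``n_samples`` positions are returned.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if viewing not in (1, 2):
        raise ValueError("viewing must be 1 or 2")
    w = _viewing_weights(profile.weights if weights is None else np.asarray(weights), viewing)
    objects = np.array([(cx, cy) for cx, cy, _ in scene.objects])
    roi_center = np.array(
        [(scene.roi[0] + scene.roi[2]) / 2.0, (scene.roi[1] + scene.roi[3]) / 2.0]
    )

    out = np.empty((n_samples, 2))
    n_done = 0
    while n_done < n_samples:
        n_need = n_samples - n_done
        comp = rng.choice(3, size=n_need, p=w)
        xy = np.empty((n_need, 2))
        m_c = comp == 0
        if m_c.any():
            xy[m_c] = rng.normal(SCREEN_CENTER, profile.sigma_center_px, size=(m_c.sum(), 2))
        m_o = comp == 1
        if m_o.any():
            which = rng.integers(len(objects), size=m_o.sum())
            xy[m_o] = objects[which] + rng.normal(
                0.0, profile.sigma_object_px, size=(m_o.sum(), 2)
            )
        m_r = comp == 2
        if m_r.any():
            xy[m_r] = roi_center + rng.normal(
                0.0, profile.sigma_object_px, size=(m_r.sum(), 2)
            )
        on = (
            (xy[:, 0] >= 0)
            & (xy[:, 0] < SCREEN_W)
            & (xy[:, 1] >= 0)
            & (xy[:, 1] < SCREEN_H)
        )
        n_keep = int(on.sum())
        out[n_done : n_done + n_keep] = xy[on]
        n_done += n_keep
    return out


def _interp_profile(
    profile: GroupGazeProfile, other: GroupGazeProfile, delta: float
) -> GroupGazeProfile:
    """Move ``profile`` toward the two-group midpoint as delta shrinks."""
    neutral = (profile.weights + other.weights) / 2.0
    w = neutral + delta * (profile.weights - neutral)
    return replace(
        profile, w_center=w[0], w_objects=w[1], w_roi_second_viewing=w[2]
    )


def generate_cohort(
    config: CohortConfig, out_dir: str | Path | None = None
) -> SyntheticCohort:
    """Simulate a full cohort; optionally write the three text artifacts.

    When ``out_dir`` is given, writes ``gaze.csv``, ``scenes.json`` and
    ``labels.csv`` in exactly the dialects :mod:`gazenest.gaze_io` reads.
    Identical configs produce byte-identical files.
    """
    rng = np.random.default_rng(config.seed)
    scenes = generate_scenes(config.n_images, rng)
    n = config.samples_per_viewing

    group_profiles = {
        1: _interp_profile(config.pwad_profile, config.hc_profile, config.delta),
        0: _interp_profile(config.hc_profile, config.pwad_profile, config.delta),
    }

    subject_ids = [f"AD{i + 1:03d}" for i in range(config.n_per_group)] + [
        f"HC{i + 1:03d}" for i in range(config.n_per_group)
    ]
    labels = {sid: (1 if sid.startswith("AD") else 0) for sid in subject_ids}

    samples: dict[str, dict[tuple[int, int], np.ndarray]] = {}
    for sid in subject_ids:
        prof = group_profiles[labels[sid]]
        alpha = prof.subject_variability * np.clip(prof.weights, 1e-3, None)
        subj_weights = rng.dirichlet(alpha)
        views: dict[tuple[int, int], np.ndarray] = {}
        for scene in scenes:
            for viewing in (1, 2):
                views[(scene.image_id, viewing)] = simulate_viewing(
                    prof, scene, viewing, n, rng, weights=subj_weights
                )
        samples[sid] = views

    cohort = SyntheticCohort(scenes=scenes, samples=samples, labels=labels, config=config)
    if out_dir is not None:
        write_cohort(cohort, out_dir)
    return cohort


def generate_views(config: CohortConfig, sigma_cells: float = 1.0):
    """Simulate a cohort and return its per-subject heatmap stacks directly."""
    from .heatmap import build_subject_views

    return build_subject_views(generate_cohort(config).as_cohort(), sigma_cells=sigma_cells)


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write gaze.csv / scenes.json / labels.csv for a simulated cohort."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dt = 1000.0 / cohort.config.rate_hz

    frames = []
    for sid in sorted(cohort.samples):
        grp = "PwAD" if cohort.labels[sid] == 1 else "HC"
        for (img, viewing), xy in sorted(cohort.samples[sid].items()):
            t = np.arange(len(xy)) * dt
            frames.append(
                pd.DataFrame(
                    {
                        "subject_id": sid,
                        "group": grp,
                        "image_id": img,
                        "viewing": viewing,
                        "t_ms": t,
                        "x_px": xy[:, 0],
                        "y_px": xy[:, 1],
                        "valid": True,
                    }
                )
            )
    gaze = pd.concat(frames, ignore_index=True)[GAZE_COLUMNS]
    paths = {
        "gaze": out / "gaze.csv",
        "scenes": out / "scenes.json",
        "labels": out / "labels.csv",
    }
    gaze.to_csv(paths["gaze"], index=False)
    write_scenes(cohort.scenes, paths["scenes"])
    pd.DataFrame(
        {
            "subject_id": sorted(cohort.labels),
            "group": ["PwAD" if cohort.labels[s] == 1 else "HC" for s in sorted(cohort.labels)],
        }
    ).to_csv(paths["labels"], index=False)
    return paths
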