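"""Synthetic fluoroscopic validation studies with exact ground truth.

Emulates the in vitro acquisition: a pelvis whose anterior pelvic plane is
aligned with the X-ray beam plane, steel teardrop beads marking the
medial-lateral axis, a hemispherical cup whose rim circle is placed on a
3 x 3 grid of target inclination/anteversion angles (each realized within a
stated jitter of the target), and three occlusion conditions modeling how a
femoral head obscures part of the rim.  Each acquisition yields two views —
full pelvis and cup-centered — that differ by an in-plane C-arm roll and
shift; raters digitize the same views independently, so rater noise is a
per-rater/per-session perturbation of a shared projected scene.

The canonical world frame is the pelvic frame itself: lateral = +x,
anterior = +y (beam axis), superior = +z; detector axes are (lateral,
superior).  Occlusion is modeled geometrically as a reduced visible rim arc
plus inflated rim digitization noise — the study reports only that rim
identification was harder with a head in place, so the arc fractions and
noise multipliers are explicit, configurable model parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry3d import CupPose, PelvicFrame, normal_from_anatomic
from .fluoro2d import Landmarks2D, RadiographPair, measure_cup

__all__ = [
    "AcquisitionGeometry",
    "NoiseModel",
    "StudyDesign",
    "SimulatedStudy",
    "CANONICAL_FRAME",
    "default_geometry",
    "default_noise_models",
    "default_design",
    "project_point",
    "project_points",
    "simulate_radiograph_pair",
    "reference_landmarks_3d",
    "simulate_study",
]

CANONICAL_FRAME = PelvicFrame(
    origin=np.zeros(3),
    lateral=np.array([1.0, 0.0, 0.0]),
    anterior=np.array([0.0, 1.0, 0.0]),
    superior=np.array([0.0, 0.0, 1.0]),
)

# fixed scene layout (mm, canonical frame); values are adult-pelvis scale
TEARDROP_SPAN = 130.0          # inter-teardrop distance
BRIM_SEGMENT = (np.array([15.0, 0.0, -10.0]), np.array([85.0, 0.0, 35.0]))
DEFAULT_CUP_CENTER = np.array([65.0, 0.0, 10.0])
DEFAULT_CUP_RADIUS = 27.0      # 54 mm outer-diameter cup


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Projection model of the C-arm.

    Orthographic mode drops the beam-axis coordinate (the parallax-free
    setup); perspective mode is a central projection from a source at
    ``source_detector_distance`` behind the detector plane (which passes
    through the world origin), available for robustness experiments.
    """

    mode: str = "orthographic"
    source_detector_distance: float = 1000.0
    beam_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))
    detector_u: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    detector_v: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    pixel_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("orthographic", "perspective"):
            raise ValueError(f"unknown projection mode {self.mode!r}")
        basis = np.vstack([self.detector_u, self.detector_v, self.beam_axis])
        if np.max(np.abs(basis @ basis.T - np.eye(3))) > 1e-9:
            raise ValueError("detector basis and beam axis must be orthonormal")
        if self.mode == "perspective" and self.source_detector_distance <= 0:
            raise ValueError("source-detector distance must be positive")


@dataclass(frozen=True)
class NoiseModel:
    """Digitization noise and rim visibility for one occlusion condition."""

    rim_sigma: float = 0.5        # mm, isotropic, per rim click
    landmark_sigma: float = 0.5   # mm, teardrop/brim clicks
    arc_fraction: float = 1.0     # fraction of the rim circle a rater can see
    n_rim_points: int = 20        # clicks a rater places along the visible arc

    def __post_init__(self) -> None:
        if self.rim_sigma < 0 or self.landmark_sigma < 0:
            raise ValueError("noise sigmas must be non-negative")
        if not 0.0 < self.arc_fraction <= 1.0:
            raise ValueError("arc_fraction must lie in (0, 1]")
        if self.n_rim_points < 5:
            raise ValueError("need at least 5 rim points for an ellipse fit")


@dataclass(frozen=True)
class StudyDesign:
    """The validation study grid and rating scheme."""

    inclination_levels: tuple[float, ...] = (20.0, 40.0, 60.0)
    anteversion_levels: tuple[float, ...] = (10.0, 25.0, 40.0)
    conditions: tuple[str, ...] = ("cup_only", "small_head", "large_head")
    n_raters: int = 2
    repeat_sessions: int = 1      # extra sessions for rater 1 (intrarater)
    placement_jitter_deg: float = 5.0
    cup_radius: float = DEFAULT_CUP_RADIUS

    def __post_init__(self) -> None:
        if not self.inclination_levels or not self.anteversion_levels:
            raise ValueError("pose grid must be non-empty")
        if not self.conditions:
            raise ValueError("need at least one condition")
        if self.n_raters < 1:
            raise ValueError("need at least one rater")
        if self.placement_jitter_deg < 0:
            raise ValueError("placement jitter must be non-negative")

    def pose_grid(self) -> list[tuple[float, float]]:
        """All (inclination, anteversion) targets, row-major over the grid."""
        return [(i, v) for i in self.inclination_levels for v in self.anteversion_levels]

    def rater_sessions(self) -> list[tuple[int, int]]:
        """(rater, session) pairs; rater 1 carries the repeat sessions."""
        out = [(r, 1) for r in range(1, self.n_raters + 1)]
        out += [(1, 1 + s) for s in range(1, self.repeat_sessions + 1)]
        return sorted(out)


def default_geometry() -> AcquisitionGeometry:
    return AcquisitionGeometry()


def default_noise_models() -> dict[str, NoiseModel]:
    """Per-condition noise: the femoral head shrinks the visible arc and
    inflates rim noise (x1 / x1.5 / x2 on a 0.5 mm base)."""
    return {
        "cup_only": NoiseModel(rim_sigma=0.5, arc_fraction=1.0),
        "small_head": NoiseModel(rim_sigma=0.75, arc_fraction=0.75),
        "large_head": NoiseModel(rim_sigma=1.0, arc_fraction=0.6),
    }


def default_design() -> StudyDesign:
    return StudyDesign()


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------

def project_points(points: np.ndarray, geometry: AcquisitionGeometry) -> np.ndarray:
    """Project (n,3) world points onto the detector, returning (n,2) mm coords."""
    p = np.atleast_2d(np.asarray(points, dtype=float))
    if geometry.mode == "orthographic":
        uv = np.column_stack([p @ geometry.detector_u, p @ geometry.detector_v])
    else:
        d = geometry.source_detector_distance
        source = -d * geometry.beam_axis
        rel = p - source
        depth = rel @ geometry.beam_axis
        if np.any(depth <= 0):
            raise ValueError("point at or behind the X-ray source")
        scale = (d / depth)[:, None]
        hit = source + rel * scale
        uv = np.column_stack([hit @ geometry.detector_u, hit @ geometry.detector_v])
    return uv / geometry.pixel_scale


def project_point(point: Sequence[float], geometry: AcquisitionGeometry) -> np.ndarray:
    """Project a single 3D point; see :func:`project_points`."""
    return project_points(np.asarray(point, float)[None, :], geometry)[0]


def _rim_points_3d(pose: CupPose, angles_rad: np.ndarray,
                   frame: PelvicFrame = CANONICAL_FRAME) -> np.ndarray:
    """World points on the rim circle at the given circle parameters."""
    n = normal_from_anatomic(pose.inclination, pose.anteversion, frame)
    e1 = np.cross(n, frame.superior)
    if np.linalg.norm(e1) < 1e-12:      # face-up cup: any in-plane basis works
        e1 = np.cross(n, frame.lateral)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    c = np.asarray(pose.center, float)
    return (c[None, :]
            + pose.rim_radius * np.cos(angles_rad)[:, None] * e1[None, :]
            + pose.rim_radius * np.sin(angles_rad)[:, None] * e2[None, :])


# ---------------------------------------------------------------------------
# single acquisition
# ---------------------------------------------------------------------------

def _in_plane_transform(uv: np.ndarray, rotation_deg: float,
                        translation: np.ndarray) -> np.ndarray:
    t = np.radians(rotation_deg)
    R = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
    return uv @ R.T + translation[None, :]


def _digitize(scene: dict, pose: CupPose, geometry: AcquisitionGeometry,
              noise: NoiseModel, rng: np.random.Generator) -> RadiographPair:
    """One rater's digitization of a fixed projected scene."""
    # rim clicks: roughly even along the visible arc, with per-click placement
    # scatter (raters do not click identical rim locations)
    span = 2.0 * np.pi * noise.arc_fraction
    k = noise.n_rim_points
    base = scene["arc_start"] + span * (np.arange(k) + 0.5) / k
    base = base + rng.uniform(-0.2, 0.2, size=k) * span / k
    rim3d = _rim_points_3d(pose, base)
    rim_uv = project_points(rim3d, geometry)
    rim_uv = _in_plane_transform(rim_uv, scene["cup_view_rot"], scene["cup_view_shift"])
    rim_uv = rim_uv + rng.normal(0.0, noise.rim_sigma, size=rim_uv.shape)

    td = scene["teardrops_uv"] + rng.normal(0.0, noise.landmark_sigma, size=(2, 2))
    brim1 = scene["brim_uv"] + rng.normal(0.0, noise.landmark_sigma, size=(2, 2))
    brim2 = _in_plane_transform(scene["brim_uv"], scene["cup_view_rot"],
                                scene["cup_view_shift"])
    brim2 = brim2 + rng.normal(0.0, noise.landmark_sigma, size=(2, 2))

    return RadiographPair(
        full_pelvis=Landmarks2D(teardrop_pair=td, brim_line=brim1),
        cup_view=Landmarks2D(brim_line=brim2, rim_points=rim_uv),
    )


def _acquisition_scene(geometry: AcquisitionGeometry,
                       rng: np.random.Generator) -> dict:
    """Per-acquisition randomness shared by all raters of the same images."""
    half = TEARDROP_SPAN / 2.0
    teardrops = np.array([[-half, 0.0, 0.0], [half, 0.0, 0.0]])  # right -> left
    return {
        "teardrops_uv": project_points(teardrops, geometry),
        "brim_uv": project_points(np.vstack(BRIM_SEGMENT), geometry),
        "arc_start": rng.uniform(0.0, 2.0 * np.pi),
        "cup_view_rot": rng.uniform(-10.0, 10.0),
        "cup_view_shift": rng.uniform(-20.0, 20.0, size=2),
    }


def simulate_radiograph_pair(
    pose: CupPose,
    geometry: AcquisitionGeometry | None = None,
    noise: NoiseModel | None = None,
    seed: int | np.random.Generator | None = 0,
) -> tuple[RadiographPair, CupPose]:
    """Simulate one digitized radiograph pair; returns (pair, exact truth pose)."""
    geometry = geometry or default_geometry()
    noise = noise or NoiseModel()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scene = _acquisition_scene(geometry, rng)
    pair = _digitize(scene, pose, geometry, noise, rng)
    return pair, pose


def reference_landmarks_3d(
    pose: CupPose,
    n_detector: int = 6,
    n_rim: int = 24,
    sigma: float = 0.0,
    seed: int | np.random.Generator | None = 0,
) -> dict:
    """3D landmark set as the digitizing arm would record it (canonical frame).

    Detector points lie in the anterior-normal plane behind the pelvis; rim
    points sample the full rim circle.  ``sigma`` adds isotropic digitization
    noise to every point.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    half = TEARDROP_SPAN / 2.0
    g = np.linspace(-120.0, 120.0, max(int(np.ceil(n_detector / 2)), 2))
    xs = np.tile(g, 2)[:n_detector]
    zs = np.repeat([-80.0, 80.0], len(g))[:n_detector]
    detector = np.column_stack([xs, np.full(n_detector, -150.0), zs])
    rim = _rim_points_3d(pose, np.linspace(0.0, 2.0 * np.pi, n_rim, endpoint=False))
    landmarks = {
        "detector": detector,
        "teardrop_right": np.array([-half, 0.0, 0.0]),
        "teardrop_left": np.array([half, 0.0, 0.0]),
        "rim": rim,
    }
    if sigma > 0:
        for key, val in landmarks.items():
            landmarks[key] = val + rng.normal(0.0, sigma, size=np.shape(val))
    return landmarks


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulatedStudy:
    """One realized validation study: digitized pairs, truth, measurements."""

    pairs: tuple[RadiographPair, ...]
    truth: pd.DataFrame          # placement_id, condition, true angles
    measurements: pd.DataFrame   # long format, one row per (pair, angle)


def simulate_study(
    design: StudyDesign | None = None,
    geometry: AcquisitionGeometry | None = None,
    noise_per_condition: Mapping[str, NoiseModel] | None = None,
    master_seed: int = 0,
) -> SimulatedStudy:
    """Run the full simulated validation study.

    For each pose target x condition one physical placement is realized
    (truth = target + uniform jitter within the design bound) along with one
    image acquisition; every (rater, session) then digitizes that same
    acquisition with an independent noise realization, and the 2D pipeline
    measures each digitization.  Substreams are spawned from ``master_seed``,
    so results are reproducible and rater realizations are independent.
    """
    design = design or default_design()
    geometry = geometry or default_geometry()
    noises = dict(noise_per_condition or default_noise_models())
    missing = [c for c in design.conditions if c not in noises]
    if missing:
        raise ValueError(f"no noise model for conditions: {missing}")

    root = np.random.SeedSequence(master_seed)
    placements = [
        (pose_idx, target, condition)
        for pose_idx, target in enumerate(design.pose_grid())
        for condition in design.conditions
    ]
    sessions = design.rater_sessions()
    seeds = root.spawn(len(placements) * (1 + len(sessions)))

    pairs: list[RadiographPair] = []
    truth_rows: list[dict] = []
    meas_rows: list[dict] = []
    seed_it = iter(seeds)
    for pose_idx, (inc_t, av_t), condition in placements:
        placement_rng = np.random.default_rng(next(seed_it))
        j = design.placement_jitter_deg
        inc = inc_t + placement_rng.uniform(-j, j)
        av = av_t + placement_rng.uniform(-j, j)
        pose = CupPose(inclination=inc, anteversion=av,
                       rim_radius=design.cup_radius, center=DEFAULT_CUP_CENTER)
        scene = _acquisition_scene(geometry, placement_rng)
        pose_id = f"P{pose_idx + 1:02d}"
        placement_id = f"{pose_id}-{condition}"
        truth_rows.append({
            "placement_id": placement_id,
            "pose_id": pose_id,
            "condition": condition,
            "target_inclination": inc_t,
            "target_anteversion": av_t,
            "true_inclination": inc,
            "true_anteversion": av,
        })
        for rater, session in sessions:
            rater_rng = np.random.default_rng(next(seed_it))
            raw = _digitize(scene, pose, geometry, noises[condition], rater_rng)
            pair = RadiographPair(
                full_pelvis=raw.full_pelvis, cup_view=raw.cup_view,
                pose_id=pose_id, condition=condition, rater=rater, session=session,
            )
            pairs.append(pair)
            m = measure_cup(pair)
            for angle, value in (("inclination", m.pose.inclination),
                                 ("anteversion", m.pose.anteversion)):
                meas_rows.append({
                    "placement_id": placement_id,
                    "pose_id": pose_id,
                    "condition": condition,
                    "rater": rater,
                    "session": session,
                    "method": "fluoro2d",
                    "angle": angle,
                    "value": value,
                    "ri": m.radiographic.ri,
                    "ra": m.radiographic.ra,
                    "fit_rms": m.fit_rms,
                    "flags": ";".join(m.flags),
                })

    return SimulatedStudy(
        pairs=tuple(pairs),
        truth=pd.DataFrame(truth_rows),
        measurements=pd.DataFrame(meas_rows),
    )
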