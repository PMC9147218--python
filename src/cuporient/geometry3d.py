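"""3D reference method: pelvic frame from digitized landmarks, cup angles from rim points.

This is the coordinate-measuring-machine side of the validation: a best-fit
plane through points digitized on the X-ray receiver defines the anterior
axis, the inter-teardrop line defines a provisional lateral axis, and cross
products complete an orthonormal anatomic frame (lateral, anterior, superior).
The cup orientation is then expressed as the anatomic angles of Murray:

* inclination  — angle between the cup-rim plane and the pelvic transverse
  plane, ``arccos(n . superior)`` for the sign-disambiguated rim normal ``n``;
* anteversion — angle in the transverse plane between the lateral axis and
  the projection of ``n`` onto that plane.

All public angles are degrees; lengths are millimetres.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np

__all__ = [
    "DegenerateInputError",
    "Plane3",
    "PelvicFrame",
    "Circle3D",
    "CupPose",
    "AnatomicAngles",
    "fit_plane",
    "build_pelvic_frame",
    "fit_circle_3d",
    "anatomic_angles_from_normal",
    "normal_from_anatomic",
    "measure_reference",
    "read_landmarks_3d",
    "write_landmarks_3d",
]

#: orthonormality tolerance for constructed frames (pure double-precision geometry)
ORTHO_TOL = 1e-9
#: tolerance below which an input configuration is treated as degenerate
DEGENERATE_TOL = 1e-6

_LANDMARK3D_LABELS = {"detector", "teardrop_left", "teardrop_right", "rim"}


class DegenerateInputError(ValueError):
    """Raised when input geometry is too degenerate to define the result."""


def _as_points(points: Iterable, dim: int) -> np.ndarray:
    arr = np.atleast_2d(np.asarray(points, dtype=float))
    if arr.ndim != 2 or arr.shape[1] != dim:
        raise ValueError(f"expected an (n, {dim}) point array, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("points must be finite")
    return arr


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < DEGENERATE_TOL:
        raise DegenerateInputError("cannot normalize a (near-)zero vector")
    return v / n


@dataclass(frozen=True)
class Plane3:
    """A plane through ``point`` with unit ``normal``."""

    point: np.ndarray
    normal: np.ndarray


@dataclass(frozen=True)
class PelvicFrame:
    """Right-handed orthonormal anatomic frame (lateral, anterior, superior).

    ``lateral x anterior = superior``; superior points cranially.
    """

    origin: np.ndarray
    lateral: np.ndarray
    anterior: np.ndarray
    superior: np.ndarray

    def axes(self) -> np.ndarray:
        """Rows are the lateral, anterior and superior unit vectors."""
        return np.vstack([self.lateral, self.anterior, self.superior])

    def validate(self, tol: float = ORTHO_TOL) -> None:
        R = self.axes()
        if np.max(np.abs(R @ R.T - np.eye(3))) > tol:
            raise ValueError("frame axes are not orthonormal")
        if np.dot(np.cross(self.lateral, self.anterior), self.superior) < 0:
            raise ValueError("frame is not right-handed")


@dataclass(frozen=True)
class Circle3D:
    """A circle in 3D: center, radius (mm) and unit plane normal."""

    center: np.ndarray
    radius: float
    normal: np.ndarray


@dataclass(frozen=True)
class CupPose:
    """Anatomic cup orientation: inclination/anteversion (deg), rim radius and center (mm)."""

    inclination: float
    anteversion: float
    rim_radius: float
    center: np.ndarray

    def __post_init__(self) -> None:
        if not (0.0 <= self.inclination <= 90.0):
            raise ValueError(f"inclination {self.inclination} outside [0, 90] degrees")
        if not (0.0 <= self.anteversion <= 90.0):
            raise ValueError(f"anteversion {self.anteversion} outside [0, 90] degrees")
        if not self.rim_radius > 0:
            raise ValueError("rim_radius must be positive")


class AnatomicAngles(NamedTuple):
    inclination: float
    anteversion: float
    degenerate: bool


# ---------------------------------------------------------------------------
# plane / frame construction
# ---------------------------------------------------------------------------

def fit_plane(points: Iterable, normal_hint: Sequence[float] | None = None) -> Plane3:
    """Total-least-squares plane through ``points``.

    The plane minimizes the sum of squared orthogonal distances; its normal is
    the smallest principal direction of the centered cloud.  ``normal_hint``
    (if given) picks the normal sign pointing into the same half-space.
    """
    pts = _as_points(points, 3)
    if len(pts) < 3:
        raise DegenerateInputError("plane fit needs at least 3 points")
    centroid = pts.mean(axis=0)
    _, s, vt = np.linalg.svd(pts - centroid)
    # collinear cloud: only one significant spread direction
    scale = max(s[0], 1.0)
    if s[1] <= DEGENERATE_TOL * scale:
        raise DegenerateInputError("points are collinear; plane is not unique")
    normal = vt[2]
    if normal_hint is not None and np.dot(normal, np.asarray(normal_hint, float)) < 0:
        normal = -normal
    return Plane3(point=centroid, normal=normal)


def build_pelvic_frame(
    detector_points: Iterable,
    teardrop_pair: Iterable,
    superior_hint: Sequence[float] = (0.0, 0.0, 1.0),
) -> PelvicFrame:
    """Anatomic frame from detector-plane points and the two teardrop beads.

    Construction order (and hence which constraint is satisfied exactly):
    the anterior axis is the detector-plane normal; the provisional lateral
    axis joins the two teardrops (first point to second point); the superior
    axis is ``anterior x lateral`` with its sign matched to ``superior_hint``;
    the final lateral axis is recomputed as ``anterior x superior`` so the
    frame is exactly orthonormal even when the teardrop line is slightly out
    of the detector plane.
    """
    t = _as_points(teardrop_pair, 3)
    if len(t) != 2:
        raise ValueError("teardrop_pair must contain exactly two points")
    sep = np.linalg.norm(t[1] - t[0])
    if sep < DEGENERATE_TOL:
        raise DegenerateInputError("teardrop points coincide")
    lateral0 = (t[1] - t[0]) / sep

    plane = fit_plane(detector_points)
    anterior = plane.normal
    if np.linalg.norm(np.cross(anterior, lateral0)) < DEGENERATE_TOL:
        raise DegenerateInputError("teardrop line is parallel to the detector normal")

    superior = _unit(np.cross(anterior, lateral0))
    if np.dot(superior, np.asarray(superior_hint, float)) < 0:
        superior = -superior
    lateral = np.cross(anterior, superior)
    # the detector normal sign is arbitrary; orient so lateral follows the teardrops
    if np.dot(lateral, lateral0) < 0:
        anterior = -anterior
        lateral = -lateral

    origin = 0.5 * (t[0] + t[1])
    frame = PelvicFrame(origin=origin, lateral=lateral, anterior=anterior, superior=superior)
    frame.validate()
    return frame


# ---------------------------------------------------------------------------
# rim circle
# ---------------------------------------------------------------------------

def fit_circle_3d(rim_points: Iterable) -> Circle3D:
    """Best-fit circle: fit the rim plane, project into it, fit a circle in 2D.

    The in-plane fit is the algebraic (Kasa) circle fit followed by one
    Gauss-Newton refinement step on the geometric residuals; exact on exact
    circular data, near-optimal at the noise levels a digitizing arm produces.
    """
    pts = _as_points(rim_points, 3)
    if len(pts) < 3:
        raise DegenerateInputError("circle fit needs at least 3 points")
    plane = fit_plane(pts)
    # in-plane orthonormal basis
    e1 = _unit(np.cross(plane.normal, [1.0, 0.0, 0.0])
               if abs(plane.normal[0]) < 0.9 else np.cross(plane.normal, [0.0, 1.0, 0.0]))
    e2 = np.cross(plane.normal, e1)
    rel = pts - plane.point
    xy = np.column_stack([rel @ e1, rel @ e2])

    x, y = xy[:, 0], xy[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x * x + y * y
    (cx, cy, c), *_ = np.linalg.lstsq(A, b, rcond=None)
    r = float(np.sqrt(max(c + cx * cx + cy * cy, 0.0)))

    # one Gauss-Newton step on f_i = |p_i - c| - r
    for _ in range(1):
        dx, dy = x - cx, y - cy
        d = np.hypot(dx, dy)
        if np.any(d < DEGENERATE_TOL):
            break
        J = np.column_stack([-dx / d, -dy / d, -np.ones_like(d)])
        delta, *_ = np.linalg.lstsq(J, -(d - r), rcond=None)
        cx, cy, r = cx + delta[0], cy + delta[1], r + delta[2]

    if r <= 0:
        raise DegenerateInputError("circle fit collapsed to non-positive radius")
    center = plane.point + cx * e1 + cy * e2
    return Circle3D(center=center, radius=float(r), normal=plane.normal)


# ---------------------------------------------------------------------------
# anatomic angles
# ---------------------------------------------------------------------------

def _disambiguate_normal(n: np.ndarray, frame: PelvicFrame) -> np.ndarray:
    """Pick the rim normal sign: non-negative superior, then non-negative lateral.

    A rim plane has two unit normals; this octant convention makes the
    reported (inclination, anteversion) pair unique and non-negative.
    """
    s = np.dot(n, frame.superior)
    if s < -DEGENERATE_TOL:
        return -n
    if abs(s) <= DEGENERATE_TOL and np.dot(n, frame.lateral) < 0:
        return -n
    return n


def anatomic_angles_from_normal(cup_normal: Sequence[float], frame: PelvicFrame) -> AnatomicAngles:
    """Murray anatomic inclination/anteversion (deg) of a cup-rim normal.

    The transverse plane is spanned by the lateral and anterior axes.  When
    the rim normal is (anti)parallel to the superior axis its transverse
    projection vanishes, anteversion is undefined and reported as 0 with the
    ``degenerate`` flag set.  Retroversion is folded onto the non-negative
    branch (a single projection cannot distinguish the sign).
    """
    n = _unit(np.asarray(cup_normal, dtype=float))
    n = _disambiguate_normal(n, frame)
    ns = float(np.clip(np.dot(n, frame.superior), -1.0, 1.0))
    inclination = float(np.degrees(np.arccos(abs(ns))))
    nl = float(np.dot(n, frame.lateral))
    na = float(np.dot(n, frame.anterior))
    if np.hypot(nl, na) < 1e-9:
        return AnatomicAngles(inclination, 0.0, True)
    anteversion = float(np.degrees(np.arctan2(abs(na), abs(nl))))
    return AnatomicAngles(inclination, anteversion, False)


def normal_from_anatomic(inclination: float, anteversion: float, frame: PelvicFrame) -> np.ndarray:
    """Unit rim normal for anatomic angles (deg); inverse of angle extraction.

    ``n = sin(I)cos(V) lateral + sin(I)sin(V) anterior + cos(I) superior``.
    """
    if not (0.0 <= inclination <= 90.0 and 0.0 <= anteversion <= 90.0):
        raise ValueError("anatomic angles must lie in [0, 90] degrees")
    i = np.radians(inclination)
    v = np.radians(anteversion)
    return (
        np.sin(i) * np.cos(v) * frame.lateral
        + np.sin(i) * np.sin(v) * frame.anterior
        + np.cos(i) * frame.superior
    )


# ---------------------------------------------------------------------------
# reference-method pipeline + landmark file I/O
# ---------------------------------------------------------------------------

def measure_reference(
    landmarks: dict,
    superior_hint: Sequence[float] = (0.0, 0.0, 1.0),
) -> tuple[CupPose, PelvicFrame]:
    """Full reference measurement from a 3D landmark set.

    ``landmarks`` maps ``detector`` -> (n,3) array, ``teardrop_left`` /
    ``teardrop_right`` -> (3,) points, ``rim`` -> (m,3) array.  The provisional
    lateral axis runs right teardrop -> left teardrop; pass a mirrored
    ``superior_hint``/input for the opposite side convention.
    """
    frame = build_pelvic_frame(
        landmarks["detector"],
        [landmarks["teardrop_right"], landmarks["teardrop_left"]],
        superior_hint=superior_hint,
    )
    circle = fit_circle_3d(landmarks["rim"])
    angles = anatomic_angles_from_normal(circle.normal, frame)
    pose = CupPose(
        inclination=angles.inclination,
        anteversion=angles.anteversion,
        rim_radius=circle.radius,
        center=circle.center,
    )
    return pose, frame


def read_landmarks_3d(path: str | Path) -> dict:
    """Read a ``label,x,y,z`` landmark file (mm) into a landmark dict."""
    rows: dict[str, list[list[float]]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"label", "x", "y", "z"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"{path}: expected header with columns {sorted(required)}")
        for rec in reader:
            label = rec["label"].strip()
            if label not in _LANDMARK3D_LABELS:
                raise ValueError(f"{path}: unknown landmark label {label!r}")
            rows.setdefault(label, []).append(
                [float(rec["x"]), float(rec["y"]), float(rec["z"])]
            )
    out: dict = {}
    for label, pts in rows.items():
        arr = np.asarray(pts, dtype=float)
        out[label] = arr[0] if label.startswith("teardrop") else arr
    return out


def write_landmarks_3d(path: str | Path, landmarks: dict) -> None:
    """Write a landmark dict to a ``label,x,y,z`` file with 6-decimal mm values."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["label", "x", "y", "z"])
        for label in ("detector", "teardrop_left", "teardrop_right", "rim"):
            if label not in landmarks:
                continue
            pts = np.atleast_2d(np.asarray(landmarks[label], dtype=float))
            for p in pts:
                writer.writerow([label] + [f"{c:.6f}" for c in p])
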