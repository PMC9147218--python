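"""2D fluoroscopic method: ellipse fit, reference-axis transfer, anatomic angles.

The cup rim is a circle in 3D; on a parallel-beam (parallax-free) AP view it
projects to an ellipse.  Two images are digitized: a full-pelvis view giving
the inter-teardrop (medial-lateral) line and the pelvic brim line, and a
cup-centered view giving the brim line again plus points on the projected
rim.  Because the brim line is visible in both views, the angle it makes with
the teardrop line on the first image transfers the medial-lateral axis into
the second image, where the cup is measured.

Radiographic angles read off the ellipse:

* ``RI`` — acute angle between the ellipse major axis and the transferred
  medial-lateral axis;
* ``RA`` — ``asin(b/a)`` of the semi-axis ratio.

For a rim circle at anatomic inclination ``AI`` and anteversion ``AV`` viewed
along the anterior axis, orthographic projection gives

    tan RI = tan AI * cos AV          sin RA = sin AI * sin AV

whose closed-form inverse (used by :func:`anatomic_from_radiographic`) is

    AA = atan( tan RA / sin RI )      AI = atan2( sin RI, cos RI * cos AA )

The identity ``1 - sin^2 AI sin^2 AV = cos^2 AI + sin^2 AI cos^2 AV`` makes
the first relation exact.  A single projection cannot distinguish ante- from
retroversion; the non-negative branch is always reported and flagged.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .geometry3d import CupPose, DegenerateInputError

__all__ = [
    "NonEllipticalInputError",
    "InconsistentMeasurementError",
    "Ellipse2D",
    "Landmarks2D",
    "RadiographPair",
    "RadiographicAngles",
    "AnatomicEstimate",
    "CupMeasurement",
    "fit_ellipse",
    "line_angle",
    "ml_axis_from_teardrops",
    "transfer_ml_axis",
    "radiographic_angles",
    "anatomic_from_radiographic",
    "measure_cup",
    "read_landmarks_2d",
    "write_landmarks_2d",
]

#: below this radiographic inclination (deg) the anatomic inversion is flagged
RI_DEGENERACY_TOL = 0.1
#: relative semi-axis difference under which an ellipse is treated as circular
CIRCULAR_TOL = 1e-9

_IMAGE_NAMES = ("full_pelvis", "cup_view")
_LANDMARK2D_LABELS = {"teardrop_left", "teardrop_right", "brim_a", "brim_b", "rim"}


class NonEllipticalInputError(ValueError):
    """The best-fit conic is not an ellipse (hyperbolic/parabolic/degenerate)."""


class InconsistentMeasurementError(ValueError):
    """Radiographic angles that no cup orientation can produce."""


@dataclass(frozen=True)
class Ellipse2D:
    """Geometric ellipse: center, semi-major/minor (mm), major-axis angle (deg, [0,180))."""

    center: tuple[float, float]
    semi_major: float
    semi_minor: float
    major_axis_angle: float

    def __post_init__(self) -> None:
        if not (self.semi_major > 0 and 0 <= self.semi_minor <= self.semi_major):
            raise ValueError("ellipse requires a >= b >= 0, a > 0")


@dataclass(frozen=True)
class Landmarks2D:
    """Digitized landmarks of one image (detector-plane mm)."""

    teardrop_pair: np.ndarray | None = None   # (2, 2)
    brim_line: np.ndarray | None = None       # (2, 2)
    rim_points: np.ndarray | None = None      # (n, 2)


@dataclass(frozen=True)
class RadiographPair:
    """The two digitized AP views of one acquisition, plus study metadata."""

    full_pelvis: Landmarks2D
    cup_view: Landmarks2D
    pose_id: str = ""
    condition: str = ""
    rater: int = 1
    session: int = 1

    def __post_init__(self) -> None:
        if self.full_pelvis.teardrop_pair is None or self.full_pelvis.brim_line is None:
            raise ValueError("full-pelvis view needs teardrop pair and brim line")
        if self.cup_view.brim_line is None:
            raise ValueError("cup view needs a brim line")
        rim = self.cup_view.rim_points
        if rim is None or len(rim) < 5:
            raise ValueError("cup view needs at least 5 rim points")


class RadiographicAngles(NamedTuple):
    ri: float          # major axis vs medial-lateral axis, deg in [0, 90]
    ra: float          # asin(b/a), deg in [0, 90]
    circular: bool     # a == b: RI undefined, reported 0


class AnatomicEstimate(NamedTuple):
    inclination: float
    anteversion: float
    degenerate: bool


@dataclass(frozen=True)
class CupMeasurement:
    """Everything :func:`measure_cup` extracts from one radiograph pair."""

    pose: CupPose
    radiographic: RadiographicAngles
    ellipse: Ellipse2D
    ml_axis_deg: float
    fit_rms: float
    flags: tuple[str, ...] = field(default=())


# ---------------------------------------------------------------------------
# ellipse fitting (direct constrained least squares, Halir-Flusser form)
# ---------------------------------------------------------------------------

def _fit_conic_ellipse(xy: np.ndarray) -> np.ndarray:
    """Conic coefficients (A,B,C,D,E,F) of the ellipse-constrained LS fit.

    Numerically stabilized variant of the direct method: the quadratic and
    linear parts of the design matrix are handled separately so the constraint
    matrix never has to be inverted.
    """
    x, y = xy[:, 0], xy[:, 1]
    D1 = np.column_stack([x * x, x * y, y * y])
    D2 = np.column_stack([x, y, np.ones_like(x)])
    S1 = D1.T @ D1
    S2 = D1.T @ D2
    S3 = D2.T @ D2
    try:
        T = -np.linalg.solve(S3, S2.T)
    except np.linalg.LinAlgError as exc:
        raise NonEllipticalInputError("degenerate rim point configuration") from exc
    M = S1 + S2 @ T
    M = np.vstack([M[2] / 2.0, -M[1], M[0] / 2.0])
    eigval, eigvec = np.linalg.eig(M)
    # the ellipse solution is the eigenvector with 4AC - B^2 > 0 (unique)
    cond = 4.0 * eigvec[0] * eigvec[2] - eigvec[1] ** 2
    idx = np.where(np.isreal(eigval) & (cond.real > 0))[0]
    if len(idx) == 0:
        raise NonEllipticalInputError("best-fit conic is not an ellipse")
    a1 = eigvec[:, idx[0]].real
    return np.concatenate([a1, T @ a1])


def _conic_to_geometric(coeffs: np.ndarray) -> Ellipse2D:
    A, B, C, D, E, F = coeffs
    den = 4.0 * A * C - B * B
    if den <= 0:
        raise NonEllipticalInputError("conic is not an ellipse")
    x0 = (B * E - 2.0 * C * D) / den
    y0 = (B * D - 2.0 * A * E) / den
    F0 = A * x0 * x0 + B * x0 * y0 + C * y0 * y0 + D * x0 + E * y0 + F
    M2 = np.array([[A, B / 2.0], [B / 2.0, C]])
    lam, vec = np.linalg.eigh(M2)
    axes2 = -F0 / lam
    if np.any(axes2 <= 0):
        raise NonEllipticalInputError("conic has no real ellipse points")
    order = np.argsort(axes2)[::-1]          # major axis first
    a = float(np.sqrt(axes2[order[0]]))
    b = float(np.sqrt(axes2[order[1]]))
    if (a - b) <= CIRCULAR_TOL * a:
        theta = 0.0  # circular: major-axis direction is arbitrary
    else:
        v = vec[:, order[0]]
        theta = float(np.degrees(np.arctan2(v[1], v[0]))) % 180.0
    return Ellipse2D(center=(float(x0), float(y0)), semi_major=a, semi_minor=b,
                     major_axis_angle=theta)


def fit_ellipse(rim_points: Iterable) -> Ellipse2D:
    """Direct ellipse-specific least-squares fit of >= 5 digitized rim points.

    Input coordinates are centered and scaled before fitting and the conic is
    mapped back, so recovery on exact ellipse data is at rounding level.
    """
    pts = np.atleast_2d(np.asarray(rim_points, dtype=float))
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("rim_points must be an (n, 2) array")
    if len(pts) < 5:
        raise ValueError("ellipse fit needs at least 5 points")
    mean = pts.mean(axis=0)
    scale = float(np.sqrt(((pts - mean) ** 2).sum(axis=1).mean()))
    if scale <= 0:
        raise NonEllipticalInputError("all rim points coincide")
    norm = (pts - mean) / scale

    A, B, C, D, E, F = _fit_conic_ellipse(norm)
    # undo x' = (x - mx)/s, y' = (y - my)/s on the conic
    mx, my = mean
    s = scale
    A2, B2, C2 = A / s**2, B / s**2, C / s**2
    D2 = D / s - (2 * A * mx + B * my) / s**2
    E2 = E / s - (2 * C * my + B * mx) / s**2
    F2 = (F + (A * mx * mx + B * mx * my + C * my * my) / s**2
          - (D * mx + E * my) / s)
    ellipse = _conic_to_geometric(np.array([A2, B2, C2, D2, E2, F2]))
    # (near-)degenerate input lets the constrained fit escape to an absurdly
    # large conic; an ellipse actually supported by the data stays near it
    if not np.isfinite(ellipse.semi_major) or ellipse.semi_major > 1e6 * scale:
        raise NonEllipticalInputError(
            "degenerate rim point configuration (no supported ellipse)"
        )
    return ellipse


def ellipse_fit_rms(ellipse: Ellipse2D, rim_points: np.ndarray) -> float:
    """RMS approximate orthogonal distance of points to the fitted ellipse.

    Uses the gradient-weighted (Sampson) distance of the implicit conic,
    adequate as a fit diagnostic.
    """
    pts = np.atleast_2d(np.asarray(rim_points, dtype=float))
    t = np.radians(ellipse.major_axis_angle)
    R = np.array([[np.cos(t), np.sin(t)], [-np.sin(t), np.cos(t)]])
    q = (pts - np.asarray(ellipse.center)) @ R.T
    a, b = ellipse.semi_major, max(ellipse.semi_minor, 1e-12)
    f = (q[:, 0] / a) ** 2 + (q[:, 1] / b) ** 2 - 1.0
    grad = np.hypot(2 * q[:, 0] / a**2, 2 * q[:, 1] / b**2)
    grad = np.maximum(grad, 1e-12)
    return float(np.sqrt(np.mean((f / grad) ** 2)))


# ---------------------------------------------------------------------------
# reference-axis geometry
# ---------------------------------------------------------------------------

def line_angle(p: Sequence[float], q: Sequence[float]) -> float:
    """Angle (deg, [0,180)) of the undirected line through two distinct points."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    d = q - p
    if np.hypot(*d) < 1e-9:
        raise DegenerateInputError("line endpoints coincide")
    return float(np.degrees(np.arctan2(d[1], d[0]))) % 180.0


def ml_axis_from_teardrops(full_pelvis: Landmarks2D) -> float:
    """Image-plane angle (deg) of the inter-teardrop medial-lateral line."""
    if full_pelvis.teardrop_pair is None:
        raise ValueError("full-pelvis landmarks lack teardrop points")
    t = np.asarray(full_pelvis.teardrop_pair, float)
    return line_angle(t[0], t[1])


def transfer_ml_axis(full_pelvis: Landmarks2D, cup_view: Landmarks2D) -> float:
    """Medial-lateral axis angle in cup-view coordinates via the brim line.

    The teardrop-to-brim angle is measured on the full-pelvis image and
    applied to the cup-view brim line, so any in-plane rotation between the
    two acquisitions cancels.
    """
    if full_pelvis.brim_line is None or cup_view.brim_line is None:
        raise ValueError("both views need a digitized brim line")
    teardrop = ml_axis_from_teardrops(full_pelvis)
    brim1 = line_angle(*np.asarray(full_pelvis.brim_line, float))
    brim2 = line_angle(*np.asarray(cup_view.brim_line, float))
    return (teardrop + (brim2 - brim1)) % 180.0


def _acute(delta_deg: float) -> float:
    d = abs(delta_deg) % 180.0
    return min(d, 180.0 - d)


def radiographic_angles(ellipse: Ellipse2D, ml_axis_angle: float) -> RadiographicAngles:
    """Radiographic inclination/anteversion read directly off the ellipse."""
    a, b = ellipse.semi_major, ellipse.semi_minor
    if a <= 0:
        raise ValueError("ellipse semi-major axis must be positive")
    circular = (a - b) <= CIRCULAR_TOL * a
    ra = float(np.degrees(np.arcsin(np.clip(b / a, 0.0, 1.0))))
    if circular:
        return RadiographicAngles(0.0, ra, True)  # face-on: major axis arbitrary
    ri = _acute(ellipse.major_axis_angle - ml_axis_angle)
    return RadiographicAngles(ri, ra, False)


def anatomic_from_radiographic(r: RadiographicAngles) -> AnatomicEstimate:
    """Invert the orthographic projection: (RI, RA) -> anatomic (AI, AV).

    ``AA = atan(tan RA / sin RI)`` then ``AI = atan2(sin RI, cos RI cos AA)``;
    exact on the open domain, limits handled explicitly (RA=0 edge-on ellipse
    gives AI=RI; RI=90 gives AI=90, AV=RA).
    """
    if not (0.0 <= r.ri <= 90.0 and 0.0 <= r.ra <= 90.0):
        raise ValueError("radiographic angles must lie in [0, 90] degrees")
    if r.ri < RI_DEGENERACY_TOL:
        if r.ra < RI_DEGENERACY_TOL:
            return AnatomicEstimate(0.0, 0.0, True)
        if not r.circular:
            raise InconsistentMeasurementError(
                "nonzero axis ratio with near-zero radiographic inclination"
            )
        # circular projection: cup faces the beam
        return AnatomicEstimate(90.0, 90.0, True)
    ri = np.radians(r.ri)
    ra = np.radians(r.ra)
    aa = np.arctan2(np.tan(ra), np.sin(ri))
    ai = np.arctan2(np.sin(ri), np.cos(ri) * np.cos(aa))
    return AnatomicEstimate(float(np.degrees(ai)), float(np.degrees(aa)), False)


# ---------------------------------------------------------------------------
# full measurement pipeline
# ---------------------------------------------------------------------------

def measure_cup(pair: RadiographPair) -> CupMeasurement:
    """Measure one radiograph pair: ellipse -> axis transfer -> anatomic angles.

    The rim-radius estimate equals the semi-major axis (exact under the
    parallel-beam assumption).  Flags: ``circular`` (face-on cup),
    ``degenerate`` (angles undefined at the reported values) and
    ``retroversion_ambiguous`` (always present for nonzero anteversion: a
    single projection cannot sign the version).
    """
    rim = np.asarray(pair.cup_view.rim_points, float)
    ellipse = fit_ellipse(rim)
    ml_axis = transfer_ml_axis(pair.full_pelvis, pair.cup_view)
    radio = radiographic_angles(ellipse, ml_axis)
    est = anatomic_from_radiographic(radio)
    flags = []
    if radio.circular:
        flags.append("circular")
    if est.degenerate:
        flags.append("degenerate")
    if est.anteversion > 0:
        flags.append("retroversion_ambiguous")
    cx, cy = ellipse.center
    pose = CupPose(
        inclination=est.inclination,
        anteversion=est.anteversion,
        rim_radius=ellipse.semi_major,
        center=np.array([cx, cy, 0.0]),
    )
    return CupMeasurement(
        pose=pose,
        radiographic=radio,
        ellipse=ellipse,
        ml_axis_deg=ml_axis,
        fit_rms=ellipse_fit_rms(ellipse, rim),
        flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# landmark file I/O (``image,label,u,v`` CSV, mm)
# ---------------------------------------------------------------------------

def read_landmarks_2d(path: str | Path) -> tuple[Landmarks2D, Landmarks2D]:
    """Read one radiograph pair's 2D landmark file into (full_pelvis, cup_view)."""
    per_image: dict[str, dict[str, list]] = {name: {} for name in _IMAGE_NAMES}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"image", "label", "u", "v"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"{path}: expected header with columns {sorted(required)}")
        for rec in reader:
            image = rec["image"].strip()
            label = rec["label"].strip()
            if image not in _IMAGE_NAMES:
                raise ValueError(f"{path}: unknown image {image!r}")
            if label not in _LANDMARK2D_LABELS:
                raise ValueError(f"{path}: unknown landmark label {label!r}")
            per_image[image].setdefault(label, []).append(
                [float(rec["u"]), float(rec["v"])]
            )

    def build(d: dict) -> Landmarks2D:
        teardrops = None
        if "teardrop_left" in d and "teardrop_right" in d:
            teardrops = np.asarray([d["teardrop_right"][0], d["teardrop_left"][0]], float)
        brim = None
        if "brim_a" in d and "brim_b" in d:
            brim = np.asarray([d["brim_a"][0], d["brim_b"][0]], float)
        rim = np.asarray(d["rim"], float) if "rim" in d else None
        return Landmarks2D(teardrop_pair=teardrops, brim_line=brim, rim_points=rim)

    return build(per_image["full_pelvis"]), build(per_image["cup_view"])


def write_landmarks_2d(path: str | Path, pair: RadiographPair) -> None:
    """Write one radiograph pair's landmarks to an ``image,label,u,v`` file."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image", "label", "u", "v"])

        def rows(image: str, lm: Landmarks2D):
            if lm.teardrop_pair is not None:
                t = np.asarray(lm.teardrop_pair, float)
                writer.writerow([image, "teardrop_right", f"{t[0,0]:.6f}", f"{t[0,1]:.6f}"])
                writer.writerow([image, "teardrop_left", f"{t[1,0]:.6f}", f"{t[1,1]:.6f}"])
            if lm.brim_line is not None:
                b = np.asarray(lm.brim_line, float)
                writer.writerow([image, "brim_a", f"{b[0,0]:.6f}", f"{b[0,1]:.6f}"])
                writer.writerow([image, "brim_b", f"{b[1,0]:.6f}", f"{b[1,1]:.6f}"])
            if lm.rim_points is not None:
                for p in np.asarray(lm.rim_points, float):
                    writer.writerow([image, "rim", f"{p[0]:.6f}", f"{p[1]:.6f}"])

        rows("full_pelvis", pair.full_pelvis)
        rows("cup_view", pair.cup_view)
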