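"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def _acute_deg(angle_deg: float) -> float:
    d = abs(angle_deg) % 180.0
    return min(d, 180.0 - d)


def rim_projection_oracle(ai_deg: float, av_deg: float,
                          n: int = 360, radius: float = 27.0):
    """Brute-force forward model, independent of the package internals.

    Samples ``n`` points on a rim circle at anatomic (inclination,
    anteversion), orthographically projects along the anterior (+y) axis
    onto the (lateral, superior) detector, and reads the projected ellipse
    off the principal axes of the point cloud.  Returns (RI, RA, a, b) with
    angles in degrees; RI is measured against the medial-lateral (+u) axis.
    """
    i = np.radians(ai_deg)
    v = np.radians(av_deg)
    normal = np.array([np.sin(i) * np.cos(v), np.sin(i) * np.sin(v), np.cos(i)])
    ref = np.array([0.0, 0.0, 1.0]) if abs(normal[2]) < 0.99 else np.array([1.0, 0.0, 0.0])
    e1 = np.cross(normal, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    pts = radius * (np.cos(t)[:, None] * e1 + np.sin(t)[:, None] * e2)
    uv = pts[:, [0, 2]]                      # drop the beam-axis coordinate
    centered = uv - uv.mean(axis=0)
    cov = centered.T @ centered / n
    w, vecs = np.linalg.eigh(cov)            # ascending
    a = float(np.sqrt(2.0 * max(w[1], 0.0)))
    b = float(np.sqrt(2.0 * max(w[0], 0.0)))
    major = vecs[:, 1]
    ri = _acute_deg(np.degrees(np.arctan2(major[1], major[0])))
    ra = float(np.degrees(np.arcsin(np.clip(b / a, 0.0, 1.0))))
    return ri, ra, a, b


@pytest.fixture(scope="session")
def projection_oracle():
    return rim_projection_oracle


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
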