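import numpy as np
import pytest

from vfareg.core import AttributedPointCloud, RigidTransform
from vfareg.synthetic import PhantomConfig, ScanConfig, make_phantom, simulate_amode_scan


@pytest.fixture(scope="session")
def small_phantom() -> AttributedPointCloud:
    """A small but fully featured phantom (fast; ~105 attributed points)."""
    return make_phantom(PhantomConfig(n_surface_points=400, points_per_arm=30,
                                      protuberance_points=15, seed=3))


@pytest.fixture(scope="session")
def default_phantom() -> AttributedPointCloud:
    """The default-condition phantom (420 attributed points, 4 classes)."""
    return make_phantom(PhantomConfig(seed=1))


@pytest.fixture(scope="session")
def scan_pair(default_phantom):
    """Default phantom plus its simulated noisy A-mode scan."""
    scan = simulate_amode_scan(default_phantom,
                               ScanConfig(seed=3, center_O=PhantomConfig().center_mm))
    return default_phantom, scan


def random_cloud(rng: np.random.Generator, n: int, n_classes: int,
                 scale: float = 50.0) -> AttributedPointCloud:
    """A random attributed cloud with all classes 1..n_classes present."""
    pts = rng.normal(size=(n, 3)) * scale
    attrs = rng.integers(0, n_classes + 1, size=n)
    attrs[:n_classes] = np.arange(1, n_classes + 1)  # guarantee presence
    return AttributedPointCloud(pts, attrs)


def random_transform(rng: np.random.Generator, max_angle: float = 360.0,
                     max_translation: float = 200.0) -> RigidTransform:
    return RigidTransform(rng.uniform(0, max_angle, 3),
                          rng.uniform(-max_translation, max_translation, 3),
                          rng.uniform(-50, 50, 3))


def rotation_angle_deg(matrix: np.ndarray) -> float:
    """Geodesic rotation angle of a rotation matrix, in degrees."""
    return float(np.rad2deg(np.arccos(np.clip((np.trace(matrix) - 1.0) / 2.0, -1.0, 1.0))))
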