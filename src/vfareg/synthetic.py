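"""Synthetic study data: a skull-like attributed surface and its polar A-mode scan.

The phantom stands in for a CT-segmented occiput: a smoothly perturbed
hemispherical shell (the bump field breaks all rotational symmetries) with
suture-like attributed curves radiating from a "Lambda" junction point and a
compact attributed blob standing in for the protuberantia occipitalis
externa.  The scan generator emulates a mechanically positioned single-beam
ultrasound ranging device: rays cast radially from the shell center on a
polar grid, with Gaussian radial noise and random ray dropout.

Everything is bit-reproducible given the configuration (including its seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .core import AttributedPointCloud, RigidTransform, apply_transform

__all__ = [
    "PhantomConfig",
    "ScanConfig",
    "make_phantom",
    "simulate_amode_scan",
    "scan_grid",
    "fit_sphere_center",
    "displace",
    "standard_pair",
]

log = logging.getLogger(__name__)

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass
class PhantomConfig:
    """Geometry of the synthetic attributed skull surface.

    The defaults give ~5000 background surface points and
    ``n_suture_arms * points_per_arm + protuberance_points`` attributed points
    (420 with the defaults: 3 arms x 120 + 60), in ``n_suture_arms + 1``
    feature classes.
    """

    n_surface_points: int = 5000
    radius_mm: float = 90.0
    bump_amplitude_mm: float = 5.0
    n_suture_arms: int = 3
    points_per_arm: int = 120
    protuberance_points: int = 60
    center_mm: tuple = (20.0, -15.0, 35.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_surface_points, self.n_suture_arms, self.points_per_arm,
               self.protuberance_points) < 1:
            raise ValueError("all counts must be >= 1")
        if self.radius_mm <= 0:
            raise ValueError("radius must be positive")


@dataclass
class ScanConfig:
    """Polar-grid A-mode acquisition parameters.

    The grid is inclusive at 1-degree resolution: Phi in [0, 360] and Theta in
    [-60, 60] give 361 x 121 ray nodes before dropout.  ``center_O`` is the
    shell center the rays emanate from; ``None`` fits a sphere to the surface.
    """

    phi_range_deg: tuple = (0.0, 360.0)
    theta_range_deg: tuple = (-60.0, 60.0)
    resolution_deg: float = 1.0
    center_O: tuple | None = None
    noise_sd_mm: float = 0.3
    dropout_rate: float = 0.3
    cone_tolerance_deg: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if self.phi_range_deg[1] < self.phi_range_deg[0] or \
                self.theta_range_deg[1] < self.theta_range_deg[0]:
            raise ValueError("angle ranges must be well-ordered")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.resolution_deg <= 0:
            raise ValueError("resolution must be positive")


def _hemisphere_directions(n: int) -> np.ndarray:
    """Quasi-uniform unit vectors on the upper hemisphere (Fibonacci lattice)."""
    i = np.arange(n)
    z = (i + 0.5) / n
    rho = np.sqrt(1.0 - z**2)
    az = i * _GOLDEN_ANGLE
    return np.column_stack([rho * np.cos(az), rho * np.sin(az), z])


class _BumpField:
    """Smooth seeded radial perturbation; breaks every rotational symmetry."""

    def __init__(self, amplitude: float, rng: np.random.Generator, n_lobes: int = 6):
        self.centers = rng.normal(size=(n_lobes, 3))
        self.centers /= np.linalg.norm(self.centers, axis=1, keepdims=True)
        self.widths = rng.uniform(0.35, 0.8, n_lobes)     # radians
        self.weights = rng.uniform(-1.0, 1.0, n_lobes)
        self.amplitude = amplitude

    def __call__(self, directions: np.ndarray) -> np.ndarray:
        cosang = np.clip(directions @ self.centers.T, -1.0, 1.0)
        ang = np.arccos(cosang)
        return self.amplitude * (np.exp(-(ang / self.widths) ** 2) @ self.weights)


def _suture_arc(start: np.ndarray, tangent: np.ndarray, extent_rad: float,
                n: int, wiggle_rad: float, phase: float, cycles: float) -> np.ndarray:
    """Directions along a wiggly geodesic-like arc from ``start``.

    A transverse sinusoidal deviation is superimposed on the great circle
    through ``start`` and ``tangent``: sutures are irregular curves, and the
    wiggle also removes the reversal symmetry of a plain arc (under which a
    half-turn about the arc midpoint maps the arc onto itself).
    """
    t = np.linspace(extent_rad / n, extent_rad, n)
    base = np.cos(t)[:, None] * start + np.sin(t)[:, None] * tangent
    binormal = np.cross(start, tangent)
    dev = wiggle_rad * np.sin(cycles * 2.0 * np.pi * t / extent_rad + phase) * np.sin(
        np.pi * t / extent_rad)
    out = base + dev[:, None] * binormal
    return out / np.linalg.norm(out, axis=1, keepdims=True)


def make_phantom(cfg: PhantomConfig | None = None) -> AttributedPointCloud:
    """Generate the synthetic attributed skull surface.

    Background points (attribute 0) sample the perturbed hemisphere
    quasi-uniformly.  Attribute classes 1..n_suture_arms lie along
    geodesic-like arms meeting at a Lambda point near the apex, with unequal
    azimuths and arc lengths so no rotation maps the feature set onto itself;
    class n_suture_arms+1 marks the compact protuberance blob.
    """
    cfg = cfg or PhantomConfig()
    rng = np.random.default_rng(cfg.seed)
    bump = _BumpField(cfg.bump_amplitude_mm, rng)
    center = np.asarray(cfg.center_mm, float)

    def on_surface(directions: np.ndarray) -> np.ndarray:
        r = cfg.radius_mm + bump(directions)
        return center + r[:, None] * directions

    dirs = _hemisphere_directions(cfg.n_surface_points)
    points = [on_surface(dirs)]
    attrs = [np.zeros(cfg.n_surface_points, dtype=np.int64)]

    # Lambda junction slightly off-apex
    lam_polar, lam_az = np.deg2rad(8.0), np.deg2rad(90.0)
    lam = np.array([np.sin(lam_polar) * np.cos(lam_az),
                    np.sin(lam_polar) * np.sin(lam_az),
                    np.cos(lam_polar)])

    # unevenly spaced arm azimuths and arc lengths (asymmetric by construction)
    base_az = 20.0 + np.arange(cfg.n_suture_arms) * 360.0 / cfg.n_suture_arms
    az_jitter = np.resize([15.0, -28.0, 40.0, -10.0, 22.0], cfg.n_suture_arms)
    extents = np.resize([82.0, 70.0, 76.0, 60.0, 66.0], cfg.n_suture_arms)

    # orthonormal frame at the Lambda point for tangent directions
    e1 = np.cross(lam, [0.0, 0.0, 1.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(lam, e1)
    wiggle = np.resize([0.10, 0.13, 0.08, 0.11, 0.09], cfg.n_suture_arms)
    phases = np.resize([0.0, 1.3, 2.6, 0.7, 2.0], cfg.n_suture_arms)
    cycles = np.resize([1.5, 2.0, 2.5, 1.8, 2.2], cfg.n_suture_arms)
    for j in range(cfg.n_suture_arms):
        beta = np.deg2rad(base_az[j] + az_jitter[j])
        tangent = np.cos(beta) * e1 + np.sin(beta) * e2
        arc = _suture_arc(lam, tangent, np.deg2rad(extents[j]), cfg.points_per_arm,
                          wiggle[j], phases[j], cycles[j])
        points.append(on_surface(arc))
        attrs.append(np.full(cfg.points_per_arm, j + 1, dtype=np.int64))

    # protuberance: a compact blob of directions in a narrow cone
    blob_polar, blob_az = np.deg2rad(66.0), np.deg2rad(210.0)
    blob_dir = np.array([np.sin(blob_polar) * np.cos(blob_az),
                         np.sin(blob_polar) * np.sin(blob_az),
                         np.cos(blob_polar)])
    raw = blob_dir + 0.06 * rng.normal(size=(cfg.protuberance_points, 3))
    raw /= np.linalg.norm(raw, axis=1, keepdims=True)
    points.append(on_surface(raw))
    attrs.append(np.full(cfg.protuberance_points, cfg.n_suture_arms + 1, dtype=np.int64))

    return AttributedPointCloud(np.vstack(points), np.concatenate(attrs), name="phantom")


def fit_sphere_center(points: np.ndarray) -> np.ndarray:
    """Algebraic least-squares sphere fit; returns the center."""
    p = np.asarray(points, float)
    a = np.column_stack([2.0 * p, np.ones(len(p))])
    b = np.einsum("ij,ij->i", p, p)
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    return sol[:3]


def scan_grid(cfg: ScanConfig) -> tuple[np.ndarray, np.ndarray]:
    """Inclusive (phi, theta) grid node values in degrees."""
    lo, hi = cfg.phi_range_deg
    n_phi = int(round((hi - lo) / cfg.resolution_deg)) + 1
    phi = lo + cfg.resolution_deg * np.arange(n_phi)
    lo, hi = cfg.theta_range_deg
    n_th = int(round((hi - lo) / cfg.resolution_deg)) + 1
    theta = lo + cfg.resolution_deg * np.arange(n_th)
    return phi, theta


def simulate_amode_scan(surface: AttributedPointCloud,
                        cfg: ScanConfig | None = None) -> AttributedPointCloud:
    """Simulate a polar-grid A-mode acquisition of ``surface``.

    For every (Phi, Theta) grid node a ray is cast radially from the shell
    center; the hit is approximated by the surface point nearest in angle to
    the ray (within ``cone_tolerance_deg``, else the ray misses and is
    counted, not fatal).  The returned Cartesian point sits at the hit radius
    plus Gaussian radial noise along the ray and inherits the form attribute
    of the hit surface point; a ``dropout_rate`` fraction of hits is then
    discarded at random.
    """
    cfg = cfg or ScanConfig()
    rng = np.random.default_rng(cfg.seed)
    center = (fit_sphere_center(surface.points) if cfg.center_O is None
              else np.asarray(cfg.center_O, float))

    rel = surface.points - center
    radii = np.linalg.norm(rel, axis=1)
    units = rel / radii[:, None]
    tree = cKDTree(units)

    phi, theta = scan_grid(cfg)
    pg, tg = np.meshgrid(np.deg2rad(phi), np.deg2rad(theta), indexing="ij")
    pg, tg = pg.ravel(), tg.ravel()
    rays = np.column_stack([np.sin(tg) * np.cos(pg),
                            np.sin(tg) * np.sin(pg),
                            np.cos(tg)])

    chord, idx = tree.query(rays, k=1)
    angle = 2.0 * np.arcsin(np.clip(chord / 2.0, 0.0, 1.0))
    hit = angle <= np.deg2rad(cfg.cone_tolerance_deg)
    n_miss = int((~hit).sum())
    if n_miss:
        log.info("A-mode scan: %d of %d rays missed the surface", n_miss, len(rays))

    idx = idx[hit]
    r = radii[idx] + cfg.noise_sd_mm * rng.standard_normal(hit.sum())
    pts = center + r[:, None] * rays[hit]
    attr = surface.attributes[idx]

    if cfg.dropout_rate > 0:
        keep = rng.random(len(pts)) >= cfg.dropout_rate
        pts, attr = pts[keep], attr[keep]

    return AttributedPointCloud(pts, attr, name="amode_scan")


def displace(cloud: AttributedPointCloud, transform: RigidTransform) -> AttributedPointCloud:
    """Apply a ground-truth misalignment (thin alias of apply_transform, logged)."""
    log.info("displacing %r by angles %s deg, translation %s mm (pivot %s)",
             cloud.name, transform.angles_deg, transform.translation_mm, transform.pivot_mm)
    out = apply_transform(cloud, transform)
    out.name = f"{cloud.name}_displaced"
    return out


def standard_pair(seed: int = 1) -> tuple[AttributedPointCloud, AttributedPointCloud]:
    """The standard CT-like / scan-like pair used by the evaluation protocols.

    Fixed: the default phantom.  Moving: its simulated A-mode scan with the
    default noise (0.3 mm radial s.d.) and dropout (30%).
    """
    phantom = make_phantom(PhantomConfig(seed=seed))
    scan = simulate_amode_scan(phantom, ScanConfig(seed=seed * 2 + 1,
                                                   center_O=PhantomConfig().center_mm))
    return phantom, scan
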