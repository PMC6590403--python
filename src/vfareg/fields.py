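"""Gaussian scale-space energy and its spatial vector-field analysis.

The registration energy assigns each attributed moving point ``q_n`` the
potential ``U_n = 1 - exp(-d_n^2 / sigma^2)``, where ``d_n`` is its binary-
matching closest distance to the fixed cloud and ``sigma`` the Gaussian
aperture.  The total energy ``E_sigma = sum U_n`` is 0 at perfect alignment
and saturates at N when every point is far.

The *vector field analysis* treats the negative potential gradient as a force
of attraction ``F_n = -grad U_n`` acting on each moving point.  The curl of
this scattered force field is estimated from a local moving-least-squares
affine fit; the attributed point of minimal curl magnitude within the active
region of the field (the "vortex") gains no rotational velocity under the
induced rigid motion and serves as the instant center of rotation (ICR) for
the pivoted rotation parameterization during optimization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .core import AttributedPointCloud, GaussianEnergyParams
from .errors import DegenerateNeighborhoodError
from .matching import Correspondence, closest_points

__all__ = [
    "FieldSamples",
    "potential",
    "hooke_energy",
    "total_energy",
    "potential_gradient",
    "curl_field",
    "find_vortex",
    "analyze_force_field",
]


@dataclass
class FieldSamples:
    """Per-point field quantities for the attributed moving points.

    Arrays are aligned with ``moving_index``: ``potential`` is U_n in [0, 1),
    ``gradient`` is grad U_n (1/mm), ``force`` is -gradient, ``curl`` the
    estimated curl of the force field and ``curl_magnitude`` its norm.
    """

    moving_index: np.ndarray
    positions: np.ndarray
    potential: np.ndarray
    gradient: np.ndarray
    force: np.ndarray
    curl: np.ndarray | None = None
    curl_magnitude: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.moving_index)


def potential(d, sigma: float):
    """Gaussian per-point potential ``1 - exp(-d^2/sigma^2)``.

    Strictly increasing in ``d``; 0 at d=0, saturating toward 1.  Accepts
    scalars or arrays.  Uses ``-expm1`` so small distances keep full relative
    precision.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    d = np.asarray(d, dtype=float)
    if (d < 0).any():
        raise ValueError("distances must be non-negative")
    out = -np.expm1(-(d / sigma) ** 2)
    return float(out) if out.ndim == 0 else out


def hooke_energy(corr: Correspondence, spring_k: float = 1.0) -> float:
    """Quadratic spring energy ``k * sum d_n^2`` of a correspondence (k=1)."""
    return float(spring_k * np.sum(corr.distance_mm**2))


def total_energy(corr: Correspondence, params: GaussianEnergyParams) -> float:
    """Total Gaussian energy ``E_sigma = sum_n (1 - exp(-d_n^2/sigma^2))``."""
    if len(corr) < 1:
        raise ValueError("correspondence must contain at least one entry")
    return float(np.sum(potential(corr.distance_mm, params.sigma)))


def potential_gradient(moving: AttributedPointCloud, fixed: AttributedPointCloud,
                       corr: Correspondence, params: GaussianEnergyParams) -> FieldSamples:
    """Analytic gradient and force of the potential at each attributed moving point.

    With the closest-point correspondence held fixed at the current pose,
    ``grad U_n = (2/sigma^2) exp(-d_n^2/sigma^2) (q_n - p*)`` where ``p*`` is
    the matched fixed point; the force ``F_n = -grad U_n`` points from the
    moving point toward its match.
    """
    q = moving.points[corr.moving_index]
    p = fixed.points[corr.fixed_index]
    diff = q - p
    d2 = corr.distance_mm**2
    s2 = params.sigma**2
    coeff = (2.0 / s2) * np.exp(-d2 / s2)
    grad = coeff[:, None] * diff
    return FieldSamples(
        moving_index=corr.moving_index.copy(),
        positions=q,
        potential=potential(corr.distance_mm, params.sigma),
        gradient=grad,
        force=-grad,
    )


def curl_field(points: np.ndarray, forces: np.ndarray, k_neighbors: int = 12) -> np.ndarray:
    """Estimate the curl of a vector field sampled at scattered 3-D points.

    At each point, an affine field ``F(x) ~ F0 + J (x - x_i)`` is fitted over
    the ``k_neighbors`` nearest neighbors (plus the point itself) by weighted
    least squares with Gaussian distance weights; the curl is read off the
    antisymmetric part of the fitted Jacobian:
    ``(dFz/dy - dFy/dz, dFx/dz - dFz/dx, dFy/dx - dFx/dy)``.

    The estimator reproduces affine fields exactly.  Raises
    :class:`DegenerateNeighborhoodError` when a neighborhood is rank-deficient
    (e.g. collinear points); callers may retry with a larger ``k_neighbors``.
    """
    points = np.asarray(points, float)
    forces = np.asarray(forces, float)
    n = len(points)
    if k_neighbors < 4:
        raise ValueError("k_neighbors must be >= 4")
    if n < k_neighbors + 1:
        raise ValueError(f"need at least k_neighbors+1={k_neighbors + 1} points; got {n}")

    tree = cKDTree(points)
    dist, idx = tree.query(points, k=k_neighbors + 1)  # includes self at distance 0

    nb = points[idx]                       # (n, k+1, 3)
    dx = nb - points[:, None, :]           # neighbor offsets
    fb = forces[idx]                       # (n, k+1, 3)

    # Gaussian weights with per-point bandwidth = mean nonzero neighbor distance
    h = dist[:, 1:].mean(axis=1)
    h = np.where(h > 0, h, 1.0)
    wgt = np.exp(-(dist / h[:, None]) ** 2)

    ones = np.ones(dx.shape[:2])
    design = np.concatenate([ones[..., None], dx], axis=2)     # (n, k+1, 4)
    dw = design * wgt[..., None]
    ata = np.einsum("nki,nkj->nij", dw, design)                # (n, 4, 4)
    atb = np.einsum("nki,nkj->nij", dw, fb)                    # (n, 4, 3)

    # rank check on the spatial block of the weighted normal matrix
    spatial = ata[:, 1:, 1:]
    sv = np.linalg.svd(spatial, compute_uv=False)
    bad = sv[:, -1] <= 1e-12 * np.maximum(sv[:, 0], 1e-300)
    if bad.any():
        raise DegenerateNeighborhoodError(
            f"{int(bad.sum())} neighborhood(s) are rank-deficient (e.g. collinear); "
            "increase k_neighbors")

    sol = np.linalg.solve(ata, atb)        # (n, 4, 3): row 0 = F0, rows 1:4 = J^T
    jt = sol[:, 1:, :]                     # jt[n, a, b] = dF_b / dx_a
    curl = np.stack([
        jt[:, 1, 2] - jt[:, 2, 1],
        jt[:, 2, 0] - jt[:, 0, 2],
        jt[:, 0, 1] - jt[:, 1, 0],
    ], axis=1)
    return curl


def find_vortex(points: np.ndarray, curls: np.ndarray, forces: np.ndarray,
                min_force_fraction: float = 1e-3) -> tuple[int, np.ndarray]:
    """Select the vortex: the point of minimal curl magnitude in the active field.

    Only points whose force magnitude is at least ``min_force_fraction`` times
    the maximum force are candidates: where the Gaussian potential has
    saturated the force field vanishes numerically and its curl is zero for
    the trivial reason that there is no field, not because the point is a
    rotation center.  Ties are broken by smaller force magnitude, then by
    lower index.  Returns ``(index, position)``; the position is used as the
    optimization pivot (instant center of rotation).
    """
    points = np.asarray(points, float)
    curls = np.asarray(curls, float)
    forces = np.asarray(forces, float)
    if len(points) < 1:
        raise ValueError("need at least one field sample")

    cmag = np.linalg.norm(curls, axis=1)
    fmag = np.linalg.norm(forces, axis=1)
    fmax = fmag.max()
    active = fmag >= min_force_fraction * fmax if fmax > 0 else np.ones(len(points), bool)
    if not active.any():
        active = np.ones(len(points), bool)

    cand = np.flatnonzero(active)
    # lexicographic argmin: curl magnitude, then force magnitude, then index
    order = np.lexsort((cand, fmag[cand], cmag[cand]))
    best = int(cand[order[0]])
    return best, points[best].copy()


def analyze_force_field(moving: AttributedPointCloud, fixed: AttributedPointCloud,
                        params: GaussianEnergyParams | None = None,
                        k_neighbors: int = 12) -> tuple[FieldSamples, int, np.ndarray]:
    """Full vector field analysis: potentials, forces, curl, and vortex.

    Convenience driver used by the registration front-end and the CLI.
    Returns ``(samples, vortex_index, vortex_position)`` where the index is
    into ``samples`` (i.e. the attributed moving points).  If the curl fit is
    degenerate at the requested ``k_neighbors``, the neighborhood is enlarged
    (doubled up to three times); as a last resort the centroid of the
    attributed moving points is used as the pivot.
    """
    params = params or GaussianEnergyParams()
    corr = closest_points(moving, fixed, params)
    samples = potential_gradient(moving, fixed, corr, params)

    k = k_neighbors
    curl = None
    for _ in range(4):
        if len(samples) < k + 1:
            break
        try:
            curl = curl_field(samples.positions, samples.force, k_neighbors=k)
            break
        except DegenerateNeighborhoodError:
            k *= 2
    if curl is None:
        centroid = samples.positions.mean(axis=0)
        samples.curl = np.zeros_like(samples.force)
        samples.curl_magnitude = np.zeros(len(samples))
        idx = int(np.argmin(np.linalg.norm(samples.positions - centroid, axis=1)))
        return samples, idx, samples.positions[idx].copy()

    samples.curl = curl
    samples.curl_magnitude = np.linalg.norm(curl, axis=1)
    idx, pos = find_vortex(samples.positions, curl, samples.force)
    return samples, idx, pos
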