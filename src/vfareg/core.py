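"""Core domain types: attributed point clouds, rigid transforms, energy parameters.

Conventions used throughout the package
---------------------------------------
* Coordinates are millimetres in a right-handed Cartesian frame.
* Form attributes are non-negative integers; 0 marks unattributed background
  points, nonzero values name feature classes (e.g. individual suture arms of
  the Lambda fissure, the protuberantia occipitalis externa).
* Rotations are parameterized by three angles (phi, theta, psi) in degrees
  about the x, y and z axes, composed extrinsically (fixed axes):
  ``R = Rz(psi) @ Ry(theta) @ Rx(phi)``.
* A rigid transform may carry a pivot ``c``; points map as
  ``p -> R @ (p - c) + c + t``.  The pivot is a parameterization detail only:
  two transforms with different pivots but identical net maps act identically
  on every point.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "AttributedPointCloud",
    "RigidTransform",
    "GaussianEnergyParams",
    "apply_transform",
    "invert_transform",
    "compose_transforms",
]

AXIS_ORDER = "xyz-extrinsic"


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"points must have shape (n, 3); got {pts.shape}")
    return pts


@dataclass
class AttributedPointCloud:
    """A 3-D point cloud with one non-negative integer form attribute per point.

    Parameters
    ----------
    points : (n, 3) array_like
        Cartesian coordinates in millimetres.
    attributes : (n,) array_like of int
        Form attribute per point; 0 = unattributed background.
    name : str
        Free-text label carried through I/O.
    """

    points: np.ndarray
    attributes: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.points = _as_points(self.points)
        self.attributes = np.asarray(self.attributes, dtype=np.int64)
        if self.attributes.ndim != 1 or len(self.attributes) != len(self.points):
            raise ValueError(
                "attributes must be a 1-D array matching the number of points "
                f"({len(self.points)}); got shape {self.attributes.shape}"
            )
        if len(self.points) < 1:
            raise ValueError("a point cloud must contain at least one point")
        if not np.isfinite(self.points).all():
            raise ValueError("all coordinates must be finite")
        if (self.attributes < 0).any():
            raise ValueError("form attributes must be non-negative integers")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def feature_classes(self) -> np.ndarray:
        """Sorted array of distinct nonzero attribute values."""
        vals = np.unique(self.attributes)
        return vals[vals > 0]

    @property
    def attributed_mask(self) -> np.ndarray:
        return self.attributes > 0

    @property
    def n_attributed(self) -> int:
        return int(np.count_nonzero(self.attributes))

    def attributed_subset(self) -> "AttributedPointCloud":
        """The sub-cloud of points carrying a nonzero form attribute."""
        m = self.attributed_mask
        if not m.any():
            from .errors import EmptyFeatureError

            raise EmptyFeatureError(f"cloud {self.name!r} has no attributed points")
        return AttributedPointCloud(self.points[m], self.attributes[m], name=self.name)

    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def copy(self) -> "AttributedPointCloud":
        return AttributedPointCloud(self.points.copy(), self.attributes.copy(), self.name)


def rotation_matrix(angles_deg) -> np.ndarray:
    """3x3 rotation matrix for extrinsic x-y-z angles in degrees."""
    return Rotation.from_euler("xyz", np.asarray(angles_deg, float), degrees=True).as_matrix()


@dataclass
class RigidTransform:
    """Rigid transform: rotation about a pivot plus translation.

    Maps a point ``p`` to ``R @ (p - pivot) + pivot + translation`` where ``R``
    is built from ``angles_deg`` (degrees about x, y, z, extrinsic order).
    """

    angles_deg: np.ndarray = field(default_factory=lambda: np.zeros(3))
    translation_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    pivot_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.angles_deg = np.asarray(self.angles_deg, dtype=float).reshape(3)
        self.translation_mm = np.asarray(self.translation_mm, dtype=float).reshape(3)
        self.pivot_mm = np.asarray(self.pivot_mm, dtype=float).reshape(3)
        for arr, label in ((self.angles_deg, "angles"), (self.translation_mm, "translation"),
                           (self.pivot_mm, "pivot")):
            if not np.isfinite(arr).all():
                raise ValueError(f"{label} must be finite")

    @property
    def matrix(self) -> np.ndarray:
        return rotation_matrix(self.angles_deg)

    @property
    def origin_translation(self) -> np.ndarray:
        """Net translation b of the equivalent origin-pivot form p -> R p + b."""
        r = self.matrix
        c = self.pivot_mm
        return self.translation_mm + c - r @ c

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        out = pts @ self.matrix.T + self.origin_translation
        return out if np.asarray(points).ndim == 2 else out[0]

    def as_origin_pivot(self) -> "RigidTransform":
        """Equivalent transform with pivot at the origin (identical point map)."""
        return RigidTransform(self.angles_deg.copy(), self.origin_translation, np.zeros(3))

    def inverse(self) -> "RigidTransform":
        """The transform undoing this one (origin pivot)."""
        rot = Rotation.from_euler("xyz", self.angles_deg, degrees=True)
        rinv = rot.inv()
        b = self.origin_translation
        return RigidTransform(
            rinv.as_euler("xyz", degrees=True),
            -rinv.as_matrix() @ b,
            np.zeros(3),
        )

    def to_dict(self) -> dict:
        return {
            "angles_deg": self.angles_deg.tolist(),
            "axis_order": AXIS_ORDER,
            "translation_mm": self.translation_mm.tolist(),
            "pivot_mm": self.pivot_mm.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        order = d.get("axis_order", AXIS_ORDER)
        if order != AXIS_ORDER:
            raise ValueError(f"unsupported axis_order {order!r}; expected {AXIS_ORDER!r}")
        return cls(
            np.asarray(d["angles_deg"], float),
            np.asarray(d.get("translation_mm", [0, 0, 0]), float),
            np.asarray(d.get("pivot_mm", [0, 0, 0]), float),
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path) -> "RigidTransform":
        return cls.from_dict(json.loads(Path(path).read_text()))


def compose_transforms(second: RigidTransform, first: RigidTransform) -> RigidTransform:
    """Transform equivalent to applying ``first`` then ``second`` (origin pivot)."""
    r1 = Rotation.from_euler("xyz", first.angles_deg, degrees=True)
    r2 = Rotation.from_euler("xyz", second.angles_deg, degrees=True)
    rnet = r2 * r1
    b = r2.as_matrix() @ first.origin_translation + second.origin_translation
    return RigidTransform(rnet.as_euler("xyz", degrees=True), b, np.zeros(3))


def apply_transform(cloud: AttributedPointCloud, transform: RigidTransform) -> AttributedPointCloud:
    """Return a new cloud with transformed coordinates; attributes are unchanged."""
    return AttributedPointCloud(transform.apply(cloud.points), cloud.attributes.copy(), cloud.name)


def invert_transform(transform: RigidTransform) -> RigidTransform:
    """Functional alias for :meth:`RigidTransform.inverse`."""
    return transform.inverse()


@dataclass
class GaussianEnergyParams:
    """Parameters of the Gaussian scale-space registration energy.

    sigma : Gaussian aperture of the per-point potential 1 - exp(-d^2/sigma^2).
        A unitless scale applied to mm coordinates; default 10.
    w : attribute weighting factor of the weighted 4-D distance; a very large
        real number so that cross-class matches are rejected (default 1e9).
    spring_k : Hooke spring constant of the quadratic energy; fixed at 1.
    """

    sigma: float = 10.0
    w: float = 1e9
    spring_k: float = 1.0

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")
        if not self.w >= 1e6:
            raise ValueError("w must be >= 1e6 (a very large weighting factor)")
        if self.spring_k != 1:
            raise ValueError("spring_k is fixed at 1")
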