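"""Attribute-constrained closest-point search (binary matching).

Two routes are provided:

* :func:`closest_points` — the production path.  One KD-tree per feature
  class; a moving point may only match a fixed point of the same nonzero
  attribute.  This realizes the exact w -> infinity limit of the weighted
  4-D distance while keeping full floating-point precision on the spatial
  term.
* :func:`brute_force_closest` — an O(M*N) oracle that evaluates the literal
  weighted distance with a finite w for every pair.  Used in tests as an
  independent reference and available for small clouds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .core import AttributedPointCloud, GaussianEnergyParams
from .errors import EmptyFeatureError, MissingClassError

__all__ = ["Correspondence", "weighted_distance", "closest_points", "brute_force_closest"]

# Distances closer than this are treated as exact ties and broken by lowest
# fixed index, keeping fast path and oracle bit-identical.
_TIE_TOL = 1e-12


@dataclass
class Correspondence:
    """Per-moving-point closest fixed match under binary attribute matching.

    Arrays are aligned: entry ``i`` pairs moving point ``moving_index[i]``
    with fixed point ``fixed_index[i]`` at Euclidean distance
    ``distance_mm[i]``; ``attribute[i]`` is the shared form attribute.
    """

    moving_index: np.ndarray
    fixed_index: np.ndarray
    distance_mm: np.ndarray
    attribute: np.ndarray

    def __post_init__(self) -> None:
        self.moving_index = np.asarray(self.moving_index, dtype=np.int64)
        self.fixed_index = np.asarray(self.fixed_index, dtype=np.int64)
        self.distance_mm = np.asarray(self.distance_mm, dtype=float)
        self.attribute = np.asarray(self.attribute, dtype=np.int64)
        n = len(self.moving_index)
        if not (len(self.fixed_index) == len(self.distance_mm) == len(self.attribute) == n):
            raise ValueError("correspondence arrays must have equal length")
        if (self.distance_mm < 0).any():
            raise ValueError("distances must be non-negative")

    def __len__(self) -> int:
        return len(self.moving_index)


def weighted_distance(p, q, w: float) -> float:
    """Weighted 4-D distance between two attributed points.

    ``p`` and ``q`` are length-4 sequences (x, y, z, a).  Returns
    ``sqrt(dx^2 + dy^2 + dz^2 + w*(da)^2)``; for equal attributes this is the
    plain Euclidean distance.
    """
    if w < 0:
        raise ValueError("w must be non-negative")
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    spatial = p[:3] - q[:3]
    da = p[3] - q[3]
    return float(np.sqrt(spatial @ spatial + w * da * da))


def _resolve_ties(fixed_pts: np.ndarray, query: np.ndarray, dist: np.ndarray,
                  idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Among k-NN candidates, pick the lowest index within _TIE_TOL of the minimum.

    Returns the exact Euclidean distance to the chosen candidate.
    """
    best_d = dist[:, 0]
    tied = dist <= (best_d + _TIE_TOL)[:, None]
    # lowest original index among tied candidates
    masked = np.where(tied, idx, np.iinfo(np.int64).max)
    choice = masked.min(axis=1)
    exact = np.linalg.norm(query - fixed_pts[choice], axis=1)
    return exact, choice


def closest_points(moving: AttributedPointCloud, fixed: AttributedPointCloud,
                   params: GaussianEnergyParams | None = None) -> Correspondence:
    """Binary-matching closest-point search.

    For every moving point with a nonzero form attribute, finds the fixed
    point of the *same* attribute class at minimal Euclidean distance; pairs
    with differing attributes are rejected outright.  Moving points with
    attribute 0 do not participate.

    Raises
    ------
    EmptyFeatureError
        If the moving cloud has no attributed points.
    MissingClassError
        If a moving feature class is absent from the fixed cloud (the
        weighted distance would be uniformly huge: no valid match exists).
    """
    del params  # matching is the exact w->infinity limit; w does not appear
    moving_classes = moving.feature_classes
    if moving_classes.size == 0:
        raise EmptyFeatureError(
            f"moving cloud {moving.name!r} has no nonzero form attributes")
    fixed_classes = set(fixed.feature_classes.tolist())
    missing = [int(c) for c in moving_classes if int(c) not in fixed_classes]
    if missing:
        raise MissingClassError(
            f"moving feature classes {missing} are absent from the fixed cloud")

    m_idx_parts, f_idx_parts, d_parts, a_parts = [], [], [], []
    for cls in moving_classes:
        cls = int(cls)
        f_sel = np.flatnonzero(fixed.attributes == cls)
        m_sel = np.flatnonzero(moving.attributes == cls)
        tree = cKDTree(fixed.points[f_sel])
        k = min(4, len(f_sel))
        dist, idx = tree.query(moving.points[m_sel], k=k)
        if k == 1:
            dist, idx = dist[:, None], idx[:, None]
        d, local = _resolve_ties(fixed.points[f_sel], moving.points[m_sel], dist, idx)
        m_idx_parts.append(m_sel)
        f_idx_parts.append(f_sel[local])
        d_parts.append(d)
        a_parts.append(np.full(len(m_sel), cls, dtype=np.int64))

    m_idx = np.concatenate(m_idx_parts)
    order = np.argsort(m_idx, kind="stable")
    return Correspondence(
        m_idx[order],
        np.concatenate(f_idx_parts)[order],
        np.concatenate(d_parts)[order],
        np.concatenate(a_parts)[order],
    )


def brute_force_closest(moving: AttributedPointCloud, fixed: AttributedPointCloud,
                        w: float) -> Correspondence:
    """Exhaustive closest-point search with the literal finite-w weighted distance.

    Evaluates the weighted 4-D distance for every (moving, fixed) pair and
    takes the per-moving-point minimum; ties go to the lowest fixed index.
    All moving points participate (with w=0 this is a plain all-against-all
    Euclidean nearest-neighbor search that ignores attributes).  Intended for
    clouds up to a few thousand points.
    """
    if len(moving) * len(fixed) > 5000 * 5000:
        raise ValueError("brute_force_closest is limited to <= 5000x5000 pairs")
    diff = moving.points[:, None, :] - fixed.points[None, :, :]
    sq = np.einsum("mnk,mnk->mn", diff, diff)
    da = moving.attributes[:, None] - fixed.attributes[None, :]
    dist = np.sqrt(sq + w * (da.astype(float)) ** 2)
    best = dist.min(axis=1)
    tied = dist <= (best + _TIE_TOL)[:, None]
    idx = np.where(tied, np.arange(len(fixed))[None, :], np.iinfo(np.int64).max).min(axis=1)
    return Correspondence(
        np.arange(len(moving), dtype=np.int64),
        idx,
        dist[np.arange(len(moving)), idx],
        moving.attributes.copy(),
    )
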