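"""Rigid registration drivers: VFA (pivot = instant center of rotation) and
the Gaussian-fields (GF) baseline (pivot = origin, soft attribute distance).

Both methods minimize the Gaussian scale-space energy over 6 rigid parameters
(three rotation angles in degrees about the pivot, three translations in mm)
with the quasi-Newton/backtracking optimizer.  They differ in

* matching — VFA uses binary attribute-constrained matching (cross-class
  pairs rejected outright); GF uses a soft 4-D distance
  ``sqrt(||dq||^2 + w_gf * (da)^2)`` over all fixed points;
* pivot — VFA rotates about the vortex of the force field (the instant
  center of rotation found by vector field analysis); GF rotates about the
  coordinate origin.

Numerical note: the optimizer works on ``-log(sum_n exp(-d_n^2/sigma^2))``, a
strictly monotone transform of ``E_sigma`` with identical minimizers and
basins.  When every ``d_n`` greatly exceeds the aperture the Gaussian terms
are smaller than the floating-point resolution of ``E_sigma ~ N`` (and can
underflow outright), so decreases of the energy itself become invisible; the
log-domain objective keeps full relative precision at any distance.  All
reported energies and traces are ``E_sigma``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import logsumexp

from .core import AttributedPointCloud, GaussianEnergyParams, RigidTransform, \
    apply_transform, compose_transforms
from .errors import EmptyFeatureError, MissingClassError
from .fields import analyze_force_field
from .optimize import quasi_newton_minimize

__all__ = [
    "RegistrationConfig",
    "RegistrationResult",
    "energy_of_params",
    "jacobian_of_params",
    "register_vfa",
    "register_gf",
    "register",
]

_DEG = np.pi / 180.0

_GX = np.array([[0.0, 0, 0], [0, 0, -1], [0, 1, 0]])
_GY = np.array([[0.0, 0, 1], [0, 0, 0], [-1, 0, 0]])
_GZ = np.array([[0.0, -1, 0], [1, 0, 0], [0, 0, 0]])


@dataclass
class RegistrationConfig:
    """Settings shared by both registration methods.

    ``w_gf`` is the soft attribute weight of the GF baseline; ``None`` means
    ``sigma**2`` (attributes matter at the scale of one aperture).
    ``refresh_icr_every`` > 0 recomputes the instant center of rotation every
    that many accepted iterations (0 = compute once, the default).
    """

    method: str = "vfa"
    sigma: float = 10.0
    w: float = 1e9
    w_gf: float | None = None
    k_neighbors: int = 12
    max_iterations: int = 500
    gradient_tolerance: float = 1e-6
    function_tolerance: float = 1e-9
    backtracking_shrink: float = 0.5
    armijo_c: float = 1e-4
    max_halvings: int = 30
    refresh_icr_every: int = 0
    # stepping-out of local minima: bounded exploratory rotations about the
    # pivot with the attributed mass centers mapped onto each other,
    # committed only when the subsequent descent ends strictly below the
    # departure energy (the accepted trace stays non-increasing).  This
    # exploration is part of the field-analysis assistance: None enables it
    # for the VFA driver and disables it for the original GF formulation.
    stepout_enabled: bool | None = None
    stepout_trials: int = 5
    stepout_iterations: int = 60
    max_stepout_rounds: int = 8

    @property
    def stepout_active(self) -> bool:
        if self.stepout_enabled is None:
            return self.method == "vfa"
        return self.stepout_enabled

    def __post_init__(self) -> None:
        if self.method not in ("vfa", "gf"):
            raise ValueError(f"method must be 'vfa' or 'gf'; got {self.method!r}")
        if self.sigma <= 0 or self.gradient_tolerance <= 0 or self.function_tolerance <= 0:
            raise ValueError("sigma and tolerances must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")

    @property
    def energy_params(self) -> GaussianEnergyParams:
        return GaussianEnergyParams(sigma=self.sigma, w=self.w)

    @property
    def soft_attribute_weight(self) -> float:
        return self.sigma**2 if self.w_gf is None else self.w_gf


@dataclass
class RegistrationResult:
    """Outcome of a registration run.

    ``transform`` is the net moving->fixed map expressed pivot-free (pivot at
    the origin); ``energy_trace`` holds E_sigma at each accepted optimizer
    step and is non-increasing, with ``residual`` its last entry.
    """

    transform: RigidTransform
    residual: float
    iterations: int
    energy_trace: list = field(default_factory=list)
    converged: bool = False
    pivot_used: np.ndarray = field(default_factory=lambda: np.zeros(3))
    method: str = "vfa"

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "transform": self.transform.to_dict(),
            "residual": self.residual,
            "iterations": self.iterations,
            "converged": self.converged,
            "pivot_used": np.asarray(self.pivot_used, float).tolist(),
            "energy_trace": [float(v) for v in self.energy_trace],
        }


class _BinaryMatcher:
    """Per-class KD-trees over the fixed cloud (exact w->infinity matching)."""

    def __init__(self, fixed: AttributedPointCloud, moving_classes: np.ndarray):
        fixed_classes = set(fixed.feature_classes.tolist())
        missing = [int(c) for c in moving_classes if int(c) not in fixed_classes]
        if missing:
            raise MissingClassError(
                f"moving feature classes {missing} are absent from the fixed cloud")
        self.trees = {}
        self.fixed_points = {}
        for cls in moving_classes:
            cls = int(cls)
            sel = fixed.attributes == cls
            pts = fixed.points[sel]
            self.trees[cls] = cKDTree(pts)
            self.fixed_points[cls] = pts

    def query(self, points: np.ndarray, class_slices) -> tuple[np.ndarray, np.ndarray]:
        """Distances and matched fixed coordinates for class-grouped points."""
        d = np.empty(len(points))
        p = np.empty_like(points)
        for cls, sl in class_slices:
            dist, idx = self.trees[cls].query(points[sl], k=1)
            d[sl] = dist
            p[sl] = self.fixed_points[cls][idx]
        return d, p


class _SoftMatcher:
    """Single 4-D KD-tree realizing the GF soft attribute distance."""

    def __init__(self, fixed: AttributedPointCloud, w_gf: float):
        self.scale = np.sqrt(w_gf)
        data = np.column_stack([fixed.points, self.scale * fixed.attributes.astype(float)])
        self.tree = cKDTree(data)
        self.fixed_points = fixed.points

    def query(self, points: np.ndarray, attributes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        q = np.column_stack([points, self.scale * attributes.astype(float)])
        dist, idx = self.tree.query(q, k=1)
        return dist, self.fixed_points[idx]


def _rotation_and_derivatives(angles_deg: np.ndarray):
    """R = Rz(psi) Ry(theta) Rx(phi) and its derivatives w.r.t. each angle in degrees."""
    phi, theta, psi = np.asarray(angles_deg, float) * _DEG
    cx, sx = np.cos(phi), np.sin(phi)
    cy, sy = np.cos(theta), np.sin(theta)
    cz, sz = np.cos(psi), np.sin(psi)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    r = rz @ ry @ rx
    dr = (
        _DEG * (rz @ ry @ _GX @ rx),
        _DEG * (rz @ _GY @ ry @ rx),
        _DEG * (_GZ @ rz @ ry @ rx),
    )
    return r, dr


class _Objective:
    """Registration objective over 6 parameters for a fixed pivot.

    Holds the attributed moving points (grouped by class for the binary
    matcher) and the fixed-cloud search structure; evaluates the energy, its
    log-domain counterpart, and analytic gradients of both.
    """

    def __init__(self, fixed: AttributedPointCloud, moving: AttributedPointCloud,
                 cfg: RegistrationConfig, pivot: np.ndarray):
        if moving.n_attributed == 0:
            raise EmptyFeatureError("moving cloud has no attributed points")
        self.cfg = cfg
        self.pivot = np.asarray(pivot, float)
        sub = moving.attributed_subset()
        order = np.argsort(sub.attributes, kind="stable")
        self.q0 = sub.points[order]
        self.attrs = sub.attributes[order]
        self.n = len(self.q0)

        if cfg.method == "vfa":
            classes = np.unique(self.attrs)
            self.class_slices = []
            for cls in classes:
                sel = np.flatnonzero(self.attrs == cls)
                self.class_slices.append((int(cls), slice(sel[0], sel[-1] + 1)))
            self.matcher = _BinaryMatcher(fixed, classes)
        else:
            shared = np.intersect1d(np.unique(self.attrs), fixed.feature_classes)
            if shared.size == 0:
                raise MissingClassError("fixed and moving clouds share no feature class")
            self.matcher = _SoftMatcher(fixed, cfg.soft_attribute_weight)

        self.q0_centered = self.q0 - self.pivot

    def _pose(self, params6: np.ndarray):
        params6 = np.asarray(params6, float)
        r, dr = _rotation_and_derivatives(params6[:3])
        # q0 @ R.T + (c + t - R c): exact no-op at zero parameters
        q = self.q0 @ r.T + (self.pivot + params6[3:] - r @ self.pivot)
        return q, r, dr

    def _match(self, q: np.ndarray):
        if self.cfg.method == "vfa":
            return self.matcher.query(q, self.class_slices)
        return self.matcher.query(q, self.attrs)

    # -- energy ------------------------------------------------------------
    def energy(self, params6) -> float:
        q, _, _ = self._pose(params6)
        d, _ = self._match(q)
        return float(np.sum(-np.expm1(-(d / self.cfg.sigma) ** 2)))

    def log_objective(self, params6) -> float:
        q, _, _ = self._pose(params6)
        d, _ = self._match(q)
        return float(-logsumexp(-(d / self.cfg.sigma) ** 2))

    # -- gradients ---------------------------------------------------------
    def _weighted_gradient(self, params6, weights_from):
        q, _, dr = self._pose(params6)
        d, p = self._match(q)
        a = -(d / self.cfg.sigma) ** 2
        wgt = weights_from(a) * (2.0 / self.cfg.sigma**2)
        diff = q - p  # spatial residual; attribute term has zero spatial derivative
        wd = wgt[:, None] * diff
        grad = np.empty(6)
        for i in range(3):
            grad[i] = np.sum(wd * (self.q0_centered @ dr[i].T))
        grad[3:] = wd.sum(axis=0)
        return grad

    def energy_gradient(self, params6) -> np.ndarray:
        """Analytic dE_sigma/dparams with the correspondence frozen at the pose."""
        return self._weighted_gradient(params6, np.exp)

    def log_gradient(self, params6) -> np.ndarray:
        """Gradient of the log-domain objective (softmax-weighted, underflow-safe)."""
        def softmax(a):
            e = np.exp(a - a.max())
            return e / e.sum()
        return self._weighted_gradient(params6, softmax)

    def energy_from_log(self, f: float) -> float:
        return float(max(0.0, self.n - np.exp(-f)))


def _build_objective(fixed, moving, cfg, pivot) -> _Objective:
    return _Objective(fixed, moving, cfg, pivot)


def energy_of_params(params6, pivot, fixed: AttributedPointCloud,
                     moving: AttributedPointCloud, cfg: RegistrationConfig | None = None) -> float:
    """E_sigma after transforming the moving cloud by (angles, translation) about ``pivot``."""
    cfg = cfg or RegistrationConfig()
    return _build_objective(fixed, moving, cfg, pivot).energy(params6)


def jacobian_of_params(params6, pivot, fixed: AttributedPointCloud,
                       moving: AttributedPointCloud,
                       cfg: RegistrationConfig | None = None) -> np.ndarray:
    """Analytic 6-vector dE_sigma/d(phi,theta,psi,tx,ty,tz), correspondence frozen."""
    cfg = cfg or RegistrationConfig()
    return _build_objective(fixed, moving, cfg, pivot).energy_gradient(params6)


def _stepout_probe_angles() -> np.ndarray:
    """Euler triples of the 60 icosahedral rotations (identity dropped).

    A deterministic, well-spread sample of the rotation group (covering
    radius ~37 degrees) used as exploratory pivoted rotations when the
    descent has converged: the discrete realization of the optimizer's
    "stepping-out" of local minima.
    """
    import warnings

    from scipy.spatial.transform import Rotation

    rots = Rotation.create_group("I")
    mats = rots.as_matrix()
    keep = np.array([np.trace(m) < 3.0 - 1e-9 for m in mats])
    with warnings.catch_warnings():
        # gimbal-lock triples are fine: any valid decomposition maps identically
        warnings.simplefilter("ignore", UserWarning)
        return rots[keep].as_euler("xyz", degrees=True)


_PROBE_ANGLES: np.ndarray | None = None


def _probe_angles() -> np.ndarray:
    global _PROBE_ANGLES
    if _PROBE_ANGLES is None:
        _PROBE_ANGLES = _stepout_probe_angles()
    return _PROBE_ANGLES


def _select_pivot(fixed, moving, cfg: RegistrationConfig) -> np.ndarray:
    if cfg.method == "gf":
        return np.zeros(3)
    _, _, pos = analyze_force_field(moving, fixed, cfg.energy_params,
                                    k_neighbors=cfg.k_neighbors)
    return pos


def _register(fixed: AttributedPointCloud, moving: AttributedPointCloud,
              cfg: RegistrationConfig,
              initial_transform: RigidTransform | None = None) -> RegistrationResult:
    net = (initial_transform or RigidTransform()).as_origin_pivot()
    current = apply_transform(moving, net) if initial_transform is not None else moving

    trace_e: list[float] = []
    total_iters = 0
    converged = False
    pivot = _select_pivot(fixed, current, cfg)
    first_pivot = pivot.copy()

    # Outer rounds re-center the parameterization at the current pose (x0 = 0)
    # with a fresh Hessian; with refresh_icr_every > 0 the pivot is also
    # recomputed between rounds.  When a round converges without improving,
    # the driver "steps out": it probes large exploratory rotations about the
    # pivot, runs a bounded trial descent from the most promising ones, and
    # commits the excursion only if it ends strictly below the departure
    # energy — so the accepted energy trace stays non-increasing.
    max_rounds = 40
    stepout_rounds = 0

    def commit(x, obj, trace_f):
        nonlocal net, current
        step = RigidTransform(x[:3], x[3:], pivot).as_origin_pivot()
        net = compose_transforms(step, net)
        current = apply_transform(current, step)
        new_e = [obj.energy_from_log(f) for f in trace_f]
        trace_e.extend(new_e if not trace_e else new_e[1:])

    for _ in range(max_rounds):
        chunk = cfg.max_iterations - total_iters
        if chunk <= 0:
            break
        if cfg.refresh_icr_every > 0:
            chunk = min(chunk, cfg.refresh_icr_every)
        obj = _Objective(fixed, current, cfg, pivot)
        res = quasi_newton_minimize(
            obj.log_objective, obj.log_gradient, np.zeros(6),
            max_iterations=chunk,
            gradient_tolerance=cfg.gradient_tolerance,
            function_tolerance=cfg.function_tolerance,
            shrink=cfg.backtracking_shrink,
            armijo_c=cfg.armijo_c,
            max_halvings=cfg.max_halvings,
        )
        commit(res.x, obj, res.trace)
        total_iters += res.n_iterations
        converged = res.converged
        improved = res.trace[-1] < res.trace[0] - cfg.function_tolerance
        if cfg.refresh_icr_every > 0:
            pivot = _select_pivot(fixed, current, cfg)
        if not (converged and not improved):
            continue

        # Descent is done; try stepping out of a possible local minimum.
        # Exploratory poses rotate about the (re-detected) pivot and map the
        # attributed mass center of the moving cloud onto the fixed one —
        # the decoupling of rotation from translation the pivoted
        # parameterization is built around.
        if not cfg.stepout_active or stepout_rounds >= cfg.max_stepout_rounds \
                or total_iters >= cfg.max_iterations:
            break
        stepout_rounds += 1
        if cfg.method == "vfa":
            pivot = _select_pivot(fixed, current, cfg)
        obj = _Objective(fixed, current, cfg, pivot)
        f_cur = obj.log_objective(np.zeros(6))
        c_mov = obj.q0.mean(axis=0)
        c_fix = fixed.attributed_subset().points.mean(axis=0)
        angles = np.vstack([np.zeros(3), _probe_angles()])
        probes = []
        for a in angles:
            r, _ = _rotation_and_derivatives(a)
            t = c_fix - r @ (c_mov - pivot) - pivot
            probes.append(np.concatenate([a, t]))
        probe_f = np.array([obj.log_objective(x) for x in probes])
        best = None
        for j in np.argsort(probe_f, kind="stable")[:cfg.stepout_trials]:
            trial = quasi_newton_minimize(
                obj.log_objective, obj.log_gradient, probes[j],
                max_iterations=cfg.stepout_iterations,
                gradient_tolerance=cfg.gradient_tolerance,
                function_tolerance=cfg.function_tolerance,
                shrink=cfg.backtracking_shrink,
                armijo_c=cfg.armijo_c,
                max_halvings=cfg.max_halvings,
            )
            if best is None or trial.fun < best.fun:
                best = trial
        if best is not None and best.fun < f_cur - cfg.function_tolerance:
            commit(best.x, obj, [f_cur, best.fun])
            total_iters += best.n_iterations
        else:
            break

    # exact final energy (full precision near zero)
    final_obj = _Objective(fixed, current, cfg, np.zeros(3))
    residual = final_obj.energy(np.zeros(6))
    if trace_e:
        trace_e[-1] = min(residual, trace_e[-1])
        residual = trace_e[-1]
    return RegistrationResult(
        transform=net,
        residual=residual,
        iterations=total_iters,
        energy_trace=trace_e,
        converged=converged,
        pivot_used=first_pivot,
        method=cfg.method,
    )


def register_vfa(fixed: AttributedPointCloud, moving: AttributedPointCloud,
                 cfg: RegistrationConfig | None = None,
                 initial_transform: RigidTransform | None = None) -> RegistrationResult:
    """Vector-field-analysis registration: binary matching, rotation about the ICR."""
    cfg = replace(cfg, method="vfa") if cfg is not None else RegistrationConfig(method="vfa")
    return _register(fixed, moving, cfg, initial_transform)


def register_gf(fixed: AttributedPointCloud, moving: AttributedPointCloud,
                cfg: RegistrationConfig | None = None,
                initial_transform: RigidTransform | None = None) -> RegistrationResult:
    """Gaussian-fields baseline: soft attribute distance, rotation about the origin."""
    cfg = replace(cfg, method="gf") if cfg is not None else RegistrationConfig(method="gf")
    return _register(fixed, moving, cfg, initial_transform)


def register(fixed, moving, cfg: RegistrationConfig,
             initial_transform: RigidTransform | None = None) -> RegistrationResult:
    """Dispatch on ``cfg.method``."""
    fn = register_vfa if cfg.method == "vfa" else register_gf
    return fn(fixed, moving, cfg, initial_transform)
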