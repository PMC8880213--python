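"""String method for minimum-energy paths.

A minimum-energy path (MEP) is a curve in configuration space whose
potential-gradient component perpendicular to the curve vanishes
everywhere.  The string method discretizes the curve into images,
evolves each image down the (projected) gradient with forward-Euler
steps, and periodically redistributes the images to equal arc lengths
to prevent clustering.  For two-layer systems the active coordinates
are evolved with the environment frozen, and the environment of each
image is then relaxed with the active coordinates frozen, alternating
until the mean per-image energy change between cycles falls below a
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .constants import DEFAULT_DELTA_V_TOL, DEFAULT_MAX_STEP
from .errors import (
    DegeneratePathError,
    DegenerateTangentError,
    InvalidInputError,
    InvalidTangentError,
    NumericalFailureError,
    OptimizationFailureError,
    ShapeError,
)

__all__ = [
    "StringPath",
    "ConvergenceReport",
    "init_linear_path",
    "unit_tangent",
    "perpendicular_project",
    "evolve_images",
    "reparametrize",
    "relax_environment",
    "optimize_string",
    "densify_path",
    "path_distance_series",
]


@dataclass
class StringPath:
    """Discretized path: ordered images with active and environment coords.

    Attributes
    ----------
    sigmas : ndarray, shape (n,)
        Normalized reaction coordinate, strictly increasing from 0 to 1.
    active : ndarray, shape (n, d)
        Flattened active coordinates per image, Å.
    env : ndarray, shape (n, m)
        Flattened environment coordinates per image, Å (m may be 0).
    energies : ndarray or None
        Per-image energies, kcal/mol, when evaluated.
    endpoint_policy : {"fixed", "free"}
        Whether the first and last images may move during evolution.
    """

    sigmas: np.ndarray
    active: np.ndarray
    env: np.ndarray
    energies: np.ndarray | None = None
    endpoint_policy: str = "fixed"

    def __post_init__(self):
        self.sigmas = np.asarray(self.sigmas, dtype=float)
        self.active = np.atleast_2d(np.asarray(self.active, dtype=float))
        self.env = np.atleast_2d(np.asarray(self.env, dtype=float))
        if self.env.shape[0] != self.active.shape[0]:
            if self.env.size == 0:
                self.env = np.zeros((self.active.shape[0], 0))
            else:
                raise ShapeError("active and env must have one row per image")
        n = self.active.shape[0]
        if self.sigmas.shape != (n,):
            raise ShapeError(f"sigmas has shape {self.sigmas.shape}, expected ({n},)")
        if n < 2:
            raise ShapeError("a path needs at least 2 images")
        if not (np.all(np.diff(self.sigmas) > 0)
                and abs(self.sigmas[0]) < 1e-12 and abs(self.sigmas[-1] - 1) < 1e-12):
            raise ShapeError("sigmas must increase strictly from 0 to 1")
        if self.endpoint_policy not in ("fixed", "free"):
            raise InvalidInputError(f"unknown endpoint policy {self.endpoint_policy!r}")

    @property
    def n_images(self) -> int:
        return self.active.shape[0]

    def copy(self) -> "StringPath":
        return StringPath(self.sigmas.copy(), self.active.copy(), self.env.copy(),
                          None if self.energies is None else self.energies.copy(),
                          self.endpoint_policy)


@dataclass
class ConvergenceReport:
    """Diagnostics of a string optimization run."""

    cycles: int = 0
    delta_v_history: list = field(default_factory=list)
    converged: bool = False
    perp_grad_norm: float = np.nan
    relaxation_warnings: list = field(default_factory=list)


def init_linear_path(active_A, active_B, env_A=None, env_B=None,
                     n_images: int = 16) -> StringPath:
    """Linear Cartesian interpolation between two end states.

    The default image count of 16 matches the protocol's coarse path
    stage; sigma_k = k/(n-1).
    """
    active_A = np.asarray(active_A, dtype=float).ravel()
    active_B = np.asarray(active_B, dtype=float).ravel()
    if active_A.shape != active_B.shape:
        raise ShapeError(
            f"endpoint shapes differ: {active_A.shape} vs {active_B.shape}"
        )
    if n_images < 3:
        raise InvalidInputError(f"n_images must be >= 3, got {n_images}")
    env_A = np.zeros(0) if env_A is None else np.asarray(env_A, dtype=float).ravel()
    env_B = env_A if env_B is None else np.asarray(env_B, dtype=float).ravel()
    if env_A.shape != env_B.shape:
        raise ShapeError(f"env endpoint shapes differ: {env_A.shape} vs {env_B.shape}")
    w = np.linspace(0.0, 1.0, n_images)
    active = (1.0 - w)[:, None] * active_A[None, :] + w[:, None] * active_B[None, :]
    env = (1.0 - w)[:, None] * env_A[None, :] + w[:, None] * env_B[None, :]
    # endpoints bit-identical to the inputs
    active[0], active[-1] = active_A, active_B
    env[0], env[-1] = env_A, env_B
    return StringPath(w, active, env)


def unit_tangent(path: StringPath, index: int) -> np.ndarray:
    """Normalized discrete tangent to the string at one image.

    Central difference of the active coordinates for interior images,
    one-sided differences at the endpoints.
    """
    n = path.n_images
    if not 0 <= index < n:
        raise IndexError(f"image index {index} out of range for {n} images")
    z = path.active
    if index == 0:
        d = z[1] - z[0]
    elif index == n - 1:
        d = z[-1] - z[-2]
    else:
        d = z[index + 1] - z[index - 1]
    norm = np.linalg.norm(d)
    if norm < 1e-14:
        raise DegenerateTangentError(
            f"neighboring images around index {index} coincide"
        )
    return d / norm


def perpendicular_project(v, tau) -> np.ndarray:
    """Apply the projector P = I - tau tau^T onto the plane normal to tau."""
    v = np.asarray(v, dtype=float)
    tau = np.asarray(tau, dtype=float)
    norm = np.linalg.norm(tau)
    if abs(norm - 1.0) > 1e-8:
        raise InvalidTangentError(f"tangent is not normalized: |tau| = {norm}")
    return v - tau * (tau @ v)


def evolve_images(path: StringPath, model, dt: float, n_steps: int = 1,
                  project: bool = True, max_step: float | None = DEFAULT_MAX_STEP
                  ) -> StringPath:
    """Forward-Euler evolution of the images down the gradient.

    Each free image is updated ``z <- z - g dt`` where ``g`` is the
    active gradient, by default projected perpendicular to the local
    tangent (the projected form is what defines an MEP; the unprojected
    Euler update is available with ``project=False``).  Displacements
    are capped at ``max_step`` per update (default 1 Bohr in Å), the
    protocol's update step size, which keeps early far-from-path images
    stable.  Environment coordinates are untouched.
    """
    if dt <= 0:
        raise InvalidInputError(f"dt must be positive, got {dt}")
    out = path.copy()
    free = (range(1, out.n_images - 1) if out.endpoint_policy == "fixed"
            else range(out.n_images))
    for _ in range(n_steps):
        new_active = out.active.copy()
        for k in free:
            g = np.asarray(model.active_gradient(out.active[k], out.env[k]),
                           dtype=float)
            if not np.all(np.isfinite(g)):
                raise NumericalFailureError(f"non-finite gradient at image {k}")
            if project:
                g = perpendicular_project(g, unit_tangent(out, k))
            step = g * dt
            if max_step is not None:
                norm = np.linalg.norm(step)
                if norm > max_step:
                    step *= max_step / norm
            new_active[k] = out.active[k] - step
        out.active = new_active
    out.energies = None
    return out


def _arc_lengths(active: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(active, axis=0), axis=1)
    return np.concatenate(([0.0], np.cumsum(seg)))


def locate_on_polyline(point, polyline) -> float:
    """Arc-length parameter of the closest point on a polyline.

    Utility for verifying reparametrization: projects ``point`` onto
    each segment and returns the cumulative arc length of the nearest
    projection.
    """
    pts = np.atleast_2d(polyline)
    s = _arc_lengths(pts)
    best_d, best_t = np.inf, 0.0
    p = np.asarray(point, dtype=float)
    for k in range(pts.shape[0] - 1):
        a, b = pts[k], pts[k + 1]
        v = b - a
        vv = float(v @ v)
        u = 0.0 if vv == 0 else np.clip(float((p - a) @ v) / vv, 0.0, 1.0)
        proj = a + u * v
        d = float(np.linalg.norm(p - proj))
        if d < best_d:
            best_d, best_t = d, s[k] + u * (s[k + 1] - s[k])
    return best_t


def _resample(path: StringPath, n_out: int) -> StringPath:
    """Resample to n_out images at equal arc spacing along the polyline.

    Arc length is measured along the existing piecewise-linear curve;
    the new images sit exactly at fractions k/(n_out-1) of the total
    length, which is the classic string-method redistribution.
    """
    s = _arc_lengths(path.active)
    total = s[-1]
    if total <= 0:
        raise DegeneratePathError("path has zero total arc length")

    def place(tvals, coords):
        out = np.empty((n_out, coords.shape[1]))
        for j in range(coords.shape[1]):
            out[:, j] = np.interp(tvals, s, coords[:, j])
        return out

    t = np.linspace(0.0, total, n_out)
    active = place(t, path.active)
    env = place(t, path.env) if path.env.shape[1] else np.zeros((n_out, 0))
    # endpoints bit-identical
    active[0], active[-1] = path.active[0], path.active[-1]
    if path.env.shape[1]:
        env[0], env[-1] = path.env[0], path.env[-1]
    return StringPath(np.linspace(0.0, 1.0, n_out), active, env,
                      endpoint_policy=path.endpoint_policy)


def reparametrize(path: StringPath) -> StringPath:
    """Redistribute images to equal arc lengths along the polyline.

    Arc length is measured in plain Cartesian coordinates of the active
    region only; environment coordinates ride along by the same
    piecewise-linear interpolation.  Endpoints are unchanged and sigma
    is reset to a uniform grid.
    """
    if path.n_images < 3:
        raise ShapeError("reparametrization needs at least 3 images")
    return _resample(path, path.n_images)


def densify_path(path: StringPath, n_out: int) -> StringPath:
    """Resample the path to ``n_out`` equal-arc-length images.

    The protocol refines a converged coarse string (16 images) to a
    denser one (45 images) before the free-energy stage; endpoints are
    preserved bit-identically.
    """
    if n_out < 2:
        raise InvalidInputError(f"n_out must be >= 2, got {n_out}")
    if n_out < path.n_images:
        raise InvalidInputError(
            f"n_out = {n_out} is smaller than the current {path.n_images} images"
        )
    return _resample(path, n_out)


def relax_environment(path: StringPath, model, tol: float = 1e-6,
                      max_iter: int = 200):
    """Locally minimize each image's environment at frozen active coords.

    Returns the relaxed path and the list of per-image final gradient
    norms.  Images whose minimization hits ``max_iter`` are recorded as
    warnings, not errors.
    """
    out = path.copy()
    norms, warnings = [], []
    if out.env.shape[1] == 0:
        return out, [], []
    for k in range(out.n_images):
        r = out.active[k]  # frozen: never passed to the optimizer as variables

        def f(R, r=r):
            return model.environment_energy(r, R)

        def g(R, r=r):
            return model.env_gradient(r, R)

        res = optimize.minimize(f, out.env[k], jac=g, method="L-BFGS-B",
                                options={"maxiter": max_iter, "gtol": tol})
        out.env[k] = res.x
        gnorm = float(np.max(np.abs(g(res.x))))
        norms.append(gnorm)
        if not res.success and gnorm > tol:
            warnings.append(f"image {k}: {res.message} (|g|_max = {gnorm:.3e})")
    out.energies = None
    return out, norms, warnings


def _path_energies(path: StringPath, model) -> np.ndarray:
    return np.array([model.active_energy(path.active[k], path.env[k])
                     for k in range(path.n_images)])


def max_perpendicular_gradient(path: StringPath, model) -> float:
    """Max over interior images of |P grad V|, the discrete MEP residual."""
    worst = 0.0
    for k in range(1, path.n_images - 1):
        g = model.active_gradient(path.active[k], path.env[k])
        p = perpendicular_project(g, unit_tangent(path, k))
        worst = max(worst, float(np.linalg.norm(p)))
    return worst


def optimize_string(path: StringPath, model, dt: float,
                    evolve_steps_per_cycle: int = 1,
                    max_cycles: int = 500,
                    delta_v_tol: float = DEFAULT_DELTA_V_TOL,
                    project: bool = True,
                    max_step: float | None = DEFAULT_MAX_STEP,
                    relax_tol: float = 1e-6,
                    relax_max_iter: int = 200,
                    log=None):
    """Iterate [evolve -> reparametrize -> relax environment] to an MEP.

    Convergence is declared when the mean over images of the absolute
    per-image energy change between consecutive cycles drops below
    ``delta_v_tol`` (default: 1e-10 Hartree expressed in kcal/mol).  The
    report carries the full per-cycle history.
    """
    if delta_v_tol <= 0:
        raise InvalidInputError(f"delta_v_tol must be positive, got {delta_v_tol}")
    current = path.copy()
    report = ConvergenceReport()
    prev_energies = _path_energies(current, model)
    has_env = current.env.shape[1] > 0 and model.has_environment
    for cycle in range(1, max_cycles + 1):
        try:
            trial = evolve_images(current, model, dt, evolve_steps_per_cycle,
                                  project=project, max_step=max_step)
            trial = reparametrize(trial)
            if has_env:
                trial, _, warns = relax_environment(trial, model, tol=relax_tol,
                                                    max_iter=relax_max_iter)
                report.relaxation_warnings.extend(warns)
            energies = _path_energies(trial, model)
        except NumericalFailureError as exc:
            raise OptimizationFailureError(
                f"cycle {cycle}: {exc}", last_path=current) from exc
        if not np.all(np.isfinite(energies)):
            raise OptimizationFailureError(
                f"cycle {cycle}: non-finite path energy", last_path=current)
        delta_v = float(np.mean(np.abs(energies - prev_energies)))
        report.delta_v_history.append(delta_v)
        report.cycles = cycle
        if log is not None:
            log(cycle, delta_v)
        current = trial
        current.energies = energies
        prev_energies = energies
        if delta_v < delta_v_tol:
            report.converged = True
            break
    report.perp_grad_norm = max_perpendicular_gradient(current, model)
    return current, report


def path_distance_series(path: StringPath, pair_list):
    """Interatomic distances of active-atom pairs along the path.

    Parameters
    ----------
    pair_list : sequence of (int, int)
        Active-atom index pairs (atom indices within the active region).

    Returns
    -------
    pandas.DataFrame
        One row per image, columns ``sigma`` and ``d<i>_<j>`` (Å),
        ordered by sigma.
    """
    import pandas as pd

    xyz = path.active.reshape(path.n_images, -1, 3)
    n_atoms = xyz.shape[1]
    data = {"sigma": path.sigmas}
    for i, j in pair_list:
        if not (0 <= i < n_atoms and 0 <= j < n_atoms):
            raise IndexError(
                f"pair ({i}, {j}) out of range for {n_atoms} active atoms"
            )
        data[f"d{i}_{j}"] = np.linalg.norm(xyz[:, i] - xyz[:, j], axis=1)
    return pd.DataFrame(data)
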