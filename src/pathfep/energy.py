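"""Energy backends for the two-layer hybrid model.

This module defines the pluggable :class:`EnergyModel` contract and the
concrete backends used throughout the package:

* :class:`MuellerBrown` — the standard four-Gaussian analytic benchmark
  surface with analytic gradient and Hessian, used to validate the
  string minimum-energy-path optimizer against independently located
  stationary points.
* pairwise Lennard-Jones / Coulomb terms and their double sums over an
  active region and a charged environment (no cutoff, no periodicity);
* :class:`TwoLayerModel` — an active surface combined with
  active–environment interaction terms and an internal environment
  energy (tethers plus environment–environment nonbonded pairs).

Units are kcal/mol, Å, e throughout.
"""

from __future__ import annotations

from abc import ABC, abstractmethod

import numpy as np
from scipy import optimize

from .constants import CONSTANTS
from .errors import (
    InvalidDistanceError,
    InvalidGeometryError,
    InvalidInputError,
    ShapeError,
)
from .system import HybridSystem

__all__ = [
    "EnergyModel",
    "MuellerBrown",
    "MuellerBrownModel",
    "HarmonicCouplingModel",
    "lj_pair_energy",
    "coulomb_pair_energy",
    "combine_lj",
    "interaction_energy",
    "interaction_gradients",
    "newton_stationary_point",
]

_MIN_SEPARATION = 1e-8  # Å; below this two atoms are treated as coincident


class EnergyModel(ABC):
    """Contract for energy backends.

    A backend evaluates the active-region energy as a function of the
    active coordinates ``r`` (flattened, Å) and the environment
    coordinates ``R`` (flattened, Å), together with the corresponding
    analytic gradients.  Backends with environment degrees of freedom
    additionally expose ``environment_energy``/``env_gradient`` for
    environment relaxation and canonical sampling.  ``charge_model`` is
    an optional callable mapping active coordinates to per-active-atom
    point charges (the classical stand-in for a wavefunction-derived
    charge distribution).
    """

    #: optional callable r -> per-active-atom charges (e)
    charge_model = None

    @abstractmethod
    def active_energy(self, r: np.ndarray, R: np.ndarray) -> float:
        """Active-region energy (kcal/mol)."""

    @abstractmethod
    def active_gradient(self, r: np.ndarray, R: np.ndarray) -> np.ndarray:
        """Gradient of :meth:`active_energy` w.r.t. ``r`` (kcal/mol/Å)."""

    def environment_energy(self, r: np.ndarray, R: np.ndarray) -> float:
        """Total environment-dependent energy at fixed active coords."""
        raise NotImplementedError(
            f"{type(self).__name__} has no environment degrees of freedom"
        )

    def env_gradient(self, r: np.ndarray, R: np.ndarray) -> np.ndarray:
        """Gradient of :meth:`environment_energy` w.r.t. ``R``."""
        raise NotImplementedError(
            f"{type(self).__name__} has no environment degrees of freedom"
        )

    @property
    def has_environment(self) -> bool:
        return type(self).environment_energy is not EnergyModel.environment_energy


# ---------------------------------------------------------------------------
# Müller-Brown benchmark surface
# ---------------------------------------------------------------------------

class MuellerBrown:
    """Four-Gaussian analytic benchmark surface on the plane.

    V(x, y) = sum_i A_i exp(a_i (x-x_i)^2 + b_i (x-x_i)(y-y_i)
                            + c_i (y-y_i)^2)

    with the standard parameter table.  The surface has three minima and
    two first-order saddle points and is the conventional test case for
    reaction-path algorithms.  Energy, gradient and Hessian are analytic.
    """

    A = np.array([-200.0, -100.0, -170.0, 15.0])
    a = np.array([-1.0, -1.0, -6.5, 0.7])
    b = np.array([0.0, 0.0, 11.0, 0.6])
    c = np.array([-10.0, -10.0, -6.5, 0.7])
    x0 = np.array([1.0, 0.0, -0.5, -1.0])
    y0 = np.array([0.0, 0.5, 1.5, 1.0])

    def _terms(self, point):
        point = np.asarray(point, dtype=float)
        if point.shape != (2,):
            raise ShapeError(f"expected a 2-vector, got shape {point.shape}")
        if not np.all(np.isfinite(point)):
            raise InvalidInputError(f"non-finite input point {point}")
        dx = point[0] - self.x0
        dy = point[1] - self.y0
        expo = self.a * dx**2 + self.b * dx * dy + self.c * dy**2
        return dx, dy, self.A * np.exp(expo)

    def energy(self, point) -> float:
        _, _, t = self._terms(point)
        return float(t.sum())

    def gradient(self, point) -> np.ndarray:
        dx, dy, t = self._terms(point)
        gx = np.sum(t * (2.0 * self.a * dx + self.b * dy))
        gy = np.sum(t * (self.b * dx + 2.0 * self.c * dy))
        return np.array([gx, gy])

    def hessian(self, point) -> np.ndarray:
        dx, dy, t = self._terms(point)
        fx = 2.0 * self.a * dx + self.b * dy
        fy = self.b * dx + 2.0 * self.c * dy
        hxx = np.sum(t * (fx**2 + 2.0 * self.a))
        hyy = np.sum(t * (fy**2 + 2.0 * self.c))
        hxy = np.sum(t * (fx * fy + self.b))
        return np.array([[hxx, hxy], [hxy, hyy]])


def mueller_brown_energy(point) -> float:
    """Evaluate the Müller-Brown surface at a 2-D point."""
    return MuellerBrown().energy(point)


class MuellerBrownModel(EnergyModel):
    """Müller-Brown surface wrapped as an :class:`EnergyModel`.

    The active region is the 2-D point; there is no environment, so the
    environment coordinate vector is empty and ignored.
    """

    def __init__(self):
        self.surface = MuellerBrown()

    def active_energy(self, r, R=None):
        return self.surface.energy(r)

    def active_gradient(self, r, R=None):
        return self.surface.gradient(r)


def newton_stationary_point(gradient, hessian, x0, tol: float = 1e-12) -> np.ndarray:
    """Locate a stationary point of a surface by Newton iteration on grad = 0.

    Converges to minima and saddles alike from a nearby guess; the
    character of the point is read off the Hessian afterwards.  Used as
    the independent oracle against which path-based saddle estimates are
    compared.
    """
    def gnorm(p):
        try:
            g = np.asarray(gradient(p), dtype=float)
        except Exception:
            return None, np.inf
        if not np.all(np.isfinite(g)):
            return None, np.inf
        return g, float(np.linalg.norm(g))

    # Levenberg-Marquardt on the gradient field first: damped steps keep
    # the iterate inside the basin of the guess even where the Hessian
    # is indefinite or near-singular.
    sol = optimize.root(gradient, np.asarray(x0, dtype=float), jac=hessian,
                        method="lm")
    x = np.asarray(sol.x, dtype=float)
    g, res = gnorm(x)
    for _ in range(500):
        if res < tol:
            return x
        step = np.linalg.solve(hessian(x), g)
        # backtrack on |grad| so steps never leave the basin of the guess
        t = 1.0
        while t > 1e-6:
            g_new, res_new = gnorm(x - t * step)
            if res_new < res:
                x, g, res = x - t * step, g_new, res_new
                break
            t *= 0.5
        else:
            break
    raise RuntimeError(
        f"Newton search stalled from {np.asarray(x0)}; final |grad| = {res:.3e}"
    )


# ---------------------------------------------------------------------------
# Pairwise nonbonded terms
# ---------------------------------------------------------------------------

def lj_pair_energy(r: float, epsilon: float, sigma: float) -> float:
    """Lennard-Jones 12-6 pair energy 4 eps [(sigma/r)^12 - (sigma/r)^6]."""
    if not np.isfinite(r) or r <= 0:
        raise InvalidDistanceError(f"pair distance must be positive, got {r}")
    sr6 = (sigma / r) ** 6
    return float(4.0 * epsilon * (sr6 * sr6 - sr6))


def coulomb_pair_energy(r: float, Q: float, q: float) -> float:
    """Coulomb pair energy k Q q / r (kcal/mol with charges in e, r in Å)."""
    if not np.isfinite(r) or r <= 0:
        raise InvalidDistanceError(f"pair distance must be positive, got {r}")
    return float(CONSTANTS.coulomb_k * (Q * q) / r)


def combine_lj(epsilon_a: float, sigma_a: float,
               epsilon_b: float, sigma_b: float) -> tuple:
    """Lorentz-Berthelot combining rules for cross LJ parameters."""
    if epsilon_a < 0 or epsilon_b < 0:
        raise InvalidInputError("epsilon must be non-negative")
    if sigma_a <= 0 or sigma_b <= 0:
        raise InvalidInputError("sigma must be positive")
    return float(np.sqrt(epsilon_a * epsilon_b)), 0.5 * (sigma_a + sigma_b)


def _pair_geometry(active_coords, env_coords):
    ra = np.asarray(active_coords, dtype=float).reshape(-1, 3)
    Rb = np.asarray(env_coords, dtype=float).reshape(-1, 3)
    diff = ra[:, None, :] - Rb[None, :, :]        # (n, m, 3)
    dist = np.sqrt(np.sum(diff * diff, axis=2))   # (n, m)
    if dist.size and dist.min() < _MIN_SEPARATION:
        alpha, beta = np.unravel_index(np.argmin(dist), dist.shape)
        raise InvalidGeometryError(
            f"active atom {alpha} and environment atom {beta} coincide "
            f"(separation {dist[alpha, beta]:.3e} Å)"
        )
    return diff, dist


def _cross_lj_params(system: HybridSystem):
    eps = np.sqrt(np.outer(system.active_lj_epsilon, system.env_lj_epsilon))
    sig = 0.5 * (system.active_lj_sigma[:, None] + system.env_lj_sigma[None, :])
    return eps, sig


def interaction_energy(active_coords, active_charges, system: HybridSystem,
                       env_coords=None):
    """Active–environment interaction energy.

    Full double sum over active atoms alpha and environment atoms beta of
    Lennard-Jones (Lorentz-Berthelot cross parameters) plus Coulomb terms
    with the supplied active charges and the system's fixed environment
    charges.  No cutoff, no periodic images.

    Returns
    -------
    (E_vdW, E_es, E_int) : tuple of float
        van der Waals, electrostatic and total interaction energy,
        kcal/mol, with ``E_int = E_vdW + E_es``.
    """
    if env_coords is None:
        env_coords = system.env_positions
    Q = np.asarray(active_charges, dtype=float)
    if Q.size != system.n_active:
        raise ShapeError(
            f"{Q.size} active charges for {system.n_active} active atoms"
        )
    diff, dist = _pair_geometry(active_coords, env_coords)
    if dist.shape != (system.n_active, system.n_env):
        raise ShapeError(
            f"coordinate arrays imply {dist.shape} pairs, expected "
            f"({system.n_active}, {system.n_env})"
        )
    eps, sig = _cross_lj_params(system)
    sr6 = (sig / dist) ** 6
    e_vdw = float(np.sum(4.0 * eps * (sr6 * sr6 - sr6)))
    e_es = float(CONSTANTS.coulomb_k *
                 np.sum(np.outer(Q, system.env_charges) / dist))
    return e_vdw, e_es, e_vdw + e_es


def interaction_gradients(active_coords, active_charges, system: HybridSystem,
                          env_coords=None):
    """Analytic gradients of the interaction energy.

    Returns
    -------
    (g_active, g_env) : tuple of ndarray
        Flattened gradients w.r.t. active and environment coordinates,
        kcal/mol/Å.
    """
    if env_coords is None:
        env_coords = system.env_positions
    Q = np.asarray(active_charges, dtype=float)
    diff, dist = _pair_geometry(active_coords, env_coords)
    eps, sig = _cross_lj_params(system)
    sr6 = (sig / dist) ** 6
    # dU/dd for LJ and Coulomb, then dU/dr_alpha = (dU/dd) * diff/d
    dU_dd = (4.0 * eps * (-12.0 * sr6 * sr6 + 6.0 * sr6) / dist
             - CONSTANTS.coulomb_k * np.outer(Q, system.env_charges) / dist**2)
    coef = dU_dd / dist                              # (n, m)
    g_active = np.sum(coef[:, :, None] * diff, axis=1).ravel()
    g_env = -np.sum(coef[:, :, None] * diff, axis=0).ravel()
    return g_active, g_env


def esp_sums(active_coords, system: HybridSystem, env_coords=None) -> np.ndarray:
    """Per-active-atom sums S_alpha = k sum_beta q_beta / d_alpha_beta.

    The electrostatic interaction is ``sum_alpha Q_alpha S_alpha``; the
    sums are the sensitivities of E_es to the active charges, needed for
    chain-rule gradients through a geometry-dependent charge model.
    """
    if env_coords is None:
        env_coords = system.env_positions
    _, dist = _pair_geometry(active_coords, env_coords)
    return CONSTANTS.coulomb_k * np.sum(system.env_charges[None, :] / dist, axis=1)


# ---------------------------------------------------------------------------
# Two-layer hybrid combiner
# ---------------------------------------------------------------------------

class TwoLayerModel(EnergyModel):
    """Active surface plus active–environment and environment terms.

    The active-region energy is the bare surface energy plus the
    LJ/Coulomb interaction with the environment, with active charges
    supplied by ``charge_model`` (zero charges if absent).  The
    environment energy adds harmonic tethers anchoring each environment
    atom to a reference site (the stand-in for the covalent scaffold a
    protein matrix would provide) and environment–environment nonbonded
    pairs.

    Parameters
    ----------
    system : HybridSystem
        Particle partition, environment charges and LJ parameters.
    active_surface : object
        Provides ``energy(r)`` and ``gradient(r)`` on flattened active
        coordinates.
    charge_model : object, optional
        Provides ``charges(r)`` and optionally ``jacobian(r)`` (shape
        ``(n_active, 3 n_active)``); the jacobian is finite-differenced
        when absent.
    tether_k : float
        Tether force constant, kcal/mol/Å^2.
    tether_sites : ndarray, optional
        Flattened anchor coordinates; defaults to the system's
        environment positions.
    env_pairs : bool
        Include environment–environment LJ/Coulomb pairs.
    """

    def __init__(self, system: HybridSystem, active_surface, charge_model=None,
                 tether_k: float = 2.0, tether_sites=None, env_pairs: bool = True):
        self.system = system
        self.surface = active_surface
        self.charge_model = charge_model
        self.tether_k = float(tether_k)
        self.tether_sites = (np.array(system.env_positions, dtype=float)
                             if tether_sites is None
                             else np.asarray(tether_sites, dtype=float).copy())
        self.env_pairs = env_pairs
        m = system.n_env
        self._iu = np.triu_indices(m, k=1) if m > 1 else None

    # -- charges ----------------------------------------------------------

    def charges(self, r) -> np.ndarray:
        if self.charge_model is None:
            return np.zeros(self.system.n_active)
        return self.charge_model.charges(r)

    def _charge_jacobian(self, r) -> np.ndarray:
        cm = self.charge_model
        if hasattr(cm, "jacobian"):
            return cm.jacobian(r)
        r = np.asarray(r, dtype=float)
        h = 1e-6
        J = np.empty((self.system.n_active, r.size))
        for j in range(r.size):
            rp, rm = r.copy(), r.copy()
            rp[j] += h
            rm[j] -= h
            J[:, j] = (cm.charges(rp) - cm.charges(rm)) / (2.0 * h)
        return J

    # -- active layer ------------------------------------------------------

    def active_energy(self, r, R) -> float:
        _, _, e_int = interaction_energy(r, self.charges(r), self.system, R)
        return self.surface.energy(r) + e_int

    def active_gradient(self, r, R) -> np.ndarray:
        Q = self.charges(r)
        g = self.surface.gradient(r).astype(float).copy()
        g_int, _ = interaction_gradients(r, Q, self.system, R)
        g += g_int
        if self.charge_model is not None:
            # chain rule through geometry-dependent charges:
            # dE_es/dr += sum_alpha S_alpha dQ_alpha/dr
            S = esp_sums(r, self.system, R)
            g += S @ self._charge_jacobian(r)
        return g

    # -- environment layer -------------------------------------------------

    def _env_internal(self, R, want_gradient=False):
        R = np.asarray(R, dtype=float)
        disp = R - self.tether_sites
        e = 0.5 * self.tether_k * float(disp @ disp)
        g = self.tether_k * disp if want_gradient else None
        if self.env_pairs and self._iu is not None:
            xyz = R.reshape(-1, 3)
            i, j = self._iu
            d_vec = xyz[i] - xyz[j]
            d = np.sqrt(np.sum(d_vec * d_vec, axis=1))
            if d.size and d.min() < _MIN_SEPARATION:
                k = int(np.argmin(d))
                raise InvalidGeometryError(
                    f"environment atoms {i[k]} and {j[k]} coincide"
                )
            eps = np.sqrt(self.system.env_lj_epsilon[i] * self.system.env_lj_epsilon[j])
            sig = 0.5 * (self.system.env_lj_sigma[i] + self.system.env_lj_sigma[j])
            qq = self.system.env_charges[i] * self.system.env_charges[j]
            sr6 = (sig / d) ** 6
            e += float(np.sum(4.0 * eps * (sr6 * sr6 - sr6)))
            e += float(CONSTANTS.coulomb_k * np.sum(qq / d))
            if want_gradient:
                dU_dd = (4.0 * eps * (-12.0 * sr6 * sr6 + 6.0 * sr6) / d
                         - CONSTANTS.coulomb_k * qq / d**2)
                f = (dU_dd / d)[:, None] * d_vec
                gp = np.zeros_like(xyz)
                np.add.at(gp, i, f)
                np.add.at(gp, j, -f)
                g = g + gp.ravel()
        return e, g

    def environment_energy(self, r, R) -> float:
        _, _, e_int = interaction_energy(r, self.charges(r), self.system, R)
        e_env, _ = self._env_internal(R)
        return e_int + e_env

    def env_gradient(self, r, R) -> np.ndarray:
        _, g_env = interaction_gradients(r, self.charges(r), self.system, R)
        _, g_int = self._env_internal(R, want_gradient=True)
        return g_env + g_int


# ---------------------------------------------------------------------------
# Analytic FEP benchmark backend
# ---------------------------------------------------------------------------

class HarmonicCouplingModel(EnergyModel):
    """Harmonic environment with a linear active coupling.

    One 3-D environment particle bound by ``(k/2)|R|^2``, with the active
    "coordinate" r interpreted as a scalar coupling c that adds ``c R_x``.
    The free energy is Gaussian-exact: F(c) = -c^2/(2k) + const, so the
    free-energy difference for switching c_A -> c_B is
    ``(c_A^2 - c_B^2)/(2k)`` — a closed form against which the sampled
    Zwanzig estimate is validated.
    """

    def __init__(self, k: float = 1.0):
        if k <= 0:
            raise InvalidInputError("force constant must be positive")
        self.k = float(k)

    def active_energy(self, r, R) -> float:
        return 0.0

    def active_gradient(self, r, R) -> np.ndarray:
        return np.zeros(np.asarray(r).size)

    def environment_energy(self, r, R) -> float:
        R = np.asarray(R, dtype=float)
        c = float(np.asarray(r, dtype=float).ravel()[0])
        return 0.5 * self.k * float(R @ R) + c * R[0]

    def env_gradient(self, r, R) -> np.ndarray:
        R = np.asarray(R, dtype=float)
        c = float(np.asarray(r, dtype=float).ravel()[0])
        g = self.k * R.copy()
        g[0] += c
        return g

    def exact_delta_f(self, c_a: float, c_b: float) -> float:
        """Closed-form free-energy difference for c_A -> c_B."""
        return (c_a**2 - c_b**2) / (2.0 * self.k)
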