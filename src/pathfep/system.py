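"""Two-layer hybrid system container.

A :class:`HybridSystem` partitions a particle system into an *active*
region (treated by an explicit energy surface, the analogue of a QM
subsystem) and an *environment* (point charges with Lennard-Jones
parameters, the analogue of an MM subsystem).  The two layers are not
covalently connected; they interact only through van der Waals and
electrostatic terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ShapeError


@dataclass
class HybridSystem:
    """Particle system split into active and environment layers.

    Parameters
    ----------
    positions : ndarray, shape (3N,)
        Flattened Cartesian coordinates of all N atoms, Å.
    active_indices : ndarray of int
        Ordered atom indices of the active region.
    environment_indices : ndarray of int
        Ordered atom indices of the environment; disjoint from
        ``active_indices`` and jointly covering all atoms.
    env_charges : ndarray, shape (n_env,)
        Fixed point charges q_beta of environment atoms, e.
    lj_epsilon : ndarray, shape (N,)
        Per-atom Lennard-Jones well depths, kcal/mol (>= 0).
    lj_sigma : ndarray, shape (N,)
        Per-atom Lennard-Jones diameters, Å (> 0).
    labels : list of str
        Per-atom names (element symbols or force-field types).
    """

    positions: np.ndarray
    active_indices: np.ndarray
    environment_indices: np.ndarray
    env_charges: np.ndarray
    lj_epsilon: np.ndarray
    lj_sigma: np.ndarray
    labels: list = field(default_factory=list)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.active_indices = np.asarray(self.active_indices, dtype=int)
        self.environment_indices = np.asarray(self.environment_indices, dtype=int)
        self.env_charges = np.asarray(self.env_charges, dtype=float)
        self.lj_epsilon = np.asarray(self.lj_epsilon, dtype=float)
        self.lj_sigma = np.asarray(self.lj_sigma, dtype=float)
        n = self.n_atoms
        if self.positions.size != 3 * n:
            raise ShapeError(
                f"positions has {self.positions.size} entries, expected {3 * n}"
            )
        overlap = np.intersect1d(self.active_indices, self.environment_indices)
        if overlap.size:
            raise ShapeError(f"active/environment overlap at indices {overlap}")
        union = np.union1d(self.active_indices, self.environment_indices)
        if union.size != n or not np.array_equal(union, np.arange(n)):
            raise ShapeError("active and environment indices must cover all atoms")
        if self.env_charges.size != self.environment_indices.size:
            raise ShapeError("env_charges length must match environment_indices")
        if self.lj_epsilon.size != n or self.lj_sigma.size != n:
            raise ShapeError("lj_epsilon and lj_sigma must be per-atom arrays")
        if np.any(self.lj_epsilon < 0):
            raise ValueError("lj_epsilon must be non-negative")
        if np.any(self.lj_sigma <= 0):
            raise ValueError("lj_sigma must be positive")
        if not self.labels:
            self.labels = [f"X{i}" for i in range(n)]

    @property
    def n_atoms(self) -> int:
        return self.active_indices.size + self.environment_indices.size

    @property
    def n_active(self) -> int:
        return self.active_indices.size

    @property
    def n_env(self) -> int:
        return self.environment_indices.size

    @property
    def active_positions(self) -> np.ndarray:
        """Flattened coordinates of the active atoms, Å."""
        return self.positions.reshape(-1, 3)[self.active_indices].ravel()

    @property
    def env_positions(self) -> np.ndarray:
        """Flattened coordinates of the environment atoms, Å."""
        return self.positions.reshape(-1, 3)[self.environment_indices].ravel()

    @property
    def active_lj_epsilon(self) -> np.ndarray:
        return self.lj_epsilon[self.active_indices]

    @property
    def active_lj_sigma(self) -> np.ndarray:
        return self.lj_sigma[self.active_indices]

    @property
    def env_lj_epsilon(self) -> np.ndarray:
        return self.lj_epsilon[self.environment_indices]

    @property
    def env_lj_sigma(self) -> np.ndarray:
        return self.lj_sigma[self.environment_indices]
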