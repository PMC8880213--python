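"""Point-charge fitting to an electrostatic potential grid.

Active-region point charges are obtained by least-squares fitting the
Coulomb potential of the candidate charges to reference potentials on a
grid of points surrounding the atoms, subject to a single equality
constraint fixing the total charge (solved exactly via a Lagrange
multiplier).  This is the generic form of ESP fitting; no restraints
toward zero charge and no scheme-specific grid weighting are applied.

Group analysis sums fitted charges over disjoint atom groups along a
path, the observable used to follow charge redistribution during a
reaction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import CONSTANTS
from .errors import (
    GroupingError,
    IllConditionedFitError,
    InvalidGeometryError,
    ShapeError,
)

__all__ = [
    "ESPGrid",
    "ChargeSet",
    "AtomGroup",
    "esp_potential",
    "fit_charges",
    "group_sums",
    "build_shell_grid",
]

_MAX_CONDITION = 1e6


@dataclass
class ESPGrid:
    """Electrostatic-potential samples: points (Å) and potentials
    (kcal mol^-1 e^-1)."""

    points: np.ndarray      # (n_grid, 3)
    potentials: np.ndarray  # (n_grid,)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.potentials = np.asarray(self.potentials, dtype=float).ravel()
        if self.points.shape[0] != self.potentials.size:
            raise ShapeError("points and potentials must have equal length")


@dataclass
class ChargeSet:
    """Per-active-atom fitted charges with their exact total."""

    charges: np.ndarray
    total_charge: float
    state_sigma: float = np.nan

    def __post_init__(self):
        self.charges = np.asarray(self.charges, dtype=float).ravel()


def _distances(positions, grid_points):
    pos = np.asarray(positions, dtype=float).reshape(-1, 3)
    pts = np.asarray(grid_points, dtype=float).reshape(-1, 3)
    d = np.linalg.norm(pts[:, None, :] - pos[None, :, :], axis=2)  # (g, n)
    if d.size and d.min() < 1e-8:
        g, a = np.unravel_index(np.argmin(d), d.shape)
        raise InvalidGeometryError(f"grid point {g} coincides with atom {a}")
    return d


def esp_potential(charges, positions, grid_points) -> np.ndarray:
    """Coulomb potential of point charges at grid points.

    phi(g) = k sum_alpha Q_alpha / |g - r_alpha|, in kcal mol^-1 e^-1.
    ``charges`` may be a ChargeSet or a plain array.
    """
    q = charges.charges if isinstance(charges, ChargeSet) else np.asarray(charges)
    d = _distances(positions, grid_points)
    if d.shape[1] != q.size:
        raise ShapeError(f"{q.size} charges for {d.shape[1]} atom positions")
    return CONSTANTS.coulomb_k * (1.0 / d) @ q


def fit_charges(grid: ESPGrid, positions, total_charge: float,
                state_sigma: float = np.nan) -> ChargeSet:
    """Total-charge-constrained linear least-squares ESP fit.

    Minimizes ``sum_g (phi_model(g) - phi_grid(g))^2`` subject to
    ``sum Q = total_charge``, solving the KKT system directly.  The fit
    is deterministic; a rank-deficient or badly conditioned design
    matrix raises :class:`IllConditionedFitError` with the condition
    number.
    """
    pos = np.asarray(positions, dtype=float).reshape(-1, 3)
    n = pos.shape[0]
    if grid.points.shape[0] < n + 1:
        raise IllConditionedFitError(
            f"{grid.points.shape[0]} grid points cannot determine {n} charges "
            "plus the constraint"
        )
    A = CONSTANTS.coulomb_k / _distances(pos, grid.points)  # (g, n)
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > _MAX_CONDITION:
        raise IllConditionedFitError(
            f"ESP design matrix is ill-conditioned (cond = {cond:.3e})",
            condition_number=cond,
        )
    # KKT system of the equality-constrained normal equations
    H = np.empty((n + 1, n + 1))
    H[:n, :n] = 2.0 * A.T @ A
    H[:n, n] = 1.0
    H[n, :n] = 1.0
    H[n, n] = 0.0
    rhs = np.empty(n + 1)
    rhs[:n] = 2.0 * A.T @ grid.potentials
    rhs[n] = total_charge
    sol = np.linalg.solve(H, rhs)
    q = sol[:n]
    # enforce the constraint to machine precision despite solver round-off
    q = q + (total_charge - q.sum()) / n
    return ChargeSet(charges=q, total_charge=float(total_charge),
                     state_sigma=state_sigma)


def fit_residual(grid: ESPGrid, positions, charge_set: ChargeSet) -> float:
    """Sum of squared potential residuals of a fit on its grid."""
    model = esp_potential(charge_set, positions, grid.points)
    r = model - grid.potentials
    return float(r @ r)


@dataclass
class AtomGroup:
    """Named set of active-atom indices."""

    name: str
    indices: tuple

    def __post_init__(self):
        self.indices = tuple(int(i) for i in self.indices)


def group_sums(charge_sets, groups, sigmas=None) -> pd.DataFrame:
    """Arithmetic per-group charge sums along a path.

    ``groups`` must be disjoint and jointly cover every active atom.
    Returns one row per path state with columns ``sigma``, one per
    group, and ``total`` (the conservation check: the sum of all group
    columns, which equals each state's constrained total charge).
    """
    charge_sets = list(charge_sets)
    if not charge_sets:
        raise ShapeError("no charge sets given")
    n_atoms = charge_sets[0].charges.size
    seen = [i for g in groups for i in g.indices]
    if len(seen) != len(set(seen)):
        raise GroupingError("groups overlap")
    if set(seen) != set(range(n_atoms)):
        raise GroupingError(
            f"groups cover atoms {sorted(set(seen))}, expected 0..{n_atoms - 1}"
        )
    if sigmas is None:
        sigmas = [cs.state_sigma for cs in charge_sets]
    rows = []
    for s, cs in zip(sigmas, charge_sets):
        if cs.charges.size != n_atoms:
            raise ShapeError("charge sets differ in length")
        row = {"sigma": float(s)}
        for g in groups:
            row[g.name] = float(sum(cs.charges[i] for i in sorted(g.indices)))
        row["total"] = float(sum(row[g.name] for g in groups))
        rows.append(row)
    return pd.DataFrame(rows)


def build_shell_grid(positions, radii=None, scales=(1.4, 2.0),
                     n_per_shell: int = 64) -> np.ndarray:
    """Conventional two-shell ESP grid around a set of atoms.

    Deterministic Fibonacci-sphere points on concentric shells at
    ``scales`` times each atom's nominal radius (default 1.7 Å), culled
    when they fall inside any atom's inner shell.
    """
    pos = np.asarray(positions, dtype=float).reshape(-1, 3)
    n = pos.shape[0]
    radii = np.full(n, 1.7) if radii is None else np.asarray(radii, dtype=float)
    # deterministic unit sphere covering
    i = np.arange(n_per_shell)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - 2.0 * (i + 0.5) / n_per_shell
    theta = 2.0 * np.pi * i / golden
    rho = np.sqrt(1.0 - z * z)
    unit = np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])
    points = []
    for a in range(n):
        for s in scales:
            points.append(pos[a] + radii[a] * s * unit)
    pts = np.concatenate(points, axis=0)
    inner = min(scales) * radii
    d = np.linalg.norm(pts[:, None, :] - pos[None, :, :], axis=2)
    keep = np.all(d >= inner[None, :] - 1e-9, axis=1)
    return pts[keep]
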