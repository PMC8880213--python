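"""Free-energy perturbation along a reaction path.

The free-energy difference between adjoining path states A and B of a
two-layer system splits into

    dF(A->B) = dE_qm(A->B) + dF_int(A->B)

where dE_qm is the difference of ensemble-averaged active-region
energies and dF_int is the Zwanzig exponential average

    dF_int = -(1/beta) ln < exp(-beta dE_int) >_A

of the interaction-energy perturbation dE_int sampled over the A-state
environment ensemble.  The perturbation moves the active atoms (and
their fitted point charges) from state A to state B while every
environment atom stays at its A-state snapshot position.

Per-step results accumulate into a cumulative profile F(sigma) anchored
at F(0) = 0, decomposed into the active-energy curve and the cumulative
interaction contribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .constants import beta as _beta
from .energy import interaction_energy
from .errors import GridMismatchError, InsufficientSamplesError, InvalidInputError
from .sampler import Ensemble

__all__ = [
    "FEPStep",
    "FreeEnergyProfile",
    "delta_E_int",
    "zwanzig_free_energy",
    "delta_E_qm",
    "step_free_energy",
    "assemble_profile",
    "profile_summary",
    "hysteresis_check",
]


@dataclass
class FEPStep:
    """One perturbation step between adjoining path states."""

    from_index: int
    to_index: int
    delta_E_qm: float
    delta_F_int: float
    n_samples: int
    std_err: float

    @property
    def delta_F(self) -> float:
        """Total step free energy; by construction dE_qm + dF_int exactly."""
        return self.delta_E_qm + self.delta_F_int


@dataclass
class FreeEnergyProfile:
    """Cumulative free energy along the path, F(0) = 0."""

    sigma: np.ndarray
    F: np.ndarray
    E_qm_curve: np.ndarray
    F_int_curve: np.ndarray
    stderr: np.ndarray

    def __post_init__(self):
        lengths = {len(self.sigma), len(self.F), len(self.E_qm_curve),
                   len(self.F_int_curve), len(self.stderr)}
        if len(lengths) != 1:
            raise GridMismatchError("profile curves must share one grid")


def delta_E_int(state_A, state_B, env_snapshot, system) -> float:
    """Interaction-energy perturbation for one A-state snapshot.

    ``state_A``/``state_B`` are ``(active_coords, charges)`` pairs.  The
    environment is fixed at the A-state snapshot for both evaluations;
    only the active geometry and its charges switch.
    """
    (r_a, q_a), (r_b, q_b) = state_A, state_B
    _, _, e_b = interaction_energy(r_b, q_b, system, env_snapshot)
    _, _, e_a = interaction_energy(r_a, q_a, system, env_snapshot)
    return e_b - e_a


def zwanzig_free_energy(delta_E_samples, temperature: float,
                        n_bootstrap: int = 200, bootstrap_seed: int = 0):
    """Exponential-average free-energy estimate with bootstrap error.

    Computes ``-(1/beta) ln mean(exp(-beta dE))`` through log-sum-exp,
    so arbitrarily large |dE| values cannot overflow.  The standard
    error is a seeded nonparametric bootstrap over the samples (0 for a
    single sample).
    """
    x = np.asarray(delta_E_samples, dtype=float).ravel()
    if x.size == 0:
        raise InsufficientSamplesError("no perturbation samples given")
    b = _beta(temperature)

    def estimate(values):
        return -(logsumexp(-b * values) - np.log(values.size)) / b

    est = float(estimate(x))
    if x.size == 1 or n_bootstrap == 0:
        return est, 0.0
    rng = np.random.default_rng(bootstrap_seed)
    idx = rng.integers(0, x.size, size=(n_bootstrap, x.size))
    reps = np.array([estimate(x[i]) for i in idx])
    return est, float(reps.std(ddof=1))


def delta_E_qm(state_A, state_B, ensemble_A: Ensemble, ensemble_B: Ensemble,
               model) -> float:
    """Difference of ensemble-averaged active energies between two states.

    ``<E_act(r_B, R)>_B - <E_act(r_A, R)>_A``, each average over that
    state's own environment snapshots.
    """
    r_a = state_A[0] if isinstance(state_A, tuple) else state_A
    r_b = state_B[0] if isinstance(state_B, tuple) else state_B
    mean_b = np.mean([model.active_energy(r_b, R) for R in ensemble_B.snapshots])
    mean_a = np.mean([model.active_energy(r_a, R) for R in ensemble_A.snapshots])
    return float(mean_b - mean_a)


def step_free_energy(state_A, state_B, ensemble_A: Ensemble,
                     ensemble_B: Ensemble, system, model, temperature: float,
                     from_index: int = 0, to_index: int = 1,
                     n_bootstrap: int = 200, bootstrap_seed: int = 0) -> FEPStep:
    """Full perturbation step: averaged active-energy difference plus the
    Zwanzig estimate over the A-ensemble interaction perturbations."""
    de_qm = delta_E_qm(state_A, state_B, ensemble_A, ensemble_B, model)
    samples = np.array([delta_E_int(state_A, state_B, R, system)
                        for R in ensemble_A.snapshots])
    df_int, se = zwanzig_free_energy(samples, temperature,
                                     n_bootstrap=n_bootstrap,
                                     bootstrap_seed=bootstrap_seed)
    return FEPStep(from_index=from_index, to_index=to_index,
                   delta_E_qm=de_qm, delta_F_int=df_int,
                   n_samples=samples.size, std_err=se)


def assemble_profile(steps, sigma_grid) -> FreeEnergyProfile:
    """Accumulate contiguous steps into a cumulative profile.

    The grid has one more point than there are steps; F, the averaged
    active-energy curve and the cumulative interaction curve all start
    at 0, and F equals their sum pointwise by construction.  Step
    standard errors propagate in quadrature.
    """
    steps = list(steps)
    sigma = np.asarray(sigma_grid, dtype=float)
    if len(steps) + 1 != sigma.size:
        raise GridMismatchError(
            f"{len(steps)} steps need a grid of {len(steps) + 1} points, "
            f"got {sigma.size}"
        )
    for prev, nxt in zip(steps, steps[1:]):
        if prev.to_index != nxt.from_index:
            raise InvalidInputError(
                f"steps are not contiguous: {prev.to_index} != {nxt.from_index}"
            )
    de_qm = np.concatenate(([0.0], np.cumsum([s.delta_E_qm for s in steps])))
    df_int = np.concatenate(([0.0], np.cumsum([s.delta_F_int for s in steps])))
    var = np.concatenate(([0.0], np.cumsum([s.std_err**2 for s in steps])))
    return FreeEnergyProfile(sigma=sigma, F=de_qm + df_int,
                             E_qm_curve=de_qm, F_int_curve=df_int,
                             stderr=np.sqrt(var))


def profile_summary(profile: FreeEnergyProfile) -> dict:
    """Activation and total free energy of a profile.

    Returns a dict with ``activation`` (max F minus F at sigma 0),
    ``total`` (F at sigma 1 minus F at sigma 0) and ``sigma_at_max``.
    """
    if profile.F.size == 0:
        raise InvalidInputError("empty profile")
    k = int(np.argmax(profile.F))
    return {
        "activation": float(profile.F[k] - profile.F[0]),
        "total": float(profile.F[-1] - profile.F[0]),
        "sigma_at_max": float(profile.sigma[k]),
    }


def hysteresis_check(forward: FreeEnergyProfile,
                     backward: FreeEnergyProfile) -> float:
    """Forward/backward consistency diagnostic.

    The backward profile, computed along the reversed path, is mapped
    back onto the forward frame; the return value is the maximum
    absolute discrepancy max |F_fwd(s) - (F_bwd_total - F_bwd(1-s))|.
    Zero for exact per-step free energies; sampling noise makes it a
    convergence indicator.
    """
    if forward.sigma.size != backward.sigma.size or not np.allclose(
            forward.sigma, 1.0 - backward.sigma[::-1], atol=1e-12):
        raise GridMismatchError("backward grid does not mirror the forward grid")
    # state i seen from the reverse direction: F_bwd[n-1-i] - F_bwd_total
    mapped = backward.F[::-1] - backward.F[-1]
    return float(np.max(np.abs(forward.F - mapped)))
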