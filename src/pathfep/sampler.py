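"""Canonical sampling of the environment with the active region frozen.

Free-energy perturbation needs canonical ensembles of environment
configurations at each path state, with the active atoms held fixed.
The original protocol obtains them from restrained molecular dynamics;
here the same sampling contract is fulfilled by Metropolis Monte Carlo
over the environment coordinates — all that the exponential-averaging
estimator requires is Boltzmann-distributed snapshots at the target
temperature.

Moves are single-particle uniform displacements in a cube of side
``2 * step_size``; the step size is auto-tuned during burn-in toward a
40% acceptance rate.  A given seed yields a bit-identical ensemble.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import DEFAULT_TEMPERATURE, beta as _beta
from .errors import InsufficientSamplesError, InvalidInputError, SamplingFailureError

__all__ = ["SamplerConfig", "Ensemble", "sample_environment", "subsample",
           "autocorrelation_time"]


@dataclass
class SamplerConfig:
    """Parameters of a Metropolis run.

    Attributes
    ----------
    temperature : float
        Target temperature, K (default 358 K, the thermophile optimum
        the protocol samples at).
    n_sweeps : int
        Total sweeps (one attempted move per environment particle each).
    step_size : float
        Initial half-width of the uniform displacement cube, Å.
    seed : int
        Seed of the named generator; recorded in the ensemble.
    restraint_k : float or None
        Optional harmonic restraint (kcal/mol/Å^2) tying particles to
        their starting coordinates during burn-in only, mirroring a
        heating-stage restraint; off by default.
    burn_in : int
        Sweeps discarded before snapshots are collected.
    thin : int
        Keep every ``thin``-th post-burn-in sweep.
    """

    temperature: float = DEFAULT_TEMPERATURE
    n_sweeps: int = 1000
    step_size: float = 0.3
    seed: int = 0
    restraint_k: float | None = None
    burn_in: int = 100
    thin: int = 1

    def __post_init__(self):
        if self.temperature <= 0:
            raise InvalidInputError("temperature must be positive")
        if not self.n_sweeps > self.burn_in >= 0:
            raise InvalidInputError("need n_sweeps > burn_in >= 0")
        if self.thin < 1:
            raise InvalidInputError("thin must be >= 1")
        if self.step_size <= 0:
            raise InvalidInputError("step_size must be positive")


@dataclass
class Ensemble:
    """Fixed-active-geometry set of environment snapshots."""

    active_coords_ref: np.ndarray
    snapshots: np.ndarray            # (n_snapshots, 3 * n_env)
    temperature: float
    seed: int
    acceptance_rate: float
    step_size: float = np.nan        # final (tuned) step size, Å

    @property
    def n_snapshots(self) -> int:
        return self.snapshots.shape[0]


def sample_environment(system, model, active_coords, config: SamplerConfig,
                       env_start=None) -> Ensemble:
    """Metropolis chain over environment coordinates at fixed active coords.

    Parameters
    ----------
    system : HybridSystem or None
        Used only for its particle count when ``env_start`` is absent;
        the energy always comes from ``model.environment_energy``.
    model : EnergyModel
        Must implement ``environment_energy(r, R)``.
    active_coords : ndarray
        Frozen active coordinates, bit-identical in every evaluation.
    config : SamplerConfig
    env_start : ndarray, optional
        Starting environment coordinates; defaults to the system's.

    Returns
    -------
    Ensemble
        Thinned post-burn-in snapshots with the recorded seed,
        acceptance rate and tuned step size.
    """
    r = np.array(active_coords, dtype=float)
    if env_start is None:
        env_start = system.env_positions
    R = np.array(env_start, dtype=float)
    n_env = R.size // 3
    if n_env == 0:
        raise InvalidInputError("no environment particles to sample")
    rng = np.random.default_rng(config.seed)
    b = _beta(config.temperature)
    step = config.step_size
    anchor = R.copy()

    def total(Rv, in_burn):
        e = model.environment_energy(r, Rv)
        if in_burn and config.restraint_k is not None:
            d = Rv - anchor
            e += 0.5 * config.restraint_k * float(d @ d)
        return e

    energy = total(R, True)
    if not np.isfinite(energy):
        raise SamplingFailureError("non-finite energy at the starting configuration")

    snapshots = []
    accepted = attempted = 0
    tune_acc = tune_att = 0
    for sweep in range(config.n_sweeps):
        in_burn = sweep < config.burn_in
        for p in range(n_env):
            delta = rng.uniform(-step, step, size=3)
            R_new = R.copy()
            R_new[3 * p:3 * p + 3] += delta
            e_new = total(R_new, in_burn)
            if not np.isfinite(e_new):
                raise SamplingFailureError(
                    f"non-finite energy at sweep {sweep}, particle {p}"
                )
            if e_new <= energy or rng.random() < np.exp(-b * (e_new - energy)):
                R, energy = R_new, e_new
                if in_burn:
                    tune_acc += 1
                else:
                    accepted += 1
            if in_burn:
                tune_att += 1
            else:
                attempted += 1
        if in_burn:
            # robbins-monro-ish tuning toward 40% acceptance
            if tune_att >= 20 * n_env:
                rate = tune_acc / tune_att
                step *= np.clip(rate / 0.40, 0.5, 2.0)
                tune_acc = tune_att = 0
            if sweep == config.burn_in - 1 and config.restraint_k is not None:
                energy = total(R, False)  # restraint released after burn-in
        elif (sweep - config.burn_in) % config.thin == 0:
            snapshots.append(R.copy())

    rate = accepted / attempted if attempted else 0.0
    if not 0.01 < rate < 0.99:
        _warnings.warn(
            f"acceptance rate {rate:.3f} outside (0.01, 0.99); consider "
            f"{'decreasing' if rate < 0.5 else 'increasing'} step_size "
            f"(final tuned value {step:.3g} Å)",
            stacklevel=2,
        )
    return Ensemble(active_coords_ref=r, snapshots=np.array(snapshots),
                    temperature=config.temperature, seed=config.seed,
                    acceptance_rate=rate, step_size=step)


def subsample(ensemble: Ensemble, n: int = 300, seed: int = 0) -> Ensemble:
    """Uniform without-replacement selection of ``n`` snapshots.

    Chain order is preserved.  The default of 300 matches the number of
    samples per path state the protocol carries into the free-energy
    estimator.
    """
    avail = ensemble.n_snapshots
    if n > avail:
        raise InsufficientSamplesError(f"requested {n} of {avail} snapshots")
    if n == avail:
        return ensemble
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(avail, size=n, replace=False))
    return Ensemble(active_coords_ref=ensemble.active_coords_ref,
                    snapshots=ensemble.snapshots[idx],
                    temperature=ensemble.temperature,
                    seed=ensemble.seed,
                    acceptance_rate=ensemble.acceptance_rate,
                    step_size=ensemble.step_size)


def autocorrelation_time(series: np.ndarray, max_lag: int | None = None) -> float:
    """Integrated autocorrelation time of a scalar chain observable.

    Diagnostic only — reported so users can judge snapshot independence
    and choose a thinning stride; it does not gate any computation.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 2:
        return np.nan
    x = x - x.mean()
    var = float(x @ x) / n
    if var == 0:
        return 1.0
    if max_lag is None:
        max_lag = n // 2
    tau = 1.0
    for lag in range(1, max_lag):
        c = float(x[:-lag] @ x[lag:]) / ((n - lag) * var)
        if c < 0.05:  # standard truncation at first negligible lag
            break
        tau += 2.0 * c
    return tau
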