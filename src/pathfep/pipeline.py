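"""End-to-end protocol on the transfer toy.

The full analysis chain, mirroring the reaction-path free-energy
protocol at desk scale:

1. build the toy hybrid system and its end-state minima;
2. optimize a coarse string (default 16 images) between the end states
   on the two-layer energy, alternating image evolution with
   environment relaxation;
3. densify the converged path (default 45 points) and relax each
   point's environment;
4. fit point charges at every path state against the toy charge model's
   electrostatic potential on a two-shell grid (generate-and-recover:
   the toy model plays the role an electronic-structure engine would);
5. draw a canonical environment ensemble at each path state (default
   358 K, 300 retained snapshots) with the active atoms frozen;
6. run forward free-energy perturbation between consecutive states and
   assemble the cumulative profile;
7. report activation/total free energies, bond-distance series and
   group-charge series.

Every stochastic stage derives its seed deterministically from the one
pipeline seed, so identical configurations reproduce byte-identical
output files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .charges import ESPGrid, build_shell_grid, esp_potential, fit_charges, group_sums
from .constants import DEFAULT_DELTA_V_TOL, DEFAULT_TEMPERATURE
from .fep import assemble_profile, profile_summary, step_free_energy
from .mep import (
    StringPath,
    densify_path,
    init_linear_path,
    optimize_string,
    path_distance_series,
    relax_environment,
)
from .sampler import Ensemble, SamplerConfig, sample_environment, subsample
from .toys import ToyTransferSpec, ToyTransferSystem, make_toy_transfer

__all__ = ["PipelineConfig", "PipelineResult", "run_toy_pipeline",
           "write_artifacts", "point_seed"]


class _BareActiveModel:
    """Active surface exposed as an R-independent energy backend.

    Used as the E_qm term of the perturbation: the active-environment
    interaction enters the free energy only through the Zwanzig term,
    so it is deliberately absent here (the two-layer model that includes
    it drives only the path optimization).
    """

    def __init__(self, surface):
        self.surface = surface

    def active_energy(self, r, R=None):
        return self.surface.energy(r)

    def active_gradient(self, r, R=None):
        return self.surface.gradient(r)


@dataclass
class PipelineConfig:
    """Knobs of the toy pipeline; defaults are the protocol constants."""

    seed: int = 0
    # toy construction
    n_env: int = 10
    barrier_height: float = 15.0
    env_charge_magnitude: float = 0.5
    # string stage
    n_images: int = 16
    densify_to: int = 45
    dt: float = 2e-3
    evolve_steps_per_cycle: int = 20
    max_cycles: int = 300
    delta_v_tol: float = 1e-6
    # sampling stage
    temperature: float = DEFAULT_TEMPERATURE
    n_sweeps: int = 760
    burn_in: int = 100
    thin: int = 2
    n_samples: int = 300
    mc_step: float = 0.25
    # fep stage
    bootstrap_n: int = 200

    def __post_init__(self):
        if self.delta_v_tol <= 0:
            raise ValueError("delta_v_tol must be positive")
        if self.n_images < 3:
            raise ValueError("n_images must be >= 3")
        if self.densify_to < self.n_images:
            raise ValueError("densify_to must be >= n_images")


@dataclass
class PipelineResult:
    toy: ToyTransferSystem
    coarse_path: StringPath
    report: object
    path: StringPath
    charge_sets: list
    ensembles: list
    steps: list
    profile: object
    summary: dict
    distances: pd.DataFrame
    groups: pd.DataFrame
    config: PipelineConfig = field(default=None)


def _relax_endpoint(model, r0, R0, rounds: int = 4, gtol: float = 1e-8):
    """Alternate active/environment minimization on the two-layer energy."""
    from scipy import optimize

    r, R = np.array(r0, dtype=float), np.array(R0, dtype=float)
    for _ in range(rounds):
        res = optimize.minimize(lambda x: model.active_energy(x, R), r,
                                jac=lambda x: model.active_gradient(x, R),
                                method="BFGS", options={"gtol": gtol})
        r = res.x
        res = optimize.minimize(lambda x: model.environment_energy(r, x), R,
                                jac=lambda x: model.env_gradient(r, x),
                                method="L-BFGS-B", options={"gtol": gtol})
        R = res.x
    return r, R


def point_seed(base_seed: int, index: int, stream: int = 0) -> int:
    """Deterministic per-point seed below 2^31."""
    return (base_seed * 100003 + 7919 * index + 104729 * stream + 1) % (2**31)


def run_toy_pipeline(config: PipelineConfig = None, log=None) -> PipelineResult:
    """Run the full protocol on the transfer toy; see the module docstring."""
    cfg = config or PipelineConfig()
    toy = make_toy_transfer(ToyTransferSpec(
        n_env=cfg.n_env, barrier_height=cfg.barrier_height,
        env_charge_magnitude=cfg.env_charge_magnitude, seed=cfg.seed))
    model = toy.model

    # --- end-state stage --------------------------------------------------
    # re-optimize both end states on the full two-layer energy (the bare
    # surface minima shift slightly once the environment interacts), so
    # the fixed string endpoints are genuine minima of the sampled model
    env0 = toy.system.env_positions
    r_a, env_a = _relax_endpoint(model, toy.active_A, env0)
    r_b, env_b = _relax_endpoint(model, toy.active_B, env0)

    # --- string stage ---------------------------------------------------
    path0 = init_linear_path(r_a, r_b, env_a, env_b, n_images=cfg.n_images)
    coarse, report = optimize_string(
        path0, model, dt=cfg.dt,
        evolve_steps_per_cycle=cfg.evolve_steps_per_cycle,
        max_cycles=cfg.max_cycles, delta_v_tol=cfg.delta_v_tol,
        log=log)
    path = densify_path(coarse, cfg.densify_to)
    path, _, _ = relax_environment(path, model, tol=1e-5)

    # --- charge-fit stage -------------------------------------------------
    charge_sets = []
    for k in range(path.n_images):
        r = path.active[k]
        true_q = toy.charge_model.charges(r)
        grid_pts = build_shell_grid(r)
        grid = ESPGrid(points=grid_pts,
                       potentials=esp_potential(true_q, r, grid_pts))
        charge_sets.append(fit_charges(grid, r, total_charge=0.0,
                                       state_sigma=path.sigmas[k]))

    # --- sampling stage ---------------------------------------------------
    ensembles = []
    for k in range(path.n_images):
        scfg = SamplerConfig(temperature=cfg.temperature,
                             n_sweeps=cfg.n_sweeps, burn_in=cfg.burn_in,
                             thin=cfg.thin, step_size=cfg.mc_step,
                             seed=point_seed(cfg.seed, k))
        ens = sample_environment(toy.system, model, path.active[k], scfg,
                                 env_start=path.env[k])
        ensembles.append(subsample(ens, cfg.n_samples,
                                   seed=point_seed(cfg.seed, k, stream=1)))

    # --- fep stage --------------------------------------------------------
    bare = _BareActiveModel(toy.surface)
    steps = []
    for k in range(path.n_images - 1):
        state_a = (path.active[k], charge_sets[k].charges)
        state_b = (path.active[k + 1], charge_sets[k + 1].charges)
        steps.append(step_free_energy(
            state_a, state_b, ensembles[k], ensembles[k + 1],
            toy.system, bare, cfg.temperature,
            from_index=k, to_index=k + 1,
            n_bootstrap=cfg.bootstrap_n,
            bootstrap_seed=point_seed(cfg.seed, k, stream=2)))
    profile = assemble_profile(steps, path.sigmas)
    summary = profile_summary(profile)

    distances = path_distance_series(path, [(0, 1), (1, 2)]).rename(
        columns={"d0_1": "breaking", "d1_2": "forming"})
    groups = group_sums(charge_sets, toy.groups)
    return PipelineResult(toy=toy, coarse_path=coarse, report=report,
                          path=path, charge_sets=charge_sets,
                          ensembles=ensembles, steps=steps, profile=profile,
                          summary=summary, distances=distances, groups=groups,
                          config=cfg)


def write_artifacts(result: PipelineResult, outdir) -> dict:
    """Write the pipeline's text artifacts; returns the path map."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    labels = result.toy.system.labels
    paths = {
        "coarse_path": out / "path_coarse.xyz",
        "path": out / "path.xyz",
        "profile": out / "profile.csv",
        "summary": out / "summary.json",
        "distances": out / "distances.csv",
        "groups": out / "group_charges.csv",
        "convergence": out / "convergence.csv",
        "meta": out / "meta.json",
    }
    pio.write_path_xyz(paths["coarse_path"], result.coarse_path, labels)
    pio.write_path_xyz(paths["path"], result.path, labels)
    pio.write_profile_csv(result.profile, paths["profile"])
    with open(paths["summary"], "w") as fh:
        json.dump(result.summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    result.distances.to_csv(paths["distances"], index=False,
                            float_format="%.17g")
    result.groups.to_csv(paths["groups"], index=False, float_format="%.17g")
    pd.DataFrame({
        "cycle": np.arange(1, len(result.report.delta_v_history) + 1),
        "mean_abs_delta_v": result.report.delta_v_history,
    }).to_csv(paths["convergence"], index=False, float_format="%.17g")
    with open(paths["meta"], "w") as fh:
        json.dump({"config": asdict(result.config),
                   "converged": bool(result.report.converged),
                   "cycles": int(result.report.cycles),
                   "perp_grad_norm": float(result.report.perp_grad_norm),
                   "acceptance_rates": [float(e.acceptance_rate)
                                        for e in result.ensembles],
                   "sampler_seeds": [point_seed(result.config.seed, k)
                                     for k in range(result.path.n_images)]},
                  fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
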