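# pathfep

String-method reaction paths and free-energy perturbation on two-layer
(active/environment) hybrid systems.

## What this is for

Enzyme-catalyzed group-transfer reactions — the motivating case is the
phosphoryl transfer from ATP to glycine in an ATP-grasp enzyme — are
commonly modeled with a two-layer hybrid: a small *active* region whose
bonds rearrange, embedded in a large *environment* of fixed-topology
point charges with Lennard-Jones parameters. `pathfep` implements the
reaction-path free-energy protocol for such systems as a reusable,
tested library plus CLI:

1. **Minimum-energy path (MEP)** by the string method: a chain of
   images z(σ), σ ∈ [0, 1], is evolved down the gradient component
   perpendicular to the path, P∇V with P = I − ττᵀ, and redistributed
   to equal arc lengths each cycle. For hybrid systems the active
   coordinates evolve with the environment frozen and each image's
   environment is then relaxed with the active atoms frozen,
   alternating to convergence of the mean per-image energy change
   |ΔV̄| (default threshold 10⁻¹⁰ Hartree in kcal/mol). The converged
   16-image string is densified to 45 points for analysis.
2. **Free-energy perturbation (FEP)** between adjoining path states A
   and B: ΔF = ΔE_qm + ΔF_int, where ΔE_qm is the difference of
   ensemble-averaged active-region energies and ΔF_int is the Zwanzig
   exponential average −β⁻¹ ln⟨exp(−β ΔE_int)⟩_A of the
   interaction-energy perturbation, sampled over a canonical ensemble
   of environment configurations drawn by Metropolis Monte Carlo at
   fixed active geometry (default 358 K, 300 snapshots per state).
3. **ESP charge analysis**: active-region point charges are fitted to
   an electrostatic potential grid under an exact total-charge
   constraint, and summed over atom groups along the path to follow
   charge redistribution during the reaction.

Everything runs on desk-scale inputs: the analytic Müller-Brown
benchmark surface validates the path optimizer against independently
located stationary points, and a synthetic donor–transfer–acceptor toy
system (4 active particles on a two-state mixing surface, a charged
Lennard-Jones environment shell) exercises the full pipeline with known
qualitative structure. User systems can be supplied as PDB coordinates
plus a plain-text per-atom parameter table; paths are serialized as
multi-frame XYZ.

## Worked example

Run the full protocol on the transfer toy (16-image string → densify to
45 → 300 environment snapshots per point at 358 K → FEP profile →
group charges):

```sh
pathfep pipeline --seed 1 -o out/
```

which logs the per-cycle |ΔV̄| during path optimization and finishes
with

```
activation = 7.616 kcal/mol, total = -3.679 kcal/mol; artifacts in out/
```

meaning the sampled free-energy profile F(σ) climbs 7.6 kcal/mol to its
single barrier (at σ ≈ 0.55) and ends 3.7 kcal/mol below the reactant
state — the transfer is exergonic, as built into the toy's asymmetric
wells. `out/` contains:

* `path.xyz` — the 45-point MEP (σ and energy on each comment line);
* `profile.csv` — columns `sigma,E_qm_rel,F_int_cum,F,stderr`, with
  `F = E_qm_rel + F_int_cum` exactly per row;
* `summary.json` — activation, total, σ at the barrier;
* `distances.csv` — forming (P–acceptor) and breaking (donor–P)
  distances along σ: the forming contact shortens then plateaus while
  the breaking contact plateaus then lengthens, the classic
  approach-then-transfer signature;
* `group_charges.csv` — per-σ group charge sums; the `total` column is
  0 at every state (charge conservation under the constrained fit);
* `convergence.csv`, `meta.json` — optimization history, seeds,
  acceptance rates.

Rerunning with the same seed reproduces every artifact byte for byte.

The same stages are available separately (`pathfep toy`, `mep`,
`interp`, `sample`, `fep`, `charges`) and as library calls; see
`docs/methods.md` for the model details and numerical choices.

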