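# Methods

## Model

A system is a set of point particles partitioned into an **active
region** (the atoms whose bonding changes; the analogue of a QM
subsystem) and an **environment** (fixed point charges q_β with
Lennard-Jones parameters; the analogue of an MM subsystem). The layers
are not covalently connected. The total energy is

    E(r, R) = E_act(r) + E_int(r, R) + E_env(R)

with r the active and R the environment coordinates (Å). E_act is
supplied by a pluggable backend (`EnergyModel`); E_int is the exact
double sum over active–environment pairs of 12-6 Lennard-Jones terms
(Lorentz–Berthelot cross parameters) and Coulomb terms k·Q_α q_β / r_αβ
with k = 332.0637 kcal·Å·mol⁻¹·e⁻², where the active charges Q_α may
depend on the active geometry through a charge model (the classical
stand-in for a wavefunction-derived charge distribution; its geometry
dependence is propagated into the active gradient by the chain rule).
No nonbonded cutoff and no periodicity: desk-scale systems are small
enough for exact sums, which also keeps brute-force test oracles exact.
Internal units are kcal/mol, Å, e and K throughout; Hartree/Bohr inputs
are converted at the configuration boundary (627.5095 kcal/mol per
Hartree, 0.529177 Å per Bohr).

One deliberate ambiguity is resolved rather than hidden: whether the
"active energy" already contains the active–environment electrostatics
depends on the embedding convention. The backend contract exposes both
pieces separately. The pipeline uses the *bare* active surface as the
E_qm term of the free-energy decomposition, so the interaction enters
the profile only through ΔF_int; the two-layer model (active +
interaction) drives only the geometry optimization. This avoids double
counting at the cost of treating the active-energy curve as unpolarized
by the environment — acceptable for the classical surrogate surfaces
used here.

## String method

A path is a sequence of images, each holding active coordinates, an
environment configuration, and σ ∈ [0, 1]. Optimization cycles through:

1. **Evolve**: forward-Euler steps z ← z − g·Δt on each interior image,
   where g is by default the gradient projected perpendicular to the
   discrete tangent (P = I − ττᵀ; the perpendicular condition P∇V = 0
   is what defines an MEP). The unprojected update is available via a
   flag, since the plain-gradient Euler form appears in the literature;
   with per-cycle reparametrization both converge to the same curve,
   the projected form with less tangential churn. Tangents are central
   differences of neighboring images (one-sided at the ends) — the
   simplest scheme in the string-method literature. Per-update
   displacements are capped (default 1 Bohr in Å) so far-from-path
   initial images cannot overshoot on steep walls.
2. **Reparametrize**: images are redistributed to exactly equal arc
   spacing along the current piecewise-linear curve, measured in plain
   Cartesian coordinates of the active region only (no mass weighting;
   the environment rides along by the same interpolation). Equal
   *chord* placement is deliberately not attempted: for non-smooth
   polylines an exact equal-chord solution need not exist, while
   equal-arc placement is exact and is the classic redistribution. For
   smooth converged strings the two agree to discretization error.
3. **Relax environment**: each image's environment is locally minimized
   (L-BFGS with analytic gradients, default gradient tolerance
   10⁻⁶ kcal·mol⁻¹·Å⁻¹) with the active coordinates bitwise frozen.

Endpoints are fixed by default (paths connect pre-optimized end
states). Convergence is declared when the mean over images of the
absolute per-image energy change between cycles falls below a
threshold, default 10⁻¹⁰ Hartree expressed in kcal/mol; the full ΔV
history is reported. Divergence (non-finite energy) raises an error
carrying the last good path. The protocol's default geometry is a
16-image linear Cartesian initialization, densification of the
converged string to 45 equal-arc points, and analysis on the dense
path. On the Müller-Brown surface this two-stage protocol places the
maximum-energy image within ~0.01 position units and ~0.013 energy
units of the independently Newton-located saddle; with 16 images alone
the equal-arc spacing (~0.19 units) limits how close the barrier image
can land, which is exactly why the densification stage exists.

## Canonical sampling

FEP needs Boltzmann-distributed environment configurations at fixed
active geometry. This sampling contract is fulfilled by Metropolis
Monte Carlo: single-particle uniform cube moves, step size auto-tuned
during burn-in toward 40% acceptance, burn-in discarded, optional
thinning, optional harmonic restraint during burn-in only (mirroring a
heating-stage restraint). Molecular-dynamics machinery (thermostats,
constraint solvers, Ewald sums) is out of scope on purpose: only the
canonical distribution matters to the estimator, not the dynamics that
produced it. The default temperature is 358 K — the growth optimum of
the thermophilic organism whose enzyme motivated the protocol — and
the default analysis set is 300 snapshots per path state, subsampled
uniformly without replacement from the thinned chain. Every ensemble
records its seed; identical seeds give bit-identical snapshot lists.
An integrated autocorrelation time is reported as a diagnostic only, so
users can judge snapshot independence when choosing the thinning
stride.

## Free-energy perturbation

For adjoining states A and B:

* ΔE_qm = ⟨E_act(r_B, R)⟩_B − ⟨E_act(r_A, R)⟩_A over each state's own
  ensemble;
* ΔE_int(R) = E_int(r_B, R; Q_B) − E_int(r_A, R; Q_A) on A-state
  snapshots (the perturbation moves the active atoms and their fitted
  charges; every environment atom stays put);
* ΔF_int = −β⁻¹ ln⟨exp(−β ΔE_int)⟩_A, computed through log-sum-exp so
  no magnitude of ΔE_int can overflow;
* ΔF = ΔE_qm + ΔF_int, an identity that holds exactly in every emitted
  step by construction.

Standard errors come from a seeded nonparametric bootstrap (default 200
resamples) over the perturbation samples; they are honest only when the
snapshots are effectively independent, hence the thinning guidance
above. Steps accumulate into a profile F(σ) with F(0) = 0, decomposed
into the active-energy curve and the cumulative interaction curve
(their pointwise sum reproduces F exactly; both are written to the
profile CSV). Forward-only estimation is the default; a
forward/backward hysteresis check is available as a convergence
diagnostic. The estimator is validated against two closed forms: the
Gaussian cumulant identity (ΔF = μ − βs²/2 for normal perturbations)
and the harmonic-coupling model, one environment particle in a
quadratic well with a linear active coupling c·R_x, for which
ΔF(c_A→c_B) = (c_A² − c_B²)/(2k) exactly.

## ESP charge fitting

Charges on the active atoms are fitted by unweighted linear least
squares to reference potentials on a grid, subject to a single equality
constraint on the total charge, solved exactly via the KKT system.
Grids for testing use deterministic Fibonacci-sphere points on two
shells per atom (1.4× and 2.0× a nominal 1.7 Å radius, points inside
any atom's inner shell culled) — a conventional ESP recipe. A
rank-deficient or badly conditioned design matrix (condition number
above 10⁶) raises an error reporting the condition number rather than
returning garbage charges. No restraints toward zero charge and no
scheme-specific grid weighting are applied; the fit is the generic core
shared by all ESP schemes. Group analysis requires disjoint groups
covering all active atoms and appends a conservation column (the per-σ
total, equal to the constrained charge by construction).

## The transfer toy

The synthetic fixture mimics the essential structure of an
enzyme-catalyzed group transfer without any electronic-structure input:

* **Active region** (4 particles): donor D, transferred group P,
  acceptor A, spectator charge center M (the stand-in for a divalent
  cation). The surface is the lower eigenvalue of a 2×2 valence-bond
  Hamiltonian whose diabats bind P to D (with A parked at a far site)
  or P to A (with A drawn to a near site), plus weak orientation wells
  on P (the role of angular force-field terms; without them P could
  swing freely on its bond sphere and any environment force would
  produce spurious minima) and stiff tethers on D and M. This yields
  exactly one barrier along the transfer coordinate, genuine end-state
  minima, and an approach-then-transfer MEP: the forming P–A distance
  shortens then plateaus while the breaking D–P distance plateaus then
  lengthens. The whole surface is rescaled once at construction so the
  barrier along the linear reactant→product scan equals the requested
  height (default 15 kcal/mol, a plausible enzymatic barrier); a
  diabatic offset (default −6 kcal/mol before scaling) makes the
  transfer exergonic.
* **Environment** (default 10 particles): a shell of radius ~12 Å
  around the active center with alternating charges of magnitude 0.5 e,
  six negative and four positive — echoing the anionic excess typical
  of nucleotide binding sites — plus Lennard-Jones parameters and
  harmonic tethers (10 kcal·mol⁻¹·Å⁻²) standing in for the covalent
  scaffold a protein matrix provides. The shell radius and tether
  stiffness were chosen so the environment perturbs the active surface
  (end-state shifts of ~0.25 Å, interaction forces of ~1 kcal/mol/Å)
  without overwhelming it; a closer or looser shell lets the ±0.9 e
  active charges dominate the 15 kcal/mol surface and the path
  degenerates into ion-pairing artifacts.
* **Charge model**: per-atom charges interpolate smoothly (tanh switch
  on the transfer coordinate (d_DP − d_PA)/(d_DP + d_PA)) between
  end-state vectors that both sum to zero — so total charge is
  conserved exactly at every geometry — and whose product-side group
  sums (±0.56 e) sit strictly below the formal charges (±1), the
  delocalization motif of metal-assisted phosphoryl transfer.

What the toy does *not* emulate: electronic polarization of either
layer, bond topology changes outside the single transfer, solvent,
periodicity, and any quantitative correspondence to a real enzyme's
energetics. Passing tests on the toy demonstrate that the machinery —
path optimization, sampling, exponential averaging, charge fitting,
conservation laws, reproducibility — is correct, not that a particular
enzyme's numbers are reproduced; real applications must supply a real
active-region energy backend.

## Pipeline defaults and problem sizes

The end-to-end pipeline re-optimizes both end states on the full
two-layer energy before building the string (the bare-surface minima
shift slightly once the environment interacts, and fixed endpoints
should be genuine minima of the sampled model). Defaults: 16 images,
Euler step 2×10⁻³ (energy-gradient units) with 20 steps per cycle, at
most 300 cycles to a mean-|ΔV| tolerance of 10⁻⁶ kcal/mol (tighter
thresholds change the profile by less than the sampling noise),
densification to 45 points, 100 burn-in sweeps then 660 sweeps thinned
by 2 at 358 K per point, subsampled to 300 snapshots, 200 bootstrap
resamples. A full run takes about 40 s on one CPU. Per-point sampler
seeds, subsampling seeds and bootstrap seeds are derived
deterministically from the single pipeline seed, which is why reruns
are byte-identical.

## Numerical choices and degenerate inputs

* Coincident atom pairs (separation < 10⁻⁸ Å) raise a geometry error
  naming the pair; zero or negative pair distances are rejected.
* Tangents of coincident neighboring images, zero-length paths, and
  non-normalized projector inputs raise specific errors rather than
  propagating NaNs.
* The stationary-point finder (test oracle) runs Levenberg-Marquardt on
  the gradient field followed by a backtracking Newton polish, which
  tolerates the indefinite Hessians around saddle points.
* Floats in all text artifacts are written with 17 significant digits
  and re-parsed with round-trip-exact converters, so every format round
  trip is bit-exact.
* The Zwanzig implementation subtracts the sample maximum inside the
  log-sum-exp (via `scipy.special.logsumexp`), making the estimator
  overflow-free for arbitrary perturbation magnitudes.

## Known limitations

* Forward Euler only; no higher-order integrators, no climbing-image
  refinement, no Hessian-based transition-state search, no on-the-fly
  free-energy string.
* Forward-only FEP (with hysteresis as a diagnostic); no BAR/MBAR, no
  thermodynamic integration, no cross-temperature reweighting.
* The sampler is a surrogate for the canonical distribution only;
  kinetic observables are meaningless by construction.
* Charge fitting is plain constrained least squares; no conformational
  averaging, no restraints, no scheme-specific grid weighting.
* The barrier image of a discretized string is at best half an image
  spacing from the true saddle; densify before reading off barrier
  properties.
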