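# Methods

## Scope and design

`smd-unbind` implements the analysis layer of a steered-unbinding study of
LDHA (lactate dehydrogenase A) inhibitors: converting experimental
dissociation constants to standard free energies, extracting work and peak
force from constant-velocity pull traces, estimating the potential-of-mean-
force difference via the Jarzynski equality, and computing the trajectory
geometry statistics used to characterise ligand binding (mobile-loop state
populations, contact/ionic/hydrogen-bond occupancy, RMSF, gromos
clustering, representative-structure selection).

The cluster-scale all-atom steered MD that generates real force–distance
curves is replaced by a 1-D surrogate: a particle on an explicit free-energy
landscape G(x), pulled by a harmonic spring whose anchor moves at constant
velocity. Because the landscape is known in closed form, the true
free-energy difference along the pulling path is exact ground truth, so
estimator properties (convergence, finite-sample bias) can be measured
directly — something impossible with the real simulations. Everything the
analysis layer consumes (force–distance curves at a fixed output cadence,
replicate sets, trace files) is preserved.

**What this does and does not show.** The synthetic suites validate the
statistical machinery — integration, exponential averaging, clustering,
occupancy counting — on data with known ground truth. They do not, and
cannot, reproduce the published trajectory-derived magnitudes: loop-state
populations of the real complexes, contact and salt-bridge occupancies,
absolute work/peak-force values, or ΔPMF magnitudes of the actual
protein–ligand systems. Those depend on the all-atom potential, solvent and
protein environment and require the original cluster-scale simulations.

## The pulling model

Overdamped Langevin dynamics with a moving harmonic restraint,

    dx = [ -G'(x) + k (z - x) ] / (γ m) dt + sqrt(2 kB T / (γ m)) dW,
    z(t) = z0 + v t,

integrated with Euler–Maruyama. Units are kJ/mol, nm, ps, amu (in which
1 amu·nm²/ps² = 1 kJ/mol); kB T is expressed per mole with
R = 0.0083145 kJ mol⁻¹ K⁻¹.

Defaults mirror the study protocol: spring constant k = 1000 kJ mol⁻¹ nm⁻²,
pulling speed v = 0.5 nm/ns, 10 ns duration with force and position
recorded every 1 ps (exactly 10,000 samples per trace), T = 298 K,
12 replicates. The anchor starts on top of the particle at the bound-well
minimum, so the initial spring force is zero, matching an equilibrated
start. Replicate i uses seed = base_seed + i; identical seeds give
bit-identical traces.

Parameter choices that matter:

- **Timestep 0.01 ps.** Euler–Maruyama for the stiffest mode (spring +
  well curvature, ~1200 kJ mol⁻¹ nm⁻²) is stable when dt·k/(γm) < 2; at the
  default drag the factor is ~1.2×10⁻³, far inside the stable region. A
  diverging trajectory (non-finite coordinate, or particle–anchor
  separation beyond 1000 nm) raises an error carrying the step index.
- **Drag γm = 200 ps⁻¹ × 50 amu = 10,000 amu/ps.** Unbinding pulls drag the
  ligand through solvent and breaking contacts, and the study's pulls are
  strongly dissipative (mean work far above ΔG). The default drag puts the
  standard 0.5 nm/ns protocol in that regime — viscous dissipation
  γ·v·d ≈ 25 kJ/mol over a 5 nm pull, work SD of several kJ/mol — while a
  ten-fold slower pull (0.05 nm/ns) is nearly quasi-static. A much smaller
  drag would make both speeds quasi-static, erasing the finite-replicate
  overestimation that the estimator-bias analysis is meant to exhibit.
- **Landscapes.** Four forms: harmonic well; a Gaussian bound well of
  given depth and width merging into a flat "solvent" region (the standard
  unbinding test case — exact ΔG equals the depth by construction); a
  quartic double well with optional tilt; and piecewise-linear
  interpolation through nodes. All expose analytic gradients and exact ΔG
  between any two positions as closed-form energy differences (the
  double-well value is cross-checked against adaptive quadrature of the
  gradient in the tests).

With a stiff spring the PMF along the anchor coordinate differs from G(x)
by a small convolution correction: for the default well (depth 20, width
0.3 nm) the exact anchor-PMF difference is 19.76 kJ/mol rather than 20.
The 2.5 kJ/mol (~1 kB T) recovery tolerance used in the tests absorbs this.

## Work, Jarzynski estimate, and statistics

Work is the trapezoidal integral of the spring force over the **anchor**
displacement — the controlled parameter, which is the coordinate for which
the Jarzynski equality holds. Traces are evenly sampled, where the
trapezoid rule is standard practice; tests cross-check against composite
Simpson on smooth traces (0.1 %).

ΔPMF = −kB T · ln⟨exp(−W/kB T)⟩ is evaluated through log-sum-exp, so work
sets of order 10⁴ kJ/mol stay finite. The estimate satisfies
ΔPMF ≤ ⟨W⟩ (Jensen) and min W − kB T ln n ≤ ΔPMF; the reported
`jensen_gap = ⟨W⟩ − ΔPMF` is the dissipated work of the estimate. An
optional percentile bootstrap CI over replicates (seeded, 2.5/97.5
percentiles) is provided as a diagnostic beyond the original analysis and
is flagged as such.

Finite-replicate bias: with n = 12 at the standard speed the estimator is
dominated by the rarely sampled low-work tail and systematically
overestimates the true ΔG; the suites measure this as the median estimate
over 50 independent 12-replicate sets on the 20 kJ/mol well (typically
~30 kJ/mol). With 64 replicates at 0.05 nm/ns the estimate lands within
1 kB T of the exact value.

Pilot-direction selection picks the candidate with the least mean pilot
work (lexicographic tie-break). Work-distribution comparisons default to a
one-sided Welch unequal-variance t-test (a > b), with Mann–Whitney behind a
flag; variances differ visibly between ligand systems, which is why the
unequal-variance form is the default. Two identical zero-variance samples
return p = 1 for the one-sided test.

## Affinity conversion

ΔG_dissoc = −RT ln(Kd / 1 M) at 298 K (the simulation temperature; it
reproduces every published ΔG value from the Kd table to the printed 0.1
precision, which is how the choice was validated). The 1 M standard state
is implied by the unit conversion and stated in the code contract. ΔΔ
columns against a reference ligand are formed from 1-decimal-rounded ΔG
entries, matching how the published difference column was constructed
(22.0 − 17.8 = 4.2; the unrounded difference is 4.28). Rank concordance
reports order identity plus Kendall's τ with the exact small-sample
p-value. The shipped Kd table includes NADH and PYR, which are loadable but
take no part in pulling comparisons.

## Trajectory geometry

- **Loop state:** centroid distance between the loop Cα set (residues
  100–103) and the anchor Cα set (Tyr238, Lys242); identical atomic masses
  make the centre of mass an unweighted centroid. Closed below 0.9 nm, open
  above 1.05 nm, intermediate otherwise — boundary values are intermediate
  because the defining inequalities are strict. Residue numbering follows
  the mature-protein convention of the crystal structure used (initiator
  methionine not counted).
- **Contacts:** any heavy-atom cross pair within 0.4 nm (inclusive);
  hydrogens are excluded from the selections. Ionic occupancy is the same
  statistic between named charged groups, reported as a percentage.
- **Hydrogen bonds:** donor–acceptor distance ≤ 0.35 nm and H–donor–
  acceptor angle ≤ 30°, both configurable; the geometric criteria are the
  common MD-analysis convention.
- **Superposition:** Kabsch SVD with proper-rotation correction and
  optional weights; degenerate (collinear or < 3 atom) inputs are rejected.
  An independent quaternion implementation serves as the test oracle.
- **RMSF:** frames are iteratively superposed onto the running mean
  structure until the fit reaches a fixed point (tolerance 1e-12, at most
  100 passes), making the result invariant under rigid motion of the input
  frames to 1e-9; RMSF is then the RMS deviation about the converged mean.
  For an atom fluctuating isotropically with per-axis SD σ, RMSF = σ√3.
- **gromos clustering:** repeatedly extract the frame with the most
  neighbours within the RMSD cutoff (ties: lowest frame index) together
  with its neighbours; cluster sizes are non-increasing in extraction
  order. The adaptive cutoff walks the grid 0.05, 0.055, ... nm and stops
  at the first cutoff whose largest cluster holds a strict majority of
  frames; the representative structure is that cluster's seeding frame.
  "Least RMSF" monomer selection aggregates by the arithmetic mean over the
  selection (the simplest order statistic consistent with the procedure),
  with a lexicographic tie-break.

## Synthetic trajectories

`generate_toy_trajectory` places atoms at fixed mean positions with
isotropic Gaussian fluctuations of prescribed per-atom SD, and can impose a
per-frame loop–anchor centroid distance schedule by rigidly translating the
loop group along the separation axis (plus optional Gaussian noise on the
target). This provides exact ground truth for loop-state populations
(classification is deterministic, so scheduled fractions are recovered
exactly) and known RMSF targets. It emulates stationary fluctuations about
a single conformation only: no conformational exchange, no anisotropy, no
correlated motions — so RMSF/occupancy tests validate the estimators, not
the dynamics of real proteins.

## Problem sizes

The heavier computations are sized for a single CPU: the slow-pull
convergence study uses 64 replicates of a 40 ns pull (0.05 nm/ns over 2 nm)
and the bias study 50 independent 12-replicate sets of the standard 10 ns
protocol, about a minute in total with the JIT-compiled integrator. Oracle
cross-checks run on ≤ 20-frame instances where brute force is exact.

## Known limitations

- The 1-D reaction coordinate cannot represent pulling-direction geometry;
  direction selection operates on pilot work sets supplied by the caller.
- Euler–Maruyama inflates the stationary variance of stiff modes by
  ~dt·k/(2γm); at the default parameters this is ≈ 0.06 % and negligible,
  but custom protocols with small drag should shrink the timestep.
- The PDB reader handles coordinate records (fixed-column, multi-model);
  mmCIF and binary trajectory formats are out of scope.
- p-values from Welch's test assume approximate normality of replicate
  works; the Mann–Whitney option covers heavy-tailed cases.
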