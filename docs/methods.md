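# Methods

This note documents the models implemented in `lipas`, the defaults and
why they were chosen, what the synthetic generators do and do not
emulate, and the numerical decisions that matter when interpreting
output.

## Chain representation and geometry

Fatty acids are united-atom chains: one interaction site per backbone
carbon, with the carboxylate head collapsed into a single united site at
position C1. Geometry is rigid internal coordinates — C–C 1.53 Å, C=C
1.33 Å, valence angles 111° at sp³ and 120° at sp² carbons — so a
conformation is fully specified by its n−3 backbone dihedrals (IUPAC
signed convention, degrees, (−180, 180]). Coordinates are built by
sequential natural-extension chain growth from three canonically placed
atoms; rebuilding dihedrals from coordinates reproduces the input to
well below 1e-6°, which the test suite asserts on random torsion
vectors for every registered chain.

Torsions whose central bond is a C=C are frozen at the declared geometry
(cis 0°, trans 180°) and are never proposed as Monte Carlo moves. The
registry covers the four chains of interest — stearic (18:0), oleic
(18:1 cis-9), linoleic (18:2 cis-9,12) and cis-vaccenic (18:1 cis-11) —
and arbitrary topologies within 2–24 carbons, no cumulated dienes.

Hydrogens, carboxylate protonation state, and glycerol/phospholipid head
groups are out of scope: the torsional statistics of the acyl chain are
the object of study, and a united-atom chain preserves them at a small
fraction of the cost of an all-atom force field.

## Energy model

The energy is a declared, minimal model — not a reproduction of any
published all-atom force field — chosen to preserve two features the
ensemble analysis depends on: gauche/anti torsion statistics and chain
sterics.

* Torsion series V(φ) = a₁(1 + cos φ) + a₃(1 + cos 3φ), zero at anti.
  sp³–sp³ bonds use (a₁, a₃) = (0.6, 2.0) kcal/mol, i.e. a 0.9 kcal/mol
  gauche(60°)–anti gap and a ~5.2 kcal/mol cis barrier, alkane-like
  values. Allylic bonds (single bonds adjacent to a C=C) use the
  softened (0.2, 0.8).
* 12-6 Lennard-Jones between sites ≥ 4 bonds apart, Lorentz–Berthelot
  combination, 12 Å cutoff. Site parameters (ε kcal/mol, σ Å):
  CH3 (0.175, 3.905), CH2 (0.118, 3.905), CH= (0.115, 3.85),
  carboxylate united site (0.20, 4.20).
* No electrostatics, no solvent: the ensemble models the desolvated
  (vacuum) chain.

Consequently *absolute* energies are not comparable with values from
other force fields; externally supplied bound-state enthalpies are used
only as query points against the sampled distribution, never as
quantities this model is expected to reproduce.

## Metropolis sampler

One uniformly chosen rotatable torsion is perturbed per step by
uniform(−30°, +30°) and accepted with min(1, e^(−ΔE/kT)),
k_B = 1.9872×10⁻³ kcal/(mol·K). Defaults: 10⁶ steps, T = 300 K
(kT ≈ 0.59616 kcal/mol), burn-in 10% of the run, all-anti start, seed 0
in the library and explicit in the CLI. The inner loop is
numba-compiled; the compiled energy is tested to agree with the pure
numpy reference implementation to 1e-9, and identical seeds give
bitwise-identical traces.

A discrete-proposal mode (new value drawn uniformly from a supplied
angle set) exists for exhaustively enumerable toy systems; the proposal
is symmetric, so the Metropolis criterion is unchanged. The test suite
uses a 3-rotor hexane restricted to {−60, 60, 180}° — 27 microstates —
with the Lennard-Jones term disabled so the Boltzmann distribution is
exactly enumerable, and requires chi-square agreement (α = 0.01, ten
seeds, samples thinned ×10 against autocorrelation).

## P(s), entropy, bound-state frequency

The energy trace is discretized into fixed-width bins (default
0.5 kcal/mol) spanning its observed range; bin masses sum to one. The
entropy estimate is the Gibbs/Shannon form S = −Σ P ln P in nats, with
0·ln 0 ≡ 0; it is zero for a delta distribution and ln k for a uniform
k-bin one, which the tests assert to 1e-12. The choice of natural
logarithm is a convention — any other base rescales all entropies by a
constant and preserves ordering. Because S is computed on the *energy*
histogram, it measures the breadth of the sampled energy distribution,
which at fixed bin width grows with the number of active torsions; this
is the sense in which saturated chains show larger ensemble entropy than
unsaturated ones. The bin width trades resolution against counting
noise; 0.5 kcal/mol (roughly kT at 300 K) keeps hundreds of counts per
occupied bin at the default run length.

`bound_state_frequency` reports the histogram mass of the bin containing
a query enthalpy (zero if outside the sampled range) and the query's
percentile in the trace (fraction of samples ≤ the query, ×100).

Torsion classes: cis |θ| ≤ 30°, gauche 30° < |θ| ≤ 120°, anti
|θ| > 120°; out-of-range angles are normalized first. Gauche counting
excludes frozen double-bond torsions by default.

## Cavity detection

A regular grid (default spacing 0.6 Å) covers the structure plus a
margin; the origin is snapped to an absolute lattice so results do not
depend on the margin. A voxel is *occupied* for a probe of radius p when
it lies within (atom radius + p) of any atom. Bulk solvent is the
probe-out-free region connected to the box boundary, dilated by the
probe-out radius (computed exactly via a Euclidean distance transform).
Cavities are voxels free to the probe-in (1.4 Å, water-sized) but not
covered by bulk; 6-connected components below 5 ų are dropped and
volume is voxel count × spacing³. Defaults (0.6 / 1.4 / 4.0 Å, 5 ų)
follow the published defaults of the grid cavity tools in common use.
The hollow-sphere oracle fixture reproduces its analytic volume within
5%, halving the spacing moves it by under 2%, and rigid motions by under
3% (grid-alignment tolerance).

PDB input goes through gemmi: first model only, highest-occupancy
alternate locations (first on ties), water always removed, heteroatoms
removed on request. Cavity surveys of a holo structure should strip
heteroatoms first — a pocket filled by its ligand otherwise reports
near-zero volume. Van der Waals radii come from a single element table
(C 1.70, N 1.55, O 1.52, S 1.80, P 1.80, H 1.20 Å) with a logged 1.70 Å
fallback. Synthetic structures may carry per-atom radii in the B-factor
column, flagged by a REMARK marker that the reader auto-detects.

Ligand chain torsions: carbons of the named residue are bonded when
≤ 1.8 Å apart; the skeleton must be a single linear path (two termini,
no branch carbons), walked from C1 (or the lowest-numbered/serial
terminus) outward, yielding ordered dihedrals for classification.

## Binding fits

*ANS titrations*: four-parameter logistic on log₁₀ concentration,
R = bottom + (top − bottom)/(1 + 10^(h(log Kd − log c))); the EC50 is
reported as the apparent K_d, with the Hill slope free — fixing h = 1
was considered and rejected since the data decide it cheaply.
Zero-concentration anchor wells contribute residuals against the c→0
asymptote but stay out of the log predictor. Fitting is multi-start
nonlinear least squares (five starts: plateaus from the response
extremes, K_d grid across the observed concentration range; tolerances
1e-10). "No binding" is declared when the *realized* dynamic range —
the fitted curve evaluated at the observed concentration extremes, not
the asymptote difference, which can be an unreached extrapolation — is
below 3× the residual standard deviation (with a tiny scale-relative
floor so exactly flat data are never called binding). Standard errors
are Jacobian-based; bootstrap is deliberately not the default.

*FP heterodimerization*: with the labeled probe fixed at 20 nM,
candidate K_d values are of the same order, so free ≈ total ligand
fails. The bound probe fraction uses the exact quadratic root of
P + L ⇌ PL at fixed totals, and FP = FP_free + (FP_bound − FP_free) ×
bound fraction. In the probe ≪ K_d limit this reduces to the hyperbola,
which the tests confirm against an independent hyperbolic fit.

Both fits are deterministic given the data (multi-start grid is
data-driven, not random), hence permutation-invariant, and response
rescaling moves only the plateau parameters.

## CSP analysis

Matching is by residue id only — assignments are taken as given, peak
tracking is out of scope. The combined perturbation is
√((Δδ¹⁵N/10)² + (Δδ¹H)²) in ppm; intensity changes are (I − I₀)/I₀ with
I₀ = 0 rows flagged rather than divided. Residues present in only one
list are reported separately as exchange-broadening candidates. The
default significance rule, mean + 1 SD of the combined CSP, is a
declared convention (no universal standard exists); injected
perturbations ≥ 3× a 0.02 ppm background are recovered with sensitivity
1.0 across seeds in the tests.

## Mixture dichotomization

"Fixed variance" is implemented as the equal-variance model family: both
components share one variance parameter estimated by EM, matching the
common univariate mixture convention — not a hard-coded numeric
variance, for which no value exists. Initialization is a median split
(component means from the lower/upper halves, pooled variance, π = 0.5)
plus four seeded jittered restarts, keeping the best log-likelihood.
Convergence at log-likelihood improvement < 1e-8, max 1000 iterations; a
variance floor of 1e-10 × data variance guards collapse. The
log-likelihood is asserted non-decreasing on every run. Components are
ordered μ₁ < μ₂ and a sample is *expressing* when its posterior for the
upper component is ≥ 0.5 (ties expressing). The mean-expression
prefilter is strict: a cohort with mean exactly 5 is dropped. Fitting is
done on the expression values as supplied; whether to log-transform
upstream is the caller's decision. scikit-learn's tied-covariance EM
serves as an independent cross-check in the tests, never as the
implementation.

## Synthetic generators

Each generator is deterministic given (parameters, seed) and writes its
ground truth next to the data. Designs emulated: the 13-point 1:3 ANS
dilution ladder from 33 µM; the 20-point 1:2 FP ladder from 1 mM scaled
by the 18.75/25 in-well mixing ratio with the 20 nM probe; HSQC pairs
with amide shifts drawn in realistic ranges (¹H 6–10, ¹⁵N 100–135 ppm);
hollow pseudo-atom shells whose probe-in-excluded interior is exactly a
ball (the pseudo-atom radius is derived as shell − inner − probe_in, so
the analytic truth is exact by construction); and two-Gaussian cohorts
with recorded memberships.

Noise models: multiplicative Gaussian for fluorescence/FP (reader noise
scales with signal; defaults 2% and 3%), additive in ppm for shifts,
none for structures. Not emulated: raw emission spectra or plate-reader
exports, NMR FIDs or peak picking, pipetting/dilution error,
plate-position effects, real expression-count overdispersion. Passing
recovery tests on these generators therefore demonstrates estimator
correctness under the declared noise model, not robustness to every
artifact of real instruments.

## Problem sizes and determinism

Default study conditions are used throughout the tests: 10⁶-step
ensembles for the three-chain entropy comparison, 100-seed Kd-recovery
simulations, 50-seed mixture recovery, 10-seed chi-square sampler
checks. The toy-chain oracle runs 200k steps thinned ×10. All
randomness flows through explicit seeds; the acceptance script derives
its per-simulation seeds from the single `--seed` argument.

## Known limitations

* The energy model is intentionally minimal; entropy *orderings* and
  gauche statistics are meaningful, absolute energies are not.
* Energy-histogram entropy is not configurational entropy; it inherits
  bin-width dependence and should be compared only across chains run at
  identical settings.
* Single-torsion moves mix slowly for long chains near steric locking;
  the defaults are adequate for 18-carbon chains but no replica
  exchange is provided.
* The cavity detector reports grid volumes; surface-area and lining
  hydrophobicity analyses are out of scope, and volumes carry a
  grid-dialect tolerance of a few percent.
* CSP titration trajectories are reported per residue, not fitted to a
  binding isotherm.
* The mixture model is single-gene, univariate; downstream differential
  expression and enrichment are out of scope by design — the module
  emits the two sample lists those tools consume.
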