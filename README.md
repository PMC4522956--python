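# lipas — lipid/PAS-domain analysis suite

`lipas` is a Python toolkit for the computational characterization of
unsaturated free fatty acids as ligands of a hydrophobic protein cavity,
built around the hypoxia-inducible-factor HIF-3α PASb domain as the model
system. It is aimed at structural bioinformaticians and biophysicists who
want each analysis stage as a tested, reusable library function with a
matching command-line interface — and a synthetic-data generator for every
stage, so the whole pipeline runs and validates without any external
downloads.

## What it computes

**Torsional Monte Carlo ensembles** (`lipas.mc_ensemble`). The canonical
ensemble of a free (vacuum) acyl chain at temperature *T* is sampled by a
Metropolis Markov chain over backbone dihedrals: one uniformly chosen
rotatable torsion is perturbed per step and accepted with probability
min(1, e^(−ΔE/kT)). The united-atom energy model combines a torsion series
a₁(1+cos φ) + a₃(1+cos 3φ) (anti minimum, 0.9 kcal/mol gauche–anti gap)
with 12-6 Lennard-Jones sterics for sites four or more bonds apart.
Microstate probabilities P(s) come from a fixed-width histogram of the
energy trace, and the ensemble entropy is the Gibbs/Shannon estimate

    S = −Σ_s P(s) ln P(s)   (nats).

The frequency of a putative bound-state enthalpy within the unbound
ensemble (its histogram bin mass and trace percentile) quantifies how
accessible the bound conformation is from solution. Chain geometry —
stearic 18:0, oleic 18:1 cis-9, linoleic 18:2 cis-9,12, cis-vaccenic 18:1
cis-11, or any custom topology — is handled by `lipas.lipid_models` with
rigid internal coordinates and frozen cis/trans torsions across double
bonds.

**Cavity detection** (`lipas.cavity`). A dual-probe grid algorithm: voxels
free to a small probe (1.4 Å) but unreachable by a large probe (4.0 Å)
rolling in from bulk solvent form interior cavities; volumes are reported
in ų as voxel count × spacing³. The same module extracts a bound ligand's
acyl-chain dihedrals for gauche/anti/cis classification.

**Apparent-Kd fitting** (`lipas.binding`). ANS-displacement titrations are
fitted with a four-parameter logistic in log₁₀ concentration (EC50
reported as apparent K_d); series whose realized dynamic range stays below
3× the residual noise are flagged non-binding. Fluorescence-polarization
heterodimerization series are fitted with the depletion-corrected one-site
model (exact quadratic solution of P + L ⇌ PL), required because the
labeled probe (20 nM) is comparable to the dissociation constants.

**NMR chemical-shift perturbation** (`lipas.nmr`). Combined amide CSPs,
Δδ = √((Δδ¹⁵N/10)² + (Δδ¹H)²), relative intensity changes (I − I₀)/I₀,
and mean + 1 SD significance ranking between assigned free/bound
¹⁵N-HSQC peak lists.

**Cohort dichotomization** (`lipas.mixture`). Tumor cohorts are classified
into expressing / non-expressing samples by a two-component univariate
Gaussian mixture with a common (equal) variance fitted by EM, after a
strict mean-expression > 5 prefilter; labels follow the posterior ≥ 0.5
rule.

## Worked example

Generate a synthetic ANS titration at the oleic-acid-like affinity
(true K_d = 39 nM, the 33 µM → 1:3 × 12 dilution design, 2% noise) and
fit it:

```bash
$ lipas synth ans --kd 39e-9 --seed 0 --out ans_demo
$ lipas kdfit ans ans_demo/titration.csv
{
  "model": "4pl",
  "kd_apparent_molar": 3.7219062607926164e-08,
  "hill": 0.9892560256144223,
  "bottom": 95.48579116229635,
  "top": 1001.5495329306991,
  "converged": true,
  ...
}
```

The fitted apparent K_d (37.2 nM) recovers the injected 39 nM within the
noise of a single simulated experiment; `bottom`/`top` are the fitted
response plateaus and `hill` the slope of the sigmoid. The flat
(saturated-chain) scenario `lipas synth ans --flat` instead yields
`"converged": false` — no K_d is reported when there is no resolvable
dose response.

Ensembles, run at the default one million steps and 300 K:

```bash
$ lipas ensemble run --lipid oleic --steps 1000000 --seed 0 --out oleic.csv
$ lipas ensemble bound-freq oleic.csv --e-bound 4.0
```

With seed 0 the three registered 18-carbon chains give histogram
entropies S(stearic) = 2.89 > S(oleic) = 2.83 > S(linoleic) = 2.77 nats —
entropy falls as unsaturation rises, since each cis bond freezes a
torsion and softens its neighbours — and a 4 kcal/mol bound-state
enthalpy sits at the 24th percentile of the oleic ensemble (bin mass
0.083).

Other stages follow the same pattern; every `lipas synth <scenario>`
writes a `truth.json` beside its data so recovery can be checked:

```bash
$ lipas synth cavity --inner-radius 4.0 --out cav && \
  lipas cavity detect cav/shell.pdb            # ≈268 ų analytic void
$ lipas synth hsqc --perturb 17:1.5:0.1 --out h && \
  lipas csp compute h/free.tsv h/bound.tsv
$ lipas synth cohort --n 500 --out coh && \
  lipas cohort classify coh/expression.csv --mean-filter 1
```

## Layout

```
src/lipas/
  lipid_models.py   chain topologies, torsion→Cartesian builder, exports
  mc_ensemble.py    energy model, Metropolis sampler, P(s), entropy
  _kernels.py       numba-compiled sampler inner loops
  cavity.py         PDB parsing, dual-probe grid detector, ligand torsions
  binding.py        4PL and depletion-corrected FP fitting
  nmr.py            CSP quadrature, intensity changes, ranking
  mixture.py        equal-variance 2-component GMM by EM
  synthetic.py      truth-injected generators for every stage
  cli.py            click entry point (`lipas`)
docs/methods.md     models, defaults, numerical choices, limitations
```
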