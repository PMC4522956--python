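"""Torsional Metropolis–Monte Carlo ensembles of free fatty acids.

The canonical ensemble of an isolated (vacuum) acyl chain at temperature T
is sampled by a Markov chain over backbone torsions: one uniformly chosen
rotatable torsion is perturbed per step and the move accepted with the
Metropolis probability min(1, exp(−ΔE/kT)). Microstate probabilities P(s)
are then obtained by discretizing the sampled energy trace into a
fixed-width histogram, and the ensemble entropy is the Gibbs/Shannon form

    S = −Σ_s P(s) ln P(s)     (nats)

computed over the occupied bins. The frequency with which a putative
bound-state enthalpy occurs in the unbound ensemble is read off the same
histogram (bin mass at that energy, plus its percentile in the trace).

Energy model
------------
A deliberately minimal united-atom model that preserves gauche/anti
torsion statistics and chain sterics:

* torsion series V(φ) = a1·(1 + cos φ) + a3·(1 + cos 3φ), zero at anti,
  with a 0.9 kcal/mol gauche(60°)–anti gap for sp³–sp³ bonds and a
  softened series for allylic bonds;
* 12-6 Lennard-Jones between united sites four or more bonds apart
  (Lorentz–Berthelot combination, 12 Å cutoff);
* no electrostatics, no solvent.

Torsions spanning a C=C are frozen at the declared geometry and are never
proposed as moves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .errors import ConfigurationError, ValidationError
from .lipid_models import (
    CLASS_ALLYLIC,
    CLASS_FROZEN,
    CLASS_SP3,
    AcylChainTopology,
    Conformation,
    make_topology,
    normalize_angle,
)

#: Boltzmann constant in kcal/(mol·K)
K_B = 1.9872e-3


@dataclass(frozen=True)
class EnergyModel:
    """United-atom torsion + Lennard-Jones energy model.

    ``torsion_coefficients`` maps a torsion class to ``(a1, a3)`` of the
    series a1(1+cos φ) + a3(1+cos 3φ) in kcal/mol; ``lj_params`` maps a
    site type to ``(epsilon kcal/mol, sigma Å)``.
    """

    torsion_coefficients: tuple = (
        (CLASS_SP3, (0.6, 2.0)),      # gauche−anti gap at 60° = 1.5·a1 = 0.9
        (CLASS_ALLYLIC, (0.2, 0.8)),  # softened barrier next to a C=C
    )
    lj_params: tuple = (
        ("CH3", (0.175, 3.905)),
        ("CH2", (0.118, 3.905)),
        ("CH", (0.115, 3.850)),
        ("COO", (0.200, 4.200)),
    )
    temperature: float = 300.0
    lj_cutoff: float = 12.0
    min_bond_separation: int = 4

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValidationError("temperature must be positive")

    @property
    def kT(self) -> float:
        """Thermal energy k_B·T in kcal/mol (≈0.59616 at 300 K)."""
        return K_B * self.temperature

    def with_temperature(self, temperature: float) -> "EnergyModel":
        return EnergyModel(
            torsion_coefficients=self.torsion_coefficients,
            lj_params=self.lj_params,
            temperature=temperature,
            lj_cutoff=self.lj_cutoff,
            min_bond_separation=self.min_bond_separation,
        )

    # ---- compiled-kernel parameter arrays --------------------------------

    def arrays_for(self, topology: AcylChainTopology) -> dict:
        """Precompute per-topology parameter arrays for the sampler."""
        tc = dict(self.torsion_coefficients)
        lj = dict(self.lj_params)
        classes = topology.torsion_classes()
        a1 = np.zeros(topology.n_torsions)
        a3 = np.zeros(topology.n_torsions)
        for t, cls in enumerate(classes):
            if cls == CLASS_FROZEN:
                continue
            if cls not in tc:
                raise ConfigurationError(
                    f"energy model lacks coefficients for torsion class {cls!r}"
                )
            a1[t], a3[t] = tc[cls]
        sites = topology.site_types()
        missing = sorted(set(sites) - set(lj))
        if missing:
            raise ConfigurationError(f"energy model lacks LJ parameters for {missing}")
        eps = np.array([lj[s][0] for s in sites])
        sig = np.array([lj[s][1] for s in sites])
        n = topology.n_carbons
        pi, pj, eps4, sigma2 = [], [], [], []
        for i in range(n):
            for j in range(i + self.min_bond_separation, n):
                pi.append(i)
                pj.append(j)
                eps4.append(4.0 * math.sqrt(eps[i] * eps[j]))
                sigma2.append(((sig[i] + sig[j]) / 2.0) ** 2)
        rotatable = np.array(
            [t for t, c in enumerate(classes) if c != CLASS_FROZEN], dtype=np.int64
        )
        return {
            "n": n,
            "r": topology.bond_lengths(),
            "theta": np.radians(topology.bond_angles()),
            "a1": a1,
            "a3": a3,
            "rotatable": rotatable,
            "pair_i": np.array(pi, dtype=np.int64),
            "pair_j": np.array(pj, dtype=np.int64),
            "eps4": np.array(eps4),
            "sigma2": np.array(sigma2),
            "cutoff2": self.lj_cutoff**2,
        }


def torsion_energy(model: EnergyModel, cls: str, angle_deg: float) -> float:
    """Evaluate the torsion series of one class at one angle (kcal/mol)."""
    a1, a3 = dict(model.torsion_coefficients)[cls]
    phi = math.radians(angle_deg)
    return a1 * (1.0 + math.cos(phi)) + a3 * (1.0 + math.cos(3.0 * phi))


def lj_pair(epsilon: float, sigma: float, r: float) -> float:
    """12-6 Lennard-Jones pair energy 4ε[(σ/r)¹² − (σ/r)⁶] in kcal/mol."""
    s6 = (sigma / r) ** 6
    return 4.0 * epsilon * (s6 * s6 - s6)


def total_energy(conf: Conformation, model: EnergyModel) -> float:
    """Total energy of a conformation: torsion terms + LJ (kcal/mol).

    Pure-numpy reference path; the sampler uses a compiled kernel that is
    tested to agree with this function.
    """
    topo = conf.topology
    tc = dict(model.torsion_coefficients)
    classes = topo.torsion_classes()
    e = 0.0
    for t, cls in enumerate(classes):
        if cls == CLASS_FROZEN:
            continue
        if cls not in tc:
            raise ConfigurationError(
                f"energy model lacks coefficients for torsion class {cls!r}"
            )
        e += torsion_energy(model, cls, conf.torsions[t])
    lj = dict(model.lj_params)
    sites = topo.site_types()
    eps = np.array([lj[s][0] for s in sites])
    sig = np.array([lj[s][1] for s in sites])
    n = topo.n_carbons
    coords = conf.coordinates
    for i in range(n):
        for j in range(i + model.min_bond_separation, n):
            d2 = float(((coords[i] - coords[j]) ** 2).sum())
            if d2 < model.lj_cutoff**2:
                s2 = ((sig[i] + sig[j]) / 2.0) ** 2 / d2
                s6 = s2**3
                e += 4.0 * math.sqrt(eps[i] * eps[j]) * (s6 * s6 - s6)
    return e


@dataclass
class EnsembleResult:
    """Energy trace and derived histogram statistics of one MC run."""

    energies: np.ndarray = field(repr=False)
    accepted_fraction: float
    bin_edges: np.ndarray = field(repr=False)
    probabilities: np.ndarray = field(repr=False)
    entropy: float
    n_steps: int
    burn_in: int
    seed: int
    temperature: float
    topology_name: str
    torsion_snapshots: np.ndarray | None = field(default=None, repr=False)


def metropolis_sample(
    topology,
    model: EnergyModel | None = None,
    n_steps: int = 1_000_000,
    seed: int = 0,
    max_step_deg: float = 30.0,
    burn_in: int | None = None,
    bin_width: float = 0.5,
    initial_torsions=None,
    discrete_states=None,
    record_snapshots: bool = False,
) -> EnsembleResult:
    """Sample the torsional canonical ensemble of one chain.

    Parameters
    ----------
    topology : registry key, dict or AcylChainTopology
    model : EnergyModel, default model at 300 K if omitted
    n_steps : total Markov-chain steps (default one million)
    seed : RNG seed; identical (seed, inputs) give identical traces
    max_step_deg : half-width of the uniform torsion perturbation
    burn_in : steps discarded before recording (default 10% of n_steps)
    bin_width : energy histogram bin width in kcal/mol
    initial_torsions : starting rotatable torsions (default all-anti)
    discrete_states : optional angle set (degrees); when given, proposals
        are drawn uniformly from these states instead of perturbing
        continuously (used e.g. for exhaustively enumerable toy chains)
    record_snapshots : keep per-step torsion vectors (memory-heavy)
    """
    topology = make_topology(topology)
    model = model or EnergyModel()
    if n_steps < 1:
        raise ValidationError(f"n_steps must be >= 1, got {n_steps}")
    if burn_in is None:
        burn_in = n_steps // 10
    if not (0 <= burn_in < n_steps):
        raise ValidationError(f"burn_in must lie in [0, n_steps), got {burn_in}")
    arrays = model.arrays_for(topology)
    frozen = topology.frozen_torsions()
    phi0 = np.full(topology.n_torsions, math.pi)
    for t, v in frozen.items():
        phi0[t] = math.radians(v)
    if initial_torsions is not None:
        from .lipid_models import _expand_torsions

        phi0 = np.radians(_expand_torsions(topology, initial_torsions))
    if discrete_states is not None:
        states = np.radians(np.asarray(discrete_states, dtype=float))
        if states.size == 0:
            raise ValidationError("discrete_states must be non-empty")
        max_step = 0.0
        rot = arrays["rotatable"]
        for t in rot:
            phi0[t] = states[0]
    else:
        states = np.zeros(1)
        max_step = math.radians(max_step_deg)
    trace, acc, phi_final, snaps = _kernels.run_metropolis(
        arrays["n"], arrays["r"], arrays["theta"], phi0,
        arrays["a1"], arrays["a3"], arrays["rotatable"],
        arrays["pair_i"], arrays["pair_j"], arrays["eps4"], arrays["sigma2"],
        arrays["cutoff2"], model.kT, n_steps, burn_in, seed, max_step, states,
        1 if record_snapshots else 0,
    )
    edges, probs = discretize_boltzmann(trace, bin_width)
    return EnsembleResult(
        energies=trace,
        accepted_fraction=acc,
        bin_edges=edges,
        probabilities=probs,
        entropy=ensemble_entropy(probs),
        n_steps=n_steps,
        burn_in=burn_in,
        seed=seed,
        temperature=model.temperature,
        topology_name=topology.name,
        torsion_snapshots=np.degrees(snaps) if record_snapshots else None,
    )


def discretize_boltzmann(energies, bin_width: float):
    """Fixed-width histogram of an energy trace, normalized to unit mass.

    Returns ``(bin_edges, probabilities)`` where probabilities are bin
    masses (density × width) summing to 1 and the bins cover the trace's
    [min, max] range.
    """
    energies = np.asarray(energies, dtype=float)
    if energies.size < 1:
        raise ValidationError("empty energy trace")
    if bin_width <= 0:
        raise ValidationError(f"bin_width must be positive, got {bin_width}")
    lo = float(energies.min())
    hi = float(energies.max())
    n_bins = max(1, int(math.ceil((hi - lo) / bin_width - 1e-12)))
    while lo + n_bins * bin_width < hi:  # guard float round-off at the top edge
        n_bins += 1
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, edges = np.histogram(energies, bins=edges)
    probs = counts / counts.sum()
    return edges, probs


def ensemble_entropy(probabilities) -> float:
    """Gibbs/Shannon entropy −Σ P ln P in nats, with 0·ln 0 ≡ 0."""
    p = np.asarray(probabilities, dtype=float)
    if (p < 0).any():
        raise ValidationError("negative probability in distribution")
    total = p.sum()
    if abs(total - 1.0) > 1e-6:
        raise ValidationError(f"probabilities sum to {total}, not 1")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def bound_state_frequency(result: EnsembleResult, e_bound: float):
    """Frequency of a putative bound-state enthalpy in the unbound ensemble.

    Returns ``(mass, percentile)``: the probability mass of the histogram
    bin containing ``e_bound`` (0 if it lies outside all bins) and the
    percentile of ``e_bound`` within the post-burn-in energy trace
    (fraction of samples ≤ e_bound, ×100).
    """
    edges = result.bin_edges
    probs = result.probabilities
    mass = 0.0
    if edges[0] <= e_bound <= edges[-1]:
        idx = int(np.searchsorted(edges, e_bound, side="right")) - 1
        idx = min(max(idx, 0), len(probs) - 1)
        mass = float(probs[idx])
    percentile = float((result.energies <= e_bound).mean() * 100.0)
    return mass, percentile


def classify_torsion(angle_deg: float) -> str:
    """Classify a dihedral as cis (|θ|≤30°), gauche (30°<|θ|≤120°) or anti."""
    a = abs(normalize_angle(angle_deg))
    if a <= 30.0:
        return "cis"
    if a <= 120.0:
        return "gauche"
    return "anti"


def count_gauche(conf_or_torsions, exclude_frozen: bool = True) -> int:
    """Number of backbone torsions in the gauche class.

    Accepts a :class:`Conformation` or a raw torsion vector in degrees.
    With ``exclude_frozen`` (default) torsions spanning a declared double
    bond are not counted; for raw vectors there is nothing to exclude.
    """
    if isinstance(conf_or_torsions, Conformation):
        torsions = conf_or_torsions.torsions
        frozen = (
            set(conf_or_torsions.topology.frozen_torsions())
            if exclude_frozen
            else set()
        )
    else:
        torsions = np.asarray(conf_or_torsions, dtype=float)
        frozen = set()
    return sum(
        1
        for t, a in enumerate(torsions)
        if t not in frozen and classify_torsion(float(a)) == "gauche"
    )
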