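"""Truth-injected synthetic inputs for every pipeline stage.

Each generator is deterministic given its parameters and seed, emulates
the corresponding experimental design, and returns its ground truth
alongside the data so consuming stages can be validated by parameter
recovery:

* ANS fluorescence titrations — 33 µM start, twelve consecutive 1:3
  dilutions (13 points), 4PL response, multiplicative Gaussian noise
  (plate-reader noise scales with signal);
* FP dilution series — 1 mM start, nineteen consecutive 1:2 dilutions
  scaled by the 18.75/25 in-well mixing ratio (20 points), 20 nM labeled
  probe, depletion-model response;
* HSQC peak-list pairs with injected shift perturbations and broadened
  residues;
* hollow pseudo-atom shells with analytically known cavity volume;
* two-component Gaussian expression cohorts with recorded memberships.
"""

from __future__ import annotations

import math

import numpy as np

from .binding import TitrationSeries, bound_fraction_depletion, four_pl
from .cavity import Structure
from .errors import ValidationError
from .mixture import ExpressionCohort
from .nmr import PeakList

ANS_START_M = 33e-6
ANS_DILUTION = 3.0
ANS_N_DILUTIONS = 12
FP_STOCK_START_M = 1e-3
FP_DILUTION = 2.0
FP_N_DILUTIONS = 19
FP_MIXING_RATIO = 18.75 / 25.0
FP_PROBE_M = 20e-9


def _check_noise(noise):
    if not (0.0 <= noise <= 0.5):
        raise ValidationError(f"noise fraction must be in [0, 0.5], got {noise}")


def ans_concentrations() -> np.ndarray:
    """The 13-point 1:3 dilution ladder starting at 33 µM, in molar."""
    return ANS_START_M / ANS_DILUTION ** np.arange(ANS_N_DILUTIONS + 1)


def fp_concentrations() -> np.ndarray:
    """The 20-point in-well titrant ladder: 1 mM stock, 1:2 × 19, ×18.75/25."""
    stock = FP_STOCK_START_M / FP_DILUTION ** np.arange(FP_N_DILUTIONS + 1)
    return stock * FP_MIXING_RATIO


def gen_ans_titration(true_kd: float, hill: float = 1.0, noise: float = 0.02,
                      bottom: float = 100.0, top: float = 1000.0,
                      flat: bool = False, seed: int = 0):
    """Synthetic ANS-displacement titration.

    ``flat`` emulates the non-binding scenario (constant response at
    ``bottom`` plus noise, zero dynamic range). Returns
    ``(TitrationSeries, truth_dict)``.
    """
    if true_kd <= 0:
        raise ValidationError("true_kd must be positive")
    _check_noise(noise)
    conc = ans_concentrations()
    if flat:
        clean = np.full_like(conc, bottom)
    else:
        clean = four_pl(conc, bottom, top, true_kd, hill)
    rng = np.random.default_rng(seed)
    resp = clean * (1.0 + noise * rng.standard_normal(conc.shape))
    series = TitrationSeries(concentrations=conc, responses=resp)
    truth = {
        "scenario": "ans_flat" if flat else "ans_4pl",
        "true_kd_molar": None if flat else true_kd,
        "hill": hill,
        "bottom": bottom,
        "top": top,
        "noise": noise,
        "seed": seed,
    }
    return series, truth


def gen_fp_series(true_kd: float, probe_total: float = FP_PROBE_M,
                  noise: float = 0.03, fp_free: float = 50.0,
                  fp_bound: float = 250.0, seed: int = 0):
    """Synthetic FP heterodimerization series (depletion model)."""
    if true_kd <= 0:
        raise ValidationError("true_kd must be positive")
    if probe_total <= 0:
        raise ValidationError("probe_total must be positive")
    _check_noise(noise)
    conc = fp_concentrations()
    frac = bound_fraction_depletion(conc, probe_total, true_kd)
    clean = fp_free + (fp_bound - fp_free) * frac
    rng = np.random.default_rng(seed)
    resp = clean * (1.0 + noise * rng.standard_normal(conc.shape))
    series = TitrationSeries(concentrations=conc, responses=resp)
    truth = {
        "scenario": "fp_depletion",
        "true_kd_molar": true_kd,
        "probe_total_molar": probe_total,
        "fp_free": fp_free,
        "fp_bound": fp_bound,
        "noise": noise,
        "seed": seed,
    }
    return series, truth


def gen_hsqc_pair(n_residues: int = 100, perturbed: dict | None = None,
                  broadened=(), shift_noise: float = 0.0,
                  background_csp: float = 0.0, seed: int = 0):
    """Free/bound HSQC peak-list pair with injected perturbations.

    ``perturbed`` maps residue id → (Δδ¹⁵N, Δδ¹H) in ppm; ``broadened``
    residues get bound intensity 0. ``background_csp`` adds small random
    combined-magnitude perturbations to every other residue (drawn
    isotropically in the scaled plane so the combined CSP equals the
    magnitude). Returns ``((free, bound), truth)``.
    """
    perturbed = dict(perturbed or {})
    broadened = list(broadened)
    ids = list(range(1, n_residues + 1))
    bad = [r for r in list(perturbed) + broadened if r not in ids]
    if bad:
        raise ValidationError(f"perturbed/broadened ids {bad} outside 1..{n_residues}")
    rng = np.random.default_rng(seed)
    d1h = rng.uniform(6.0, 10.0, n_residues)
    d15n = rng.uniform(100.0, 135.0, n_residues)
    inten = rng.uniform(0.5e6, 2e6, n_residues)
    import pandas as pd

    free = pd.DataFrame(
        {
            "residue_id": ids,
            "delta_15N_ppm": d15n,
            "delta_1H_ppm": d1h,
            "intensity": inten,
        }
    )
    bound = free.copy()
    for rid in ids:
        i = rid - 1
        if rid in perturbed:
            dn, dh = perturbed[rid]
        elif background_csp > 0:
            mag = abs(rng.normal(0.0, background_csp))
            ang = rng.uniform(0.0, 2.0 * math.pi)
            dn, dh = 10.0 * mag * math.cos(ang), mag * math.sin(ang)
        else:
            dn, dh = 0.0, 0.0
        if shift_noise > 0:
            dn += rng.normal(0.0, shift_noise * 10.0)
            dh += rng.normal(0.0, shift_noise)
        bound.loc[i, "delta_15N_ppm"] += dn
        bound.loc[i, "delta_1H_ppm"] += dh
        if rid in broadened:
            bound.loc[i, "intensity"] = 0.0
    truth = {
        "scenario": "hsqc_pair",
        "n_residues": n_residues,
        "perturbed": {str(k): list(v) for k, v in perturbed.items()},
        "broadened": broadened,
        "background_csp": background_csp,
        "shift_noise": shift_noise,
        "seed": seed,
    }
    return (PeakList(free), PeakList(bound)), truth


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately equidistant unit vectors."""
    i = np.arange(n) + 0.5
    phi = math.pi * (1.0 + math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def gen_cavity_shell(inner_radius: float = 4.0, shell_radius: float = 8.0,
                     probe_in: float = 1.4, site_spacing: float = 0.9,
                     centers=((0.0, 0.0, 0.0),)):
    """Hollow pseudo-atom shell(s) with analytically known void volume.

    Pseudo-atoms sit on a sphere of ``shell_radius`` with radius
    ``shell_radius − inner_radius − probe_in``, so the probe_in-excluded
    interior is exactly a ball of ``inner_radius`` — the analytic truth
    volume is (4/3)·π·inner_radius³ per void. ``inner_radius = 0``
    produces a solid plug with no cavity. Site density is validated to
    seal the shell against the default 4 Å outer probe. Returns
    ``(Structure, truth_dict)``.
    """
    if inner_radius < 0:
        raise ValidationError("inner_radius must be >= 0")
    atom_radius = shell_radius - inner_radius - probe_in
    if atom_radius <= 0:
        raise ValidationError(
            "shell_radius must exceed inner_radius + probe_in "
            f"(got atom radius {atom_radius:.2f} Å)"
        )
    if site_spacing > atom_radius:
        raise ValidationError(
            f"site spacing {site_spacing} Å too sparse to seal a shell of "
            f"atom radius {atom_radius:.2f} Å"
        )
    area = 4.0 * math.pi * shell_radius**2
    n_sites = max(int(math.ceil(area / site_spacing**2 * 1.5)), 16)
    unit = _fibonacci_sphere(n_sites)
    xyz = []
    for c in centers:
        xyz.append(np.asarray(c, dtype=float) + shell_radius * unit)
    xyz = np.vstack(xyz)
    structure = Structure.from_arrays(xyz, atom_radius, element="X",
                                      resname="SHL")
    true_vol = (4.0 / 3.0) * math.pi * inner_radius**3
    truth = {
        "scenario": "cavity_shell",
        "inner_radius": inner_radius,
        "shell_radius": shell_radius,
        "atom_radius": atom_radius,
        "calibrated_probe_in": probe_in,
        "n_voids": len(centers) if inner_radius > 0 else 0,
        "true_volume_A3_per_void": true_vol,
        "centers": [list(c) for c in centers],
    }
    return structure, truth


def gen_solid_slab(nx: int = 8, ny: int = 8, nz: int = 4,
                   spacing: float = 1.5):
    """Close-packed rectangular slab of carbon-like atoms (no cavities)."""
    g = np.mgrid[0:nx, 0:ny, 0:nz].reshape(3, -1).T * spacing
    return Structure.from_arrays(g, 1.7, element="C", resname="SLB")


def gen_expression_cohort(mu1: float = 0.0, mu2: float = 6.0,
                          sigma: float = 1.0, pi2: float = 0.5,
                          n: int = 500, seed: int = 0,
                          label: str = "synthetic"):
    """Two-component Gaussian cohort with recorded memberships.

    ``pi2`` is the probability of the upper (expressing) component and
    must be strictly inside (0, 1). Returns
    ``(ExpressionCohort, truth_dict)`` where the truth carries the
    per-sample component memberships.
    """
    if sigma <= 0:
        raise ValidationError("sigma must be positive")
    if not (0.0 < pi2 < 1.0):
        raise ValidationError(f"mixing weight must be in (0, 1), got {pi2}")
    rng = np.random.default_rng(seed)
    member = rng.random(n) < pi2
    values = np.where(member, mu2, mu1) + sigma * rng.standard_normal(n)
    cohort = ExpressionCohort(
        sample_ids=[f"S{i:04d}" for i in range(n)], values=values, label=label
    )
    truth = {
        "scenario": "expression_cohort",
        "mu1": mu1,
        "mu2": mu2,
        "sigma": sigma,
        "pi2": pi2,
        "n": n,
        "seed": seed,
        "memberships": member.astype(int).tolist(),
    }
    return cohort, truth
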