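"""Dose-response fitting for ligand-binding titrations.

Two models are provided:

* :func:`fit_dose_response` — four-parameter logistic (4PL) on log10
  concentration for the ANS-displacement fluorescence assay; the EC50 is
  reported as the apparent Kd. A fit whose dynamic range is not resolved
  above the residual noise is flagged ``converged = False`` ("no
  binding"), the behaviour expected of a non-binding saturated chain.

* :func:`fit_fp_dimerization` — depletion-corrected one-site binding for
  fluorescence-polarization heterodimerization, where the labeled probe
  (20 nM in the reference design) is comparable to the Kd so the simple
  hyperbola is invalid; the bound fraction comes from the exact quadratic
  solution of P + L ⇌ PL at fixed total probe.

Both use multi-start nonlinear least squares (data-driven starts, Kd grid
over the observed concentration range) and report Jacobian-based standard
errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import ValidationError

_NOISE_RANGE_FACTOR = 3.0  # dynamic range below 3× residual SD ⇒ "no binding"


@dataclass
class TitrationSeries:
    """Concentration–response data for a single titration."""

    concentrations: np.ndarray  # molar; zero allowed only as anchor points
    responses: np.ndarray
    replicate: np.ndarray | None = None

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.concentrations.shape != self.responses.shape:
            raise ValidationError("concentrations and responses differ in length")
        if (self.concentrations < 0).any():
            raise ValidationError("negative concentrations not allowed")
        if self.replicate is not None:
            self.replicate = np.asarray(self.replicate)
            if self.replicate.shape != self.concentrations.shape:
                raise ValidationError("replicate ids differ in length")

    def require_fittable(self, min_distinct: int = 5) -> None:
        nz = self.concentrations[self.concentrations > 0]
        if len(np.unique(nz)) < min_distinct:
            raise ValidationError(
                f"need >= {min_distinct} distinct nonzero concentrations, "
                f"got {len(np.unique(nz))}"
            )

    @classmethod
    def from_csv(cls, path) -> "TitrationSeries":
        df = pd.read_csv(path)
        required = {"concentration_molar", "response"}
        if not required.issubset(df.columns):
            raise ValidationError(
                f"titration CSV must have columns {sorted(required)}"
            )
        rep = df["replicate"].to_numpy() if "replicate" in df.columns else None
        return cls(
            concentrations=df["concentration_molar"].to_numpy(),
            responses=df["response"].to_numpy(),
            replicate=rep,
        )

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            {
                "concentration_molar": self.concentrations,
                "response": self.responses,
                "replicate": (
                    self.replicate
                    if self.replicate is not None
                    else np.ones(len(self.concentrations), dtype=int)
                ),
            }
        )
        df.to_csv(path, index=False)


@dataclass
class DoseResponseFit:
    """Result of a titration fit; ``kd_apparent`` in molar."""

    model: str
    kd_apparent: float
    hill: float
    bottom: float
    top: float
    standard_errors: dict = field(default_factory=dict)
    converged: bool = True
    rss: float = float("nan")
    message: str = ""

    def to_dict(self):
        return {
            "model": self.model,
            "kd_apparent_molar": None if math.isnan(self.kd_apparent) else self.kd_apparent,
            "hill": self.hill,
            "bottom": self.bottom,
            "top": self.top,
            "standard_errors": self.standard_errors,
            "converged": self.converged,
            "rss": self.rss,
            "message": self.message,
        }


def four_pl(conc, bottom, top, kd, hill):
    """4PL response at molar concentration(s), log10 predictor."""
    conc = np.asarray(conc, dtype=float)
    with np.errstate(divide="ignore"):
        logc = np.log10(conc)
    return bottom + (top - bottom) / (
        1.0 + 10.0 ** (hill * (math.log10(kd) - logc))
    )


def bound_fraction_depletion(l_total, probe_total, kd):
    """Exact bound probe fraction of P + L ⇌ PL at fixed total probe."""
    l_total = np.asarray(l_total, dtype=float)
    s = probe_total + l_total + kd
    pl = 0.5 * (s - np.sqrt(np.maximum(s * s - 4.0 * probe_total * l_total, 0.0)))
    return pl / probe_total


def _jacobian_se(res) -> np.ndarray:
    """Standard errors from the least-squares Jacobian at the solution."""
    m, k = res.jac.shape
    dof = max(m - k, 1)
    s2 = 2.0 * res.cost / dof
    try:
        cov = np.linalg.inv(res.jac.T @ res.jac) * s2
        return np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        return np.full(k, np.nan)


def _multistart(residual_fn, starts, bounds):
    best = None
    for x0 in starts:
        try:
            res = least_squares(
                residual_fn, x0, bounds=bounds, xtol=1e-10, ftol=1e-10,
                gtol=1e-10, max_nfev=5000,
            )
        except ValueError:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    return best


def fit_dose_response(series: TitrationSeries) -> DoseResponseFit:
    """Fit the 4PL sigmoid; EC50 reported as apparent Kd.

    Zero-concentration anchor points contribute ``response − bottom``
    residuals (the c→0 asymptote) but stay out of the log-domain
    predictor. The fit is flagged non-binding (``converged = False``)
    when the fitted dynamic range |top − bottom| is below 3× the residual
    standard deviation.
    """
    series.require_fittable()
    conc = series.concentrations
    resp = series.responses
    nz = conc > 0
    c, r = conc[nz], resp[nz]
    r0 = resp[~nz]
    order = np.argsort(c)
    c_s, r_s = c[order], r[order]
    k = max(min(3, len(c_s) // 2), 1)
    bottom0 = float(np.mean(np.concatenate([r_s[:k], r0])) if len(r0) else np.mean(r_s[:k]))
    top0 = float(np.mean(r_s[-k:]))
    scale = max(abs(top0 - bottom0), np.std(resp), 1e-12)

    def residuals(p):
        bottom, top, log10kd, hill = p
        out = four_pl(c, bottom, top, 10.0**log10kd, hill) - r
        if len(r0):
            out = np.concatenate([out, bottom - r0])
        return out

    lo_c, hi_c = math.log10(c.min()), math.log10(c.max())
    starts = [
        np.array([bottom0, top0, lk, 1.0])
        for lk in np.linspace(lo_c, hi_c, 5)
    ]
    bounds = (
        [-np.inf, -np.inf, lo_c - 6.0, 0.01],
        [np.inf, np.inf, hi_c + 6.0, 10.0],
    )
    best = _multistart(residuals, starts, bounds)
    if best is None:
        return DoseResponseFit(
            model="4pl", kd_apparent=float("nan"), hill=float("nan"),
            bottom=float("nan"), top=float("nan"), converged=False,
            message="optimizer failed from every start",
        )
    bottom, top, log10kd, hill = best.x
    n_pts = len(c) + len(r0)
    resid_sd = math.sqrt(2.0 * best.cost / max(n_pts - 4, 1))
    se = _jacobian_se(best)
    kd = 10.0**log10kd
    # realized dynamic range over the observed window — an asymptote the
    # data never approaches must not count as signal
    dynamic = abs(
        four_pl(c.max(), bottom, top, kd, hill)
        - four_pl(c.min(), bottom, top, kd, hill)
    )
    floor = 1e-6 * max(np.abs(resp).max(), 1e-300)  # exactly flat data
    binding = dynamic >= max(_NOISE_RANGE_FACTOR * resid_sd, floor)
    if not binding:
        return DoseResponseFit(
            model="4pl", kd_apparent=float("nan"), hill=hill,
            bottom=bottom, top=top, converged=False,
            rss=2.0 * best.cost,
            message=(
                f"no binding: dynamic range {dynamic:.3g} < "
                f"{_NOISE_RANGE_FACTOR}x residual SD {resid_sd:.3g}"
            ),
        )
    return DoseResponseFit(
        model="4pl",
        kd_apparent=kd,
        hill=hill,
        bottom=bottom,
        top=top,
        standard_errors={
            "bottom": se[0],
            "top": se[1],
            "kd": kd * math.log(10.0) * se[2],
            "hill": se[3],
        },
        converged=True,
        rss=2.0 * best.cost,
    )


def fit_fp_dimerization(series: TitrationSeries, probe_total: float) -> DoseResponseFit:
    """Fit the depletion-corrected one-site model to an FP dilution series.

    ``probe_total`` is the fixed labeled-probe concentration in molar
    (20 nM in the reference design). Parameters are Kd and the free/bound
    polarization plateaus.
    """
    if probe_total <= 0:
        raise ValidationError("probe_total must be positive")
    series.require_fittable()
    conc = series.concentrations
    resp = series.responses
    nz = conc > 0
    c, r = conc[nz], resp[nz]
    r0 = resp[~nz]
    order = np.argsort(c)
    c_s, r_s = c[order], r[order]
    k = max(min(3, len(c_s) // 2), 1)
    fp_free0 = float(np.mean(np.concatenate([r_s[:k], r0])) if len(r0) else np.mean(r_s[:k]))
    fp_bound0 = float(np.mean(r_s[-k:]))

    def residuals(p):
        fp_free, fp_bound, log10kd = p
        frac = bound_fraction_depletion(c, probe_total, 10.0**log10kd)
        out = fp_free + (fp_bound - fp_free) * frac - r
        if len(r0):
            out = np.concatenate([out, fp_free - r0])
        return out

    lo_c, hi_c = math.log10(c.min()), math.log10(c.max())
    starts = [
        np.array([fp_free0, fp_bound0, lk]) for lk in np.linspace(lo_c, hi_c, 5)
    ]
    bounds = ([-np.inf, -np.inf, lo_c - 6.0], [np.inf, np.inf, hi_c + 6.0])
    best = _multistart(residuals, starts, bounds)
    if best is None:
        return DoseResponseFit(
            model="fp_depletion", kd_apparent=float("nan"), hill=1.0,
            bottom=float("nan"), top=float("nan"), converged=False,
            message="optimizer failed from every start",
        )
    fp_free, fp_bound, log10kd = best.x
    n_pts = len(c) + len(r0)
    resid_sd = math.sqrt(2.0 * best.cost / max(n_pts - 3, 1))
    se = _jacobian_se(best)
    kd = 10.0**log10kd
    frac_ends = bound_fraction_depletion(
        np.array([c.min(), c.max()]), probe_total, kd
    )
    dynamic = abs((fp_bound - fp_free) * (frac_ends[1] - frac_ends[0]))
    floor = 1e-6 * max(np.abs(resp).max(), 1e-300)
    if dynamic < max(_NOISE_RANGE_FACTOR * resid_sd, floor):
        return DoseResponseFit(
            model="fp_depletion", kd_apparent=float("nan"), hill=1.0,
            bottom=fp_free, top=fp_bound, converged=False,
            rss=2.0 * best.cost,
            message=(
                f"no binding: dynamic range {dynamic:.3g} < "
                f"{_NOISE_RANGE_FACTOR}x residual SD {resid_sd:.3g}"
            ),
        )
    return DoseResponseFit(
        model="fp_depletion",
        kd_apparent=kd,
        hill=1.0,
        bottom=fp_free,
        top=fp_bound,
        standard_errors={
            "fp_free": se[0],
            "fp_bound": se[1],
            "kd": kd * math.log(10.0) * se[2],
        },
        converged=True,
        rss=2.0 * best.cost,
    )
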