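"""Expression dichotomization by a common-variance two-Gaussian mixture.

Each tumor cohort's per-sample expression of a single transcript is
modelled as a mixture of two univariate Gaussians sharing one variance
("fixed variance" in the mclust sense of the equal-variance model
family — the variance is a free parameter, common to both components,
not a hard-coded number). The model is fitted by expectation–
maximization; samples are labelled *expressing* when their posterior
probability of the upper component is ≥ 0.5. Cohorts whose mean
expression is not strictly above a threshold (default 5) are excluded
before fitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

_SQRT2PI = math.sqrt(2.0 * math.pi)


@dataclass
class ExpressionCohort:
    """Per-sample expression values of one transcript in one cohort."""

    sample_ids: list
    values: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.sample_ids) != len(self.values):
            raise ValidationError("sample_ids and values differ in length")
        if not np.isfinite(self.values).all():
            raise ValidationError("non-finite expression values")

    def __len__(self):
        return len(self.values)

    @property
    def mean_expression(self) -> float:
        return float(self.values.mean())

    @classmethod
    def from_csv(cls, path, label: str = "") -> "ExpressionCohort":
        df = pd.read_csv(path)
        if not {"sample_id", "expression"}.issubset(df.columns):
            raise ValidationError(
                "expression CSV must have columns sample_id, expression"
            )
        return cls(
            sample_ids=df["sample_id"].astype(str).tolist(),
            values=df["expression"].to_numpy(),
            label=label,
        )


def filter_cohorts(cohorts, mean_threshold: float = 5.0):
    """Keep cohorts whose mean expression is strictly above the threshold."""
    if not math.isfinite(mean_threshold):
        raise ValidationError("mean threshold must be finite")
    return [c for c in cohorts if c.mean_expression > mean_threshold]


@dataclass
class MixtureFit:
    """Equal-variance two-component Gaussian mixture fit (μ₁ < μ₂)."""

    mu1: float
    mu2: float
    sigma2: float
    weight2: float  # mixing weight π of the upper (expressing) component
    posteriors: np.ndarray = field(repr=False)  # P(component 2 | x)
    log_likelihood: float
    ll_trace: np.ndarray = field(repr=False)
    n_iterations: int
    converged: bool

    @property
    def labels(self) -> np.ndarray:
        """Boolean per-sample labels: True = expressing (posterior ≥ 0.5)."""
        return self.posteriors >= 0.5

    def to_dict(self):
        return {
            "mu1": self.mu1,
            "mu2": self.mu2,
            "sigma2": self.sigma2,
            "weight_expressing": self.weight2,
            "log_likelihood": self.log_likelihood,
            "n_iterations": self.n_iterations,
            "converged": self.converged,
            "n_expressing": int(self.labels.sum()),
            "n_samples": int(len(self.posteriors)),
        }


def _em_once(x, mu1, mu2, sigma2, pi2, max_iter, tol):
    n = len(x)
    ll_trace = []
    ll_prev = -np.inf
    converged = False
    it = 0
    var_floor = max(x.var(), 1.0) * 1e-10
    for it in range(1, max_iter + 1):
        sigma = math.sqrt(max(sigma2, var_floor))
        d1 = (1.0 - pi2) * np.exp(-0.5 * (x - mu1) ** 2 / sigma2) / (sigma * _SQRT2PI)
        d2 = pi2 * np.exp(-0.5 * (x - mu2) ** 2 / sigma2) / (sigma * _SQRT2PI)
        tot = d1 + d2
        tot = np.where(tot > 0, tot, np.finfo(float).tiny)
        ll = float(np.log(tot).sum())
        ll_trace.append(ll)
        gamma = d2 / tot
        if ll - ll_prev < tol and it > 1:
            converged = True
            break
        ll_prev = ll
        n2 = gamma.sum()
        n1 = n - n2
        if n1 <= 0 or n2 <= 0:
            break
        mu1 = float((x * (1 - gamma)).sum() / n1)
        mu2 = float((x * gamma).sum() / n2)
        sigma2 = float(
            ((1 - gamma) * (x - mu1) ** 2 + gamma * (x - mu2) ** 2).sum() / n
        )
        sigma2 = max(sigma2, var_floor)
        pi2 = float(n2 / n)
    return mu1, mu2, sigma2, pi2, gamma, ll_trace, it, converged


def fit_two_component_gmm(values, seed: int = 0, max_iter: int = 1000,
                          tol: float = 1e-8, n_restarts: int = 5) -> MixtureFit:
    """EM fit of the equal-variance two-component univariate mixture.

    Initialization is a median split (means of the lower/upper halves,
    pooled variance, π = 0.5); ``n_restarts − 1`` additional seeded
    restarts jitter the initial means by up to half a standard deviation
    and the best log-likelihood fit is kept. Components are ordered so
    that μ₁ < μ₂ and the reported weight/posteriors refer to the upper
    component.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 10:
        raise ValidationError(f"need >= 10 samples to fit a mixture, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValidationError("all values identical; mixture is degenerate")
    med = np.median(x)
    lower = x[x <= med]
    upper = x[x > med]
    if len(upper) == 0:  # heavy ties at the median
        lower = x[x < med] if (x < med).any() else x[:1]
        upper = x[x >= med]
    mu1_0, mu2_0 = float(lower.mean()), float(upper.mean())
    sigma2_0 = float(
        (((lower - mu1_0) ** 2).sum() + ((upper - mu2_0) ** 2).sum()) / len(x)
    )
    sigma2_0 = max(sigma2_0, x.var() * 1e-6, 1e-12)
    sd = math.sqrt(x.var()) or 1.0
    rng = np.random.default_rng(seed)
    best = None
    for restart in range(max(n_restarts, 1)):
        if restart == 0:
            m1, m2 = mu1_0, mu2_0
        else:
            m1 = mu1_0 + rng.uniform(-0.5, 0.5) * sd
            m2 = mu2_0 + rng.uniform(-0.5, 0.5) * sd
        m1, m2 = min(m1, m2), max(m1, m2)
        out = _em_once(x, m1, m2, sigma2_0, 0.5, max_iter, tol)
        if best is None or out[5][-1] > best[5][-1]:
            best = out
    mu1, mu2, sigma2, pi2, gamma, ll_trace, n_iter, converged = best
    if mu1 > mu2:  # order components; posterior refers to the upper one
        mu1, mu2 = mu2, mu1
        pi2 = 1.0 - pi2
        gamma = 1.0 - gamma
    return MixtureFit(
        mu1=mu1,
        mu2=mu2,
        sigma2=sigma2,
        weight2=pi2,
        posteriors=gamma,
        log_likelihood=ll_trace[-1],
        ll_trace=np.asarray(ll_trace),
        n_iterations=n_iter,
        converged=converged,
    )


def classify_samples(fit: MixtureFit) -> np.ndarray:
    """Boolean labels per sample: True = expressing (posterior ≥ 0.5)."""
    return fit.labels


def dichotomize_cohort(cohort: ExpressionCohort, seed: int = 0,
                       **fit_kwargs) -> tuple[MixtureFit, pd.DataFrame]:
    """Fit a cohort and return the per-sample label table."""
    fit = fit_two_component_gmm(cohort.values, seed=seed, **fit_kwargs)
    table = pd.DataFrame(
        {
            "sample_id": cohort.sample_ids,
            "expression": cohort.values,
            "posterior_expressing": fit.posteriors,
            "label": np.where(fit.labels, "expressing", "non-expressing"),
        }
    )
    return fit, table
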