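"""Three-component Gaussian mixture on SNP read ratios and ploidy calling.

A histogram of reference-read fractions is summarized by an EM fit of a
fixed three-component univariate Gaussian mixture started from means
(0.25, 0.5, 0.75) and standard deviation 0.05 per component.  The
mixing weights (lambda) act as relative peak heights: the peak ratio
statistic compares the outer peaks (0.25 and 0.75, populated by dosage
1-of-4 / 3-of-4 genotypes or collapsed paralogs) to the central 0.5
peak.  Diploids score well below 1; functional tetraploids at or above 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm

from .snp_ratio import RatioSet

SIGMA_FLOOR = 1e-4

CATEGORIES = ("diploid-like", "intermediate", "tetraploid-like")


@dataclass(frozen=True)
class MixtureFit:
    """A fitted 3-component univariate Gaussian mixture.

    Components are reported sorted by mean.  ``loglik_trace`` records the
    log-likelihood after every EM iteration (non-decreasing by
    construction of EM; asserted in the test suite).
    """

    mu: np.ndarray
    sigma: np.ndarray
    lam: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    loglik_trace: np.ndarray = field(repr=False, default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        if abs(float(np.sum(self.lam)) - 1.0) > 1e-9:
            raise ValueError("mixing weights must sum to 1")
        if np.any(self.sigma <= 0):
            raise ValueError("sigmas must be positive")
        if not np.all(np.diff(self.mu) >= 0):
            raise ValueError("components must be sorted by mean")


@dataclass(frozen=True)
class PloidyCall:
    """Per-sample peak-ratio statistic and its categorical reading."""

    sample: str
    peak_ratio: float
    category: str

    def __post_init__(self) -> None:
        if self.peak_ratio < 0:
            raise ValueError("peak ratio must be non-negative")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def _em(
    x: np.ndarray,
    mu: np.ndarray,
    sigma: np.ndarray,
    lam: np.ndarray,
    tol: float,
    max_iter: int,
    fixed_means: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, int, bool]:
    n = len(x)
    trace = []
    prev = -np.inf
    converged = False
    degenerate = False
    for it in range(1, max_iter + 1):
        logp = np.log(lam)[:, None] + norm.logpdf(x[None, :], mu[:, None], sigma[:, None])
        lse = logsumexp(logp, axis=0)
        loglik = float(np.sum(lse))
        trace.append(loglik)
        resp = np.exp(logp - lse[None, :])  # (3, n)
        nk = resp.sum(axis=1)
        lam = nk / n
        if not fixed_means:
            mu = np.where(nk > 0, resp @ x / np.maximum(nk, 1e-300), mu)
        var = (resp * (x[None, :] - mu[:, None]) ** 2).sum(axis=1) / np.maximum(nk, 1e-300)
        sigma = np.sqrt(np.maximum(var, 0.0))
        if np.any(sigma < SIGMA_FLOOR):
            # a component collapsing onto few points: floor and flag
            sigma = np.maximum(sigma, SIGMA_FLOOR)
            degenerate = True
        if prev > -np.inf and loglik - prev < tol * abs(prev):
            converged = True
            break
        prev = loglik
    # score the final parameters (the trace above lags one M-step behind)
    logp = np.log(np.maximum(lam, 1e-300))[:, None] + norm.logpdf(x[None, :], mu[:, None], sigma[:, None])
    trace.append(float(np.sum(logsumexp(logp, axis=0))))
    return mu, sigma, lam, np.array(trace), it, converged and not degenerate


def fit_three_component_gmm(
    ratios: RatioSet | np.ndarray,
    init_mu: Sequence[float] = (0.25, 0.5, 0.75),
    init_sigma: float = 0.05,
    tol: float = 1e-8,
    max_iter: int = 1000,
    fixed_means: bool = False,
) -> MixtureFit:
    """EM fit of the k=3 mixture from the fixed deterministic start.

    Means, standard deviations and weights are all free (``fixed_means``
    pins the means to their starting values for samples where the outer
    peaks carry almost no mass).  The fit is deterministic given the
    data: the initialization is fixed and no random restarts are used.
    """
    x = np.asarray(ratios.ratios if isinstance(ratios, RatioSet) else ratios, dtype=float)
    if len(x) < 30:
        raise ValueError(f"need at least 30 ratios to fit, got {len(x)}")
    init_mu = np.asarray(init_mu, dtype=float)
    if init_mu.shape != (3,) or np.any(init_mu <= 0) or np.any(init_mu >= 1):
        raise ValueError("init_mu must be three values inside (0, 1)")
    if init_sigma <= 0:
        raise ValueError("init_sigma must be positive")

    mu, sigma, lam, trace, n_iter, converged = _em(
        x,
        init_mu.copy(),
        np.full(3, float(init_sigma)),
        np.full(3, 1 / 3),
        tol,
        max_iter,
        fixed_means,
    )
    order = np.argsort(mu)
    return MixtureFit(
        mu=mu[order],
        sigma=sigma[order],
        lam=lam[order] / lam.sum(),
        loglik=float(trace[-1]),
        n_iter=n_iter,
        converged=converged,
        loglik_trace=trace,
    )


def peak_ratio(fit: MixtureFit, inverse: bool = False) -> float:
    """Outer-to-central peak-weight ratio: mean(lam_low, lam_high) / lam_mid.

    Low values mean a dominant 0.5 peak (diploid-like); values near or
    above 1 mean the 0.25/0.75 peaks rival the central one
    (tetraploid-like).  ``inverse=True`` returns central/outer instead.
    """
    lam_low, lam_mid, lam_high = map(float, fit.lam)
    minor = 0.5 * (lam_low + lam_high)
    num, den = (lam_mid, minor) if inverse else (minor, lam_mid)
    if den == 0:
        warnings.warn("denominator peak weight is zero; peak ratio is infinite")
        return float("inf")
    return num / den


def species_ratio(calls: Sequence[PloidyCall | float]) -> float:
    """Arithmetic mean of individual peak ratios (typically 2 per species)."""
    if len(calls) == 0:
        raise ValueError("need at least one individual")
    vals = [c.peak_ratio if isinstance(c, PloidyCall) else float(c) for c in calls]
    return float(np.mean(vals))


def classify_ploidy(species_mean_ratio: float, t_low: float = 0.45, t_high: float = 0.9) -> str:
    """Map a species-mean peak ratio onto a ploidy category.

    Default thresholds sit midway between the observed empirical groups
    (roughly 0.25-0.4, 0.53-0.72 and 1.02-1.18); they are configuration,
    not constants of the method.
    """
    if species_mean_ratio < 0:
        raise ValueError("peak ratio cannot be negative")
    if not 0 < t_low < t_high:
        raise ValueError("thresholds must satisfy 0 < t_low < t_high")
    if species_mean_ratio < t_low:
        return "diploid-like"
    if species_mean_ratio < t_high:
        return "intermediate"
    return "tetraploid-like"


def call_sample(ratios: RatioSet, t_low: float = 0.45, t_high: float = 0.9, **fit_kwargs) -> tuple[MixtureFit, PloidyCall]:
    """Fit the mixture for one sample and classify its peak ratio."""
    fit = fit_three_component_gmm(ratios, **fit_kwargs)
    pr = peak_ratio(fit)
    return fit, PloidyCall(sample=ratios.sample, peak_ratio=pr, category=classify_ploidy(pr, t_low, t_high))


def plot_ratio_histogram(ratios: RatioSet, fit: MixtureFit | None = None, ax=None, bins: int = 60):
    """Histogram of read ratios with the fitted mixture density overlaid."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.hist(ratios.ratios, bins=bins, range=(0, 1), density=True, alpha=0.6, color="steelblue")
    if fit is not None:
        grid = np.linspace(0, 1, 400)
        dens = np.zeros_like(grid)
        for m, s, l in zip(fit.mu, fit.sigma, fit.lam):
            comp = l * norm.pdf(grid, m, s)
            ax.plot(grid, comp, lw=1, ls="--", color="grey")
            dens += comp
        ax.plot(grid, dens, lw=2, color="firebrick")
    ax.set_xlabel("reference-read fraction")
    ax.set_ylabel("density")
    ax.set_title(ratios.sample)
    return ax
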