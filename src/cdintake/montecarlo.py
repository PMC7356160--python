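"""Lognormal modeling and Monte Carlo simulation of weekly Cd intake.

Weekly intake per body weight is right-skewed and modelled as lognormal.
A fit carries (mu, sigma) on the natural-log scale, obtained either by
maximum likelihood from a cohort of positive intakes or by quantile matching
from a printed median and quartiles. The simulation draws ``n_reps``
(default 10,000) values and summarises them by median, 5th/95th percentiles
and range; the closed-form upper-tail probability at the tolerable weekly
intake gives the model-based exceedance fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps

DEFAULT_N_REPS = 10_000

# upper-quartile of the standard normal (≈ 0.67449)
_Z75 = float(sps.norm.ppf(0.75))


class MonteCarloError(ValueError):
    pass


@dataclass(frozen=True)
class LognormalFit:
    mu: float  # mean of ln(intake)
    sigma: float  # sd of ln(intake), > 0
    method: Literal["mle", "quantile_match"]
    n_source: int | None = None

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise MonteCarloError(f"degenerate lognormal fit: sigma = {self.sigma}")

    @property
    def median(self) -> float:
        return float(np.exp(self.mu))

    def quantile(self, q: float) -> float:
        return float(np.exp(self.mu + self.sigma * sps.norm.ppf(q)))


@dataclass(frozen=True)
class SimulationSummary:
    n_reps: int
    median: float
    p5: float
    p95: float
    minimum: float
    maximum: float
    seed: int | None = None


def fit_lognormal_mle(values: Sequence[float]) -> LognormalFit:
    """mu = mean of logs, sigma = sd of logs (n−1 denominator).

    Intended for use after outlier screening; every value must be positive.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise MonteCarloError("fit_lognormal_mle needs n >= 2")
    bad = np.nonzero(arr <= 0)[0]
    if bad.size:
        raise MonteCarloError(f"nonpositive value at index {int(bad[0])}")
    logs = np.log(arr)
    sigma = float(logs.std(ddof=1))
    if sigma == 0.0:
        raise MonteCarloError("degenerate fit: all values identical (sigma = 0)")
    return LognormalFit(mu=float(logs.mean()), sigma=sigma, method="mle", n_source=arr.size)


def fit_lognormal_quantiles(q25: float, median: float, q75: float) -> LognormalFit:
    """Fit from a printed median and quartiles: mu = ln(median),
    sigma = ln(q75/q25) / (2·z₀.₇₅)."""
    if not (0.0 < q25 < median < q75):
        raise MonteCarloError("quantiles must satisfy 0 < q25 < median < q75")
    mu = float(np.log(median))
    sigma = float(np.log(q75 / q25) / (2.0 * _Z75))
    return LognormalFit(mu=mu, sigma=sigma, method="quantile_match")


def simulate(
    fit: LognormalFit, n_reps: int = DEFAULT_N_REPS, seed: int | None = None
) -> np.ndarray:
    """Draw ``n_reps`` independent lognormal(mu, sigma) intakes; same seed,
    same draws."""
    if n_reps < 1:
        raise MonteCarloError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    return np.exp(rng.normal(fit.mu, fit.sigma, size=n_reps))


def summarize_simulation(draws: Sequence[float], seed: int | None = None) -> SimulationSummary:
    arr = np.asarray(draws, dtype=float)
    if arr.size == 0:
        raise MonteCarloError("no draws to summarize")
    p5, med, p95 = np.percentile(arr, [5, 50, 95])  # linear interpolation
    return SimulationSummary(
        n_reps=int(arr.size),
        median=float(med),
        p5=float(p5),
        p95=float(p95),
        minimum=float(arr.min()),
        maximum=float(arr.max()),
        seed=seed,
    )


def tail_probability(fit: LognormalFit, threshold: float = 7.0) -> float:
    """P(intake ≥ threshold) under the fitted lognormal:
    1 − Φ((ln threshold − mu)/sigma)."""
    if threshold <= 0:
        raise MonteCarloError("threshold must be > 0")
    z = (np.log(threshold) - fit.mu) / fit.sigma
    return float(sps.norm.sf(z))
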