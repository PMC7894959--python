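"""Scalar stochastic population viability analysis.

A single-population count model with environmental stochasticity (lognormal
annual growth multipliers) and optional demographic stochasticity (Poisson
realised abundance, or a Binomial-survivor + Poisson-recruit decomposition
when an adult survival rate is supplied). Density independence throughout:
the model projects a small census forward and reports the probability of
falling to or below an absorbing quasi-extinction threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .demography import growth_ratios

__all__ = ["PVAConfig", "PVAResult", "fit_growth", "simulate", "extinction_risk",
           "plot_trajectories"]


@dataclass
class PVAConfig:
    """Settings for one stochastic projection."""

    n0: int
    horizon_years: int = 50
    n_replicates: int = 10_000
    growth_mean: float = 1.0  # arithmetic mean of the annual multiplier
    growth_sd: float = 0.0  # arithmetic sd of the annual multiplier
    survival_rate: Optional[float] = None  # Sa; enables survivor/recruit split
    demographic_stochasticity: bool = True
    extinction_threshold: int = 0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n0 < 0:
            raise ValueError("n0 must be >= 0")
        if self.horizon_years < 1:
            raise ValueError("horizon_years must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.growth_sd < 0:
            raise ValueError("growth_sd must be >= 0")
        if self.survival_rate is not None and not 0.0 <= self.survival_rate <= 1.0:
            raise ValueError("survival_rate must lie in [0, 1]")

    def lognormal_params(self) -> tuple[float, float]:
        """(mu, sigma) of the lognormal matching the arithmetic mean/sd."""
        if self.growth_mean <= 0:
            raise ValueError("growth_mean must be > 0")
        if self.growth_sd == 0:
            return math.log(self.growth_mean), 0.0
        cv2 = (self.growth_sd / self.growth_mean) ** 2
        sigma2 = math.log(1.0 + cv2)
        mu = math.log(self.growth_mean) - sigma2 / 2.0
        return mu, math.sqrt(sigma2)


@dataclass
class PVAResult:
    """Trajectory ensemble summary and extinction-risk curve."""

    config: PVAConfig
    years: np.ndarray  # 0..horizon
    mean: np.ndarray
    sd: np.ndarray
    min: np.ndarray
    max: np.ndarray
    risk: np.ndarray  # cumulative extinction probability per year
    terminal_sizes: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "years": self.years.tolist(),
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "min": self.min.tolist(),
            "max": self.max.tolist(),
            "risk": self.risk.tolist(),
        }


def fit_growth(census_series: Sequence[float]) -> dict:
    """Estimate annual growth-multiplier distribution from a census series.

    Returns arithmetic and log-scale mean/sd of the year-to-year ratios
    R_t = N(t+1)/N(t).
    """
    ratios = growth_ratios(census_series)
    if ratios.size < 2:
        raise ValueError("need >= 2 ratios (>= 3 census years) for an sd")
    logs = np.log(ratios)
    return {
        "ratios": ratios,
        "mean": float(ratios.mean()),
        "sd": float(ratios.std(ddof=1)),
        "log_mean": float(logs.mean()),
        "log_sd": float(logs.std(ddof=1)),
    }


def simulate(config: PVAConfig) -> PVAResult:
    """Run the stochastic projection.

    Each year draws an environmental multiplier R_t ~ lognormal matched to
    (growth_mean, growth_sd). With demographic stochasticity the realised
    abundance is Poisson(R_t · N); when a survival rate Sa is supplied the
    draw instead decomposes into Binomial(N, Sa) survivors plus
    Poisson(N · max(R_t − Sa, 0)) recruits, so adult persistence is binomial
    and only the recruitment part is Poisson. Trajectories absorb at
    N ≤ extinction_threshold.
    """
    rng = np.random.default_rng(config.seed)
    mu, sigma = config.lognormal_params()
    T = config.horizon_years
    nrep = config.n_replicates
    N = np.full(nrep, config.n0, dtype=np.int64)
    absorbed = N <= config.extinction_threshold
    N[absorbed] = 0
    traj = np.zeros((T + 1, nrep), dtype=np.int64)
    traj[0] = N
    risk = np.zeros(T + 1)
    risk[0] = absorbed.mean()
    for t in range(1, T + 1):
        R = np.exp(rng.normal(mu, sigma, size=nrep)) if sigma > 0 else np.full(
            nrep, config.growth_mean
        )
        expected = R * N
        if config.demographic_stochasticity:
            if config.survival_rate is not None:
                Sa = config.survival_rate
                survivors = rng.binomial(N, min(Sa, 1.0) * np.ones(nrep))
                recruit_mean = np.maximum(expected - Sa * N, 0.0)
                newN = survivors + rng.poisson(recruit_mean)
            else:
                newN = rng.poisson(expected)
        else:
            newN = np.rint(expected).astype(np.int64)
        newN = np.where(absorbed, 0, newN)
        absorbed = absorbed | (newN <= config.extinction_threshold)
        newN = np.where(absorbed, 0, newN)
        N = newN.astype(np.int64)
        traj[t] = N
        risk[t] = absorbed.mean()
    return PVAResult(
        config=config,
        years=np.arange(T + 1),
        mean=traj.mean(axis=1),
        sd=traj.std(axis=1, ddof=0),
        min=traj.min(axis=1),
        max=traj.max(axis=1),
        risk=risk,
        terminal_sizes=traj[-1].copy(),
    )


def extinction_risk(
    result: PVAResult, year: int, ci_level: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Cumulative extinction probability by ``year`` with exact binomial CI."""
    if not 0 <= year <= result.config.horizon_years:
        raise ValueError(f"year {year} outside horizon")
    p = float(result.risk[year])
    n = result.config.n_replicates
    k = round(p * n)
    alpha = 1.0 - ci_level
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return p, (lo, hi)


def plot_trajectories(result: PVAResult, ax=None):
    """Mean ±1 sd band with min/max dots, one panel per projection."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    y = result.years
    ax.plot(y, result.mean, "-", color="black", label="mean")
    ax.fill_between(
        y,
        np.maximum(result.mean - result.sd, 0),
        result.mean + result.sd,
        alpha=0.3,
        color="grey",
        label="±1 sd",
    )
    ax.plot(y, result.min, ".", color="steelblue", label="min")
    ax.plot(y, result.max, ".", color="firebrick", label="max")
    ax.set_xlabel("year")
    ax.set_ylabel("mature individuals")
    ax.legend()
    return ax
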