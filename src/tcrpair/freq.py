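"""Maximum-likelihood estimation of clone frequencies from well occupancy.

A clone present at frequency f in the parent population is absent from a
well of n cells either because no cell of the clone was drawn or because
every drawn copy of at least one of its chains failed to be sequenced
(drop rate ε per chain instance).  Summing the binomial sampling
distribution against the per-chain detection terms gives a closed form for
the absence probability q:

    single pair (two chains):  q = 2(1-f+fε)^n - (1-f+fε²)^n
    dual-α clone (three chains): q = 3(1-f+fε)^n - 3(1-f+fε²)^n + (1-f+fε³)^n

The likelihood of the observed per-well-size occupancy counts is a product
of binomials in (1-q); the MLE is found by bounded scalar optimisation on
logit(f) and 95% confidence intervals are the frequencies where the
log-likelihood falls 1.96 below its maximum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.optimize import brentq, minimize_scalar
from scipy.special import expit, gammaln, logit

from .simdata import WellDataset

__all__ = [
    "OccupancyCounts",
    "FrequencyEstimate",
    "occupancy_counts",
    "well_absence_prob",
    "clone_loglik",
    "estimate_frequency",
]

_CI_OFFSET = 1.96  # logL drop defining the 95% interval


@dataclass(frozen=True)
class OccupancyCounts:
    """Occupancy of a clone's chains across wells, grouped by sample size:
    for each distinct size n_l, the number of wells w_l and the number k_l of
    those wells containing all of the clone's chains."""

    sizes: tuple[int, ...]
    wells: tuple[int, ...]
    hits: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (len(self.sizes) == len(self.wells) == len(self.hits)):
            raise ValueError("sizes, wells and hits must have equal length")
        if len(set(self.sizes)) != len(self.sizes):
            raise ValueError("duplicate well sizes")
        for n, w, k in zip(self.sizes, self.wells, self.hits):
            if n <= 0 or w <= 0:
                raise ValueError("sizes and well counts must be positive")
            if not 0 <= k <= w:
                raise ValueError("hits must lie in [0, wells]")

    @property
    def total_hits(self) -> int:
        return sum(self.hits)

    @property
    def total_wells(self) -> int:
        return sum(self.wells)


def occupancy_counts(data: WellDataset, chains: Iterable[str]) -> OccupancyCounts:
    """Count, per distinct well size, the wells containing *all* of the given
    chain ids (α or β; a dual clone requires all three of its chains)."""
    chains = list(chains)
    if not chains:
        raise ValueError("no chains given")
    sizes: dict[int, int] = {}
    hits: dict[int, int] = {}
    for w in data:
        present = w.alpha_set | w.beta_set
        sizes[w.size] = sizes.get(w.size, 0) + 1
        if all(c in present for c in chains):
            hits[w.size] = hits.get(w.size, 0) + 1
    ns = sorted(sizes)
    return OccupancyCounts(
        sizes=tuple(ns),
        wells=tuple(sizes[n] for n in ns),
        hits=tuple(hits.get(n, 0) for n in ns),
    )


@dataclass(frozen=True)
class FrequencyEstimate:
    """A clonal frequency MLE with its 95% profile-likelihood interval."""

    f_hat: float
    ci_low: float
    ci_high: float
    loglik_max: float
    epsilon_used: float
    mode: str = "single"

    def __post_init__(self) -> None:
        if not 0.0 < self.f_hat <= 1.0:
            raise ValueError("f_hat must lie in (0, 1]")
        if not self.ci_low <= self.f_hat <= self.ci_high:
            raise ValueError("CI must bracket the point estimate")

    @property
    def sigma_hat(self) -> float:
        """Quadratic-approximation standard error: CI width / 3.92."""
        return (self.ci_high - self.ci_low) / 3.92

    @property
    def cv(self) -> float:
        """Coefficient of variation of the estimate, σ̂ / f̂."""
        return self.sigma_hat / self.f_hat


def well_absence_prob(
    f: float | np.ndarray,
    n: int | np.ndarray,
    eps: float,
    mode: str = "single",
) -> float | np.ndarray:
    """Probability q that a clone of frequency ``f`` is *not* detected in a
    well of ``n`` cells, with per-chain-instance drop rate ``eps``.

    ``mode="single"`` treats the clone as a two-chain (α, β) pair;
    ``mode="dual"`` as a three-chain (α, α, β) clone, which must show all
    three chains to count as detected.
    """
    f = np.asarray(f, dtype=float)
    n = np.asarray(n)
    if np.any(f < 0) or np.any(f > 1):
        raise ValueError("f must lie in [0, 1]")
    if not 0.0 <= eps < 1.0:
        raise ValueError("eps must lie in [0, 1)")
    if np.any(n < 1):
        raise ValueError("n must be >= 1")
    g1 = (1.0 - f + f * eps) ** n
    g2 = (1.0 - f + f * eps**2) ** n
    if mode == "single":
        q = 2.0 * g1 - g2
    elif mode == "dual":
        g3 = (1.0 - f + f * eps**3) ** n
        q = 3.0 * g1 - 3.0 * g2 + g3
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return np.clip(q, 0.0, 1.0) if q.ndim else float(min(max(q, 0.0), 1.0))


def clone_loglik(
    f: float, counts: OccupancyCounts, eps: float, mode: str = "single"
) -> float:
    """Log-likelihood of the occupancy counts at clone frequency ``f``.

    Includes the binomial coefficients; returns -inf where an observed
    outcome has probability zero.
    """
    n = np.array(counts.sizes)
    w = np.array(counts.wells, dtype=float)
    k = np.array(counts.hits, dtype=float)
    q = np.asarray(well_absence_prob(f, n, eps, mode=mode))
    ll = gammaln(w + 1) - gammaln(k + 1) - gammaln(w - k + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        hit_term = np.where(k > 0, k * np.log1p(-q), 0.0)
        miss_term = np.where(w - k > 0, (w - k) * np.log(q), 0.0)
    total = ll + hit_term + miss_term
    if np.any(np.isnan(total)) or np.any(np.isneginf(total)):
        return float("-inf")
    return float(total.sum())


def estimate_frequency(
    counts: OccupancyCounts, eps: float = 0.15, mode: str = "single"
) -> FrequencyEstimate:
    """Maximise the occupancy likelihood over f in (0, 1] and bracket the 95%
    interval by bisection on logL(f) = logL_max - 1.96 on each side, clamping
    endpoints at the domain boundary."""
    if counts.total_hits == 0:
        raise ValueError(
            "clone was never observed; frequency is not estimable from "
            "all-zero occupancy counts"
        )
    f_lo = 1e-12

    def nll(t: float) -> float:
        return -clone_loglik(float(expit(t)), counts, eps, mode)

    if counts.total_hits == counts.total_wells:
        # seen in every well: likelihood is maximised at the boundary f = 1
        f_hat = 1.0
        ll_max = clone_loglik(1.0, counts, eps, mode)
    else:
        res = minimize_scalar(
            nll, bounds=(logit(f_lo), logit(1 - 1e-12)), method="bounded",
            options={"xatol": 1e-10},
        )
        f_hat = float(expit(res.x))
        ll_max = -float(res.fun)
        if clone_loglik(1.0, counts, eps, mode) >= ll_max:
            f_hat, ll_max = 1.0, clone_loglik(1.0, counts, eps, mode)

    target = ll_max - _CI_OFFSET

    def g(f: float) -> float:
        return clone_loglik(f, counts, eps, mode) - target

    if f_hat <= f_lo * 10 or g(f_lo) >= 0:
        ci_low = 0.0
    else:
        ci_low = float(brentq(g, f_lo, f_hat, xtol=1e-12))
    if f_hat >= 1.0 or g(1.0) >= 0:
        ci_high = 1.0
    else:
        ci_high = float(brentq(g, f_hat, 1.0, xtol=1e-12))

    return FrequencyEstimate(
        f_hat=f_hat,
        ci_low=ci_low,
        ci_high=ci_high,
        loglik_max=ll_max,
        epsilon_used=eps,
        mode=mode,
    )
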