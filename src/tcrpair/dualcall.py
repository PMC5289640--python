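"""Discriminating dual-TCRα clones from β-sharing clone pairs.

A candidate pair of clones sharing a β chain (α_i β, α_k β) may really be a
single clone carrying both α chains.  Two complementary routes decide:

* **coincidence-ratio clustering** — the ratio of observed to expected
  three-way co-occurrence wells (expected under independence of the two
  clones) is computed for every candidate, and the set of ratios is split by
  1-D 2-means; the high-mean cluster is called dual.  Works best for rare
  clones, whose chains should essentially never co-occur by chance.

* **full occupancy-pattern likelihood** — for wells small enough to make it
  tractable (below ``size_cap`` cells), the presence/absence pattern of the
  three chains in each well is given an exact probability under both
  hypotheses, summing over latent per-clone cell counts with independent
  per-chain detection (a chain carried by m cells is seen with probability
  1 - ε^m).  A log-likelihood difference of at least ``delta_threshold``
  (default 10) in either direction overrides the clustering verdict.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import gammaln
from sklearn.cluster import KMeans

from .freq import FrequencyEstimate, estimate_frequency, occupancy_counts
from .simdata import SamplingPlan, WellDataset

__all__ = [
    "SharingCandidate",
    "DualCall",
    "expected_coincident_wells",
    "coincidence_ratio",
    "cluster_ratios",
    "pattern_counts",
    "pattern_loglik",
    "find_sharing_candidates",
    "call_duals",
]


@dataclass
class SharingCandidate:
    """A putative β-sharing pair of clones (α1 β, α2 β) under scrutiny."""

    alpha1: str
    alpha2: str
    beta: str
    f1: FrequencyEstimate
    f2: FrequencyEstimate
    f_dual: FrequencyEstimate | None
    observed_triple_wells: int
    expected_triple_wells: float
    ratio: float
    delta_loglik: float | None = None

    def __post_init__(self) -> None:
        if self.alpha1 == self.alpha2:
            raise ValueError("candidate requires two distinct alpha chains")
        if self.observed_triple_wells < 0:
            raise ValueError("observed well count cannot be negative")

    @property
    def chains(self) -> tuple[str, str, str]:
        return (self.alpha1, self.alpha2, self.beta)


@dataclass(frozen=True)
class DualCall:
    """Verdict for one sharing candidate."""

    alpha1: str
    alpha2: str
    beta: str
    verdict: str  # "dual" | "two_clones"
    method: str  # "kmeans" | "full_likelihood"
    evidence: float  # coincidence ratio (kmeans) or delta log-likelihood

    def __post_init__(self) -> None:
        if self.verdict not in ("dual", "two_clones"):
            raise ValueError(f"unknown verdict {self.verdict!r}")
        if self.method not in ("kmeans", "full_likelihood"):
            raise ValueError(f"unknown method {self.method!r}")


def expected_coincident_wells(
    f1: float, f2: float, plan: SamplingPlan | tuple[np.ndarray, np.ndarray]
) -> float:
    """Expected number of wells in which two *independent* clones of
    frequencies f1 and f2 both appear, summed over the plan's well sizes."""
    if f1 < 0 or f2 < 0 or f1 + f2 > 1.0:
        raise ValueError("need f1, f2 >= 0 with f1 + f2 <= 1")
    if isinstance(plan, SamplingPlan):
        n_l, w_l = plan.size_summary()
    else:
        n_l, w_l = np.asarray(plan[0]), np.asarray(plan[1])
    both = 1.0 - (1.0 - f1) ** n_l - (1.0 - f2) ** n_l + (1.0 - f1 - f2) ** n_l
    return float(np.sum(w_l * both))


def coincidence_ratio(observed: int, expected: float) -> float:
    """Observed / expected three-way co-occurrence wells; +inf when chains
    co-occur that never should (E = 0 < A), 1 when both are zero."""
    if observed < 0 or expected < 0:
        raise ValueError("counts must be non-negative")
    if expected == 0.0:
        return float("inf") if observed > 0 else 1.0
    return observed / expected


def cluster_ratios(
    ratios: Sequence[float], seed: int = 0, n_init: int = 20
) -> np.ndarray:
    """Partition coincidence ratios into high (dual) and low (two-clone)
    groups by 1-D 2-means; returns a boolean "dual" verdict per ratio.

    Infinite ratios are pre-assigned to the dual group.  With fewer than two
    finite ratios, clustering is ill-posed and a fixed threshold (r > 2) is
    used instead.  If all finite ratios are identical there is no separation
    and none are called dual.
    """
    r = np.asarray(ratios, dtype=float)
    dual = np.zeros(len(r), dtype=bool)
    if len(r) == 0:
        return dual
    finite = np.isfinite(r)
    dual[~finite] = True
    x = r[finite]
    if len(x) < 2:
        dual[finite] = x > 2.0
        return dual
    if np.ptp(x) == 0.0:
        return dual
    km = KMeans(n_clusters=2, n_init=n_init, random_state=seed)
    labels = km.fit_predict(x.reshape(-1, 1))
    high = int(np.argmax(km.cluster_centers_.ravel()))
    dual[np.flatnonzero(finite)[labels == high]] = True
    return dual


# ---------------------------------------------------------------------------
# Full occupancy-pattern likelihood
# ---------------------------------------------------------------------------

_PATTERNS = list(itertools.product((0, 1), repeat=3))  # (α1, α2, β) presence


def pattern_counts(
    data: WellDataset,
    chains: tuple[str, str, str],
    size_cap: int = 50,
) -> dict[int, np.ndarray]:
    """Per well size (below ``size_cap``), the counts of the 8 possible
    presence/absence patterns of the three chains."""
    a1, a2, b = chains
    out: dict[int, np.ndarray] = {}
    for w in data:
        if w.size >= size_cap:
            continue
        present = w.alpha_set | w.beta_set
        pat = (int(a1 in present), int(a2 in present), int(b in present))
        vec = out.setdefault(w.size, np.zeros(8, dtype=int))
        vec[_PATTERNS.index(pat)] += 1
    return out


def _pattern_probs_dual(n: int, f: float, eps: float) -> np.ndarray:
    """8-pattern distribution when all three chains ride on one clone of
    frequency f: cell count m ~ Binomial(n, f), each chain independently
    detected with probability 1 - eps^m."""
    m = np.arange(n + 1)
    logpmf = (
        gammaln(n + 1) - gammaln(m + 1) - gammaln(n - m + 1)
        + m * np.log(f) + (n - m) * np.log1p(-f)
    ) if 0 < f < 1 else None
    if f == 0.0:
        pmf = np.zeros(n + 1)
        pmf[0] = 1.0
    elif f == 1.0:
        pmf = np.zeros(n + 1)
        pmf[-1] = 1.0
    else:
        pmf = np.exp(logpmf)
    p_det = 1.0 - eps**m
    p_det[0] = 0.0
    probs = np.empty(8)
    for idx, (x1, x2, xb) in enumerate(_PATTERNS):
        term = np.ones(n + 1)
        for x in (x1, x2, xb):
            term = term * (p_det if x else 1.0 - p_det)
        probs[idx] = float(np.sum(pmf * term))
    return probs


def _pattern_probs_two(n: int, f1: float, f2: float, eps: float) -> np.ndarray:
    """8-pattern distribution for two independent clones sharing the β:
    latent counts (m1, m2) ~ Multinomial(n; f1, f2, rest); α_i carried by m_i
    cells, β by m1+m2; detection 1 - eps^m per chain.  Terms whose
    multinomial log-mass falls 40 nats below the maximum are dropped."""
    if f1 + f2 > 1.0:
        raise ValueError("f1 + f2 must not exceed 1")
    m1g, m2g = np.meshgrid(np.arange(n + 1), np.arange(n + 1), indexing="ij")
    mask = m1g + m2g <= n
    m1 = m1g[mask]
    m2 = m2g[mask]
    rest = n - m1 - m2
    f0 = max(1.0 - f1 - f2, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        logpmf = (
            gammaln(n + 1) - gammaln(m1 + 1) - gammaln(m2 + 1) - gammaln(rest + 1)
            + np.where(m1 > 0, m1 * np.log(f1 if f1 > 0 else 1.0), 0.0)
            + np.where(m2 > 0, m2 * np.log(f2 if f2 > 0 else 1.0), 0.0)
            + np.where(rest > 0, rest * np.log(f0 if f0 > 0 else 1.0), 0.0)
        )
        # impossible outcomes (m_i > 0 with f_i == 0) get zero mass
        logpmf = np.where((m1 > 0) & (f1 == 0), -np.inf, logpmf)
        logpmf = np.where((m2 > 0) & (f2 == 0), -np.inf, logpmf)
        logpmf = np.where((rest > 0) & (f0 == 0), -np.inf, logpmf)
    keep = logpmf >= logpmf.max() - 40.0
    m1, m2, logpmf = m1[keep], m2[keep], logpmf[keep]
    pmf = np.exp(logpmf)

    def det(m: np.ndarray) -> np.ndarray:
        p = 1.0 - eps ** m.astype(float)
        return np.where(m > 0, p, 0.0)

    p1, p2, pb = det(m1), det(m2), det(m1 + m2)
    probs = np.empty(8)
    for idx, (x1, x2, xb) in enumerate(_PATTERNS):
        term = (p1 if x1 else 1.0 - p1) * (p2 if x2 else 1.0 - p2) * (
            pb if xb else 1.0 - pb
        )
        probs[idx] = float(np.sum(pmf * term))
    return probs


def pattern_distribution(
    n: int, hypothesis: tuple, eps: float
) -> np.ndarray:
    """8-pattern probability vector for a well of ``n`` cells.

    ``hypothesis`` is ``("dual", f)`` or ``("two_clones", f1, f2)``.  The
    returned vector sums to 1.
    """
    kind = hypothesis[0]
    if kind == "dual":
        return _pattern_probs_dual(n, float(hypothesis[1]), eps)
    if kind == "two_clones":
        return _pattern_probs_two(n, float(hypothesis[1]), float(hypothesis[2]), eps)
    raise ValueError(f"unknown hypothesis {kind!r}")


def pattern_loglik(
    counts: Mapping[int, np.ndarray], hypothesis: tuple, eps: float
) -> float:
    """Log-likelihood of observed three-chain presence/absence patterns
    (as returned by :func:`pattern_counts`) under a hypothesis."""
    if not counts:
        raise ValueError("no wells below the size cap; pattern likelihood undefined")
    total = 0.0
    for n, vec in counts.items():
        probs = pattern_distribution(n, hypothesis, eps)
        for c, p in zip(vec, probs):
            if c == 0:
                continue
            if p <= 0.0:
                return float("-inf")
            total += c * np.log(p)
    return float(total)


# ---------------------------------------------------------------------------
# The combined calling procedure
# ---------------------------------------------------------------------------

def find_sharing_candidates(
    pairs: Sequence[tuple[str, str]]
) -> list[tuple[str, str, str]]:
    """All (α1, α2, β) triples from candidate pairs sharing a β chain.
    Pairs sharing an α are never dual candidates."""
    by_beta: dict[str, list[str]] = {}
    for a, b in pairs:
        by_beta.setdefault(b, []).append(a)
    out = []
    for b, alphas in sorted(by_beta.items()):
        for a1, a2 in itertools.combinations(sorted(set(alphas)), 2):
            out.append((a1, a2, b))
    return out


def call_duals(
    pairs: Sequence[tuple[str, str]],
    data: WellDataset,
    estimates: Mapping[tuple[str, str], FrequencyEstimate],
    eps: float = 0.15,
    size_cap: int = 50,
    delta_threshold: float = 10.0,
    seed: int = 0,
) -> tuple[list[DualCall], list[SharingCandidate]]:
    """Decide dual-TCRα versus β-sharing for every candidate triple.

    The clustering route is applied to all candidates; for candidates whose
    three chains co-occur in at least one well below ``size_cap`` cells the
    full-likelihood route is additionally computed, and where
    \\|ΔlogL\\| >= ``delta_threshold`` its verdict overrides the clustering
    one.  Returns the calls and the annotated candidates.
    """
    triples = find_sharing_candidates(pairs)
    if not triples:
        return [], []

    n_l, w_l = data.size_summary()
    candidates: list[SharingCandidate] = []
    for a1, a2, b in triples:
        e1 = estimates[(a1, b)]
        e2 = estimates[(a2, b)]
        f1, f2 = e1.f_hat, e2.f_hat
        if f1 + f2 > 1.0:
            # pathological pair of abundant estimates; renormalise for the
            # independence model, which requires f1 + f2 <= 1
            scale = (1.0 - 1e-9) / (f1 + f2)
            f1, f2 = f1 * scale, f2 * scale
        triple_counts = occupancy_counts(data, (a1, a2, b))
        observed = triple_counts.total_hits
        expected = expected_coincident_wells(f1, f2, (n_l, w_l))
        f_dual = (
            estimate_frequency(triple_counts, eps=eps, mode="dual")
            if observed > 0
            else None
        )
        candidates.append(
            SharingCandidate(
                alpha1=a1,
                alpha2=a2,
                beta=b,
                f1=e1,
                f2=e2,
                f_dual=f_dual,
                observed_triple_wells=observed,
                expected_triple_wells=expected,
                ratio=coincidence_ratio(observed, expected),
            )
        )

    dual_by_cluster = cluster_ratios([c.ratio for c in candidates], seed=seed)

    calls: list[DualCall] = []
    for c, clustered_dual in zip(candidates, dual_by_cluster):
        verdict = "dual" if clustered_dual else "two_clones"
        method = "kmeans"
        evidence = c.ratio
        pat = pattern_counts(data, c.chains, size_cap=size_cap)
        triple_under_cap = any(
            vec[_PATTERNS.index((1, 1, 1))] > 0 for vec in pat.values()
        )
        if pat and triple_under_cap and c.f_dual is not None:
            f1, f2 = c.f1.f_hat, c.f2.f_hat
            if f1 + f2 > 1.0:
                scale = (1.0 - 1e-9) / (f1 + f2)
                f1, f2 = f1 * scale, f2 * scale
            ll_dual = pattern_loglik(pat, ("dual", c.f_dual.f_hat), eps)
            ll_two = pattern_loglik(pat, ("two_clones", f1, f2), eps)
            delta = ll_dual - ll_two
            c.delta_loglik = delta
            if abs(delta) >= delta_threshold or np.isinf(delta):
                verdict = "dual" if delta >= delta_threshold else "two_clones"
                method = "full_likelihood"
                evidence = delta
        calls.append(
            DualCall(
                alpha1=c.alpha1,
                alpha2=c.alpha2,
                beta=c.beta,
                verdict=verdict,
                method=method,
                evidence=float(evidence),
            )
        )
    return calls, candidates
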