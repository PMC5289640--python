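"""Candidate αβ pair discovery from well co-occurrence.

The association score between an α and a β chain sums their co-appearances
over wells, each weighted inversely by the total number of distinct chains in
the well.  Within each well the chains are matched one-to-one by solving a
maximum-weight linear sum assignment on these plate-wide scores.  Assignment
counts are filtered per replicate (a pair must be assigned more often than
the mean of the positive assignment counts), and a pseudo-jackknife consensus
over many random well subsets retains pairs supported in more than a
threshold proportion of replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .simdata import Well, WellDataset

__all__ = [
    "PairingConfig",
    "AssociationScores",
    "CandidatePairList",
    "compute_association_scores",
    "assign_pairs_in_well",
    "replicate_candidates",
    "consensus_support",
    "consensus_pairs",
    "filter_support",
]


@dataclass(frozen=True)
class PairingConfig:
    """Parameters of the jackknife consensus pairing.

    p_j : proportion of wells drawn (without replacement) per replicate.
    n_r : number of replicates.
    threshold : consensus proportion T; pairs must appear in strictly more
        than ``T * n_r`` replicates to be retained.
    """

    p_j: float = 0.75
    n_r: int = 100
    threshold: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.p_j <= 1.0:
            raise ValueError("p_j must lie in (0, 1]")
        if self.n_r < 1:
            raise ValueError("n_r must be >= 1")
        if not 0.0 <= self.threshold < 1.0:
            raise ValueError("threshold must lie in [0, 1)")


@dataclass
class AssociationScores:
    """Dense matrix of association scores over the chains of a well subset."""

    alpha_ids: list[str]
    beta_ids: list[str]
    matrix: np.ndarray
    alpha_index: dict[str, int] = field(default_factory=dict)
    beta_index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.alpha_index:
            self.alpha_index = {a: i for i, a in enumerate(self.alpha_ids)}
            self.beta_index = {b: j for j, b in enumerate(self.beta_ids)}

    def score(self, alpha_id: str, beta_id: str) -> float:
        i = self.alpha_index.get(alpha_id)
        j = self.beta_index.get(beta_id)
        if i is None or j is None:
            return 0.0
        return float(self.matrix[i, j])


@dataclass
class CandidatePairList:
    """Consensus candidate pairs with their replicate-support proportions."""

    pairs: list[tuple[str, str, float]]

    def pair_set(self) -> set[tuple[str, str]]:
        return {(a, b) for a, b, _ in self.pairs}

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)


def compute_association_scores(wells: Sequence[Well]) -> AssociationScores:
    """Association scores S_ij over a (sub)set of wells.

    S_ij sums, over wells containing both chains, 1 / (c_alpha + c_beta)
    where c_alpha and c_beta are the numbers of distinct α and β chains in
    the well.
    """
    wells = list(wells)
    if not wells:
        raise ValueError("cannot score an empty well subset")
    alpha_ids = sorted(set().union(*(w.alpha_set for w in wells)))
    beta_ids = sorted(set().union(*(w.beta_set for w in wells)))
    ai = {a: i for i, a in enumerate(alpha_ids)}
    bi = {b: j for j, b in enumerate(beta_ids)}
    m = np.zeros((len(alpha_ids), len(beta_ids)))
    for w in wells:
        if not w.alpha_set or not w.beta_set:
            continue
        weight = 1.0 / (len(w.alpha_set) + len(w.beta_set))
        rows = np.fromiter((ai[a] for a in sorted(w.alpha_set)), dtype=int)
        cols = np.fromiter((bi[b] for b in sorted(w.beta_set)), dtype=int)
        m[np.ix_(rows, cols)] += weight
    return AssociationScores(alpha_ids, beta_ids, m, ai, bi)


def assign_pairs_in_well(well: Well, scores: AssociationScores) -> set[tuple[str, str]]:
    """Maximum-weight one-to-one matching of the well's α chains to its β
    chains under the plate-wide scores.

    Rectangular wells yield min(|A|, |B|) pairs; surplus chains stay
    unpaired.  A well lacking either locus yields the empty set.
    """
    alphas = sorted(well.alpha_set)
    betas = sorted(well.beta_set)
    if not alphas or not betas:
        return set()
    sub = np.empty((len(alphas), len(betas)))
    for i, a in enumerate(alphas):
        for j, b in enumerate(betas):
            sub[i, j] = scores.score(a, b)
    rows, cols = linear_sum_assignment(sub, maximize=True)
    return {(alphas[i], betas[j]) for i, j in zip(rows, cols)}


# ---------------------------------------------------------------------------
# Fast replicate core
# ---------------------------------------------------------------------------

class _ScoreCache:
    """Precomputed global chain registries and per-well index arrays so the
    jackknife replicates avoid re-parsing the dataset."""

    def __init__(self, data: WellDataset):
        if data.n_wells == 0:
            raise ValueError("empty well dataset")
        self.alpha_ids = sorted(set().union(*(w.alpha_set for w in data), set()))
        self.beta_ids = sorted(set().union(*(w.beta_set for w in data), set()))
        ai = {a: i for i, a in enumerate(self.alpha_ids)}
        bi = {b: j for j, b in enumerate(self.beta_ids)}
        self.n_alpha = len(self.alpha_ids)
        self.n_beta = len(self.beta_ids)
        self.well_rows: list[np.ndarray] = []
        self.well_cols: list[np.ndarray] = []
        self.well_flat: list[np.ndarray] = []
        self.well_weight: list[float] = []
        nb = self.n_beta
        for w in data:
            rows = np.fromiter((ai[a] for a in sorted(w.alpha_set)), dtype=np.int64)
            cols = np.fromiter((bi[b] for b in sorted(w.beta_set)), dtype=np.int64)
            self.well_rows.append(rows)
            self.well_cols.append(cols)
            if len(rows) and len(cols):
                flat = (rows[:, None] * nb + cols[None, :]).ravel()
                weight = 1.0 / (len(rows) + len(cols))
            else:
                flat = np.empty(0, dtype=np.int64)
                weight = 0.0
            self.well_flat.append(flat)
            self.well_weight.append(weight)
        self.n_wells = data.n_wells

    def replicate(self, rng: np.random.Generator, p_j: float) -> set[tuple[int, int]]:
        """One jackknife replicate: subsample wells, score, assign, filter."""
        n_sub = max(1, math.floor(p_j * self.n_wells))
        subset = rng.choice(self.n_wells, size=n_sub, replace=False)

        flat_all = np.concatenate([self.well_flat[k] for k in subset])
        weights = np.repeat(
            np.array([self.well_weight[k] for k in subset]),
            np.array([len(self.well_flat[k]) for k in subset]),
        )
        scores = np.bincount(flat_all, weights=weights,
                             minlength=self.n_alpha * self.n_beta)

        assigned: list[np.ndarray] = []
        for k in subset:
            rows, cols, flat = self.well_rows[k], self.well_cols[k], self.well_flat[k]
            if not len(rows) or not len(cols):
                continue
            sub = scores[flat].reshape(len(rows), len(cols))
            ri, ci = linear_sum_assignment(sub, maximize=True)
            assigned.append(rows[ri] * self.n_beta + cols[ci])
        if not assigned:
            return set()
        counts_flat, counts = np.unique(np.concatenate(assigned), return_counts=True)
        filter_level = counts.mean()
        keep = counts_flat[counts > filter_level]
        nb = self.n_beta
        return {(int(p // nb), int(p % nb)) for p in keep}

    def to_ids(self, pairs: Iterable[tuple[int, int]]) -> set[tuple[str, str]]:
        return {(self.alpha_ids[i], self.beta_ids[j]) for i, j in pairs}


def replicate_candidates(
    data: WellDataset, cfg: PairingConfig, replicate_seed: int
) -> set[tuple[str, str]]:
    """One filtered candidate list: sample ⌊p_j·W⌋ wells without replacement,
    score them, assign pairs per sampled well, and keep pairs assigned
    strictly more often than the mean of the positive assignment counts."""
    cache = _ScoreCache(data)
    rng = np.random.default_rng(replicate_seed)
    return cache.to_ids(cache.replicate(rng, cfg.p_j))


def consensus_support(
    data: WellDataset, cfg: PairingConfig
) -> dict[tuple[str, str], float]:
    """Replicate-support proportion for every pair appearing in at least one
    of the ``n_r`` jackknife replicates."""
    cache = _ScoreCache(data)
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_r)
    support: dict[tuple[int, int], int] = {}
    for s in seeds:
        rng = np.random.default_rng(s)
        for p in cache.replicate(rng, cfg.p_j):
            support[p] = support.get(p, 0) + 1
    return {
        (cache.alpha_ids[i], cache.beta_ids[j]): n / cfg.n_r
        for (i, j), n in support.items()
    }


def consensus_pairs(data: WellDataset, cfg: PairingConfig) -> CandidatePairList:
    """Consensus candidate pairs: those appearing in strictly more than a
    proportion ``cfg.threshold`` of the jackknife replicates."""
    support = consensus_support(data, cfg)
    pairs = sorted(
        ((a, b, s) for (a, b), s in support.items() if s > cfg.threshold),
        key=lambda t: (-t[2], t[0], t[1]),
    )
    return CandidatePairList(pairs)


def filter_support(
    support: dict[tuple[str, str], float], threshold: float
) -> CandidatePairList:
    """Apply a consensus threshold to precomputed replicate supports (allows
    scanning several thresholds from one replicate run)."""
    pairs = sorted(
        ((a, b, s) for (a, b), s in support.items() if s > threshold),
        key=lambda t: (-t[2], t[0], t[1]),
    )
    return CandidatePairList(pairs)
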