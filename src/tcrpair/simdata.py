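"""Synthetic T-cell clone populations and simulated multi-well / single-cell sequencing.

This module builds ground-truth populations of TCR clonotypes with a skewed
clone-size distribution, configurable chain sharing between clones, dual-TCRα
and dual-TCRβ clones, and a two-part sequencing-noise model (clone-specific
chain drop-out and per-sequence in-frame errors that emit "daughter"
sequences).  Populations are then sampled into virtual 96-well plates or into
simulated single cells, providing fully known ground truth for every
downstream stage of the pairing algorithm.

Chains are opaque string identifiers; no nucleotide or amino-acid content is
synthesised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Clone",
    "ClonePopulation",
    "SharingSpec",
    "SamplingPlan",
    "Well",
    "WellDataset",
    "DEFAULT_ALPHA_SHARING",
    "DEFAULT_BETA_SHARING",
    "build_clone_size_distribution",
    "generate_population",
    "build_sampling_plan",
    "sample_wells",
    "simulate_single_cells",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Clone:
    """A T-cell clone: 1-2 α chain ids, 1-2 β chain ids, a population
    frequency and a clone-specific chain drop rate."""

    alpha_ids: tuple[str, ...]
    beta_ids: tuple[str, ...]
    frequency: float
    drop_rate: float

    def __post_init__(self) -> None:
        if not 1 <= len(self.alpha_ids) <= 2 or not 1 <= len(self.beta_ids) <= 2:
            raise ValueError("clones carry 1-2 chains per locus")
        if len(set(self.alpha_ids)) != len(self.alpha_ids):
            raise ValueError("dual-alpha clone must carry two distinct alpha chains")
        if len(set(self.beta_ids)) != len(self.beta_ids):
            raise ValueError("dual-beta clone must carry two distinct beta chains")
        if not 0.0 < self.frequency < 1.0 + 1e-12:
            raise ValueError(f"clone frequency {self.frequency} outside (0, 1)")
        if not 0.0 <= self.drop_rate <= 0.9:
            raise ValueError(f"drop rate {self.drop_rate} outside [0, 0.9]")

    @property
    def is_dual_alpha(self) -> bool:
        return len(self.alpha_ids) == 2

    @property
    def is_dual_beta(self) -> bool:
        return len(self.beta_ids) == 2

    def chain_key(self) -> tuple[tuple[str, ...], tuple[str, ...]]:
        return tuple(sorted(self.alpha_ids)), tuple(sorted(self.beta_ids))


@dataclass
class ClonePopulation:
    """Ground-truth clone population plus the error-model bookkeeping.

    ``alpha_error_rate`` / ``beta_error_rate`` map every true chain id to its
    in-frame error probability.  ``daughters`` maps every true chain id to its
    three fixed, chain-specific erroneous daughter ids; daughter ids never
    collide with true ids or with each other.
    """

    clones: list[Clone]
    alpha_error_rate: dict[str, float]
    beta_error_rate: dict[str, float]
    daughters: dict[str, tuple[str, str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.daughters:
            self.daughters = {
                cid: (f"{cid}.e1", f"{cid}.e2", f"{cid}.e3")
                for cid in list(self.alpha_error_rate) + list(self.beta_error_rate)
            }
        self.validate()

    def validate(self) -> None:
        total = sum(c.frequency for c in self.clones)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"clone frequencies sum to {total}, not 1")
        keys = [c.chain_key() for c in self.clones]
        if len(set(keys)) != len(keys):
            raise ValueError("two clones share an identical chain combination")
        for rates in (self.alpha_error_rate, self.beta_error_rate):
            for cid, e in rates.items():
                if not 0.0 <= e < 1.0:
                    raise ValueError(f"error rate for {cid} outside [0, 1)")
        true_ids = set(self.alpha_error_rate) | set(self.beta_error_rate)
        daughter_ids = [d for trio in self.daughters.values() for d in trio]
        if len(set(daughter_ids)) != len(daughter_ids):
            raise ValueError("daughter ids collide with each other")
        if set(daughter_ids) & true_ids:
            raise ValueError("daughter ids collide with true chain ids")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_clones(self) -> int:
        return len(self.clones)

    def frequencies(self) -> np.ndarray:
        return np.array([c.frequency for c in self.clones])

    def alpha_chains(self) -> list[str]:
        return sorted(self.alpha_error_rate)

    def beta_chains(self) -> list[str]:
        return sorted(self.beta_error_rate)

    def parent_of(self) -> dict[str, str]:
        """Map daughter id -> true parent chain id."""
        return {d: cid for cid, trio in self.daughters.items() for d in trio}

    def chain_multiplicities(self, locus: str) -> dict[str, int]:
        """Number of clones carrying each true chain id at ``locus``."""
        counts: dict[str, int] = {}
        for c in self.clones:
            ids = c.alpha_ids if locus == "alpha" else c.beta_ids
            for cid in ids:
                counts[cid] = counts.get(cid, 0) + 1
        return counts


@dataclass(frozen=True)
class SharingSpec:
    """Distribution of chain multiplicity: P(a chain is carried by k clones)."""

    multiplicity_probs: dict[int, float]

    def __post_init__(self) -> None:
        if not self.multiplicity_probs:
            raise ValueError("empty sharing spec")
        if any(k < 1 for k in self.multiplicity_probs):
            raise ValueError("multiplicities must be >= 1")
        if any(p < 0 for p in self.multiplicity_probs.values()):
            raise ValueError("negative probability in sharing spec")
        total = sum(self.multiplicity_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"sharing probabilities sum to {total}, not 1")

    def sample_multiplicities(self, n_slots: int, rng: np.random.Generator) -> list[int]:
        """Draw chain multiplicities until they fill exactly ``n_slots`` clone
        slots; the final draw is truncated to fit."""
        ks = np.array(sorted(self.multiplicity_probs))
        ps = np.array([self.multiplicity_probs[k] for k in ks])
        out: list[int] = []
        remaining = n_slots
        while remaining > 0:
            k = int(rng.choice(ks, p=ps))
            k = min(k, remaining)
            out.append(k)
            remaining -= k
        return out


#: α-chain sharing spectrum averaged over published epitope-specific
#: single-cell data sets (multiplicity 1..7).
DEFAULT_ALPHA_SHARING = SharingSpec(
    {1: 0.816, 2: 0.085, 3: 0.021, 4: 0.007, 5: 0.033, 6: 0.005, 7: 0.033}
)
#: β-chain sharing spectrum (multiplicity 1..5); 85.9% of β chains belong to
#: exactly one clone.
DEFAULT_BETA_SHARING = SharingSpec(
    {1: 0.859, 2: 0.076, 3: 0.037, 4: 0.019, 5: 0.009}
)


@dataclass(frozen=True)
class SamplingPlan:
    """Plate layout: a list of (number of wells, cells per well) blocks."""

    blocks: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("empty sampling plan")
        for w, n in self.blocks:
            if w <= 0 or n <= 0:
                raise ValueError("well counts and cells/well must be positive")

    @property
    def total_wells(self) -> int:
        return sum(w for w, _ in self.blocks)

    def well_sizes(self) -> np.ndarray:
        """Per-well sample sizes, in plan order."""
        return np.concatenate([np.full(w, n, dtype=int) for w, n in self.blocks])

    def size_summary(self) -> tuple[np.ndarray, np.ndarray]:
        """Summarise to the s distinct sizes (n_l) and well counts (w_l)."""
        sizes = self.well_sizes()
        n_l, w_l = np.unique(sizes, return_counts=True)
        return n_l, w_l


@dataclass(frozen=True)
class Well:
    """One sequenced well: sample size and the sets of distinct chain ids
    recovered per locus (after drop-out and in-frame errors)."""

    size: int
    alpha_set: frozenset[str]
    beta_set: frozenset[str]

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError("well sample size must be positive")


@dataclass
class WellDataset:
    wells: list[Well]

    @property
    def n_wells(self) -> int:
        return len(self.wells)

    def sizes(self) -> np.ndarray:
        return np.array([w.size for w in self.wells])

    def size_summary(self) -> tuple[np.ndarray, np.ndarray]:
        n_l, w_l = np.unique(self.sizes(), return_counts=True)
        return n_l, w_l

    def __iter__(self):
        return iter(self.wells)

    def __len__(self) -> int:
        return len(self.wells)


# ---------------------------------------------------------------------------
# Clone-size distribution
# ---------------------------------------------------------------------------

def build_clone_size_distribution(N: int, n_s: int, p_s: float) -> np.ndarray:
    """Skewed clone-size distribution: the top ``n_s`` clones comprise a
    proportion ``p_s`` of the population on a linearly decreasing ramp, and
    the remaining ``N - n_s`` clones form a flat tail sharing ``1 - p_s``.

    The ramp is anchored by two constraints: the top frequencies sum to
    ``p_s``, and the smallest top clone sits 10% above the tail level
    implied by ``p_s`` (f_{n_s} = 1.1 * p_s / (N - n_s)).

    Returns frequencies sorted in descending order, summing to 1.
    """
    if not 0 < n_s < N:
        raise ValueError("need 0 < n_s < N")
    if not 0.0 < p_s < 1.0:
        raise ValueError("need 0 < p_s < 1")
    tail = (1.0 - p_s) / (N - n_s)
    if n_s == 1:
        top = np.array([p_s])
    else:
        f_ns = 1.1 * p_s / (N - n_s)
        # n_s*f1 + r*n_s*(n_s-1)/2 = p_s ;  f1 + r*(n_s-1) = f_ns
        a = np.array(
            [[n_s, n_s * (n_s - 1) / 2.0], [1.0, float(n_s - 1)]]
        )
        b = np.array([p_s, f_ns])
        f1, r = np.linalg.solve(a, b)
        if f1 <= f_ns:
            raise ValueError(
                "parameters give a non-decreasing top ramp (f_1 <= f_{n_s})"
            )
        top = f1 + r * np.arange(n_s)
    f = np.concatenate([top, np.full(N - n_s, tail)])
    if np.any(f <= 0):
        raise ValueError("parameters yield non-positive frequencies")
    if np.any(np.diff(f) > 1e-15):
        raise ValueError("frequencies are not monotone non-increasing")
    return f


# ---------------------------------------------------------------------------
# Population generation
# ---------------------------------------------------------------------------

def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Underlying normal (mu, sigma) for a lognormal with the given mean and
    standard deviation of the variable itself."""
    if mean <= 0:
        raise ValueError("lognormal mean must be positive")
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


class _SlotConflict(ValueError):
    """Raised when a shuffled slot assignment cannot honour a chain's
    multiplicity; the caller resamples."""


def _assign_chains_to_slots(
    slot_owner: np.ndarray,
    multiplicities: Sequence[int],
    rng: np.random.Generator,
) -> list[list[int]]:
    """Distribute chains (with given clone multiplicities) onto clone slots so
    that each chain lands in distinct clones.  Returns, per chain, the list of
    clone indices carrying it."""
    owners = slot_owner.copy()
    rng.shuffle(owners)
    chains: list[list[int]] = []
    pos = 0
    n = len(owners)
    for k in multiplicities:
        for attempt in range(1000):
            block = owners[pos : pos + k]
            if len(np.unique(block)) == k:
                break
            if pos + k >= n:
                raise _SlotConflict
            # swap a duplicated entry with a random not-yet-consumed slot
            # beyond the block (earlier slots already belong to other chains)
            vals, idx = np.unique(block, return_index=True)
            dup_local = np.setdiff1d(np.arange(k), idx)[0]
            other = int(rng.integers(pos + k, n))
            j = pos + dup_local
            owners[j], owners[other] = owners[other], owners[j]
        else:  # pragma: no cover - astronomically unlikely with valid specs
            raise _SlotConflict
        chains.append([int(c) for c in owners[pos : pos + k]])
        pos += k
    return chains


def generate_population(
    N: int = 2100,
    n_s: int = 25,
    p_s: float = 0.5,
    alpha_sharing: SharingSpec = DEFAULT_ALPHA_SHARING,
    beta_sharing: SharingSpec = DEFAULT_BETA_SHARING,
    dual_alpha_prev: float = 0.30,
    dual_beta_prev: float = 0.06,
    drop_mean: float = 0.15,
    drop_sd: float = 0.01,
    err_mean: float = 0.02,
    err_sd: float = 0.005,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> ClonePopulation:
    """Generate a ground-truth clone population.

    A fraction ``dual_alpha_prev`` of clones carry two α chains and
    ``dual_beta_prev`` carry two β chains.  Chain multiplicities (how many
    clones carry each chain) are drawn from the sharing specs and chains are
    randomly matched to clone slots; frequencies from
    :func:`build_clone_size_distribution` are assigned to clones in random
    order, so sharing and dual status are independent of abundance rank.
    Per-clone drop rates are lognormal(``drop_mean``, ``drop_sd``) capped at
    0.9; per-chain in-frame error rates are lognormal(``err_mean``,
    ``err_sd``).  Lognormal parameters are the mean/sd of the variable itself.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    for prev in (dual_alpha_prev, dual_beta_prev):
        if not 0.0 <= prev <= 1.0:
            raise ValueError("dual prevalences must lie in [0, 1]")

    freqs = build_clone_size_distribution(N, n_s, p_s)[rng.permutation(N)]

    n_dual_a = int(round(dual_alpha_prev * N))
    n_dual_b = int(round(dual_beta_prev * N))
    dual_a = np.zeros(N, dtype=bool)
    dual_a[rng.choice(N, size=n_dual_a, replace=False)] = True
    dual_b = np.zeros(N, dtype=bool)
    dual_b[rng.choice(N, size=n_dual_b, replace=False)] = True

    if max(alpha_sharing.multiplicity_probs) > N or max(beta_sharing.multiplicity_probs) > N:
        raise ValueError("sharing multiplicity exceeds the number of clones")

    clone_idx = np.arange(N)
    for attempt in range(1000):
        a_slots = np.repeat(clone_idx, 1 + dual_a.astype(int))
        b_slots = np.repeat(clone_idx, 1 + dual_b.astype(int))
        a_mult = alpha_sharing.sample_multiplicities(len(a_slots), rng)
        b_mult = beta_sharing.sample_multiplicities(len(b_slots), rng)
        try:
            a_assign = _assign_chains_to_slots(a_slots, a_mult, rng)
            b_assign = _assign_chains_to_slots(b_slots, b_mult, rng)
        except _SlotConflict:
            continue

        wa = len(str(len(a_assign)))
        wb = len(str(len(b_assign)))
        alpha_of_clone: list[list[str]] = [[] for _ in range(N)]
        beta_of_clone: list[list[str]] = [[] for _ in range(N)]
        for i, clones_of_chain in enumerate(a_assign):
            cid = f"a{i:0{wa}d}"
            for c in clones_of_chain:
                alpha_of_clone[c].append(cid)
        for i, clones_of_chain in enumerate(b_assign):
            cid = f"b{i:0{wb}d}"
            for c in clones_of_chain:
                beta_of_clone[c].append(cid)

        keys = {
            (tuple(sorted(alpha_of_clone[c])), tuple(sorted(beta_of_clone[c])))
            for c in range(N)
        }
        if len(keys) == N:
            break
    else:
        raise ValueError("could not generate a population without duplicate clones")

    mu_d, sig_d = _lognormal_params(drop_mean, drop_sd)
    drops = np.minimum(rng.lognormal(mu_d, sig_d, size=N), 0.9)
    mu_e, sig_e = _lognormal_params(err_mean, err_sd)
    err_a = np.clip(rng.lognormal(mu_e, sig_e, size=len(a_assign)), 0.0, 0.999)
    err_b = np.clip(rng.lognormal(mu_e, sig_e, size=len(b_assign)), 0.0, 0.999)

    clones = [
        Clone(
            alpha_ids=tuple(sorted(alpha_of_clone[c])),
            beta_ids=tuple(sorted(beta_of_clone[c])),
            frequency=float(freqs[c]),
            drop_rate=float(drops[c]),
        )
        for c in range(N)
    ]
    alpha_err = {f"a{i:0{wa}d}": float(err_a[i]) for i in range(len(a_assign))}
    beta_err = {f"b{i:0{wb}d}": float(err_b[i]) for i in range(len(b_assign))}
    return ClonePopulation(clones, alpha_err, beta_err)


# ---------------------------------------------------------------------------
# Sampling plans
# ---------------------------------------------------------------------------

_HIGH_MIXED_1 = ((26, 20), (13, 50), (19, 100), (19, 200), (19, 300))
_HIGH_MIXED_5 = ((128, 20), (64, 50), (96, 100), (96, 200), (96, 300))
_LOW_MIXED_1 = ((26, 15), (6, 20), (13, 30), (19, 50), (19, 100), (19, 150))
_LOW_MIXED_5 = ((96, 15), (32, 20), (64, 30), (96, 50), (96, 100), (96, 150))


def build_sampling_plan(strategy: str, plates: int = 1) -> SamplingPlan:
    """Build the plate layout for a named sampling strategy.

    ``strategy`` is ``"high-mixed"``, ``"low-mixed"`` or ``"uniform-K"``
    (96 wells of K cells per plate).  For the mixed strategies the 1- and
    5-plate layouts are the published block structures; other plate counts
    tile the 1-plate block.
    """
    if plates <= 0:
        raise ValueError("plates must be positive")
    if strategy == "high-mixed":
        if plates == 1:
            return SamplingPlan(_HIGH_MIXED_1)
        if plates == 5:
            return SamplingPlan(_HIGH_MIXED_5)
        return SamplingPlan(tuple((w * plates, n) for w, n in _HIGH_MIXED_1))
    if strategy == "low-mixed":
        if plates == 1:
            return SamplingPlan(_LOW_MIXED_1)
        if plates == 5:
            return SamplingPlan(_LOW_MIXED_5)
        return SamplingPlan(tuple((w * plates, n) for w, n in _LOW_MIXED_1))
    if strategy.startswith("uniform-"):
        try:
            k = int(strategy.split("-", 1)[1])
        except ValueError as exc:
            raise ValueError(f"unknown strategy {strategy!r}") from exc
        if k <= 0:
            raise ValueError("uniform strategy needs a positive cells/well")
        return SamplingPlan(((96 * plates, k),))
    raise ValueError(f"unknown strategy {strategy!r}")


# ---------------------------------------------------------------------------
# Sequencing simulation
# ---------------------------------------------------------------------------

class _ChainLayout:
    """Flattened per-chain-instance view of a population, for vectorised
    sampling.  One entry per (clone, chain) slot."""

    def __init__(self, pop: ClonePopulation):
        registry: list[str] = []
        reg_index: dict[str, int] = {}

        def intern(cid: str) -> int:
            if cid not in reg_index:
                reg_index[cid] = len(registry)
                registry.append(cid)
            return reg_index[cid]

        clone_i: list[int] = []
        chain_i: list[int] = []
        err: list[float] = []
        is_alpha: list[bool] = []
        daughters: list[tuple[int, int, int]] = []
        for ci, clone in enumerate(pop.clones):
            for locus, ids, rates in (
                ("alpha", clone.alpha_ids, pop.alpha_error_rate),
                ("beta", clone.beta_ids, pop.beta_error_rate),
            ):
                for cid in ids:
                    clone_i.append(ci)
                    chain_i.append(intern(cid))
                    err.append(rates[cid])
                    is_alpha.append(locus == "alpha")
                    daughters.append(tuple(intern(d) for d in pop.daughters[cid]))

        self.registry = np.array(registry)
        self.clone = np.array(clone_i)
        self.chain = np.array(chain_i)
        self.err = np.array(err)
        self.is_alpha = np.array(is_alpha)
        self.daughters = np.array(daughters)
        self.drop = np.array([c.drop_rate for c in pop.clones])
        self.freq = pop.frequencies()
        # per-clone entry index lists, for the single-cell path
        order = np.argsort(self.clone, kind="stable")
        bounds = np.searchsorted(self.clone[order], np.arange(len(pop.clones) + 1))
        self.entries_of_clone = [
            order[bounds[c] : bounds[c + 1]] for c in range(len(pop.clones))
        ]


def _observed_sets(
    layout: _ChainLayout,
    sel: np.ndarray,
    copies: np.ndarray,
    rng: np.random.Generator,
) -> tuple[frozenset[str], frozenset[str]]:
    """Apply drop-out and in-frame errors to ``copies`` instances of each
    selected chain entry; return the observed (alpha, beta) id sets."""
    surv = rng.binomial(copies, 1.0 - layout.drop[layout.clone[sel]])
    mut = rng.binomial(surv, layout.err[sel])
    # each erroneous instance picks one of the chain's three daughters
    d1 = rng.binomial(mut, 1.0 / 3.0)
    d2 = rng.binomial(mut - d1, 0.5)
    d3 = mut - d1 - d2

    alpha: set[str] = set()
    beta: set[str] = set()
    true_present = (surv - mut) > 0
    for mask, chain_ids in (
        (true_present, layout.chain[sel]),
        (d1 > 0, layout.daughters[sel, 0]),
        (d2 > 0, layout.daughters[sel, 1]),
        (d3 > 0, layout.daughters[sel, 2]),
    ):
        if not mask.any():
            continue
        ids = layout.registry[chain_ids[mask]]
        for cid, a in zip(ids, layout.is_alpha[sel][mask]):
            (alpha if a else beta).add(cid)
    return frozenset(alpha), frozenset(beta)


def sample_wells(
    pop: ClonePopulation,
    plan: SamplingPlan,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[WellDataset, list[dict[int, int]]]:
    """Sample the population into wells per ``plan`` with the full error model.

    Each well draws its cells i.i.d. from the clone frequencies (with
    replacement).  Every chain instance of a sampled cell is dropped with the
    clone's drop rate; each surviving instance is replaced, with probability
    equal to the chain's in-frame error rate, by one of its three fixed
    daughter ids (uniformly).  Wells record the set of distinct surviving
    chain ids per locus.

    Returns the :class:`WellDataset` and the per-well ground truth
    (clone index -> number of sampled cells).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    layout = _ChainLayout(pop)
    wells: list[Well] = []
    truth: list[dict[int, int]] = []
    for n in plan.well_sizes():
        counts = rng.multinomial(n, layout.freq)
        sel = np.nonzero(counts[layout.clone])[0]
        copies = counts[layout.clone[sel]]
        alpha, beta = _observed_sets(layout, sel, copies, rng)
        wells.append(Well(size=int(n), alpha_set=alpha, beta_set=beta))
        nz = np.nonzero(counts)[0]
        truth.append({int(c): int(counts[c]) for c in nz})
    return WellDataset(wells), truth


def simulate_single_cells(
    pop: ClonePopulation,
    n_cells: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[tuple[frozenset[str], frozenset[str]]]:
    """Simulate single-cell sequencing of ``n_cells`` cells drawn from the
    population, under the same drop-out and in-frame error model.

    Each cell yields the (alpha_set, beta_set) of its surviving, possibly
    mutated chain ids; a cell losing all α or all β chains yields no usable
    pair but is still reported (with an empty set).
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    layout = _ChainLayout(pop)
    clone_of_cell = rng.choice(len(pop.clones), size=n_cells, p=layout.freq)
    out: list[tuple[frozenset[str], frozenset[str]]] = []
    ones_cache: dict[int, np.ndarray] = {}
    for c in clone_of_cell:
        sel = layout.entries_of_clone[int(c)]
        k = len(sel)
        copies = ones_cache.get(k)
        if copies is None:
            copies = np.ones(k, dtype=int)
            ones_cache[k] = copies
        out.append(_observed_sets(layout, sel, copies, rng))
    return out
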