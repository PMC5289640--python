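"""Scoring algorithm output against simulation ground truth.

Implements the five benchmark metrics (overall/top/tail depth, false pairing
rate, adjusted dual depth and false dual rate), per-clone precision of the
frequency estimates (coefficient of variation), and the per-locus
chain-sharing summary of a clone table.

A clone is expanded to its α×β chain combinations throughout: a dual-TCRα
clone α_j α_k β counts as the two pairs (α_j, β) and (α_k, β), and dual-TCRβ
analogously.  A candidate pair is *correct* iff it is a chain combination of
some true clone; pairs involving an erroneous daughter sequence are never
correct.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .dualcall import DualCall
from .freq import FrequencyEstimate
from .simdata import ClonePopulation

__all__ = [
    "MetricsReport",
    "truth_pairs",
    "top_clone_indices",
    "compute_metrics",
    "single_cell_report",
    "sharing_summary",
]


@dataclass
class MetricsReport:
    """The benchmark metrics; a metric whose denominator is empty is reported
    as None (absent), never as 0."""

    overall_depth: float | None
    top_depth: float | None
    tail_depth: float | None
    false_pairing_rate: float | None
    adjusted_dual_depth: float | None = None
    adjusted_dual_depth_top: float | None = None
    adjusted_dual_depth_tail: float | None = None
    false_dual_rate: float | None = None
    cv_by_clone: dict[tuple, float] = field(default_factory=dict)
    denominators: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in (
            "overall_depth", "top_depth", "tail_depth", "false_pairing_rate",
            "adjusted_dual_depth", "adjusted_dual_depth_top",
            "adjusted_dual_depth_tail", "false_dual_rate",
        ):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0 + 1e-12:
                raise ValueError(f"{name}={v} outside [0, 1]")

    def mean_cv(self) -> float | None:
        if not self.cv_by_clone:
            return None
        return float(np.mean(list(self.cv_by_clone.values())))


def _expand(clone_alpha: Iterable[str], clone_beta: Iterable[str]) -> set[tuple[str, str]]:
    return set(itertools.product(clone_alpha, clone_beta))


def truth_pairs(pop: ClonePopulation) -> set[tuple[str, str]]:
    """All true (α, β) chain combinations in the population."""
    out: set[tuple[str, str]] = set()
    for c in pop.clones:
        out |= _expand(c.alpha_ids, c.beta_ids)
    return out


def top_clone_indices(pop: ClonePopulation, top_mass: float = 0.5) -> set[int]:
    """Clones in the most abundant ``top_mass`` of the population: ranked by
    frequency, the smallest prefix whose cumulative mass reaches the target."""
    order = np.argsort(-pop.frequencies(), kind="stable")
    cum = np.cumsum(pop.frequencies()[order])
    cut = int(np.searchsorted(cum, top_mass - 1e-12) + 1)
    return {int(i) for i in order[:cut]}


def compute_metrics(
    pop: ClonePopulation,
    pairs: Sequence[tuple[str, str]],
    dual_calls: Sequence[DualCall] | None = None,
    estimates: Mapping[tuple, FrequencyEstimate] | None = None,
    top_mass: float = 0.5,
) -> MetricsReport:
    """Score a candidate pair list (and optionally dual calls and frequency
    estimates) against the ground-truth population."""
    pair_set = {(p[0], p[1]) for p in pairs}
    true_set = truth_pairs(pop)
    top_idx = top_clone_indices(pop, top_mass)

    top_pairs: set[tuple[str, str]] = set()
    tail_pairs: set[tuple[str, str]] = set()
    for i, c in enumerate(pop.clones):
        target = top_pairs if i in top_idx else tail_pairs
        target |= _expand(c.alpha_ids, c.beta_ids)
    # a pair carried by both a top and a tail clone belongs to the top set
    tail_pairs -= top_pairs

    denominators = {
        "true_pairs": len(true_set),
        "top_pairs": len(top_pairs),
        "tail_pairs": len(tail_pairs),
        "output_pairs": len(pair_set),
    }

    def ratio(num: int, den: int) -> float | None:
        return num / den if den else None

    overall = ratio(len(pair_set & true_set), len(true_set))
    top = ratio(len(pair_set & top_pairs), len(top_pairs))
    tail = ratio(len(pair_set & tail_pairs), len(tail_pairs))
    fpr = ratio(len(pair_set - true_set), len(pair_set))

    report = MetricsReport(
        overall_depth=overall,
        top_depth=top,
        tail_depth=tail,
        false_pairing_rate=fpr,
        denominators=denominators,
    )

    if dual_calls is not None:
        _add_dual_metrics(report, pop, pair_set, dual_calls, top_idx)

    if estimates is not None:
        report.cv_by_clone = {key: est.cv for key, est in estimates.items()}

    return report


def _add_dual_metrics(
    report: MetricsReport,
    pop: ClonePopulation,
    pair_set: set[tuple[str, str]],
    dual_calls: Sequence[DualCall],
    top_idx: set[int],
) -> None:
    true_duals = {
        (tuple(sorted(c.alpha_ids)), b): i
        for i, c in enumerate(pop.clones)
        if c.is_dual_alpha
        for b in c.beta_ids
    }
    called_dual = {
        (tuple(sorted((d.alpha1, d.alpha2))), d.beta)
        for d in dual_calls
        if d.verdict == "dual"
    }

    eligible = {
        key: i
        for key, i in true_duals.items()
        if (key[0][0], key[1]) in pair_set and (key[0][1], key[1]) in pair_set
    }
    correct = set(eligible) & called_dual

    def ratio(num: int, den: int) -> float | None:
        return num / den if den else None

    report.adjusted_dual_depth = ratio(len(correct), len(eligible))
    top_elig = {k for k, i in eligible.items() if i in top_idx}
    tail_elig = set(eligible) - top_elig
    report.adjusted_dual_depth_top = ratio(len(correct & top_elig), len(top_elig))
    report.adjusted_dual_depth_tail = ratio(len(correct & tail_elig), len(tail_elig))
    report.false_dual_rate = ratio(
        len(called_dual - set(true_duals)), len(called_dual)
    )
    report.denominators.update(
        {
            "eligible_duals": len(eligible),
            "dual_calls": len(called_dual),
        }
    )


def single_cell_report(
    pop: ClonePopulation,
    cells: Sequence[tuple[frozenset, frozenset]],
    top_mass: float = 0.5,
) -> MetricsReport:
    """Score simulated single-cell sequencing.

    Depths are computed on the set of distinct recovered (α, β) pairs (a
    cell's recovered pairs are its surviving α×β chain combinations).  The
    false pairing rate is computed over per-cell pair observations, i.e. each
    cell contributes each of its recovered pairs once, matching the error
    structure of a single-cell experiment (about twice the per-chain in-frame
    error rate).
    """
    true_set = truth_pairs(pop)
    observations = 0
    incorrect = 0
    recovered: set[tuple[str, str]] = set()
    for alpha_set, beta_set in cells:
        for pair in itertools.product(sorted(alpha_set), sorted(beta_set)):
            observations += 1
            if pair not in true_set:
                incorrect += 1
            recovered.add(pair)

    report = compute_metrics(pop, sorted(recovered), top_mass=top_mass)
    report.false_pairing_rate = (
        incorrect / observations if observations else None
    )
    report.denominators["pair_observations"] = observations
    return report


def sharing_summary(
    clone_table: Sequence[tuple[Sequence[str], Sequence[str]]]
) -> dict[str, dict[str, float | int]]:
    """Per-locus sharing summary of a clone table.

    Clones with identical chain combinations are collapsed first; a chain is
    *shared* iff it appears in two or more distinct clones.  Returns, per
    locus, the number of distinct chains, the number shared, and the shared
    percentage.
    """
    if not clone_table:
        raise ValueError("empty clone table")
    dedup = {
        (tuple(sorted(a)), tuple(sorted(b))) for a, b in clone_table
    }
    out: dict[str, dict[str, float | int]] = {}
    for locus, which in (("alpha", 0), ("beta", 1)):
        counts: dict[str, int] = {}
        for clone in dedup:
            for cid in clone[which]:
                counts[cid] = counts.get(cid, 0) + 1
        distinct = len(counts)
        shared = sum(1 for v in counts.values() if v >= 2)
        out[locus] = {
            "distinct": distinct,
            "shared": shared,
            "percent_shared": 100.0 * shared / distinct if distinct else 0.0,
        }
    out["n_clones"] = {"distinct": len(dedup)}
    return out
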