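"""Model/Results interface wrapping the full pairing pipeline.

:class:`TCRPairingModel` holds a well dataset and the algorithm parameters;
``fit()`` runs consensus pairing, clonal frequency estimation and dual-TCRα
discrimination, and returns a :class:`TCRPairingResults` carrying the
candidate pairs, the per-clone frequency estimates with 95% confidence
intervals, the dual calls and the assembled clone table.

Example
-------
>>> from tcrpair import simdata
>>> from tcrpair.model import TCRPairingModel
>>> pop = simdata.generate_population(N=200, n_s=10, seed=1)
>>> plan = simdata.build_sampling_plan("high-mixed", 1)
>>> wells, _ = simdata.sample_wells(pop, plan, seed=2)
>>> res = TCRPairingModel(wells, n_r=25, seed=3).fit()
>>> clones = res.clones  # DataFrame of single and dual clones with CIs
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import dualcall as _dualcall
from . import freq as _freq
from . import io as _io
from . import pairing as _pairing
from .simdata import WellDataset

__all__ = ["TCRPairingModel", "TCRPairingResults"]


class TCRPairingModel:
    """Frequency-based αβ chain pairing fitted to a multi-well dataset.

    Parameters
    ----------
    wells : WellDataset
        Observed per-well chain sets with sample sizes.
    p_j, n_r, threshold : jackknife subsample proportion, replicate count,
        and consensus threshold of the pairing stage.
    eps : assumed mean per-chain-instance drop rate used by the occupancy
        likelihoods (prior knowledge; not estimated from the data).
    size_cap, delta_threshold : parameters of the full-likelihood dual-TCRα
        route (well-size cutoff and the log-likelihood difference required
        to override the clustering verdict).
    seed : drives every stochastic component (well subsampling, k-means).
    """

    def __init__(
        self,
        wells: WellDataset,
        *,
        p_j: float = 0.75,
        n_r: int = 100,
        threshold: float = 0.6,
        eps: float = 0.15,
        size_cap: int = 50,
        delta_threshold: float = 10.0,
        seed: int = 0,
    ):
        if wells.n_wells == 0:
            raise ValueError("empty well dataset")
        self.wells = wells
        self.config = _pairing.PairingConfig(
            p_j=p_j, n_r=n_r, threshold=threshold, seed=seed
        )
        if not 0.0 <= eps < 1.0:
            raise ValueError("eps must lie in [0, 1)")
        self.eps = eps
        self.size_cap = size_cap
        self.delta_threshold = delta_threshold
        self.seed = seed

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "TCRPairingModel":
        """Build from a long-form well table (well_id, sample_size, locus,
        chain_id)."""
        return cls(_io.wells_from_dataframe(df), **kwargs)

    @classmethod
    def from_table(cls, path: str | Path, **kwargs) -> "TCRPairingModel":
        return cls(_io.read_well_table(path), **kwargs)

    # -- fitting ---------------------------------------------------------------

    def fit(
        self, support: Mapping[tuple[str, str], float] | None = None
    ) -> "TCRPairingResults":
        """Run the full pipeline.  ``support`` may carry precomputed
        replicate supports (e.g. when scanning several thresholds); it must
        come from the same wells, p_j, n_r and seed."""
        if support is None:
            support = _pairing.consensus_support(self.wells, self.config)
        pairs = _pairing.filter_support(dict(support), self.config.threshold)

        estimates: dict[tuple[str, str], _freq.FrequencyEstimate] = {}
        kept: list[tuple[str, str, float]] = []
        for a, b, s in pairs:
            counts = _freq.occupancy_counts(self.wells, (a, b))
            if counts.total_hits == 0:  # pragma: no cover - pairs always co-occur
                continue
            estimates[(a, b)] = _freq.estimate_frequency(counts, eps=self.eps)
            kept.append((a, b, s))

        calls, candidates = _dualcall.call_duals(
            [(a, b) for a, b, _ in kept],
            self.wells,
            estimates,
            eps=self.eps,
            size_cap=self.size_cap,
            delta_threshold=self.delta_threshold,
            seed=self.seed,
        )
        return TCRPairingResults(
            model=self,
            pairs=_pairing.CandidatePairList(kept),
            estimates=estimates,
            dual_calls=calls,
            candidates=candidates,
        )


@dataclass
class TCRPairingResults:
    """Fitted output: candidate pairs, frequency estimates, dual calls, and
    the final clone table."""

    model: TCRPairingModel
    pairs: _pairing.CandidatePairList
    estimates: dict[tuple[str, str], _freq.FrequencyEstimate]
    dual_calls: list[_dualcall.DualCall]
    candidates: list[_dualcall.SharingCandidate]
    clones: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        self.clones = self._assemble_clones()

    def _assemble_clones(self) -> pd.DataFrame:
        """Merge dual calls into the pair list: each accepted dual replaces
        its two constituent pairs by one dual-α clone whose frequency is the
        dual-mode re-estimate.  Overlapping dual calls (sharing a pair) are
        resolved greedily in order of decreasing evidence, likelihood-route
        calls first."""
        support = {(a, b): s for a, b, s in self.pairs}
        cand_by_key = {
            (c.alpha1, c.alpha2, c.beta): c for c in self.candidates
        }
        accepted = [d for d in self.dual_calls if d.verdict == "dual"]
        accepted.sort(
            key=lambda d: (
                0 if d.method == "full_likelihood" else 1,
                -d.evidence if math.isfinite(d.evidence) else -math.inf,
            )
        )
        consumed: set[tuple[str, str]] = set()
        rows = []
        for d in accepted:
            p1, p2 = (d.alpha1, d.beta), (d.alpha2, d.beta)
            cand = cand_by_key[(d.alpha1, d.alpha2, d.beta)]
            if p1 in consumed or p2 in consumed or cand.f_dual is None:
                continue
            consumed |= {p1, p2}
            est = cand.f_dual
            rows.append(
                {
                    "alpha_ids": f"{d.alpha1};{d.alpha2}",
                    "beta_id": d.beta,
                    "dual_flag": True,
                    "f_hat": est.f_hat,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "support": min(support[p1], support[p2]),
                    "method": d.method,
                    "evidence": d.evidence,
                }
            )
        for a, b, s in self.pairs:
            if (a, b) in consumed:
                continue
            est = self.estimates[(a, b)]
            rows.append(
                {
                    "alpha_ids": a,
                    "beta_id": b,
                    "dual_flag": False,
                    "f_hat": est.f_hat,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "support": s,
                    "method": "",
                    "evidence": float("nan"),
                }
            )
        df = pd.DataFrame(
            rows,
            columns=[
                "alpha_ids", "beta_id", "dual_flag", "f_hat", "ci_low",
                "ci_high", "support", "method", "evidence",
            ],
        )
        df = df.sort_values(
            ["f_hat", "alpha_ids", "beta_id"], ascending=[False, True, True]
        ).reset_index(drop=True)
        df.insert(0, "clone_id", [f"c{i}" for i in range(len(df))])
        return df

    # -- reporting -------------------------------------------------------------

    @property
    def n_duals(self) -> int:
        return int(self.clones["dual_flag"].sum())

    def summary(self, max_rows: int = 20) -> str:
        """Human-readable fit summary: configuration, counts, and the most
        abundant clones with their frequency estimates."""
        cfg = self.model.config
        lines = [
            "TCR alpha/beta pairing results",
            "==============================",
            f"wells: {self.model.wells.n_wells}   "
            f"p_J={cfg.p_j}  N_r={cfg.n_r}  T={cfg.threshold}  "
            f"eps={self.model.eps}",
            f"candidate pairs: {len(self.pairs)}   "
            f"clones: {len(self.clones)} ({self.n_duals} dual-alpha)",
            "",
            f"top clones (of {len(self.clones)}):",
        ]
        head = self.clones.head(max_rows)
        lines.append(
            head.to_string(
                index=False,
                columns=[
                    "clone_id", "alpha_ids", "beta_id", "dual_flag",
                    "f_hat", "ci_low", "ci_high", "support",
                ],
                float_format=lambda v: f"{v:.5f}",
            )
        )
        return "\n".join(lines)
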