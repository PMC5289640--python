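"""Table and configuration I/O, plus the end-to-end pipeline runner.

All tables are flat TSV (``sep="\\t"``).  Schemas:

* well table — one row per distinct chain per well:
  ``well_id, sample_size, locus (alpha|beta), chain_id``
* truth clone table — ``clone_id, alpha_ids, beta_ids, frequency, drop_rate``
  (chain lists semicolon-joined)
* chain registry — ``daughter_id, parent_id``
* pairs table — ``alpha_id, beta_id, support``
* clones output table —
  ``clone_id, alpha_ids, beta_id, dual_flag, f_hat, ci_low, ci_high, method, evidence``

Chain identifiers are opaque strings; numeric ids and CDR3 amino-acid
sequences both pass through untouched.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simdata import (
    ClonePopulation,
    SamplingPlan,
    SharingSpec,
    Well,
    WellDataset,
    build_sampling_plan,
    generate_population,
    sample_wells,
)

__all__ = [
    "RunConfig",
    "read_well_table",
    "write_well_table",
    "write_truth_tables",
    "read_pairs_table",
    "write_pairs_table",
    "run_all",
]

logger = logging.getLogger(__name__)

WELL_COLUMNS = ["well_id", "sample_size", "locus", "chain_id"]


def write_well_table(data: WellDataset, path: str | Path) -> None:
    rows = []
    width = len(str(data.n_wells))
    for k, w in enumerate(data):
        wid = f"w{k:0{width}d}"
        for cid in sorted(w.alpha_set):
            rows.append((wid, w.size, "alpha", cid))
        for cid in sorted(w.beta_set):
            rows.append((wid, w.size, "beta", cid))
    pd.DataFrame(rows, columns=WELL_COLUMNS).to_csv(path, sep="\t", index=False)


def wells_from_dataframe(df: pd.DataFrame) -> WellDataset:
    """Build a :class:`WellDataset` from a long-form well/chain table."""
    missing = [c for c in WELL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"well table is missing columns: {missing}")
    if len(df) == 0:
        raise ValueError("well table is empty")
    bad = ~df["locus"].isin(["alpha", "beta"])
    if bad.any():
        raise ValueError(f"unknown locus values: {sorted(df.loc[bad, 'locus'].unique())}")
    if (df["sample_size"] <= 0).any():
        raise ValueError("sample_size must be positive for every row")
    ndup = df.duplicated(subset=["well_id", "locus", "chain_id"]).sum()
    if ndup:
        warnings.warn(f"collapsed {ndup} duplicate (well, locus, chain) rows")
        df = df.drop_duplicates(subset=["well_id", "locus", "chain_id"])
    sizes = df.groupby("well_id")["sample_size"].nunique()
    if (sizes > 1).any():
        raise ValueError("conflicting sample_size values within a well")
    wells = []
    for wid, grp in df.groupby("well_id", sort=True):
        alpha = frozenset(grp.loc[grp["locus"] == "alpha", "chain_id"].astype(str))
        beta = frozenset(grp.loc[grp["locus"] == "beta", "chain_id"].astype(str))
        wells.append(Well(size=int(grp["sample_size"].iloc[0]), alpha_set=alpha, beta_set=beta))
    return WellDataset(wells)


def read_well_table(path: str | Path) -> WellDataset:
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise ValueError(f"well table {path} is missing or empty")
    df = pd.read_csv(path, sep="\t", dtype={"chain_id": str, "well_id": str})
    return wells_from_dataframe(df)


def write_truth_tables(
    pop: ClonePopulation, clone_path: str | Path, registry_path: str | Path
) -> None:
    rows = [
        (
            f"c{i}",
            ";".join(c.alpha_ids),
            ";".join(c.beta_ids),
            c.frequency,
            c.drop_rate,
        )
        for i, c in enumerate(pop.clones)
    ]
    pd.DataFrame(
        rows, columns=["clone_id", "alpha_ids", "beta_ids", "frequency", "drop_rate"]
    ).to_csv(clone_path, sep="\t", index=False)
    reg = [(d, parent) for parent, trio in sorted(pop.daughters.items()) for d in trio]
    pd.DataFrame(reg, columns=["daughter_id", "parent_id"]).to_csv(
        registry_path, sep="\t", index=False
    )


def read_truth_clone_table(path: str | Path) -> list[tuple[list[str], list[str], float]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for _, r in df.iterrows():
        out.append(
            (r["alpha_ids"].split(";"), r["beta_ids"].split(";"), float(r["frequency"]))
        )
    return out


def write_pairs_table(pairs, path: str | Path) -> None:
    pd.DataFrame(
        [(a, b, s) for a, b, s in pairs], columns=["alpha_id", "beta_id", "support"]
    ).to_csv(path, sep="\t", index=False)


def read_pairs_table(path: str | Path) -> list[tuple[str, str, float]]:
    df = pd.read_csv(path, sep="\t", dtype={"alpha_id": str, "beta_id": str})
    missing = [c for c in ("alpha_id", "beta_id") if c not in df.columns]
    if missing:
        raise ValueError(f"pairs table is missing columns: {missing}")
    if "support" not in df.columns:
        df["support"] = 1.0
    return [
        (str(r.alpha_id), str(r.beta_id), float(r.support)) for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Flat configuration for the full simulate→pair→estimate→call pipeline,
    with the published defaults."""

    # population
    n_clones: int = 2100
    n_top: int = 25
    top_mass: float = 0.5
    dual_alpha_prev: float = 0.30
    dual_beta_prev: float = 0.06
    # sharing spectra: multiplicity -> probability; None = published defaults
    alpha_sharing: dict | None = None
    beta_sharing: dict | None = None
    drop_mean: float = 0.15
    drop_sd: float = 0.01
    err_mean: float = 0.02
    err_sd: float = 0.005
    # sampling
    strategy: str = "high-mixed"
    plates: int = 1
    # pairing
    p_j: float = 0.75
    n_r: int = 100
    threshold: float = 0.6
    # estimation / dual calling
    eps: float = 0.15
    size_cap: int = 50
    delta_threshold: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.n_top < self.n_clones:
            raise ValueError("need 0 < n_top < n_clones")
        if not 0.0 < self.top_mass < 1.0:
            raise ValueError("top_mass must lie in (0, 1)")
        for name in ("dual_alpha_prev", "dual_beta_prev"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 < self.p_j <= 1.0:
            raise ValueError("p_j must lie in (0, 1]")
        if self.n_r < 1:
            raise ValueError("n_r must be >= 1")
        if not 0.0 <= self.threshold < 1.0:
            raise ValueError("threshold must lie in [0, 1)")
        if not 0.0 <= self.eps < 1.0:
            raise ValueError("eps must lie in [0, 1)")
        if self.size_cap < 2 or self.delta_threshold < 0:
            raise ValueError("invalid dual-calling parameters")
        for name in ("alpha_sharing", "beta_sharing"):
            raw = getattr(self, name)
            if raw is not None:
                # normalise keys to int and validate through SharingSpec
                spec = {int(k): float(v) for k, v in raw.items()}
                SharingSpec(spec)
                setattr(self, name, spec)

    def sharing_specs(self) -> tuple[SharingSpec, SharingSpec]:
        from .simdata import DEFAULT_ALPHA_SHARING, DEFAULT_BETA_SHARING

        a = (
            SharingSpec(self.alpha_sharing)
            if self.alpha_sharing is not None
            else DEFAULT_ALPHA_SHARING
        )
        b = (
            SharingSpec(self.beta_sharing)
            if self.beta_sharing is not None
            else DEFAULT_BETA_SHARING
        )
        return a, b

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValueError("config must be a flat key -> value mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

def run_all(config: RunConfig, outdir: str | Path) -> dict[str, Path]:
    """Simulate a dataset per the config, run the full pairing pipeline, score
    it against the ground truth, and write every artifact (plus a manifest)
    under ``outdir``.  Deterministic given the config seed."""
    from . import __version__
    from .evaluate import compute_metrics
    from .model import TCRPairingModel

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    ss = np.random.SeedSequence(config.seed)
    pop_seed, well_seed, fit_seed = [
        int(s.generate_state(1, dtype="uint64")[0] % (2**31)) for s in ss.spawn(3)
    ]
    alpha_spec, beta_spec = config.sharing_specs()
    pop = generate_population(
        N=config.n_clones,
        n_s=config.n_top,
        p_s=config.top_mass,
        alpha_sharing=alpha_spec,
        beta_sharing=beta_spec,
        dual_alpha_prev=config.dual_alpha_prev,
        dual_beta_prev=config.dual_beta_prev,
        drop_mean=config.drop_mean,
        drop_sd=config.drop_sd,
        err_mean=config.err_mean,
        err_sd=config.err_sd,
        seed=pop_seed,
    )
    plan = build_sampling_plan(config.strategy, config.plates)
    data, _truth = sample_wells(pop, plan, seed=well_seed)
    timings["simulate"] = time.perf_counter() - t0

    paths = {
        "wells": outdir / "wells.tsv",
        "truth_clones": outdir / "truth_clones.tsv",
        "chain_registry": outdir / "chain_registry.tsv",
        "pairs": outdir / "pairs.tsv",
        "clones": outdir / "clones.tsv",
        "metrics": outdir / "metrics.json",
        "manifest": outdir / "manifest.json",
    }
    write_well_table(data, paths["wells"])
    write_truth_tables(pop, paths["truth_clones"], paths["chain_registry"])

    t0 = time.perf_counter()
    model = TCRPairingModel(
        data,
        p_j=config.p_j,
        n_r=config.n_r,
        threshold=config.threshold,
        eps=config.eps,
        size_cap=config.size_cap,
        delta_threshold=config.delta_threshold,
        seed=fit_seed,
    )
    result = model.fit()
    timings["fit"] = time.perf_counter() - t0

    write_pairs_table(result.pairs, paths["pairs"])
    result.clones.to_csv(paths["clones"], sep="\t", index=False)

    t0 = time.perf_counter()
    report = compute_metrics(
        pop,
        [(a, b) for a, b, _ in result.pairs],
        dual_calls=result.dual_calls,
        estimates=result.estimates,
        top_mass=config.top_mass,
    )
    timings["evaluate"] = time.perf_counter() - t0

    metrics = {
        k: getattr(report, k)
        for k in (
            "overall_depth", "top_depth", "tail_depth", "false_pairing_rate",
            "adjusted_dual_depth", "adjusted_dual_depth_top",
            "adjusted_dual_depth_tail", "false_dual_rate",
        )
    }
    metrics["mean_cv"] = report.mean_cv()
    metrics["denominators"] = report.denominators
    paths["metrics"].write_text(json.dumps(metrics, indent=2, sort_keys=True))

    cfg_dict = dataclasses.asdict(config)
    manifest = {
        "version": __version__,
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "n_wells": data.n_wells,
        "n_candidate_pairs": len(result.pairs),
        "n_clones_out": int(len(result.clones)),
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
    for stage, secs in timings.items():
        logger.info("stage %-8s %7.2fs", stage, secs)
    return paths
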