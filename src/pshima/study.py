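"""Monte-Carlo evaluation of the mediation pipelines.

Runs R independent replicates of the synthetic study per (mode, n, p,
method) cell and tallies the benchmark metrics: per-mediator MCP selection
counts, joint-test true-positive rates, the mean false-positive count per
replicate, the mean per-replicate false discovery proportion, and the mean
indirect-effect estimate (conditional on MCP selection) with its MSE.

Replicate r uses the seed derived from (base_seed, r) — with the default
base_seed=0 simply seed r — so results are independent of the worker count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .pipeline import RunConfig, run_hima
from .screening import METHODS
from .simulate import MediationDataset, SimulationConfig, generate_dataset

__all__ = ["ReplicateRecord", "MetricsTable", "run_replicate", "summarize", "run_study"]

logger = logging.getLogger("pshima")


@dataclass
class ReplicateRecord:
    """What one pipeline run contributes to the study metrics."""

    seed: int
    method: str
    support: np.ndarray          # 0-based mediator indices in the MCP support
    significant: np.ndarray      # 0-based indices declared by the joint test
    effects: dict[int, float]    # k -> alpha_hat*beta_hat for k in support
    error: Optional[str] = None


@dataclass
class MetricsTable:
    """Aggregated study metrics for one (mode, n, p, method) cell."""

    method: str
    n_replicates: int
    per_mediator: pd.DataFrame   # rows M1..M8: selection_count, TPR, estimate, MSE, emp. SE
    fp: float                    # mean false positives per replicate
    fdr: float                   # mean per-replicate FP / positives (0/0 -> 0)
    n_failed: int = 0


def replicate_seed(base_seed: int, r: int) -> int:
    """Deterministic per-replicate seed; equals r when base_seed is 0."""
    if base_seed == 0:
        return r
    return int(np.random.SeedSequence([base_seed, r]).generate_state(1)[0] % (2**31))


def run_replicate(config: SimulationConfig, run: RunConfig) -> ReplicateRecord:
    """Generate one dataset and run one pipeline on it."""
    dataset = generate_dataset(config)
    return _record_from_run(dataset, run, config.seed)


def _record_from_run(
    dataset: MediationDataset, run: RunConfig, seed: int
) -> ReplicateRecord:
    try:
        result = run_hima(dataset, run)
    except Exception as exc:  # noqa: BLE001 - flagged and excluded from averages
        logger.warning("replicate seed=%d method=%s failed: %s", seed, run.method, exc)
        return ReplicateRecord(
            seed=seed, method=run.method,
            support=np.empty(0, int), significant=np.empty(0, int),
            effects={}, error=str(exc),
        )
    idx = result.table["index"].to_numpy(dtype=int) if len(result.table) else np.empty(0, int)
    sig = idx[result.table["significant"].to_numpy(dtype=bool)] if len(result.table) else np.empty(0, int)
    effects = dict(zip(idx.tolist(), result.table["effect"].tolist()))
    return ReplicateRecord(
        seed=seed, method=run.method, support=idx, significant=sig, effects=effects
    )


def _one_replicate(
    config: SimulationConfig, runs: Sequence[RunConfig], seed: int
) -> list[ReplicateRecord]:
    """All requested methods on a single shared dataset."""
    cfg = replace(config, seed=seed)
    dataset = generate_dataset(cfg)
    return [_record_from_run(dataset, run, seed) for run in runs]


def summarize(
    records: Sequence[ReplicateRecord], true_effects: np.ndarray
) -> MetricsTable:
    """Tally study metrics from one method's replicate records.

    ``true_effects`` is the length-p vector of true alpha_k*beta_k; its
    nonzero positions define the true mediators (decoys and nulls count as
    false positives when declared).
    """
    records = list(records)
    if not records:
        raise ValueError("no replicate records to summarize")
    good = [r for r in records if r.error is None]
    n_failed = len(records) - len(good)
    if not good:
        raise ValueError("all replicates failed")
    true_effects = np.asarray(true_effects, dtype=float)
    true_set = np.flatnonzero(true_effects != 0)
    R = len(good)

    sel = np.zeros(len(true_set), dtype=int)
    tpr = np.zeros(len(true_set))
    est_lists: list[list[float]] = [[] for _ in true_set]
    fp_counts = np.zeros(R)
    fdr_vals = np.zeros(R)
    for ri, rec in enumerate(good):
        sup = set(rec.support.tolist())
        sig = set(rec.significant.tolist())
        for ki, k in enumerate(true_set):
            if k in sup:
                sel[ki] += 1
                est_lists[ki].append(rec.effects[k])
            if k in sig:
                tpr[ki] += 1
        fp = len(sig - set(true_set.tolist()))
        fp_counts[ri] = fp
        fdr_vals[ri] = fp / len(sig) if sig else 0.0
    tpr /= R

    rows = []
    for ki, k in enumerate(true_set):
        ests = np.array(est_lists[ki])
        rows.append(
            {
                "mediator": f"M{k + 1}",
                "index": int(k),
                "true_effect": true_effects[k],
                "selection_count": int(sel[ki]),
                "TPR": tpr[ki],
                "estimate": float(ests.mean()) if ests.size else np.nan,
                "MSE": float(np.mean((ests - true_effects[k]) ** 2)) if ests.size else np.nan,
                "emp_se": float(ests.std(ddof=1)) if ests.size > 1 else np.nan,
            }
        )
    return MetricsTable(
        method=good[0].method,
        n_replicates=R,
        per_mediator=pd.DataFrame(rows),
        fp=float(fp_counts.mean()),
        fdr=float(fdr_vals.mean()),
        n_failed=n_failed,
    )


def run_study(
    mode: int = 1,
    n: int = 300,
    p: int = 1000,
    methods: Sequence[str] = METHODS,
    reps: int = 500,
    workers: int = 1,
    base_seed: int = 0,
    run_config: Optional[RunConfig] = None,
    sim_config: Optional[SimulationConfig] = None,
) -> dict[str, MetricsTable]:
    """Full Monte-Carlo study for one (mode, n, p) cell, all methods.

    Datasets are shared across methods within a replicate. Results do not
    depend on ``workers`` (each replicate is seeded independently).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    methods = [m.upper() for m in methods]
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown method {m!r}")
    base_sim = sim_config if sim_config is not None else SimulationConfig(n=n, p=p, mode=mode)
    base_run = run_config if run_config is not None else RunConfig()
    runs = [replace(base_run, method=m) for m in methods]
    seeds = [replicate_seed(base_seed, r) for r in range(1, reps + 1)]

    if workers == 1:
        all_records = [_one_replicate(base_sim, runs, s) for s in seeds]
    else:
        all_records = Parallel(n_jobs=workers)(
            delayed(_one_replicate)(base_sim, runs, s) for s in seeds
        )

    alpha, beta = base_sim.effects()
    true_effects = alpha * beta
    out: dict[str, MetricsTable] = {}
    for mi, m in enumerate(methods):
        out[m] = summarize([recs[mi] for recs in all_records], true_effects)
    return out


def study_report(results: dict[str, MetricsTable], out_dir) -> None:
    """Write selection / testing / estimation CSVs shaped like the benchmark tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sel_rows, test_rows, est_rows = [], [], []
    for method, mt in results.items():
        pm = mt.per_mediator.set_index("mediator")
        sel_rows.append({"method": method, **pm["selection_count"].to_dict()})
        test_rows.append(
            {"method": method, **pm["TPR"].to_dict(), "FP": mt.fp, "FDR": mt.fdr}
        )
        est = {
            f"{name} (true {row.true_effect:.4f})": row.estimate
            for name, row in pm.iterrows()
        }
        est_rows.append({"method": method, **est})
    pd.DataFrame(sel_rows).to_csv(out / "selection_counts.csv", index=False)
    pd.DataFrame(test_rows).to_csv(out / "testing_metrics.csv", index=False)
    pd.DataFrame(est_rows).to_csv(out / "estimates.csv", index=False)
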