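"""End-to-end mediation pipelines (PSR, PSW, PSU, COV) and file I/O.

Each method runs the same four stages — propensity scoring (skipped for
COV), sure independence screening, MCP-penalized selection, and the
joint-significance test — differing only in how confounding is adjusted:

* PSR: the propensity score enters every regression as a covariate.
* PSW: inverse-probability weighting in the screening step-1 fit and in the
  alpha model; the MCP objective itself is unweighted.
* PSU: the hybrid — PSW's outcome-side pathway (two-step screening,
  unweighted MCP) with PSR's mediator-side alpha model. By construction its
  selected support equals PSW's and its alpha estimates equal PSR's.
* COV: all confounders enter every regression directly.

The pipeline is deterministic given its inputs.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import inference, mcp, screening
from .propensity import PropensityResult, fit_propensity
from .screening import METHODS
from .simulate import MediationDataset

__all__ = ["RunConfig", "MediationTable", "run_hima", "read_dataset", "write_dataset"]

logger = logging.getLogger("pshima")

RESULT_COLUMNS = [
    "mediator",
    "alpha",
    "alpha_se",
    "beta",
    "beta_se",
    "effect",
    "pct_te",
    "p_raw_alpha",
    "p_raw_beta",
    "p_bh_alpha",
    "p_bh_beta",
    "p_joint",
    "significant",
]


@dataclass
class RunConfig:
    """All pipeline knobs for one analysis."""

    method: str = "PSU"
    d_override: Optional[int] = None
    delta: float = mcp.DEFAULT_DELTA
    ic: str = "bic"
    nlambda: int = mcp.DEFAULT_NLAMBDA
    level: float = 0.05
    clip_scores: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.method = self.method.upper()
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        if not 0 < self.level < 1:
            raise ValueError("significance level must be in (0, 1)")


@dataclass
class MediationTable:
    """Per-candidate mediation results plus study-level direct effect."""

    table: pd.DataFrame
    gamma_hat: float
    method: str
    d: int
    lam: float = float("nan")
    support_size: int = 0
    propensity: Optional[PropensityResult] = None

    def significant_mediators(self) -> list[str]:
        return list(self.table.loc[self.table["significant"], "mediator"])

    def to_csv(self, path) -> None:
        out = self.table.copy()
        for col in out.columns:
            if out[col].dtype.kind == "f":
                out[col] = out[col].map(lambda v: f"{v:.6g}")
        out.to_csv(path, index=False)


def _empty_table(method: str, d: int, gamma: float, lam: float,
                 propensity: Optional[PropensityResult]) -> MediationTable:
    return MediationTable(
        table=pd.DataFrame(columns=RESULT_COLUMNS),
        gamma_hat=gamma,
        method=method,
        d=d,
        lam=lam,
        support_size=0,
        propensity=propensity,
    )


def run_hima(dataset: MediationDataset, config: RunConfig) -> MediationTable:
    """Run the four-stage mediation analysis for one method."""
    method = config.method
    t0 = time.perf_counter()

    # stage 1: propensity score + IPW weights (not needed for COV)
    ps: Optional[PropensityResult] = None
    if method != "COV":
        ps = fit_propensity(dataset.X, dataset.Z, clip=config.clip_scores)

    # stage 2: sure independence screening
    scr = screening.screen(dataset, method, propensity=ps, d=config.d_override)
    logger.info(
        "%s: screened %d -> %d mediators (%.2fs)",
        method, dataset.p, len(scr.kept), time.perf_counter() - t0,
    )

    # stage 3: MCP-penalized selection on the screened set
    M_scr = dataset.M[:, scr.kept]
    if method == "PSR":
        extra = ps.scores.reshape(-1, 1)
    elif method == "COV":
        extra = dataset.Z
    else:  # PSW / PSU: unweighted objective without a score term
        extra = None
    path = mcp.fit_mcp_path(
        dataset.Y, dataset.X, M_scr, extra=extra,
        nlambda=config.nlambda, delta=config.delta, strict=False,
    )
    fit = mcp.select_lambda(path, criterion=config.ic, n_candidates=len(scr.kept))
    support_local = fit.support
    C = scr.kept[support_local]  # original mediator column indices
    logger.info(
        "%s: MCP selected |C|=%d at lambda=%.4g (d=%d)",
        method, len(C), fit.lam, scr.d,
    )

    if len(C) == 0:
        return _empty_table(method, scr.d, fit.gamma_hat, fit.lam, ps)

    # stage 4a: oracle refit for beta SEs and the direct effect
    M_C = dataset.M[:, C]
    se_beta = mcp.oracle_se(dataset.Y, dataset.X, M_C, extra=extra)
    beta_hat = fit.beta[support_local]
    gamma_hat = _direct_effect(dataset, method, ps, M_C, extra)

    # stage 4b: alpha side with the method's adjustment
    if method in ("PSR", "PSU"):
        adjuster = ps.scores
    elif method == "PSW":
        adjuster = ps.weights
    else:
        adjuster = dataset.Z
    alpha_hat = np.empty(len(C))
    alpha_se = np.empty(len(C))
    for i, k in enumerate(C):
        alpha_hat[i], alpha_se[i] = inference.estimate_alpha(
            dataset.M[:, k], dataset.X, adjuster, method
        )

    # stage 4c: raw p-values, BH over the candidate set, joint decision
    p_raw_a = np.array([inference.raw_pvalue(a, s) for a, s in zip(alpha_hat, alpha_se)])
    p_raw_b = np.array([inference.raw_pvalue(b, s) for b, s in zip(beta_hat, se_beta)])
    p_bh_a = inference.bh_adjust(p_raw_a)
    p_bh_b = inference.bh_adjust(p_raw_b)
    joint = [inference.joint_decision(pa, pb, config.level) for pa, pb in zip(p_bh_a, p_bh_b)]
    p_joint = np.array([j[0] for j in joint])
    signif = np.array([j[1] for j in joint])

    effects = alpha_hat * beta_hat
    pct = np.array([inference.percent_te(e, gamma_hat, effects) for e in effects])

    names = dataset.mediator_names or [f"M{k + 1}" for k in range(dataset.p)]
    table = pd.DataFrame(
        {
            "mediator": [names[k] for k in C],
            "alpha": alpha_hat,
            "alpha_se": alpha_se,
            "beta": beta_hat,
            "beta_se": se_beta,
            "effect": effects,
            "pct_te": pct,
            "p_raw_alpha": p_raw_a,
            "p_raw_beta": p_raw_b,
            "p_bh_alpha": p_bh_a,
            "p_bh_beta": p_bh_b,
            "p_joint": p_joint,
            "significant": signif,
        }
    )
    table.insert(1, "index", C)
    return MediationTable(
        table=table,
        gamma_hat=gamma_hat,
        method=method,
        d=scr.d,
        lam=fit.lam,
        support_size=len(C),
        propensity=ps,
    )


def _direct_effect(
    dataset: MediationDataset,
    method: str,
    ps: Optional[PropensityResult],
    M_C: np.ndarray,
    extra: Optional[np.ndarray],
) -> float:
    """gamma from the method's final outcome refit on the support."""
    n = dataset.n
    if method in ("PSW", "PSU"):
        # weighted refit of Y ~ 1 + X + M_C
        w = ps.weights
        D = np.column_stack([np.ones(n), dataset.X, M_C])
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(sw[:, None] * D, sw * dataset.Y, rcond=None)
        return float(coef[1])
    cols = [np.ones(n), dataset.X]
    if extra is not None:
        cols.append(extra)
    D = np.column_stack(cols + [M_C])
    coef, *_ = np.linalg.lstsq(D, dataset.Y, rcond=None)
    return float(coef[1])


# ---------------------------------------------------------------------------
# file I/O


def _read_table(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") > header.count(",") else ","
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] > 1 and df.iloc[:, 0].dtype == object:
        df = df.set_index(df.columns[0])  # leading sample-identifier column
    return df


def _check_numeric(df: pd.DataFrame, name: str) -> np.ndarray:
    arr = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    if np.isnan(arr).any():
        i, j = np.argwhere(np.isnan(arr))[0]
        raise ValueError(
            f"{name}: missing or non-numeric value at row {i + 1}, "
            f"column {df.columns[j]!r}"
        )
    return arr


def read_dataset(
    x_path, m_path, y_path, z_path=None, directory=None
) -> MediationDataset:
    """Load (X, M, Y[, Z]) from delimited text files (samples as rows)."""
    if directory is not None:
        directory = Path(directory)
        x_path = directory / "X.csv"
        m_path = directory / "M.csv"
        y_path = directory / "Y.csv"
        zp = directory / "Z.csv"
        z_path = zp if zp.exists() else None
    X = _check_numeric(_read_table(Path(x_path)), "X").ravel()
    Y = _check_numeric(_read_table(Path(y_path)), "Y").ravel()
    m_df = _read_table(Path(m_path))
    M = _check_numeric(m_df, "M")
    if z_path is not None:
        Z = _check_numeric(_read_table(Path(z_path)), "Z")
    else:
        Z = np.empty((len(X), 0))
    if not (len(X) == len(Y) == M.shape[0] == Z.shape[0]):
        raise ValueError(
            f"inconsistent sample counts: X={len(X)}, Y={len(Y)}, "
            f"M={M.shape[0]}, Z={Z.shape[0]}"
        )
    uniq = set(np.unique(X))
    if not uniq <= {0.0, 1.0}:
        raise ValueError(
            f"exposure X must be coded 0/1, found values {sorted(uniq)}; "
            "recode (e.g. 1/2 -> 0/1) before running"
        )
    return MediationDataset(
        X=X, Y=Y, M=M, Z=Z, mediator_names=[str(c) for c in m_df.columns]
    )


def write_dataset(dataset: MediationDataset, out_dir) -> None:
    """Write X/Y/M/Z (and the simulation truth, when known) as CSV files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"X": dataset.X.astype(int)}).to_csv(out / "X.csv", index=False)
    pd.DataFrame({"Y": dataset.Y}).to_csv(out / "Y.csv", index=False)
    pd.DataFrame(dataset.M, columns=dataset.mediator_names).to_csv(
        out / "M.csv", index=False
    )
    pd.DataFrame(
        dataset.Z, columns=[f"Z{j + 1}" for j in range(dataset.w)]
    ).to_csv(out / "Z.csv", index=False)
    if dataset.true_alpha is not None and dataset.true_beta is not None:
        pd.DataFrame(
            {
                "mediator": dataset.mediator_names,
                "alpha": dataset.true_alpha,
                "beta": dataset.true_beta,
                "effect": dataset.true_alpha * dataset.true_beta,
            }
        ).to_csv(out / "truth.csv", index=False)
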