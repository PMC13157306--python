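"""Missing-data handling: diagnostics, chained-equations imputation,
multicollinearity checks, and pooling of per-imputation networks.

Imputation is chained equations with predictive mean matching (PMM) for
ordinal items and logistic draws for binary items: each incomplete column is
regressed on all other columns (both waves enter each model), missing entries
are filled from nearest-predicted-mean donors (or Bernoulli draws), and the
cycle repeats for a fixed number of iterations per chain.  m independent
chains give m completed datasets; networks estimated on them are pooled by
the point-estimation step of Rubin's rules (an elementwise mean — no
between-imputation variance, since the analysis targets structure rather
than inference).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .estimate import CLPNetwork
from .panel import PanelDataset

__all__ = [
    "MissingnessReport",
    "missingness_report",
    "ImputationSet",
    "impute_chained",
    "vif_check",
    "pool_networks",
    "listwise_delete",
]


# ---------------------------------------------------------------------------
# diagnostics

@dataclass
class MissingnessReport:
    """Per-column missingness and the correlation structure of missingness.

    ``table`` has one row per item-wave column (missing count, percentage and
    an MCAR-like / MAR-like hint); ``indicator_corr`` is the phi-correlation
    matrix of the missingness indicators (NaN where a column is never or
    always missing, reported as not applicable).
    """

    table: pd.DataFrame
    indicator_corr: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


_MAR_HINT_CUTOFF = 0.10


def missingness_report(data: PanelDataset) -> MissingnessReport:
    mask = np.concatenate([np.isnan(data.t1), np.isnan(data.t2)], axis=1).astype(float)
    cols = [f"{nid}_t1" for nid in data.node_ids] + [f"{nid}_t2" for nid in data.node_ids]
    n = data.n
    counts = mask.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = pd.DataFrame(mask, columns=cols).corr().to_numpy()
    np.fill_diagonal(corr, 1.0)
    corr_df = pd.DataFrame(corr, index=cols, columns=cols)

    hints = []
    for j in range(len(cols)):
        others = np.abs(np.delete(corr[j], j))
        mean_assoc = np.nanmean(others) if np.any(~np.isnan(others)) else np.nan
        if counts[j] == 0:
            hints.append("complete")
        elif np.isnan(mean_assoc) or mean_assoc < _MAR_HINT_CUTOFF:
            hints.append("MCAR-like")
        else:
            hints.append("MAR-like")
    table = pd.DataFrame(
        {
            "n_missing": counts.astype(int),
            "pct_missing": 100.0 * counts / n,
            "mechanism_hint": hints,
        },
        index=pd.Index(cols, name="column"),
    )
    return MissingnessReport(table=table, indicator_corr=corr_df)


def listwise_delete(data: PanelDataset, covariate_columns: Sequence[str]) -> PanelDataset:
    """Drop participants missing any of the designated (MCAR) covariates."""
    if data.covariates is None or not covariate_columns:
        return data
    keep = ~data.covariates[list(covariate_columns)].isna().any(axis=1).to_numpy()
    return data.take(np.nonzero(keep)[0])


# ---------------------------------------------------------------------------
# chained-equations imputation

@dataclass
class ImputationSet:
    """m completed copies of one incomplete panel."""

    datasets: list[PanelDataset]
    m: int
    iterations: int
    seed: int

    def __iter__(self):
        return iter(self.datasets)


def _pmm_fill(
    pred_obs: np.ndarray, y_obs: np.ndarray, pred_mis: np.ndarray,
    rng: np.random.Generator, k: int = 5,
) -> np.ndarray:
    """Draw each missing value from the k observed donors with the nearest
    predicted mean (classic type-1 PMM matching on predictions)."""
    order = np.argsort(pred_obs, kind="stable")
    sorted_pred = pred_obs[order]
    sorted_y = y_obs[order]
    pos = np.searchsorted(sorted_pred, pred_mis)
    n_obs = sorted_pred.size
    k = min(k, n_obs)
    lo = np.clip(pos - k // 2, 0, n_obs - k)
    offsets = rng.integers(0, k, size=pred_mis.size)
    return sorted_y[lo + offsets]


def _logistic_fill(
    X_obs: np.ndarray, y_obs: np.ndarray, X_mis: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    from sklearn.linear_model import LogisticRegression

    classes = np.unique(y_obs)
    if classes.size == 1:
        return np.full(X_mis.shape[0], classes[0])
    clf = LogisticRegression(max_iter=200)
    clf.fit(X_obs, y_obs)
    prob = clf.predict_proba(X_mis)[:, 1]
    return (rng.random(prob.size) < prob).astype(float)


def _impute_one_chain(
    M: np.ndarray, miss: np.ndarray, binary_cols: np.ndarray, max_codes: np.ndarray,
    iterations: int, rng: np.random.Generator, ordinal_method: str, k_pmm: int,
) -> np.ndarray:
    """One chained-equations chain over the n x (2p) stacked response matrix."""
    n, q = M.shape
    work = M.copy()
    # initial fill: random draws from each column's observed values
    for j in range(q):
        mj = miss[:, j]
        if mj.any():
            obs = work[~mj, j]
            work[mj, j] = rng.choice(obs, size=mj.sum(), replace=True)

    visit = np.argsort(miss.sum(axis=0), kind="stable")
    visit = [j for j in visit if miss[:, j].any()]
    for _ in range(iterations):
        for j in visit:
            mj = miss[:, j]
            others = np.delete(np.arange(q), j)
            X = work[:, others]
            y_obs = M[~mj, j]
            if binary_cols[j]:
                work[mj, j] = _logistic_fill(X[~mj], y_obs, X[mj], rng)
            else:
                Xd = np.column_stack([np.ones(n), X])
                beta, *_ = np.linalg.lstsq(Xd[~mj], y_obs, rcond=None)
                pred = Xd @ beta
                if ordinal_method == "pmm":
                    work[mj, j] = _pmm_fill(pred[~mj], y_obs, pred[mj], rng, k_pmm)
                else:  # rounded linear draw, kept in range
                    resid_sd = np.std(y_obs - pred[~mj])
                    draw = pred[mj] + rng.standard_normal(mj.sum()) * resid_sd
                    work[mj, j] = np.clip(np.round(draw), 0, max_codes[j])
    return work


def impute_chained(
    data: PanelDataset,
    m: int = 5,
    iterations: int = 10,
    seed: int = 0,
    ordinal_method: str = "pmm",
    k_pmm: int = 5,
) -> ImputationSet:
    """Multiple imputation by chained equations on the stacked item columns.

    Every item column of both waves predicts every other (the standard
    dense specification); columns are visited in increasing-missingness
    order each iteration.  Chains are independent, seeded from substreams of
    ``seed``.  Observed cells are never altered and imputed codes stay within
    each item's range (PMM draws observed donor values; logistic draws 0/1).
    """
    if m < 1 or iterations < 1:
        raise ValueError("need m >= 1 and iterations >= 1")
    if ordinal_method not in ("pmm", "norm_round"):
        raise ValueError("ordinal_method must be 'pmm' or 'norm_round'")
    p = data.p
    M = np.concatenate([data.t1, data.t2], axis=1)
    miss = np.isnan(M)
    fully_missing = np.nonzero(miss.all(axis=0))[0]
    if fully_missing.size:
        cols = [f"{data.node_ids[j % p]}_t{j // p + 1}" for j in fully_missing]
        raise ValueError(f"column(s) with no observed values: {cols}")

    binary_cols = np.array([it.item_type == "binary" for it in data.items] * 2)
    max_codes = np.array([it.max_code for it in data.items] * 2, dtype=float)

    children = np.random.SeedSequence(seed).spawn(m)
    datasets = []
    for chain_ss in children:
        rng = np.random.default_rng(chain_ss)
        filled = (
            M.copy()
            if not miss.any()
            else _impute_one_chain(
                M, miss, binary_cols, max_codes, iterations, rng, ordinal_method, k_pmm
            )
        )
        datasets.append(
            PanelDataset(filled[:, :p], filled[:, p:], data.items, data.covariates)
        )
    return ImputationSet(datasets=datasets, m=m, iterations=iterations, seed=seed)


# ---------------------------------------------------------------------------
# multicollinearity

def vif_check(X, columns: Sequence[str] | None = None, flag_at: float = 5.0) -> pd.DataFrame:
    """Variance inflation factors, VIF_j = 1 / (1 - R^2_j).

    A perfectly collinear predictor is reported with infinite VIF rather than
    raising.  Returns a DataFrame with columns ``vif`` and ``flagged``.
    """
    if isinstance(X, pd.DataFrame):
        columns = list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 predictors")
    if np.isnan(X).any():
        raise ValueError("VIF requires complete data")
    n, q = X.shape
    if columns is None:
        columns = [f"x{j+1}" for j in range(q)]
    Xc = X - X.mean(axis=0)
    vifs = np.empty(q)
    for j in range(q):
        y = Xc[:, j]
        ss_tot = float(y @ y)
        if ss_tot == 0:
            vifs[j] = np.inf
            continue
        others = np.delete(Xc, j, axis=1)
        beta, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        r2 = 1.0 - float(resid @ resid) / ss_tot
        vifs[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.DataFrame({"vif": vifs, "flagged": vifs >= flag_at}, index=pd.Index(columns, name="variable"))


# ---------------------------------------------------------------------------
# pooling

def pool_networks(networks: Sequence[CLPNetwork]) -> CLPNetwork:
    """Elementwise mean of per-imputation networks (Rubin point estimate)."""
    if not networks:
        raise ValueError("no networks to pool")
    first = networks[0]
    for net in networks[1:]:
        if net.node_ids != first.node_ids or net.B.shape != first.B.shape:
            raise ValueError("networks differ in dimension or node order")
    B = np.mean([net.B for net in networks], axis=0)
    return CLPNetwork(
        B=B,
        node_ids=list(first.node_ids),
        communities=list(first.communities),
        alpha=first.alpha,
        cv_folds=first.cv_folds,
        lambdas=None,
        seed=first.seed,
        meta={
            "m": len(networks),
            "per_imputation_lambdas": [
                None if net.lambdas is None else net.lambdas.tolist() for net in networks
            ],
        },
    )
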