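"""Cross-lagged network estimation by node-wise penalized regression.

Each wave-2 item is regressed on all wave-1 items (standardized) with an
elastic-net penalty; the default mixing alpha = 1 is the standard LASSO.  The
penalty weight lambda is chosen per outcome by k-fold cross-validation
minimizing mean squared error (the "lambda.min" rule) over a log-spaced grid
from lambda_max (the smallest lambda with an all-zero solution) down to
1e-3 * lambda_max.  Coefficients at the chosen lambda, refit on the full
sample, fill column j of the p x p matrix B: B[i, j] is node i at wave 1
predicting node j at wave 2, with the diagonal holding autoregressive effects.

The minimized objective is (1 / (2n)) ||y - X b||^2 +
lambda * (alpha ||b||_1 + (1 - alpha) / 2 ||b||^2), matching glmnet's
parameterization for standardized inputs without intercept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNet
from sklearn.model_selection import KFold

from ._cd import enet_path_gram

from .panel import PanelDataset

__all__ = [
    "EstimatorConfig",
    "CLPNetwork",
    "DisplayNetwork",
    "standardize",
    "lambda_grid",
    "fit_elastic_net",
    "fit_outcome",
    "OutcomeFit",
    "estimate_clpn",
    "filter_display",
    "write_network_csv",
    "read_network_csv",
    "write_network_graphml",
]


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class EstimatorConfig:
    """Settings of the node-wise penalized regressions.

    alpha=1 (pure LASSO), 10-fold CV and a 100-point lambda grid are the
    full-analysis defaults; resampling procedures use a lighter grid (see
    stability module).
    """

    alpha: float = 1.0
    cv_folds: int = 10
    n_lambdas: int = 100
    lambda_min_ratio: float = 1e-3
    reverse_score: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")

    def estimator(self) -> Callable[[PanelDataset, int], "CLPNetwork"]:
        """Callable (data, seed) -> CLPNetwork; the contract the bootstrap uses."""
        def _fit(data: PanelDataset, seed: int) -> CLPNetwork:
            return estimate_clpn(
                data,
                alpha=self.alpha,
                k=self.cv_folds,
                seed=seed,
                n_lambdas=self.n_lambdas,
                lambda_min_ratio=self.lambda_min_ratio,
                reverse_score=self.reverse_score,
            )
        return _fit


FAST_RESAMPLING_CONFIG = EstimatorConfig(cv_folds=5, n_lambdas=25)


# ---------------------------------------------------------------------------
# containers

@dataclass
class CLPNetwork:
    """Directed cross-lagged network: B[i, j] = i(T1) -> j(T2)."""

    B: np.ndarray
    node_ids: list[str]
    communities: list[str]
    alpha: float = 1.0
    cv_folds: int = 10
    lambdas: np.ndarray | None = None
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.B = np.asarray(self.B, dtype=float)
        p = len(self.node_ids)
        if self.B.shape != (p, p):
            raise ValueError("B must be p x p")
        if not np.all(np.isfinite(self.B)):
            raise ValueError("B contains non-finite entries")

    @property
    def p(self) -> int:
        return len(self.node_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.B, index=self.node_ids, columns=self.node_ids)

    def autoregressive(self) -> pd.Series:
        return pd.Series(np.diag(self.B), index=self.node_ids, name="autoregressive")


@dataclass
class DisplayNetwork:
    """A CLPNetwork plus the edge-retention mask used for display."""

    network: CLPNetwork
    mask: np.ndarray
    threshold: float
    drop_autoregressive: bool

    def retained_edges(self) -> pd.DataFrame:
        """Long table of retained edges sorted by |weight| (descending)."""
        ids = self.network.node_ids
        rows = [
            (ids[i], ids[j], self.network.B[i, j])
            for i, j in zip(*np.nonzero(self.mask))
        ]
        df = pd.DataFrame(rows, columns=["from", "to", "beta"])
        return df.reindex(df["beta"].abs().sort_values(ascending=False).index).reset_index(drop=True)

    @property
    def n_retained(self) -> int:
        return int(self.mask.sum())


# ---------------------------------------------------------------------------
# standardization

def standardize(
    data: PanelDataset, reverse_score: bool = True
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Column-standardize both waves of a complete panel.

    Returns (X1, X2, scaling) where each column of X1/X2 has mean 0 and
    (population) standard deviation 1 and ``scaling`` records the constants.
    Reverse-scored items are flipped to the construct scale first (the flip
    only changes the sign of standardized values).
    """
    if not data.is_complete():
        raise ValueError("standardize requires complete data (impute first)")
    t1, t2 = data.oriented_waves(reverse_score)
    out, scales = [], {}
    for wave, arr in (("t1", t1), ("t2", t2)):
        mu = arr.mean(axis=0)
        sd = arr.std(axis=0)  # ddof=0, the glmnet convention
        zero = np.where(sd == 0)[0]
        if zero.size:
            raise ValueError(
                f"zero-variance column(s) at wave {wave}: "
                f"{[data.node_ids[j] for j in zero]}"
            )
        out.append((arr - mu) / sd)
        scales[f"mean_{wave}"] = mu
        scales[f"sd_{wave}"] = sd
    scaling = pd.DataFrame(scales, index=data.node_ids)
    return out[0], out[1], scaling


# ---------------------------------------------------------------------------
# penalized fits

def lambda_grid(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    n_lambdas: int = 100,
    lambda_min_ratio: float = 1e-3,
) -> np.ndarray:
    """Descending log-spaced grid from lambda_max (all-zero solution)."""
    n = X.shape[0]
    lam_max = np.max(np.abs(X.T @ y)) / (n * max(alpha, 1e-3))
    lam_max = max(lam_max, 1e-12)
    return np.geomspace(lam_max, lambda_min_ratio * lam_max, n_lambdas)


def fit_elastic_net(X: np.ndarray, y: np.ndarray, lam: float, alpha: float = 1.0) -> np.ndarray:
    """Single-penalty coefficient vector (no intercept).

    lam = 0 is solved exactly by least squares; otherwise coordinate descent.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if lam == 0:
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        return coef
    model = ElasticNet(alpha=lam, l1_ratio=alpha, fit_intercept=False, tol=1e-8, max_iter=50_000)
    model.fit(X, y)
    return model.coef_


@dataclass
class OutcomeFit:
    coef: np.ndarray
    lambda_: float
    grid: np.ndarray
    cv_mse: np.ndarray  # mean CV MSE per grid value
    coef_path: np.ndarray  # p x n_lambdas full-sample path


def fit_outcome(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float = 1.0,
    k: int = 10,
    grid: np.ndarray | None = None,
    seed: int = 0,
    n_lambdas: int = 100,
    lambda_min_ratio: float = 1e-3,
    _gram: np.ndarray | None = None,
) -> OutcomeFit:
    """Cross-validated penalized regression of one outcome on all predictors.

    Folds are plain random k-fold (seed-controlled); lambda is the grid value
    minimizing mean CV MSE, ties resolved toward the stronger penalty; the
    returned coefficients are a full-sample refit at that lambda.
    """
    n = X.shape[0]
    if k > n:
        raise ValueError(f"cv folds ({k}) exceed sample size ({n})")
    if k < 2:
        raise ValueError("need k >= 2 folds")
    if grid is None:
        grid = lambda_grid(X, y, alpha, n_lambdas, lambda_min_ratio)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty lambda grid")
    grid = np.sort(grid)[::-1]

    G = X.T @ X if _gram is None else _gram
    Xy = X.T @ y

    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    mse = np.zeros((k, grid.size))
    for f, (tr, te) in enumerate(kf.split(X)):
        X_te, y_te = X[te], y[te]
        G_tr = G - X_te.T @ X_te
        Xy_tr = Xy - X_te.T @ y_te
        coefs = enet_path_gram(G_tr, Xy_tr, len(tr), grid, alpha)
        resid = y_te[:, None] - X_te @ coefs
        mse[f] = (resid ** 2).mean(axis=0)
    mean_mse = mse.mean(axis=0)
    best = int(np.argmin(mean_mse))  # grid descending: ties favor larger lambda

    path = enet_path_gram(G, Xy, n, grid, alpha)
    return OutcomeFit(
        coef=path[:, best].copy(),
        lambda_=float(grid[best]),
        grid=grid,
        cv_mse=mean_mse,
        coef_path=path,
    )


def estimate_clpn(
    data: PanelDataset,
    alpha: float = 1.0,
    k: int = 10,
    seed: int = 0,
    n_lambdas: int = 100,
    lambda_min_ratio: float = 1e-3,
    reverse_score: bool = True,
) -> CLPNetwork:
    """Estimate the full p x p cross-lagged network from a complete panel.

    Column j of B holds the penalized coefficients of outcome j (wave 2)
    regressed on all wave-1 items; fold splits are drawn independently per
    outcome from seed-derived substreams.
    """
    X1, X2, _ = standardize(data, reverse_score)
    p = data.p
    ss = np.random.SeedSequence(seed)
    outcome_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(p)]
    G = X1.T @ X1

    B = np.zeros((p, p))
    lambdas = np.zeros(p)
    for j in range(p):
        fit = fit_outcome(
            X1, X2[:, j], alpha=alpha, k=k, seed=outcome_seeds[j],
            n_lambdas=n_lambdas, lambda_min_ratio=lambda_min_ratio, _gram=G,
        )
        B[:, j] = fit.coef
        lambdas[j] = fit.lambda_
    return CLPNetwork(
        B=B,
        node_ids=data.node_ids,
        communities=[it.community for it in data.items],
        alpha=alpha,
        cv_folds=k,
        lambdas=lambdas,
        seed=seed,
        meta={"n": data.n, "reverse_score": reverse_score},
    )


def filter_display(
    network: CLPNetwork, threshold: float = 0.05, drop_autoregressive: bool = True
) -> DisplayNetwork:
    """Edge-retention mask: keep |beta| >= threshold, optionally drop loops."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    mask = np.abs(network.B) >= threshold
    if drop_autoregressive:
        np.fill_diagonal(mask, False)
    return DisplayNetwork(network, mask, threshold, drop_autoregressive)


# ---------------------------------------------------------------------------
# persistence

def write_network_csv(network: CLPNetwork, path: str | Path) -> None:
    network.to_dataframe().to_csv(path, float_format="%.10g")


def read_network_csv(path: str | Path, communities: Sequence[str] | None = None) -> CLPNetwork:
    df = pd.read_csv(path, index_col=0)
    ids = list(df.index)
    if communities is None:
        communities = ["depressive" if i.startswith("De") else "internet" for i in ids]
    return CLPNetwork(df.to_numpy(), ids, list(communities))


def write_network_graphml(
    network: CLPNetwork, path: str | Path, threshold: float = 0.0,
    drop_autoregressive: bool = False,
) -> None:
    """GraphML export with weight, sign and display-retention attributes."""
    import networkx as nx

    disp = filter_display(network, max(threshold, 0.05), drop_autoregressive=True)
    g = nx.DiGraph()
    for nid, comm in zip(network.node_ids, network.communities):
        g.add_node(nid, community=comm)
    for i, src in enumerate(network.node_ids):
        for j, dst in enumerate(network.node_ids):
            w = network.B[i, j]
            if w == 0 or (drop_autoregressive and i == j):
                continue
            if abs(w) < threshold:
                continue
            g.add_edge(src, dst, weight=float(w), sign=int(np.sign(w)),
                       retained=bool(disp.mask[i, j]))
    nx.write_graphml(g, str(path))
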