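"""Bootstrap robustness of the estimated network.

Three procedures, all estimator-agnostic (they call the estimation step
through a single ``(data, seed) -> CLPNetwork`` contract so stubs can be
injected):

* case-dropping bootstrap -> CS-coefficient per centrality index: the largest
  proportion of participants that can be dropped while the subsample
  centrality still correlates >= 0.7 with the full-sample centrality in at
  least 95% of replicates (>= 0.25 minimally interpretable, >= 0.5 preferred);
* nonparametric (row-resampling) bootstrap -> percentile 95% CIs per edge;
* bootstrapped difference tests for pairs of edges and pairs of node
  centralities (significant when the percentile CI of the difference
  excludes zero).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .estimate import CLPNetwork, EstimatorConfig, FAST_RESAMPLING_CONFIG
from .panel import PanelDataset

__all__ = [
    "Estimator",
    "cs_coefficient",
    "CaseDropResult",
    "edge_ci_bootstrap",
    "EdgeCIResult",
    "difference_tests",
    "DifferenceTests",
    "StabilityReport",
    "assess_stability",
    "DEFAULT_DROP_GRID",
]

Estimator = Callable[[PanelDataset, int], CLPNetwork]

DEFAULT_DROP_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.05, 0.76, 0.05), 2))

_CENTRALITY_INDICES = ("out_ei", "in_ei", "bridge_ei")
_MIN_SUBSAMPLE = 20


def _as_estimator(estimator: Estimator | EstimatorConfig | None) -> Estimator:
    if estimator is None:
        estimator = FAST_RESAMPLING_CONFIG
    if isinstance(estimator, EstimatorConfig):
        return estimator.estimator()
    return estimator


def _centrality_vector(network: CLPNetwork, index: str) -> np.ndarray:
    # vectorized equivalents of the centrality module (hot bootstrap path);
    # exact agreement is asserted in the test suite
    B, d = network.B, np.diag(network.B)
    if index == "out_ei":
        return B.sum(axis=1) - d
    if index == "in_ei":
        return B.sum(axis=0) - d
    if index == "bridge_ei":
        comm = np.asarray(network.communities)
        cross = comm[:, None] != comm[None, :]
        return (B * cross).sum(axis=1)
    raise ValueError(f"index must be one of {_CENTRALITY_INDICES}")


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation with the degenerate-variance convention:
    identical constant vectors correlate 1, otherwise 0."""
    if np.std(a) == 0 or np.std(b) == 0:
        return 1.0 if np.allclose(a, b) else 0.0
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class CaseDropResult:
    index: str
    cs: float
    drop_grid: tuple[float, ...]
    correlations: dict[float, np.ndarray]  # drop proportion -> B correlations
    corr_threshold: float
    prob: float

    def summary(self) -> pd.DataFrame:
        rows = []
        for d in self.drop_grid:
            c = self.correlations.get(d)
            if c is None:
                rows.append((d, np.nan, np.nan, np.nan))
            else:
                rows.append(
                    (d, np.mean(c), np.quantile(c, 0.05),
                     float(np.mean(c >= self.corr_threshold)))
                )
        return pd.DataFrame(
            rows, columns=["drop_proportion", "mean_corr", "q05_corr", "frac_above_threshold"]
        )


def cs_coefficient(
    data: PanelDataset,
    estimator: Estimator | EstimatorConfig | None = None,
    index: str = "out_ei",
    drop_grid: Sequence[float] = DEFAULT_DROP_GRID,
    n_boots: int = 1000,
    corr_threshold: float = 0.7,
    prob: float = 0.95,
    seed: int = 0,
) -> CaseDropResult:
    """Case-dropping bootstrap CS-coefficient for one centrality index.

    For each drop proportion d, ``n_boots`` subsamples of size ceil(n(1-d))
    are drawn without replacement, the network re-estimated and the chosen
    centrality correlated (Pearson, across nodes) with the full-sample value.
    CS is the largest d such that every grid value up to d keeps at least
    ``prob`` of the correlations >= ``corr_threshold``; 0 if the smallest d
    already fails.
    """
    drop_grid = tuple(sorted(drop_grid))
    if not drop_grid or drop_grid[0] <= 0 or drop_grid[-1] >= 0.9:
        raise ValueError("drop proportions must lie in (0, 0.9)")
    if n_boots < 50:
        raise ValueError("need at least 50 bootstrap replicates")
    fit = _as_estimator(estimator)
    ss = np.random.SeedSequence(seed)
    full_seed = int(ss.generate_state(1)[0] % 2**31)
    full = _centrality_vector(fit(data, full_seed), index)

    rng = np.random.default_rng(ss.spawn(1)[0])
    correlations: dict[float, np.ndarray] = {}
    cs = 0.0
    failed = False
    for d in drop_grid:
        size = int(np.ceil(data.n * (1.0 - d)))
        if size < _MIN_SUBSAMPLE:
            warnings.warn(f"drop proportion {d}: subsample of {size} too small, skipped")
            continue
        corrs = np.empty(n_boots)
        for b in range(n_boots):
            idx = rng.choice(data.n, size=size, replace=False)
            sub_seed = int(rng.integers(0, 2**31))
            net = fit(data.take(idx), sub_seed)
            corrs[b] = _safe_corr(_centrality_vector(net, index), full)
        correlations[d] = corrs
        if not failed and np.mean(corrs >= corr_threshold) >= prob:
            cs = d
        else:
            failed = True  # CS must hold for every smaller proportion too
    return CaseDropResult(index, cs, drop_grid, correlations, corr_threshold, prob)


@dataclass
class EdgeCIResult:
    node_ids: list[str]
    draws: np.ndarray  # (B, p, p)
    lower: np.ndarray
    upper: np.ndarray
    boot_mean: np.ndarray
    level: float
    sample_estimate: np.ndarray

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower

    def to_frame(self) -> pd.DataFrame:
        ids = self.node_ids
        p = len(ids)
        rows = []
        for i in range(p):
            for j in range(p):
                rows.append(
                    (ids[i], ids[j], self.sample_estimate[i, j], self.boot_mean[i, j],
                     self.lower[i, j], self.upper[i, j], self.width[i, j])
                )
        return pd.DataFrame(
            rows, columns=["from", "to", "estimate", "boot_mean", "ci_lower", "ci_upper", "ci_width"]
        )


def edge_ci_bootstrap(
    data: PanelDataset,
    estimator: Estimator | EstimatorConfig | None = None,
    n_boots: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> EdgeCIResult:
    """Percentile bootstrap CIs for every edge weight (rows resampled with
    replacement; imputation is not re-run — resampling acts on a completed
    dataset)."""
    if n_boots < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    fit = _as_estimator(estimator)
    ss = np.random.SeedSequence(seed)
    full_seed = int(ss.generate_state(1)[0] % 2**31)
    full = fit(data, full_seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    draws = np.empty((n_boots, data.p, data.p))
    for b in range(n_boots):
        idx = rng.integers(0, data.n, size=data.n)
        sub_seed = int(rng.integers(0, 2**31))
        draws[b] = fit(data.take(idx), sub_seed).B
    alpha = (1.0 - level) / 2.0
    return EdgeCIResult(
        node_ids=list(full.node_ids),
        draws=draws,
        lower=np.quantile(draws, alpha, axis=0),
        upper=np.quantile(draws, 1.0 - alpha, axis=0),
        boot_mean=draws.mean(axis=0),
        level=level,
        sample_estimate=full.B,
    )


@dataclass
class DifferenceTests:
    """Pairwise bootstrap difference tests (percentile CI excludes zero)."""

    edge_labels: list[str]
    edge_mask: np.ndarray  # (p^2, p^2) symmetric bool, False diagonal
    centrality_masks: dict[str, np.ndarray]  # index -> (p, p) bool
    node_ids: list[str]
    level: float

    def edge_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.edge_mask, index=self.edge_labels, columns=self.edge_labels)

    def centrality_frame(self, index: str) -> pd.DataFrame:
        return pd.DataFrame(self.centrality_masks[index], index=self.node_ids, columns=self.node_ids)


def _pairwise_mask(draws: np.ndarray, level: float) -> np.ndarray:
    """draws: (B, K) -> (K, K) significance mask for all pairwise differences."""
    B, K = draws.shape
    alpha = (1.0 - level) / 2.0
    mask = np.zeros((K, K), dtype=bool)
    for i in range(K):
        diff = draws[:, i][:, None] - draws  # (B, K)
        lo = np.quantile(diff, alpha, axis=0)
        hi = np.quantile(diff, 1.0 - alpha, axis=0)
        mask[i] = (lo > 0) | (hi < 0)
    np.fill_diagonal(mask, False)
    return mask | mask.T  # enforce exact symmetry against quantile asymmetries


def difference_tests(
    edge_draws: np.ndarray,
    node_ids: Sequence[str],
    communities: Sequence[str] | None = None,
    level: float = 0.95,
) -> DifferenceTests:
    """Bootstrap difference tests for every pair of edges and, per centrality
    index, every pair of nodes, from one set of edge-weight draws (B, p, p)."""
    edge_draws = np.asarray(edge_draws)
    if edge_draws.ndim != 3 or edge_draws.shape[0] < 200:
        raise ValueError("need >= 200 bootstrap draws of shape (B, p, p)")
    B, p, _ = edge_draws.shape
    ids = list(node_ids)
    labels = [f"{ids[i]}->{ids[j]}" for i in range(p) for j in range(p)]
    edge_mask = _pairwise_mask(edge_draws.reshape(B, p * p), level)

    offdiag = ~np.eye(p, dtype=bool)
    out_draws = np.einsum("bij->bi", edge_draws * offdiag)
    in_draws = np.einsum("bij->bj", edge_draws * offdiag)
    centrality_masks = {
        "out_ei": _pairwise_mask(out_draws, level),
        "in_ei": _pairwise_mask(in_draws, level),
    }
    if communities is not None:
        comm = np.asarray(list(communities))
        cross = comm[:, None] != comm[None, :]
        bridge_draws = np.einsum("bij->bi", edge_draws * cross)
        centrality_masks["bridge_ei"] = _pairwise_mask(bridge_draws, level)
    return DifferenceTests(labels, edge_mask, centrality_masks, ids, level)


@dataclass
class StabilityReport:
    """Everything the robustness analysis produces, with CSV writers."""

    cs: dict[str, CaseDropResult]
    edge_cis: EdgeCIResult
    differences: DifferenceTests
    n_boots: int
    seed: int
    extras: dict = field(default_factory=dict)

    def cs_summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": list(self.cs),
                "cs_coefficient": [r.cs for r in self.cs.values()],
            }
        ).set_index("index")

    def write(self, directory) -> None:
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.cs_summary().to_csv(d / "cs_coefficients.csv")
        for index, res in self.cs.items():
            res.summary().to_csv(d / f"case_drop_{index}.csv", index=False)
        self.edge_cis.to_frame().to_csv(d / "edge_cis.csv", index=False)
        self.differences.edge_frame().to_csv(d / "edge_difference_mask.csv")
        for index in self.differences.centrality_masks:
            self.differences.centrality_frame(index).to_csv(
                d / f"centrality_difference_mask_{index}.csv"
            )


def assess_stability(
    data: PanelDataset,
    estimator: Estimator | EstimatorConfig | None = None,
    indices: Sequence[str] = _CENTRALITY_INDICES,
    drop_grid: Sequence[float] = DEFAULT_DROP_GRID,
    n_boots: int = 1000,
    cs_boots: int | None = None,
    level: float = 0.95,
    seed: int = 0,
) -> StabilityReport:
    """Full robustness analysis: CS per index, edge CIs, difference tests."""
    ss = np.random.SeedSequence(seed)
    kids = ss.spawn(len(indices) + 1)
    cs_boots = n_boots if cs_boots is None else cs_boots
    cs = {
        index: cs_coefficient(
            data, estimator, index=index, drop_grid=drop_grid, n_boots=cs_boots,
            seed=int(k.generate_state(1)[0] % 2**31),
        )
        for index, k in zip(indices, kids[:-1])
    }
    cis = edge_ci_bootstrap(
        data, estimator, n_boots=n_boots, level=level,
        seed=int(kids[-1].generate_state(1)[0] % 2**31),
    )
    diffs = difference_tests(
        cis.draws, cis.node_ids,
        communities=[it.community for it in data.items], level=level,
    )
    return StabilityReport(cs=cs, edge_cis=cis, differences=diffs, n_boots=n_boots, seed=seed)
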