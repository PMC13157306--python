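"""Model / Results front end for cross-lagged panel network analysis.

``CrossLaggedPanelNetwork`` is constructed from a two-wave panel (optionally
incomplete); ``fit()`` runs missingness diagnostics, chained-equations
imputation (when needed), per-imputation penalized estimation and pooling,
and returns a ``CLPNResults`` object carrying the pooled network, centrality
indices, a text ``summary()``, and bootstrap methods for edge CIs and
CS-coefficients.

Example
-------
>>> from clpnet import simulate, CrossLaggedPanelNetwork
>>> gt = simulate.make_ground_truth(seed=7)
>>> panel = simulate.simulate_panel(gt, n=3000, seed=7)
>>> res = CrossLaggedPanelNetwork(panel).fit(seed=7)
>>> res.centrality().head()
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import centrality as _centrality
from .estimate import (
    CLPNetwork,
    DisplayNetwork,
    EstimatorConfig,
    estimate_clpn,
    filter_display,
)
from .items import CANONICAL_ITEMS, ItemSpec
from .panel import PanelDataset
from .preprocess import (
    ImputationSet,
    MissingnessReport,
    impute_chained,
    missingness_report,
    pool_networks,
)

__all__ = ["CrossLaggedPanelNetwork", "CLPNResults"]


class CrossLaggedPanelNetwork:
    """Penalized node-wise regression model for a two-wave symptom panel.

    Parameters
    ----------
    data : PanelDataset
        Two-wave responses; missing cells allowed (handled by MICE at fit).
    alpha : float
        Elastic-net mixing parameter; 1.0 (default) is the standard LASSO.
    cv_folds : int
        Folds for the cross-validated choice of the penalty weight.
    m, iterations : int
        Number of imputed datasets and chained-equation iterations used when
        the panel is incomplete.
    reverse_score : bool
        Flip positively worded CES-D items to the construct scale before
        estimation (default True).
    """

    def __init__(
        self,
        data: PanelDataset,
        alpha: float = 1.0,
        cv_folds: int = 10,
        n_lambdas: int = 100,
        lambda_min_ratio: float = 1e-3,
        m: int = 5,
        iterations: int = 10,
        reverse_score: bool = True,
    ) -> None:
        self.data = data
        self.config = EstimatorConfig(
            alpha=alpha,
            cv_folds=cv_folds,
            n_lambdas=n_lambdas,
            lambda_min_ratio=lambda_min_ratio,
            reverse_score=reverse_score,
        )
        self.m = m
        self.iterations = iterations

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        items: Sequence[ItemSpec] = CANONICAL_ITEMS,
        covariate_columns: Sequence[str] | None = None,
        **kwargs,
    ) -> "CrossLaggedPanelNetwork":
        """Build from a wide DataFrame with ``<node_id>_t1`` / ``_t2`` columns."""
        return cls(PanelDataset.from_dataframe(df, items, covariate_columns), **kwargs)

    def fit(self, seed: int = 0) -> "CLPNResults":
        """Impute (if needed), estimate per dataset, pool, and wrap results."""
        ss = np.random.SeedSequence(seed)
        imp_seed, *est_seeds = [
            int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(self.m + 1)
        ]
        report = missingness_report(self.data)
        cfg = self.config
        if self.data.is_complete():
            imputations = None
            networks = [
                estimate_clpn(
                    self.data, alpha=cfg.alpha, k=cfg.cv_folds, seed=est_seeds[0],
                    n_lambdas=cfg.n_lambdas, lambda_min_ratio=cfg.lambda_min_ratio,
                    reverse_score=cfg.reverse_score,
                )
            ]
        else:
            imputations = impute_chained(
                self.data, m=self.m, iterations=self.iterations, seed=imp_seed
            )
            networks = [
                estimate_clpn(
                    d, alpha=cfg.alpha, k=cfg.cv_folds, seed=s,
                    n_lambdas=cfg.n_lambdas, lambda_min_ratio=cfg.lambda_min_ratio,
                    reverse_score=cfg.reverse_score,
                )
                for d, s in zip(imputations, est_seeds)
            ]
        network = pool_networks(networks) if len(networks) > 1 else networks[0]
        return CLPNResults(self, network, networks, report, imputations, seed)


class CLPNResults:
    """Fitted cross-lagged panel network.

    Attributes
    ----------
    network : CLPNetwork
        Pooled p x p matrix B; B[i, j] is item i at wave 1 predicting item j
        at wave 2, diagonal = autoregressive effects.
    """

    def __init__(
        self,
        model: CrossLaggedPanelNetwork,
        network: CLPNetwork,
        per_imputation: list[CLPNetwork],
        missingness: MissingnessReport,
        imputations: ImputationSet | None,
        seed: int,
    ) -> None:
        self.model = model
        self.network = network
        self.per_imputation = per_imputation
        self.missingness = missingness
        self.imputations = imputations
        self.seed = seed

    # ---- views -----------------------------------------------------------
    @property
    def B(self) -> pd.DataFrame:
        return self.network.to_dataframe()

    def display(self, threshold: float = 0.05, drop_autoregressive: bool = True) -> DisplayNetwork:
        return filter_display(self.network, threshold, drop_autoregressive)

    def centrality(
        self, partition: Mapping[str, str] | None = None, standardized: bool = False
    ) -> pd.DataFrame:
        return _centrality.centrality_table(self.network, partition, standardized)

    # ---- resampling ------------------------------------------------------
    def _analysis_data(self) -> PanelDataset:
        """Dataset the bootstrap resamples: the first completed dataset when
        imputation ran, the original panel otherwise."""
        if self.imputations is not None:
            return self.imputations.datasets[0]
        return self.model.data

    def bootstrap_edges(self, n_boots: int = 1000, estimator=None, seed: int | None = None):
        from .stability import edge_ci_bootstrap

        return edge_ci_bootstrap(
            self._analysis_data(), estimator, n_boots=n_boots,
            seed=self.seed if seed is None else seed,
        )

    def cs_coefficient(self, index: str = "out_ei", n_boots: int = 1000,
                       estimator=None, seed: int | None = None, **kwargs):
        from .stability import cs_coefficient

        return cs_coefficient(
            self._analysis_data(), estimator, index=index, n_boots=n_boots,
            seed=self.seed if seed is None else seed, **kwargs,
        )

    def assess_stability(self, n_boots: int = 1000, estimator=None,
                         seed: int | None = None, **kwargs):
        from .stability import assess_stability

        return assess_stability(
            self._analysis_data(), estimator, n_boots=n_boots,
            seed=self.seed if seed is None else seed, **kwargs,
        )

    # ---- plots -----------------------------------------------------------
    def plot_network(self, threshold: float = 0.05, ax=None):
        from .plotting import plot_network

        return plot_network(self.display(threshold), ax=ax)

    def plot_centrality(self, standardized: bool = True, ax=None):
        from .plotting import plot_centrality

        return plot_centrality(self.centrality(standardized=standardized), ax=ax)

    # ---- reporting ---------------------------------------------------------
    def summary(self, threshold: float = 0.05, top: int = 10) -> str:
        """Human-readable fit summary: sample, imputation, strongest
        cross-lagged edges and the centrality ranking."""
        net = self.network
        disp = self.display(threshold)
        edges = disp.retained_edges().head(top)
        cent = self.centrality()
        lines = [
            "Cross-Lagged Panel Network Results",
            "=" * 42,
            f"nodes: {net.p}   participants: {self.model.data.n}",
            f"penalty: alpha={net.alpha:g}, {net.cv_folds}-fold CV (lambda.min)",
        ]
        if self.imputations is not None:
            lines.append(
                f"imputation: m={self.imputations.m} chained-PMM datasets, "
                f"{self.imputations.iterations} iterations"
            )
        else:
            lines.append("imputation: none (complete data)")
        lines += [
            f"cross-lagged edges with |beta| >= {threshold:g}: {disp.n_retained}",
            "",
            f"strongest cross-lagged effects (top {len(edges)}):",
        ]
        for _, r in edges.iterrows():
            lines.append(f"  {r['from']:>5s} -> {r['to']:<5s}  beta = {r['beta']:+.3f}")
        lines += ["", "centrality (expected influence):"]
        lines.append(f"  {'node':>5s} {'out_ei':>8s} {'in_ei':>8s} {'bridge_ei':>10s}")
        for nid, row in cent.iterrows():
            lines.append(
                f"  {nid:>5s} {row.out_ei:8.3f} {row.in_ei:8.3f} {row.bridge_ei:10.3f}"
            )
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<CLPNResults: {self.network.p} nodes, n={self.model.data.n}, "
            f"alpha={self.network.alpha:g}, seed={self.seed}>"
        )
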