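"""End-to-end orchestration: config -> artifacts on disk.

Stage order mirrors the analysis protocol: read/validate -> missingness
report -> listwise deletion of designated MCAR covariates -> chained
imputation (m datasets) -> VIF check -> per-imputation network -> pooled
network -> display filter -> centralities -> bootstrap stability.  A single
master seed derives every substream (imputation chains, CV fold splits,
bootstrap draws) via numpy SeedSequence spawning, so one seed reproduces a
run byte-for-byte.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__ as _pkg_version
from .estimate import (
    FAST_RESAMPLING_CONFIG,
    standardize,
    write_network_csv,
    write_network_graphml,
)
from .model import CrossLaggedPanelNetwork
from .panel import PanelDataset, read_panel_csv, write_panel_csv
from .preprocess import listwise_delete, missingness_report, vif_check
from .simulate import (
    charls_like,
    inject_missingness,
    make_ground_truth,
    save_ground_truth,
    simulate_panel,
)
from .stability import DEFAULT_DROP_GRID, assess_stability

log = logging.getLogger("clpnet")

__all__ = ["RunConfig", "run_pipeline", "load_config", "synthesize_preset"]


@dataclass
class RunConfig:
    """Everything one full run needs; serializable to/from YAML or JSON."""

    input: str | None = None          # wide CSV; None -> synthetic preset
    preset: str = "charls-like"       # used when input is None
    n: int | None = None              # override preset sample size
    output_dir: str = "clpn_run"
    # imputation
    m: int = 5
    iterations: int = 10
    listwise_covariates: tuple[str, ...] = ()
    # estimation
    alpha: float = 1.0
    cv_folds: int = 10
    n_lambdas: int = 100
    lambda_min_ratio: float = 1e-3
    reverse_score: bool = True
    display_threshold: float = 0.05
    # stability
    n_boots: int = 1000
    cs_boots: int | None = None
    drop_grid: tuple[float, ...] = DEFAULT_DROP_GRID
    run_stability: bool = True
    # misc
    seed: int = 0
    write_imputations: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must lie in [0, 1]")
        if self.display_threshold < 0:
            raise ValueError("display_threshold must be >= 0")
        if self.m < 1 or self.iterations < 1:
            raise ValueError("m and iterations must be >= 1")


def load_config(path: str | Path) -> RunConfig:
    text = Path(path).read_text()
    payload = yaml.safe_load(text)  # YAML superset covers JSON
    payload["drop_grid"] = tuple(payload.get("drop_grid", DEFAULT_DROP_GRID))
    payload["listwise_covariates"] = tuple(payload.get("listwise_covariates", ()))
    return RunConfig(**payload)


def synthesize_preset(preset: str, n: int | None, seed: int) -> tuple[PanelDataset, dict]:
    """Generate an incomplete synthetic panel for a named preset."""
    if preset == "charls-like":
        gt, default_n = charls_like(seed=seed)
    elif preset == "small":
        gt = make_ground_truth(seed=seed)
        default_n = 2000
    else:
        raise ValueError(f"unknown preset {preset!r} (use 'charls-like' or 'small')")
    n = default_n if n is None else n
    ss = np.random.SeedSequence(seed)
    sim_seed, miss_seed = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2)]
    complete = simulate_panel(gt, n=n, seed=sim_seed)
    data = inject_missingness(complete, gt, seed=miss_seed)
    return data, {"ground_truth": gt, "n": n}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full chain and write all artifacts under output_dir.

    Returns a manifest dict (also written as ``manifest.json``).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": _pkg_version,
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "stages": {},
    }
    t_start = time.time()

    def _stage(name):
        log.info("stage: %s", name)
        return time.time()

    ss = np.random.SeedSequence(config.seed)
    fit_seed, stab_seed = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2)]

    # 1. input ---------------------------------------------------------------
    t = _stage("load")
    if config.input is not None:
        data = read_panel_csv(config.input)
        manifest["input"] = str(config.input)
    else:
        data, extra = synthesize_preset(config.preset, config.n, config.seed)
        save_ground_truth(extra["ground_truth"], out / "ground_truth.json")
        write_panel_csv(data, out / "synthetic_panel.csv")
        manifest["input"] = f"synthetic:{config.preset}"
    manifest["stages"]["load"] = {
        "seconds": round(time.time() - t, 2),
        "participants": data.n,
        "items": data.p,
    }

    # 2. missingness report ----------------------------------------------------
    t = _stage("missingness")
    report = missingness_report(data)
    report.table.to_csv(out / "missingness.csv")
    report.indicator_corr.to_csv(out / "missingness_correlations.csv")
    manifest["stages"]["missingness"] = {
        "seconds": round(time.time() - t, 2),
        "max_pct_missing": float(report.table.pct_missing.max()),
    }

    # 3. listwise deletion of designated MCAR covariates -----------------------
    if config.listwise_covariates:
        before = data.n
        data = listwise_delete(data, config.listwise_covariates)
        manifest["stages"]["listwise_delete"] = {"dropped": before - data.n}

    # 4/5. fit (imputation + per-imputation networks + pooling) ----------------
    t = _stage("fit")
    model = CrossLaggedPanelNetwork(
        data,
        alpha=config.alpha,
        cv_folds=config.cv_folds,
        n_lambdas=config.n_lambdas,
        lambda_min_ratio=config.lambda_min_ratio,
        m=config.m,
        iterations=config.iterations,
        reverse_score=config.reverse_score,
    )
    results = model.fit(seed=fit_seed)
    manifest["stages"]["fit"] = {
        "seconds": round(time.time() - t, 2),
        "imputed": results.imputations is not None,
        "m": 1 if results.imputations is None else results.imputations.m,
    }
    if config.write_imputations and results.imputations is not None:
        imp_dir = out / "imputations"
        imp_dir.mkdir(exist_ok=True)
        for i, d in enumerate(results.imputations):
            write_panel_csv(d, imp_dir / f"imputed_{i + 1}.csv")
        (imp_dir / "manifest.json").write_text(json.dumps({
            "m": results.imputations.m,
            "iterations": results.imputations.iterations,
            "seed": results.imputations.seed,
        }, indent=1))

    # VIF on the (first completed) wave-1 predictor matrix ----------------------
    X1, _, _ = standardize(results._analysis_data(), config.reverse_score)
    vifs = vif_check(X1, columns=data.node_ids)
    vifs.to_csv(out / "vif.csv")
    manifest["stages"]["vif"] = {
        "max_vif": float(np.max(vifs.vif.replace(np.inf, np.nan).dropna())),
        "any_flagged": bool(vifs.flagged.any()),
    }

    # 6. network artifacts -------------------------------------------------------
    write_network_csv(results.network, out / "adjacency.csv")
    write_network_graphml(results.network, out / "network.graphml")
    disp = results.display(config.display_threshold)
    disp.retained_edges().to_csv(out / "display_edges.csv", index=False)

    # 7. centrality ---------------------------------------------------------------
    cent = results.centrality(standardized=True)
    cent.to_csv(out / "centrality.csv")

    # 8. stability ----------------------------------------------------------------
    if config.run_stability and config.n_boots > 0:
        t = _stage("stability")
        stab = assess_stability(
            results._analysis_data(),
            FAST_RESAMPLING_CONFIG,
            drop_grid=config.drop_grid,
            n_boots=config.n_boots,
            cs_boots=config.cs_boots,
            seed=stab_seed,
        )
        stab.write(out / "stability")
        manifest["stages"]["stability"] = {
            "seconds": round(time.time() - t, 2),
            "cs": {k: v.cs for k, v in stab.cs.items()},
        }

    manifest["total_seconds"] = round(time.time() - t_start, 2)
    manifest["summary"] = results.summary(config.display_threshold)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    (out / "summary.txt").write_text(manifest["summary"] + "\n")
    return manifest
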