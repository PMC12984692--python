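"""Input-variable ablation runner and result export.

For one prediction target (NH3/CH4 indoor concentration or emission rate)
the runner trains the fixed 20-10 perceptron on every input-variable
configuration, evaluates it on the held-out test partition and renders a
table with the study's column layout (Variables, ANN Structure, R, R², MSE,
RMSE, MAE, SD).  Emission targets are first derived from the records with
the CO2 mass-balance estimator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import massbalance as mb
from .dataset import AblationConfig, drop_incomplete_rows, feature_sets, split_70_15_15
from .metrics import MetricsReport, compute_metrics
from .mlp import MLPRegression, MLPResults, TrainConfig
from .synthetic import SyntheticStudy

__all__ = ["AblationResult", "run_ablation", "ablation_table",
           "prepare_target", "export_timeseries", "export_regression"]

log = logging.getLogger(__name__)


@dataclass
class AblationResult:
    """One trained configuration: its metrics and satisfaction flag."""

    config: AblationConfig
    structure: str
    metrics: MetricsReport
    satisfied: bool
    seed: int
    results: MLPResults | None = None


def prepare_target(
    study: SyntheticStudy,
    target: str,
    herd: mb.HerdState | None = None,
) -> pd.DataFrame:
    """Records table augmented with the target column for one prediction task.

    Concentration targets are the measured indoor concentration; emission
    targets are the hourly mass-balance emission rate Et (g h-1) computed
    from the records with the herd of the study configuration.  Hours where
    the balance is undefined are dropped with a logged count.
    """
    df = study.records.copy()
    gas = target.split("_")[0]
    if target.endswith("_emission"):
        herd = herd or study.config.herd
        est = mb.MassBalanceModel(df, herd, gas=gas, concentration_unit="ppm").estimate()
        df["Et"] = est.table["Et"].to_numpy()
        df["flag"] = est.table["flag"].to_numpy()
        bad = df["flag"] == mb.EmissionFlag.INVALID_GRADIENT.value
        if bad.any():
            log.info("dropping %d invalid-gradient hours", int(bad.sum()))
            df = df[~bad]
    return df.reset_index(drop=True)


def run_ablation(
    study: SyntheticStudy,
    target: str,
    seed: int = 0,
    hidden_layers: Sequence[int] = (20, 10),
    train_config: TrainConfig | None = None,
    keep_results: bool = False,
) -> list[AblationResult]:
    """Train the fixed structure on every input configuration of ``target``.

    All configurations share the study's canonical 70:15:15 split (seeded by
    the study seed) so their test metrics are comparable; ``seed`` drives the
    network initialization.  Individual configuration failures are recorded
    (metrics NaN) and the run continues.
    """
    df = prepare_target(study, target)
    configs = feature_sets(target)
    structure = " ".join(str(h) for h in hidden_layers)
    out: list[AblationResult] = []
    split = split_70_15_15(len(df), study.config.seed)
    for cfg in configs:
        df_cfg = drop_incomplete_rows(df, [cfg.target_column, *cfg.feature_columns])
        try:
            model = MLPRegression.from_dataframe(
                df_cfg, cfg.target_column, cfg.feature_columns,
                hidden_layers=hidden_layers,
                split=split if len(df_cfg) == len(df) else None,
            )
            res = model.fit(seed=seed, config=train_config)
            rep = res.metrics("test")
        except Exception:  # noqa: BLE001 - record failure, keep going
            log.exception("configuration %r failed", cfg.name)
            nan = float("nan")
            rep = MetricsReport(nan, nan, nan, nan, nan, nan, n=0, partition="test")
            res = None
        out.append(
            AblationResult(
                config=cfg,
                structure=structure,
                metrics=rep,
                satisfied=rep.satisfied,
                seed=seed,
                results=res if keep_results else None,
            )
        )
    return out


def ablation_table(results: Sequence[AblationResult]) -> pd.DataFrame:
    """Render ablation results with the study's table column layout."""
    return pd.DataFrame(
        {
            "Variables": [r.config.name for r in results],
            "ANN Structure": [r.structure for r in results],
            "R": [r.metrics.R for r in results],
            "R2": [r.metrics.R2 for r in results],
            "MSE": [r.metrics.MSE for r in results],
            "RMSE": [r.metrics.RMSE for r in results],
            "MAE": [r.metrics.MAE for r in results],
            "SD": [r.metrics.SD for r in results],
            "satisfied": [r.satisfied for r in results],
        }
    )


def _paired_frame(targets, predictions) -> pd.DataFrame:
    t = np.asarray(targets, float).ravel()
    p = np.asarray(predictions, float).ravel()
    if t.shape != p.shape:
        raise ValueError("targets and predictions must have equal length")
    return pd.DataFrame({"target": t, "prediction": p})


def export_timeseries(targets, predictions, path: str | Path, plot: bool = True) -> Path:
    """Write the measured-vs-predicted series as CSV (and a line plot)."""
    path = Path(path)
    df = _paired_frame(targets, predictions)
    df.to_csv(path, index_label="index")
    if plot:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(9, 3))
        ax.plot(df.index, df["target"], lw=0.8, label="measured")
        ax.plot(df.index, df["prediction"], lw=0.8, label="predicted")
        ax.set_xlabel("hour")
        ax.legend(frameon=False)
        fig.tight_layout()
        fig.savefig(path.with_suffix(".png"), dpi=120)
        plt.close(fig)
    return path


def export_regression(targets, predictions, path: str | Path, plot: bool = True) -> dict:
    """Write the scatter data and the fitted regression line Y = aT + b.

    Returns the fit: slope, intercept and R.  The identity line Y = T marks
    perfect prediction.
    """
    path = Path(path)
    df = _paired_frame(targets, predictions)
    slope, intercept = np.polyfit(df["target"], df["prediction"], 1)
    rep = compute_metrics(df["target"], df["prediction"], partition="all")
    df.to_csv(path, index_label="index")
    if plot:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, 4))
        ax.scatter(df["target"], df["prediction"], s=6, alpha=0.5)
        grid = np.linspace(df["target"].min(), df["target"].max(), 2)
        ax.plot(grid, slope * grid + intercept, "r-", label=f"fit Y={slope:.2f}T+{intercept:.2g}")
        ax.plot(grid, grid, "k--", lw=0.8, label="Y = T")
        ax.set_xlabel("target")
        ax.set_ylabel("prediction")
        ax.legend(frameon=False, fontsize=8)
        fig.tight_layout()
        fig.savefig(path.with_suffix(".png"), dpi=120)
        plt.close(fig)
    return {"slope": float(slope), "intercept": float(intercept), "R": rep.R}
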