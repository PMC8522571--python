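"""Monte Carlo engine and summary metrics.

`run_study` repeats draw-panel / fit-estimators over independent replicate
streams and aggregates each estimator's treatment-effect estimates against
the scenario's population ATT using three measures:

* mean absolute percent bias — ``|mean(estimates) - truth| / |truth| * 100``;
* mean SE — the average of the per-replicate cluster-robust SEs;
* RMSE — root mean squared error of the estimates around the truth.

The Monte Carlo SE of the mean estimate (``sd/sqrt(n_reps)``) is reported
alongside, since "unbiased" claims are only meaningful relative to it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .estimators import ESTIMATOR_NAMES, fit_estimator
from .exceptions import (
    DidSimError,
    StudyIntegrityError,
    UndefinedRelativeBiasError,
)
from .generators import RngSpec, draw_panel
from .panel_model import ScenarioConfig, make_scenario, true_att

__all__ = [
    "mean_abs_percent_bias",
    "mean_se",
    "rmse",
    "run_study",
    "StudySummary",
    "plot_summary",
]

#: Fraction of replicates an estimator may fail on before the study aborts.
MAX_EXCLUSION_FRACTION = 0.01


def mean_abs_percent_bias(estimates: Sequence[float], truth: float) -> float:
    """``|mean(estimates) - truth| / |truth| * 100``."""
    est = np.asarray(estimates, dtype=float)
    if est.size == 0:
        raise ValueError("estimates must be nonempty")
    if truth == 0:
        raise UndefinedRelativeBiasError(
            "percent bias is undefined for truth = 0; report absolute bias instead"
        )
    return float(abs(est.mean() - truth) / abs(truth) * 100.0)


def mean_se(ses: Sequence[float]) -> float:
    """Arithmetic mean of per-replicate SE estimates."""
    arr = np.asarray(ses, dtype=float)
    if arr.size == 0:
        raise ValueError("ses must be nonempty")
    if (arr < 0).any():
        raise ValueError("standard errors must be nonnegative")
    return float(arr.mean())


def rmse(estimates: Sequence[float], truth: float) -> float:
    """Root mean squared error of the estimates around the truth."""
    est = np.asarray(estimates, dtype=float)
    if est.size == 0:
        raise ValueError("estimates must be nonempty")
    return float(np.sqrt(np.mean((est - truth) ** 2)))


@dataclass
class StudySummary:
    """Aggregated Monte Carlo results for one scenario.

    ``metrics`` is indexed by estimator with columns ``mean_estimate``,
    ``mean_abs_pct_bias`` (NaN when the true ATT is zero), ``mean_se``,
    ``rmse``, ``mc_se_of_mean_estimate``, ``n_ok`` and ``n_excluded``;
    ``replicates`` holds the per-replicate estimates for audit.
    """

    scenario_id: str
    n_reps: int
    seed: int
    true_att_value: float
    config: ScenarioConfig
    config_hash: str
    metrics: pd.DataFrame
    replicates: pd.DataFrame

    def to_csv(self, path: str | Path) -> None:
        """One row per estimator: scenario, estimator, the three metrics,
        n_reps and the true ATT."""
        out = self.metrics.reset_index(names="estimator")
        out.insert(0, "scenario", self.scenario_id)
        out["n_reps"] = self.n_reps
        out["true_att"] = self.true_att_value
        cols = [
            "scenario", "estimator", "mean_abs_pct_bias", "mean_se", "rmse",
            "n_reps", "true_att", "mean_estimate", "mc_se_of_mean_estimate",
            "n_ok", "n_excluded",
        ]
        out[cols].to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        """JSON document embedding the resolved configuration."""
        doc = {
            "scenario": self.scenario_id,
            "n_reps": self.n_reps,
            "seed": self.seed,
            "true_att": self.true_att_value,
            "config_hash": self.config_hash,
            "config": self.config.to_dict(),
            "metrics": {
                name: {
                    k: (None if pd.isna(v) else float(v)) if k != "n_ok" and k != "n_excluded" else int(v)
                    for k, v in row.items()
                }
                for name, row in self.metrics.to_dict(orient="index").items()
            },
        }
        Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True))


def run_study(
    scenario_id: str | int,
    n_reps: int = 400,
    overrides: Mapping | None = None,
    seed: int = 0,
    estimators: Sequence[str] | None = None,
) -> StudySummary:
    """Run the scenario's Monte Carlo study.

    Replicate ``k`` draws its panel from the independent stream
    ``RngSpec(seed, k)``, so the study is deterministic given ``seed`` and
    any single replicate can be regenerated on its own. Replicates on which
    an estimator fails (e.g., a degenerate matched sample) are excluded from
    that estimator's aggregate; more than 1% exclusions aborts the study.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be positive")
    names = list(estimators) if estimators is not None else list(ESTIMATOR_NAMES)
    unknown = set(names) - set(ESTIMATOR_NAMES)
    if unknown:
        raise ValueError(f"unknown estimators: {sorted(unknown)}")

    config = make_scenario(scenario_id, overrides)
    truth = true_att(config)

    records: list[dict] = []
    failures: dict[str, int] = {name: 0 for name in names}
    for k in range(n_reps):
        panel = draw_panel(config, RngSpec(seed, k))
        for name in names:
            try:
                fit = fit_estimator(name, panel)
            except (DidSimError, np.linalg.LinAlgError, ValueError):
                failures[name] += 1
                continue
            records.append(
                {
                    "rep": k,
                    "estimator": name,
                    "gamma_hat": fit.gamma_hat,
                    "se_gamma": fit.se_gamma,
                    "n_units_used": fit.n_units_used,
                }
            )

    for name, n_fail in failures.items():
        if n_fail > MAX_EXCLUSION_FRACTION * n_reps:
            raise StudyIntegrityError(
                f"estimator {name!r} failed on {n_fail}/{n_reps} replicates "
                f"(> {MAX_EXCLUSION_FRACTION:.0%} allowed)"
            )

    replicates = pd.DataFrame.from_records(
        records, columns=["rep", "estimator", "gamma_hat", "se_gamma", "n_units_used"]
    )
    rows = []
    for name in names:
        sub = replicates[replicates["estimator"] == name]
        est = sub["gamma_hat"].to_numpy()
        rows.append(
            {
                "estimator": name,
                "mean_estimate": float(est.mean()),
                "mean_abs_pct_bias": (
                    mean_abs_percent_bias(est, truth) if truth != 0 else float("nan")
                ),
                "mean_se": mean_se(sub["se_gamma"].to_numpy()),
                "rmse": rmse(est, truth),
                "mc_se_of_mean_estimate": float(
                    est.std(ddof=1) / np.sqrt(len(est))
                ),
                "n_ok": len(est),
                "n_excluded": failures[name],
            }
        )
    metrics = pd.DataFrame(rows).set_index("estimator")
    return StudySummary(
        scenario_id=str(scenario_id),
        n_reps=n_reps,
        seed=seed,
        true_att_value=truth,
        config=config,
        config_hash=config.config_hash,
        metrics=metrics,
        replicates=replicates,
    )


def plot_summary(summary: StudySummary, path: str | Path | None = None):
    """Dot chart of percent bias and mean SE by estimator (one scenario)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(8, 3), sharey=True)
    m = summary.metrics
    y = np.arange(len(m))
    axes[0].plot(m["mean_abs_pct_bias"], y, "o")
    axes[0].set_xlabel("mean absolute percent bias")
    axes[0].axvline(0.0, color="grey", lw=0.5)
    axes[1].plot(m["mean_se"], y, "o")
    axes[1].set_xlabel("mean SE")
    for ax in axes:
        ax.set_yticks(y, m.index)
    fig.suptitle(f"Scenario {summary.scenario_id} (true ATT {summary.true_att_value:g})")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
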