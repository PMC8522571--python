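"""Synthetic panel generator.

Draws balanced unit-by-time panels from a :class:`~didsim.panel_model.ScenarioConfig`:
Bernoulli treatment-group assignment, Gaussian covariates whose group mean
paths follow the scenario (constant, parallel, divergent-from-baseline, or
divergent-only-after-treatment), and outcomes from the linear model with time
fixed effects, a possibly time-varying covariate effect, and an additive
treatment effect on the treated group after ``t0``.

Randomness is routed through :class:`RngSpec`: a ``(seed, stream_id)`` pair
that maps to an independent ``numpy`` bit-generator stream, so replicate
``k`` of a Monte Carlo study can be regenerated in isolation without storing
panels. Setting both noise SDs to zero makes generation a deterministic
function of the configuration and the group assignment, which the test-suite
oracles rely on.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DegenerateAssignmentError
from .panel_model import TIME_INVARIANT, ScenarioConfig

__all__ = ["RngSpec", "PanelData", "assign_groups", "draw_covariates",
           "outcome_matrix", "draw_panel"]

#: Long-format CSV column order used for panel export/import.
CSV_COLUMNS = ["unit", "time", "treated", "post", "x", "y"]

_MAX_ASSIGNMENT_ATTEMPTS = 100


@dataclass(frozen=True)
class RngSpec:
    """Reproducible random stream: a master seed plus a replicate index.

    Identical ``(seed, stream_id)`` pairs yield bitwise-identical panels;
    distinct ``stream_id`` values yield statistically independent streams
    (children of the same ``numpy.random.SeedSequence``).
    """

    seed: int
    stream_id: int = 0

    def generator(self) -> np.random.Generator:
        ss = np.random.SeedSequence(self.seed, spawn_key=(self.stream_id,))
        return np.random.default_rng(ss)


def _as_generator(rng: "RngSpec | np.random.Generator") -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return rng.generator()


@dataclass
class PanelData:
    """Balanced long-format panel.

    ``frame`` holds one row per (unit, time) with columns
    ``unit, time, treated, post, x, y``; ``t0`` is the first posttreatment
    time. ``treated`` is constant within unit and ``post = 1{time >= t0}``.
    """

    frame: pd.DataFrame
    t0: int

    def __post_init__(self) -> None:
        self.frame = self.frame.loc[:, CSV_COLUMNS].reset_index(drop=True)

    @property
    def n_units(self) -> int:
        return int(self.frame["unit"].nunique())

    @property
    def n_times(self) -> int:
        return int(self.frame["time"].nunique())

    def validate(self) -> None:
        """Check balance and within-unit consistency; raise ValueError if violated."""
        df = self.frame
        counts = df.groupby("unit")["time"].nunique()
        if counts.nunique() != 1 or len(df) != counts.iloc[0] * len(counts):
            raise ValueError("panel is not balanced")
        if (df.groupby("unit")["treated"].nunique() > 1).any():
            raise ValueError("treated indicator varies within unit")
        expected_post = (df["time"] >= self.t0).astype(int)
        if not (df["post"].astype(int) == expected_post).all():
            raise ValueError("post indicator inconsistent with t0")

    # ------------------------------------------------------------------
    # long-format CSV round trip
    # ------------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, t0: int | None = None) -> "PanelData":
        """Read a long-format panel; ``post`` is re-derived from ``t0`` and
        cross-checked against the stored column.

        When ``t0`` is omitted it is inferred as the earliest time with
        ``post == 1``.
        """
        df = pd.read_csv(path)
        missing = set(CSV_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"panel CSV missing columns: {sorted(missing)}")
        if t0 is None:
            post_times = df.loc[df["post"] == 1, "time"]
            if post_times.empty:
                raise ValueError("cannot infer t0: no posttreatment rows")
            t0 = int(post_times.min())
        panel = cls(frame=df, t0=int(t0))
        panel.validate()
        return panel


def assign_groups(
    n_units: int, p_treat: float, rng: RngSpec | np.random.Generator
) -> np.ndarray:
    """Independent Bernoulli(``p_treat``) treatment-group indicators.

    Panels with no treated or no control units are re-drawn (up to 100
    attempts) since every estimator requires both groups.
    """
    if n_units < 2:
        raise ValueError("n_units must be at least 2")
    gen = _as_generator(rng)
    for _ in range(_MAX_ASSIGNMENT_ATTEMPTS):
        d = (gen.random(n_units) < p_treat).astype(int)
        if 0 < d.sum() < n_units:
            return d
    raise DegenerateAssignmentError(
        f"no mixed-group assignment in {_MAX_ASSIGNMENT_ATTEMPTS} draws "
        f"(n_units={n_units}, p_treat={p_treat})"
    )


def draw_covariates(
    config: ScenarioConfig,
    d: np.ndarray,
    rng: RngSpec | np.random.Generator,
) -> np.ndarray:
    """Covariate matrix ``x`` of shape ``(n_units, n_times)``.

    Time-invariant: one Gaussian draw per unit around the group mean,
    replicated across time. Time-varying: per-(unit, time) Gaussian noise
    around the group mean path, including the treatment-induced divergence
    ``delta * (t - t0 + 1)`` for treated units after ``t0``.
    """
    gen = _as_generator(rng)
    d = np.asarray(d)
    n = d.shape[0]
    T = config.n_times
    if config.covariate_kind == TIME_INVARIANT:
        mu = config.a0 + config.a1 * d
        x = mu + gen.normal(0.0, config.sigma_x, size=n)
        return np.repeat(x[:, None], T, axis=1)
    t = config.times()[None, :]
    dcol = d[:, None]
    post = (t >= config.t0).astype(float)
    mean = (
        config.a0
        + config.a1 * dcol
        + (config.b0 + config.b1 * dcol) * t
        + config.delta * dcol * post * (t - config.t0 + 1)
    )
    return mean + gen.normal(0.0, config.sigma_x, size=(n, T))


def outcome_matrix(
    config: ScenarioConfig,
    d: np.ndarray,
    x: np.ndarray,
    rng: RngSpec | np.random.Generator,
) -> np.ndarray:
    """Outcome matrix ``y`` of shape ``(n_units, n_times)``.

    ``y_it = alpha0 + alpha1*d + zeta_t + lambda_t*x_it + gamma*post_t*d + eps``
    with i.i.d. Gaussian noise. With ``gamma = 0`` this is the untreated
    potential-outcome surface for all units.
    """
    gen = _as_generator(rng)
    d = np.asarray(d)
    zeta = np.asarray(config.zeta)[None, :]
    lam = config.lambda_schedule()[None, :]
    post = config.post_indicator()[None, :]
    mean = (
        config.alpha0
        + config.alpha1 * d[:, None]
        + zeta
        + lam * x
        + config.gamma * post * d[:, None]
    )
    return mean + gen.normal(0.0, config.sigma_y, size=x.shape)


def draw_panel(
    config: ScenarioConfig, rng: RngSpec | np.random.Generator
) -> PanelData:
    """Draw one balanced panel from the data-generating process."""
    gen = _as_generator(rng)
    d = assign_groups(config.n_units, config.p_treat, gen)
    x = draw_covariates(config, d, gen)
    y = outcome_matrix(config, d, x, gen)

    n, T = x.shape
    times = config.times()
    frame = pd.DataFrame(
        {
            "unit": np.repeat(np.arange(n), T),
            "time": np.tile(times, n),
            "treated": np.repeat(d, T),
            "post": np.tile((times >= config.t0).astype(int), n),
            "x": x.ravel(),
            "y": y.ravel(),
        }
    )
    return PanelData(frame=frame, t0=config.t0)
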