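"""Causal data model for difference-in-differences confounding scenarios.

The design under study is the canonical two-group difference-in-differences
(diff-in-diff) panel: ``n`` units observed at times ``t = 1..T``, a binary
treatment group indicator ``d`` drawn once per unit, and treatment switching
on for the treated group at a single time ``t0``. Untreated potential
outcomes follow a linear model with time fixed effects and a single covariate
whose effect on the outcome may vary over time::

    E[Y^0 | d, x] = alpha0 + alpha1 * d + zeta_t + lambda_t * x_it

and treatment adds a constant effect ``gamma`` on top (``Y^1 = Y^0 + gamma``).

Whether the covariate breaks the parallel-trends assumption depends on two
things only: the covariate-effect schedule ``lambda_t`` and the group mean
paths of the covariate. A covariate is a diff-in-diff confounder when the
product ``g(t) = lambda_t * (m1(t) - m0(t))`` — the covariate-induced outcome
gap between groups — changes over time. Constant gaps are absorbed by the
group indicator; only time-varying gaps bias the treatment-by-post
interaction coefficient.

This module holds :class:`ScenarioConfig` (a fully resolved data-generating
process), the registry of nine canonical confounding scenarios, and
closed-form diagnostics: the parallel-trends violation profile, a confounding
classifier, and the population ATT (which exceeds ``gamma`` when the
treatment shifts the covariate itself, i.e. the covariate mediates part of
the effect).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

from .exceptions import StructuralConflictError

__all__ = [
    "TIME_INVARIANT",
    "TIME_VARYING",
    "CONSTANT",
    "LINEAR",
    "CUSTOM",
    "SCENARIO_IDS",
    "ScenarioConfig",
    "ViolationProfile",
    "make_scenario",
    "violation_profile",
    "classify_confounding",
    "true_att",
]

TIME_INVARIANT = "time_invariant"
TIME_VARYING = "time_varying"

CONSTANT = "constant"
LINEAR = "linear"
CUSTOM = "custom"

#: The nine canonical scenarios: 1-3 use a time-invariant covariate, 4-6 a
#: time-varying one; the "a"/"b" suffix selects a constant / time-varying
#: covariate effect on the outcome.
SCENARIO_IDS = ("1", "2", "3", "4a", "4b", "5a", "5b", "6a", "6b")

#: Absolute range of g(t) below which the covariate-induced gap counts as
#: constant over time. All diagnostics are closed-form, so only floating
#: point noise needs to be tolerated.
PARALLEL_TOL = 1e-10


@dataclass(frozen=True)
class ScenarioConfig:
    """Full parameterization of one panel data-generating process.

    Parameters
    ----------
    n_units, n_times, t0, p_treat
        Panel dimensions: number of units, number of time points (indexed
        ``1..n_times``), first posttreatment time, and the Bernoulli
        probability of treatment-group membership.
    alpha0, alpha1, zeta, gamma
        Outcome-model coefficients: intercept, constant treated-group level
        shift, time fixed effects (length ``n_times``; defaults to
        ``0.1 * t``), and the additive treatment effect.
    covariate_kind
        ``"time_invariant"`` (one draw per unit, replicated over time) or
        ``"time_varying"`` (drawn per unit-time with a linear mean path).
    effect_kind, lam, lam_a, lam_b, lam_values
        Covariate-effect schedule ``lambda_t``: ``"constant"`` uses ``lam``;
        ``"linear"`` uses ``lam_a + lam_b * t``; ``"custom"`` uses the
        explicit length-``n_times`` vector ``lam_values``.
    a0, a1, b0, b1, delta
        Covariate mean-path parameters. Group ``d`` has intercept
        ``a0 + a1*d`` and slope ``b0 + b1*d``; ``delta`` is the per-period
        treatment-induced divergence of the treated group's covariate after
        ``t0`` (nonzero only when the covariate mediates treatment).
    sigma_x, sigma_y
        Gaussian noise SDs for the covariate and the outcome.
    """

    n_units: int = 800
    n_times: int = 10
    t0: int = 6
    p_treat: float = 0.5
    alpha0: float = 1.0
    alpha1: float = 0.5
    zeta: tuple[float, ...] | None = None
    gamma: float = 1.0
    covariate_kind: str = TIME_INVARIANT
    effect_kind: str = CONSTANT
    lam: float = 1.0
    lam_a: float = 0.5
    lam_b: float = 0.2
    lam_values: tuple[float, ...] | None = None
    a0: float = 0.0
    a1: float = 0.0
    b0: float = 0.0
    b1: float = 0.0
    delta: float = 0.0
    sigma_x: float = 0.5
    sigma_y: float = 1.0

    def __post_init__(self) -> None:
        if self.n_units < 2:
            raise ValueError("n_units must be at least 2")
        if self.n_times < 1:
            raise ValueError("n_times must be positive")
        if not 1 <= self.t0 <= self.n_times:
            raise ValueError(f"t0 must lie in 1..{self.n_times}, got {self.t0}")
        if not 0.0 <= self.p_treat <= 1.0:
            raise ValueError("p_treat must lie in [0, 1]")
        if self.sigma_x < 0 or self.sigma_y < 0:
            raise ValueError("noise SDs must be nonnegative")
        if self.covariate_kind not in (TIME_INVARIANT, TIME_VARYING):
            raise ValueError(f"unknown covariate_kind {self.covariate_kind!r}")
        if self.effect_kind not in (CONSTANT, LINEAR, CUSTOM):
            raise ValueError(f"unknown effect_kind {self.effect_kind!r}")
        if self.zeta is None:
            object.__setattr__(
                self, "zeta", tuple(0.1 * t for t in range(1, self.n_times + 1))
            )
        else:
            object.__setattr__(self, "zeta", tuple(float(z) for z in self.zeta))
        if len(self.zeta) != self.n_times:
            raise ValueError("zeta must have length n_times")
        if self.effect_kind == CUSTOM:
            if self.lam_values is None or len(self.lam_values) != self.n_times:
                raise ValueError("custom effect_kind needs length-n_times lam_values")
            object.__setattr__(
                self, "lam_values", tuple(float(v) for v in self.lam_values)
            )
        if self.covariate_kind == TIME_INVARIANT and (
            self.b0 != 0 or self.b1 != 0 or self.delta != 0
        ):
            raise ValueError(
                "time_invariant covariate requires b0 = b1 = delta = 0"
            )

    # ------------------------------------------------------------------
    # closed-form ingredients
    # ------------------------------------------------------------------
    def times(self) -> np.ndarray:
        """Time index ``1..n_times``."""
        return np.arange(1, self.n_times + 1)

    def lambda_schedule(self) -> np.ndarray:
        """Covariate-effect coefficients ``lambda_t`` for ``t = 1..n_times``."""
        t = self.times()
        if self.effect_kind == CONSTANT:
            return np.full(self.n_times, float(self.lam))
        if self.effect_kind == LINEAR:
            return self.lam_a + self.lam_b * t
        return np.asarray(self.lam_values, dtype=float)

    def post_indicator(self) -> np.ndarray:
        """Binary vector ``p_t = 1{t >= t0}``."""
        return (self.times() >= self.t0).astype(float)

    def covariate_mean(self, d: int, treated_path: bool = True) -> np.ndarray:
        """Mean covariate trajectory ``m_d(t)`` for group ``d``.

        With ``treated_path=False`` the treatment-induced shift ``delta`` is
        suppressed, giving the untreated covariate path that parallel-trends
        arguments are about.
        """
        t = self.times()
        mean = self.a0 + self.a1 * d + (self.b0 + self.b1 * d) * t
        mean = np.asarray(mean, dtype=float) * np.ones_like(t, dtype=float)
        if treated_path and d == 1 and self.delta != 0:
            mean = mean + self.delta * self.post_indicator() * (t - self.t0 + 1)
        return mean

    # ------------------------------------------------------------------
    # serialization
    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["zeta"] = list(self.zeta)
        if self.lam_values is not None:
            out["lam_values"] = list(self.lam_values)
        return out

    @classmethod
    def from_dict(cls, data: Mapping) -> "ScenarioConfig":
        data = dict(data)
        if data.get("zeta") is not None:
            data["zeta"] = tuple(data["zeta"])
        if data.get("lam_values") is not None:
            data["lam_values"] = tuple(data["lam_values"])
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "ScenarioConfig":
        return cls.from_dict(yaml.safe_load(text))

    def replace(self, **changes) -> "ScenarioConfig":
        return dataclasses.replace(self, **changes)

    @property
    def config_hash(self) -> str:
        """Stable short identifier of the resolved configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


@dataclass(frozen=True)
class ViolationProfile:
    """Closed-form parallel-trends diagnostic.

    ``g[t-1] = lambda_t * (m1(t) - m0(t))`` is the covariate-induced mean
    outcome gap between groups along the *untreated* covariate path. Parallel
    trends hold exactly when ``g`` is constant over time.
    """

    g: tuple[float, ...]
    is_parallel: bool
    treatment_affects_covariate: bool


# ----------------------------------------------------------------------
# scenario registry
# ----------------------------------------------------------------------

_SCENARIO_FIELDS: dict[str, dict] = {
    # time-invariant covariate; group means mu0 = a0, mu1 = a0 + a1
    "1": dict(covariate_kind=TIME_INVARIANT, effect_kind=CONSTANT, a0=0.0, a1=1.0),
    "2": dict(covariate_kind=TIME_INVARIANT, effect_kind=LINEAR, a0=0.0, a1=1.0),
    "3": dict(covariate_kind=TIME_INVARIANT, effect_kind=LINEAR, a0=0.0, a1=0.0),
    # time-varying covariate
    "4a": dict(covariate_kind=TIME_VARYING, effect_kind=CONSTANT,
               a0=0.0, a1=0.5, b0=0.2, b1=0.0, delta=0.0),
    "4b": dict(covariate_kind=TIME_VARYING, effect_kind=LINEAR,
               a0=0.0, a1=0.5, b0=0.2, b1=0.0, delta=0.0),
    "5a": dict(covariate_kind=TIME_VARYING, effect_kind=CONSTANT,
               a0=0.0, a1=0.5, b0=0.2, b1=0.2, delta=0.0),
    "5b": dict(covariate_kind=TIME_VARYING, effect_kind=LINEAR,
               a0=0.0, a1=0.5, b0=0.2, b1=0.2, delta=0.0),
    "6a": dict(covariate_kind=TIME_VARYING, effect_kind=CONSTANT,
               a0=0.0, a1=0.0, b0=0.2, b1=0.0, delta=0.3),
    "6b": dict(covariate_kind=TIME_VARYING, effect_kind=LINEAR,
               a0=0.0, a1=0.0, b0=0.2, b1=0.0, delta=0.3),
}

# Structural constraints each scenario must keep after overrides are applied.
# Magnitudes (means, slopes, noise, sample sizes) are free; the qualitative
# structure that defines the scenario is not.
_STRUCTURE_CHECKS: dict[str, list] = {
    "1": [("effect_kind", lambda c: c.effect_kind == CONSTANT,
           "Scenario 1 requires a constant covariate effect")],
    "2": [("effect_kind", lambda c: c.effect_kind != CONSTANT,
           "Scenario 2 requires a time-varying covariate effect")],
    "3": [("effect_kind", lambda c: c.effect_kind != CONSTANT,
           "Scenario 3 requires a time-varying covariate effect")],
    "4a": [("b1", lambda c: c.b1 == 0, "Scenario 4 requires parallel covariate evolution (b1 = 0)"),
           ("delta", lambda c: c.delta == 0, "Scenario 4 requires delta = 0"),
           ("effect_kind", lambda c: c.effect_kind == CONSTANT,
            "Scenario 4a requires a constant covariate effect")],
    "4b": [("b1", lambda c: c.b1 == 0, "Scenario 4 requires parallel covariate evolution (b1 = 0)"),
           ("delta", lambda c: c.delta == 0, "Scenario 4 requires delta = 0"),
           ("effect_kind", lambda c: c.effect_kind != CONSTANT,
            "Scenario 4b requires a time-varying covariate effect")],
    "5a": [("delta", lambda c: c.delta == 0, "Scenario 5 requires delta = 0"),
           ("effect_kind", lambda c: c.effect_kind == CONSTANT,
            "Scenario 5a requires a constant covariate effect")],
    "5b": [("delta", lambda c: c.delta == 0, "Scenario 5 requires delta = 0"),
           ("effect_kind", lambda c: c.effect_kind != CONSTANT,
            "Scenario 5b requires a time-varying covariate effect")],
    "6a": [("delta", lambda c: c.delta != 0,
            "Scenario 6 requires a treatment-affected covariate (delta != 0)"),
           ("effect_kind", lambda c: c.effect_kind == CONSTANT,
            "Scenario 6a requires a constant covariate effect")],
    "6b": [("delta", lambda c: c.delta != 0,
            "Scenario 6 requires a treatment-affected covariate (delta != 0)"),
           ("effect_kind", lambda c: c.effect_kind != CONSTANT,
            "Scenario 6b requires a time-varying covariate effect")],
}
for _sid in ("1", "2", "3"):
    _STRUCTURE_CHECKS[_sid].append(
        ("covariate_kind", lambda c: c.covariate_kind == TIME_INVARIANT,
         f"Scenarios 1-3 require a time-invariant covariate"))
for _sid in ("4a", "4b", "5a", "5b", "6a", "6b"):
    _STRUCTURE_CHECKS[_sid].append(
        ("covariate_kind", lambda c: c.covariate_kind == TIME_VARYING,
         "Scenarios 4-6 require a time-varying covariate"))


def make_scenario(
    scenario_id: str | int, overrides: Mapping | None = None
) -> ScenarioConfig:
    """Resolve a canonical scenario id into a full :class:`ScenarioConfig`.

    ``overrides`` is a flat mapping of :class:`ScenarioConfig` field names.
    Overrides that merely change magnitudes (sample size, noise SDs, means,
    the treatment effect) are applied as-is; overrides that contradict the
    scenario's defining structure raise :class:`StructuralConflictError`.
    """
    sid = str(scenario_id)
    if sid not in _SCENARIO_FIELDS:
        raise ValueError(
            f"unknown scenario id {scenario_id!r}; valid ids: {', '.join(SCENARIO_IDS)}"
        )
    fields = dict(_SCENARIO_FIELDS[sid])
    if overrides:
        fields.update(overrides)
    try:
        config = ScenarioConfig.from_dict(fields)
    except ValueError as err:
        # kind-level invariants (e.g. nonzero slope for a time-invariant
        # covariate) are structural conflicts when reached via the registry
        if overrides:
            raise StructuralConflictError(str(err)) from err
        raise
    for _field, ok, message in _STRUCTURE_CHECKS[sid]:
        if not ok(config):
            raise StructuralConflictError(message)
    return config


# ----------------------------------------------------------------------
# diagnostics
# ----------------------------------------------------------------------

def violation_profile(config: ScenarioConfig) -> ViolationProfile:
    """Parallel-trends violation profile of a data-generating process.

    Evaluates ``g(t) = lambda_t * (m1(t) - m0(t))`` along the untreated
    covariate path (``delta`` suppressed, since parallel trends is a
    statement about untreated potential outcomes). Trends are parallel iff
    ``g`` is constant: either the group covariate means coincide at every
    time, or the gap is constant and so is the effect schedule.
    """
    lam = config.lambda_schedule()
    gap = config.covariate_mean(1, treated_path=False) - config.covariate_mean(
        0, treated_path=False
    )
    g = lam * gap
    is_parallel = bool(np.ptp(g) <= PARALLEL_TOL)
    return ViolationProfile(
        g=tuple(float(v) for v in g),
        is_parallel=is_parallel,
        treatment_affects_covariate=config.delta != 0,
    )


def classify_confounding(config: ScenarioConfig) -> str:
    """Classify a data-generating process by its threat to diff-in-diff.

    Returns one of:

    * ``"treatment_affected_covariate"`` — the covariate responds to
      treatment (``delta != 0``); it mediates part of the effect and no
      covariate adjustment recovers the ATT.
    * ``"covariate_confounding"`` — the covariate induces a time-varying
      outcome gap between groups, breaking parallel trends.
    * ``"none"`` — an unadjusted diff-in-diff is unbiased.
    """
    profile = violation_profile(config)
    if profile.treatment_affects_covariate:
        return "treatment_affected_covariate"
    if not profile.is_parallel:
        return "covariate_confounding"
    return "none"


def true_att(config: ScenarioConfig) -> float:
    """Population ATT, averaged over posttreatment times ``t0..T``.

    With ``delta = 0`` the covariate is untouched by treatment and the ATT is
    exactly ``gamma``. With ``delta != 0`` the treated group's covariate is
    shifted by ``delta * (t - t0 + 1)`` at posttreatment time ``t``, and the
    covariate transmits an additional ``lambda_t *`` that shift into the
    outcome, so the ATT is ``gamma`` plus the posttreatment average of the
    mediated component.
    """
    if config.delta == 0:
        return float(config.gamma)
    t = config.times()
    post = t >= config.t0
    shift = config.delta * (t[post] - config.t0 + 1)
    lam = config.lambda_schedule()[post]
    return float(config.gamma + np.mean(lam * shift))
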