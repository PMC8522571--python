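"""The six treatment-effect estimators compared by the framework.

Three regressions, fit by weighted least squares with cluster-robust SEs
(clustered on unit):

* ``simple`` — time fixed effects, treated indicator, treated-by-post
  interaction; the covariate is ignored entirely.
* ``ca`` — covariate-adjusted: adds the covariate with a constant
  coefficient.
* ``tva`` — time-varying adjusted: adds one covariate coefficient per time
  point (covariate-by-time interactions, no separate main effect).

Three matching strategies, each 1:1 nearest-neighbor with replacement over
standardized matching vectors, followed by the simple regression on the
matched sample with match-multiplicity frequency weights:

* ``match_level`` — matched on the vector of pretreatment outcomes;
* ``match_trend`` — matched on pretreatment outcome first differences;
* ``match_cov`` — matched on pretreatment covariate values.

The treatment-by-post interaction coefficient ``gamma_hat`` equals the ATT
when the model is correctly specified for the data-generating process.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial.distance import cdist

from .exceptions import MatchingError, SingularDesignError
from .generators import PanelData

__all__ = [
    "ESTIMATOR_NAMES",
    "FitResult",
    "MatchedPanel",
    "fit_simple",
    "fit_ca",
    "fit_tva",
    "match_units",
    "fit_matched",
    "fit_estimator",
    "cluster_robust_se",
]

ESTIMATOR_NAMES = ("simple", "ca", "tva", "match_level", "match_trend", "match_cov")

MATCH_KEYS = ("level", "trend", "cov")


@dataclass(frozen=True)
class FitResult:
    """One estimator's treatment-effect estimate.

    ``gamma_hat`` is the coefficient on the treated-by-post interaction,
    ``se_gamma`` its cluster-robust standard error (clustered on unit).
    """

    estimator_name: str
    gamma_hat: float
    se_gamma: float
    n_units_used: int
    coefficients: pd.Series

    def to_record(self) -> dict:
        """Flat record suitable for appending to a results table."""
        return {
            "estimator": self.estimator_name,
            "gamma_hat": self.gamma_hat,
            "se_gamma": self.se_gamma,
            "n_units_used": self.n_units_used,
        }


@dataclass
class MatchedPanel:
    """A panel restricted to treated units and their matched controls.

    ``weights`` (indexed by unit) are 1 for every treated unit and the match
    multiplicity for each retained control; ``match_map`` records which
    control served each treated unit.
    """

    panel: PanelData
    weights: pd.Series
    match_map: dict


# ----------------------------------------------------------------------
# cluster-robust sandwich
# ----------------------------------------------------------------------

def cluster_robust_se(
    design: np.ndarray,
    residuals: np.ndarray,
    weights: np.ndarray,
    clusters: np.ndarray,
) -> np.ndarray:
    """CR1 cluster-robust standard errors for a weighted least-squares fit.

    Computes the sandwich ``(X'WX)^-1 [sum_g s_g s_g'] (X'WX)^-1`` with
    per-cluster scores ``s_g = X_g' W_g e_g``, scaled by the finite-sample
    factor ``G/(G-1) * (N-1)/(N-k)``. With unit weights and singleton
    clusters this reduces to HC1 heteroskedasticity-robust SEs.
    """
    X = np.asarray(design, dtype=float)
    e = np.asarray(residuals, dtype=float)
    w = np.asarray(weights, dtype=float)
    N, k = X.shape
    codes, uniques = pd.factorize(np.asarray(clusters))
    G = len(uniques)
    if G < 2:
        raise ValueError("cluster-robust SEs require at least 2 clusters")
    try:
        bread = np.linalg.inv(X.T @ (w[:, None] * X))
    except np.linalg.LinAlgError as err:
        raise SingularDesignError("design matrix is rank deficient") from err
    scores = (w * e)[:, None] * X
    S = np.zeros((G, k))
    np.add.at(S, codes, scores)
    meat = S.T @ S
    scale = (G / (G - 1)) * ((N - 1) / (N - k))
    cov = scale * bread @ meat @ bread
    # noiseless fits can leave the diagonal at -1e-30 from rounding
    return np.sqrt(np.clip(np.diag(cov), 0.0, None))


# ----------------------------------------------------------------------
# regression estimators
# ----------------------------------------------------------------------

def _design_matrix(df: pd.DataFrame, spec: str) -> tuple[np.ndarray, list[str]]:
    times = np.sort(df["time"].unique())
    time = df["time"].to_numpy()
    treated = df["treated"].to_numpy(dtype=float)
    post = df["post"].to_numpy(dtype=float)
    cols: dict[str, np.ndarray] = {"const": np.ones(len(df))}
    for t in times[1:]:
        cols[f"time_{t}"] = (time == t).astype(float)
    cols["treated"] = treated
    if spec == "ca":
        cols["x"] = df["x"].to_numpy(dtype=float)
    elif spec == "tva":
        x = df["x"].to_numpy(dtype=float)
        for t in times:
            cols[f"x_time_{t}"] = x * (time == t)
    cols["treated_post"] = treated * post
    return np.column_stack(list(cols.values())), list(cols)


def _check_panel(df: pd.DataFrame) -> None:
    if df["treated"].nunique() < 2:
        raise ValueError("panel must contain both treated and control units")
    if df["post"].nunique() < 2:
        raise ValueError("panel must contain both pre and post periods")


def _fit(
    df: pd.DataFrame, spec: str, name: str, weights: np.ndarray | None = None
) -> FitResult:
    _check_panel(df)
    X, names = _design_matrix(df, spec)
    y = df["y"].to_numpy(dtype=float)
    w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)
    model = sm.WLS(y, X, weights=w)
    res = model.fit(method="pinv")
    if model.rank < X.shape[1]:
        raise SingularDesignError(
            f"rank-deficient design for {name!r}: rank {model.rank} < {X.shape[1]} columns"
        )
    beta = np.asarray(res.params)
    resid = y - X @ beta
    ses = cluster_robust_se(X, resid, w, df["unit"].to_numpy())
    idx = names.index("treated_post")
    return FitResult(
        estimator_name=name,
        gamma_hat=float(beta[idx]),
        se_gamma=float(ses[idx]),
        n_units_used=int(df["unit"].nunique()),
        coefficients=pd.Series(beta, index=names),
    )


def fit_simple(panel: PanelData) -> FitResult:
    """Unadjusted diff-in-diff regression (time FE + treated + treated:post)."""
    return _fit(panel.frame, "simple", "simple")


def fit_ca(panel: PanelData) -> FitResult:
    """Covariate-adjusted regression: simple model plus a constant-coefficient
    covariate main effect."""
    return _fit(panel.frame, "ca", "ca")


def fit_tva(panel: PanelData) -> FitResult:
    """Time-varying adjusted regression: simple model plus one covariate
    coefficient per time point."""
    return _fit(panel.frame, "tva", "tva")


# ----------------------------------------------------------------------
# matching estimators
# ----------------------------------------------------------------------

def _matching_matrix(panel: PanelData, on: str) -> pd.DataFrame:
    """Per-unit matching vectors (rows indexed by unit, ascending)."""
    df = panel.frame
    pre_times = sorted(t for t in df["time"].unique() if t < panel.t0)
    if not pre_times:
        raise MatchingError("matching requires at least one pretreatment period")
    if on == "trend" and len(pre_times) < 2:
        raise MatchingError("trend matching requires at least two pretreatment periods")
    if on in ("level", "trend"):
        wide = df.pivot(index="unit", columns="time", values="y")[pre_times]
        if on == "trend":
            wide = wide.diff(axis=1).iloc[:, 1:]
    elif on == "cov":
        # for a time-invariant covariate the pretreatment columns are
        # identical, making this equivalent to matching on the scalar x_i
        wide = df.pivot(index="unit", columns="time", values="x")[pre_times]
    else:
        raise ValueError(f"unknown matching key {on!r}; expected one of {MATCH_KEYS}")
    return wide.sort_index()


def match_units(panel: PanelData, on: str) -> MatchedPanel:
    """1:1 nearest-neighbor matching with replacement, treated to control.

    Matching vectors are standardized coordinate-wise by the pooled mean and
    SD across all units; distance is Euclidean. Ties are broken toward the
    lowest control unit id. Every treated unit is retained with weight 1;
    each matched control is retained once with a weight equal to the number
    of treated units it serves.
    """
    wide = _matching_matrix(panel, on)
    treated_by_unit = panel.frame.groupby("unit")["treated"].first()
    treated_ids = treated_by_unit.index[treated_by_unit == 1].to_numpy()
    control_ids = treated_by_unit.index[treated_by_unit == 0].to_numpy()
    if len(treated_ids) == 0 or len(control_ids) == 0:
        raise MatchingError("matching requires both treated and control units")

    values = wide.to_numpy(dtype=float)
    sd = values.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    z = (values - values.mean(axis=0)) / sd
    zframe = pd.DataFrame(z, index=wide.index)

    # argmin returns the first minimum; control ids are sorted ascending,
    # so distance ties resolve to the lowest id
    dist = cdist(zframe.loc[treated_ids].to_numpy(), zframe.loc[control_ids].to_numpy())
    best = dist.argmin(axis=1)
    matched_controls = control_ids[best]

    match_map = dict(zip(treated_ids.tolist(), matched_controls.tolist()))
    multiplicity = pd.Series(matched_controls).value_counts()
    weights = pd.concat(
        [
            pd.Series(1.0, index=treated_ids),
            multiplicity.astype(float).sort_index(),
        ]
    )
    weights.index.name = "unit"

    keep = panel.frame["unit"].isin(weights.index)
    sub = panel.frame.loc[keep].reset_index(drop=True)
    return MatchedPanel(
        panel=PanelData(frame=sub, t0=panel.t0),
        weights=weights,
        match_map=match_map,
    )


def fit_matched(panel: PanelData, on: str) -> FitResult:
    """Match, then fit the simple regression on the matched sample.

    Reused controls enter through frequency weights (point estimates are
    identical to row duplication); clustering stays on unit, so a reused
    control is a single cluster.
    """
    matched = match_units(panel, on)
    df = matched.panel.frame
    row_w = df["unit"].map(matched.weights).to_numpy(dtype=float)
    result = _fit(df, "simple", f"match_{on}", weights=row_w)
    return result


def fit_estimator(name: str, panel: PanelData) -> FitResult:
    """Dispatch one of the six estimators by name."""
    if name == "simple":
        return fit_simple(panel)
    if name == "ca":
        return fit_ca(panel)
    if name == "tva":
        return fit_tva(panel)
    if name.startswith("match_"):
        key = name.removeprefix("match_")
        if key in MATCH_KEYS:
            return fit_matched(panel, key)
    raise ValueError(f"unknown estimator {name!r}; expected one of {ESTIMATOR_NAMES}")
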