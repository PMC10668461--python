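"""Dynamic logistic model of vaccine-intent transitions.

Fits, by penalized maximum likelihood, the two-state transition model

    Pr(y_it = 1) = logistic( x_i @ theta0 + y_{i,t-1} * (x_i @ gamma)
                             + alpha_k(i) + tau_t )

where y_it is 1 when household i expresses intent to vaccinate in round t,
x_i is the household/contextual covariate vector (with intercept), theta0
are effects for households that said "no" in the previous round, theta1 =
theta0 + gamma the effects for previous "yes" households, alpha_k a fixed
effect of the administrative unit and tau_t a fixed effect of the survey
round.  Survey weights enter as pseudo-likelihood multipliers (normalized
to mean 1).  Inference uses a two-way cluster-robust sandwich covariance
(administrative unit and survey round) combined by inclusion-exclusion.

Continuous covariates are z-scored internally for numerical conditioning
and all reported coefficients are back-transformed to the raw scale, so
``FitResult`` values are directly comparable to generating coefficients or
to covariates in natural units.  A small ridge penalty on the fixed-effect
coefficients only (default 1e-6) keeps the fit defined when a unit or
round has all-identical outcomes; the main coefficients stay unpenalized
maximum-likelihood estimates.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("vaxdyn")

MAX_ITER = 100
SCORE_TOL = 1e-8
STEP_TOL = 1e-10
# plateau backstop for quasi-separated samples: likelihood flat and score
# already small, but the score tolerance is unreachable along a crawling
# separation direction
PLATEAU_LL_TOL = 1e-9
PLATEAU_SCORE_TOL = 1e-5
SEPARATION_THRESHOLD = 15.0  # |coef| on the standardized scale


def logistic(z):
    return 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=float)))


class ConvergenceError(RuntimeError):
    """Raised when the Newton optimizer fails to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict):
        super().__init__(message)
        self.diagnostics = diagnostics


# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """What enters the transition model.

    ``covariate_names`` fixes the order of x_i (the intercept is implicit
    and always first).  ``ridge_penalty`` applies to unit/round fixed-effect
    coefficients only.
    """

    covariate_names: tuple[str, ...]
    include_unit_fe: bool = True
    include_round_fe: bool = True
    include_lag_interaction: bool = True  # False fits a static pooled logit
    ridge_penalty: float = 1e-6
    weight_column: str = "weight"

    def __post_init__(self) -> None:
        if len(self.covariate_names) == 0:
            raise ValueError("covariate_names must be non-empty")
        if len(set(self.covariate_names)) != len(self.covariate_names):
            raise ValueError("covariate_names contains duplicates")
        if self.ridge_penalty < 0:
            raise ValueError("ridge_penalty must be >= 0")


@dataclass
class ClusterPlan:
    """Columns defining the two clustering dimensions."""

    unit_cluster_column: str = "unit_id"
    round_cluster_column: str = "round"


@dataclass
class Design:
    """Assembled design matrix and everything needed to fit and report.

    ``X`` columns are ordered [x block, y_lag*x block, unit dummies
    (reference dropped), round dummies (reference dropped)]; the x block is
    [intercept, covariates...] with continuous covariates standardized
    (means/sds recorded for back-transformation).
    """

    X: np.ndarray
    y: np.ndarray
    w: np.ndarray  # normalized to mean 1
    colnames: list[str]
    penalty_mask: np.ndarray  # True where the ridge applies (FE columns)
    unit_labels: np.ndarray
    round_labels: np.ndarray
    unit_categories: list
    round_categories: list
    cov_means: np.ndarray  # per covariate (0 where not standardized)
    cov_sds: np.ndarray  # per covariate (1 where not standardized)
    spec: ModelSpec
    n_dropped: int

    @property
    def n_covariates(self) -> int:
        return len(self.spec.covariate_names)


def build_design(table: pd.DataFrame, spec: ModelSpec) -> Design:
    """Build the estimation design from the integrated analysis table.

    Requires columns ``response``, ``response_lag``, ``unit_id``, ``round``,
    the covariates in ``spec.covariate_names`` and the weight column.  Rows
    with any missing value among these are dropped (count logged).  A main
    covariate constant across the estimation sample is an error: its effect
    is not identified.
    """
    needed = (
        ["response", "response_lag", "unit_id", "round", spec.weight_column]
        + list(spec.covariate_names)
    )
    missing_cols = [c for c in needed if c not in table.columns]
    if missing_cols:
        raise ValueError(f"analysis table lacks columns {missing_cols}")
    sub = table[needed].copy()
    ok = sub.notna().all(axis=1)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("build_design: dropped %d rows with missing values", n_dropped)
    sub = sub.loc[ok]
    if len(sub) == 0:
        raise ValueError("no complete estimation rows")

    y = sub["response"].to_numpy(dtype=float)
    y_lag = sub["response_lag"].to_numpy(dtype=float)
    w = sub[spec.weight_column].to_numpy(dtype=float)
    if np.any(w <= 0):
        raise ValueError("survey weights must be strictly positive")
    w = w / w.mean()

    m = len(spec.covariate_names)
    raw = sub[list(spec.covariate_names)].to_numpy(dtype=float)
    means = np.zeros(m)
    sds = np.ones(m)
    for j, name in enumerate(spec.covariate_names):
        col = raw[:, j]
        uniq = np.unique(col)
        if uniq.size == 1:
            raise ValueError(f"covariate {name!r} is constant; effect not identified")
        if not set(np.round(uniq, 12)).issubset({0.0, 1.0}):
            means[j] = col.mean()
            sds[j] = col.std(ddof=0)
    Z = (raw - means) / sds

    xblock = np.column_stack([np.ones(len(sub)), Z])
    blocks = [xblock]
    names = ["theta0:intercept"] + [f"theta0:{n}" for n in spec.covariate_names]
    if spec.include_lag_interaction:
        blocks.append(xblock * y_lag[:, None])
        names += ["gamma:intercept"] + [f"gamma:{n}" for n in spec.covariate_names]
    penalty = [False] * len(names)

    unit_labels = sub["unit_id"].to_numpy()
    unit_categories = sorted(pd.unique(unit_labels))
    if spec.include_unit_fe and len(unit_categories) > 1:
        dummies = (unit_labels[:, None] == np.array(unit_categories[1:], dtype=object)[None, :]).astype(float)
        blocks.append(dummies)
        names += [f"alpha:{u}" for u in unit_categories[1:]]
        penalty += [True] * (len(unit_categories) - 1)

    round_labels = sub["round"].to_numpy()
    round_categories = sorted(pd.unique(round_labels))
    if spec.include_round_fe and len(round_categories) > 1:
        dummies = (round_labels[:, None] == np.array(round_categories[1:])[None, :]).astype(float)
        blocks.append(dummies)
        names += [f"tau:{t}" for t in round_categories[1:]]
        penalty += [True] * (len(round_categories) - 1)

    return Design(
        X=np.column_stack(blocks),
        y=y,
        w=w,
        colnames=names,
        penalty_mask=np.array(penalty),
        unit_labels=unit_labels,
        round_labels=round_labels,
        unit_categories=unit_categories,
        round_categories=round_categories,
        cov_means=means,
        cov_sds=sds,
        spec=spec,
        n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# Fit result
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Raw-scale coefficient estimates and covariance for the fitted model.

    ``theta0``/``gamma`` have length 1 + n_covariates (leading intercept) on
    the original covariate scales; ``theta1 = theta0 + gamma`` exactly.
    ``vcov`` covers the free parameters in the order
    [theta0, gamma, alpha (non-reference units), tau (non-reference rounds)];
    by default it is the inverse observed-information covariance — replace it
    via :func:`cluster_robust_vcov` for clustered inference.
    """

    covariate_names: list[str]
    theta0: np.ndarray
    gamma: np.ndarray
    unit_effects: dict
    round_effects: dict
    vcov: np.ndarray
    param_names: list[str]
    n_obs: int
    log_likelihood: float
    converged: bool
    n_iter: int
    beta_std: np.ndarray = field(repr=False)  # standardized-scale optimum
    transform: np.ndarray = field(repr=False)  # raw = transform @ beta_std
    ll_trace: list = field(default_factory=list, repr=False)  # penalized ll per iteration

    @property
    def theta1(self) -> np.ndarray:
        return self.theta0 + self.gamma

    def params_raw(self) -> np.ndarray:
        return self.transform @ self.beta_std

    def standard_errors(self) -> pd.Series:
        se = np.sqrt(np.clip(np.diag(self.vcov), 0.0, None))
        return pd.Series(se, index=self.param_names)

    def wald_intervals(self, level: float = 0.95) -> pd.DataFrame:
        """Wald confidence intervals for all free parameters (raw scale)."""
        z = stats.norm.ppf(0.5 + level / 2.0)
        est = self.params_raw()
        se = self.standard_errors().to_numpy()
        return pd.DataFrame(
            {"estimate": est, "se": se, "lower": est - z * se, "upper": est + z * se},
            index=self.param_names,
        )

    def to_json(self, path) -> None:
        payload = {
            "covariate_names": list(self.covariate_names),
            "theta0": self.theta0.tolist(),
            "gamma": self.gamma.tolist(),
            "unit_effects": {str(k): v for k, v in self.unit_effects.items()},
            "round_effects": {str(k): v for k, v in self.round_effects.items()},
            "vcov": self.vcov.tolist(),
            "param_names": list(self.param_names),
            "n_obs": self.n_obs,
            "log_likelihood": self.log_likelihood,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "beta_std": self.beta_std.tolist(),
            "transform": self.transform.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "FitResult":
        with open(path) as fh:
            d = json.load(fh)
        round_effects = {}
        for k, v in d["round_effects"].items():
            try:
                key = int(k)
            except ValueError:
                key = k
            round_effects[key] = v
        return cls(
            covariate_names=d["covariate_names"],
            theta0=np.array(d["theta0"]),
            gamma=np.array(d["gamma"]),
            unit_effects=d["unit_effects"],
            round_effects=round_effects,
            vcov=np.array(d["vcov"]),
            param_names=d["param_names"],
            n_obs=d["n_obs"],
            log_likelihood=d["log_likelihood"],
            converged=d["converged"],
            n_iter=d["n_iter"],
            beta_std=np.array(d["beta_std"]),
            transform=np.array(d["transform"]),
        )


def _raw_transform(design: Design) -> np.ndarray:
    """Linear map from standardized-scale to raw-scale parameters.

    The x block transforms by the inverse standardization (intercept absorbs
    -mean/sd terms); the y_lag interaction block transforms identically; FE
    coefficients are unchanged.
    """
    m = design.n_covariates
    Ax = np.eye(m + 1)
    Ax[0, 1:] = -design.cov_means / design.cov_sds
    Ax[1:, 1:] = np.diag(1.0 / design.cov_sds)
    p = design.X.shape[1]
    A = np.eye(p)
    A[: m + 1, : m + 1] = Ax
    if design.spec.include_lag_interaction:
        A[m + 1 : 2 * (m + 1), m + 1 : 2 * (m + 1)] = Ax
    return A


def _floored_eigh(H: np.ndarray, lam: float) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of a PSD matrix with small eigenvalues floored.

    Directions of the penalized Hessian with (numerically) zero curvature —
    exact collinearities among unpenalized columns, e.g. unit-level
    covariates spanning the whole unit space — are assigned the ridge scale
    ``lam`` instead, so Newton steps stay bounded and the corresponding
    variances read 1/lam ("not identified by the data"), matching the
    convention for ridge-pinned fixed-effect directions.
    """
    evals, evecs = np.linalg.eigh(H)
    scale = max(float(evals[-1]), 1.0)
    floor = max(lam, 1e-12 * scale)
    return np.maximum(evals, floor), evecs


def _penalized_loglik(design: Design, beta: np.ndarray, lam: float) -> float:
    eta = design.X @ beta
    ll = float(np.sum(design.w * (design.y * eta - np.logaddexp(0.0, eta))))
    pen = 0.5 * lam * float(np.sum(beta[design.penalty_mask] ** 2))
    return ll - pen


def fit_weighted_logit(
    design: Design,
    spec: ModelSpec | None = None,
    beta_init: np.ndarray | None = None,
) -> FitResult:
    """Maximize the weighted, FE-ridge-penalized Bernoulli log-likelihood.

    Newton-Raphson with step halving; converged when the maximum absolute
    score drops below 1e-8 or the parameter step below 1e-10.  Raises
    :class:`ConvergenceError` (with iteration diagnostics) otherwise, and
    warns naming the offending columns when a standardized coefficient
    exceeds 15 in magnitude (a symptom of perfect separation).
    """
    spec = spec or design.spec
    lam = spec.ridge_penalty
    X, y, w = design.X, design.y, design.w
    n, p = X.shape
    pen_diag = lam * design.penalty_mask.astype(float)

    beta = np.zeros(p) if beta_init is None else np.asarray(beta_init, dtype=float).copy()
    ll = _penalized_loglik(design, beta, lam)
    ll_trace = [ll]
    converged = False
    n_iter = 0
    max_score = np.inf
    for n_iter in range(1, MAX_ITER + 1):
        eta = X @ beta
        prob = logistic(eta)
        score = X.T @ (w * (y - prob)) - pen_diag * beta
        max_score = float(np.max(np.abs(score)))
        if max_score < SCORE_TOL:
            converged = True
            break
        wp = w * prob * (1.0 - prob)
        H = X.T @ (X * wp[:, None]) + np.diag(pen_diag)
        evals, evecs = _floored_eigh(H, lam if lam > 0 else 1e-8)
        step = evecs @ ((evecs.T @ score) / evals)
        # step halving keeps the penalized log-likelihood non-decreasing
        scale = 1.0
        for _ in range(40):
            cand = beta + scale * step
            ll_cand = _penalized_loglik(design, cand, lam)
            if ll_cand >= ll - 1e-12:
                break
            scale *= 0.5
        if float(np.max(np.abs(scale * step))) < STEP_TOL:
            beta = cand
            converged = True
            break
        plateau = abs(ll_cand - ll) < PLATEAU_LL_TOL * (1.0 + abs(ll_cand))
        beta = cand
        ll = ll_cand
        ll_trace.append(ll)
        if plateau and max_score < PLATEAU_SCORE_TOL:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"no convergence after {MAX_ITER} iterations (max |score| = {max_score:.3g})",
            {"iterations": MAX_ITER, "max_score": max_score, "loglik": ll},
        )

    sep = np.abs(beta) > SEPARATION_THRESHOLD
    if np.any(sep):
        cols = [design.colnames[j] for j in np.flatnonzero(sep)]
        warnings.warn(
            f"possible separation: standardized coefficients exceed "
            f"{SEPARATION_THRESHOLD} for columns {cols}",
            RuntimeWarning,
            stacklevel=2,
        )

    eta = X @ beta
    prob = logistic(eta)
    wp = w * prob * (1.0 - prob)
    H = X.T @ (X * wp[:, None]) + np.diag(pen_diag)
    evals, evecs = _floored_eigh(H, lam if lam > 0 else 1e-8)
    vcov_std = (evecs / evals) @ evecs.T
    A = _raw_transform(design)
    vcov_raw = A @ vcov_std @ A.T
    vcov_raw = 0.5 * (vcov_raw + vcov_raw.T)
    beta_raw = A @ beta

    m = design.n_covariates
    theta0 = beta_raw[: m + 1]
    if spec.include_lag_interaction:
        gamma = beta_raw[m + 1 : 2 * (m + 1)]
        idx = 2 * (m + 1)
    else:
        gamma = np.zeros(m + 1)
        idx = m + 1
    unit_effects = {}
    if spec.include_unit_fe and len(design.unit_categories) > 1:
        unit_effects[design.unit_categories[0]] = 0.0
        for u in design.unit_categories[1:]:
            unit_effects[u] = float(beta_raw[idx])
            idx += 1
    round_effects = {}
    if spec.include_round_fe and len(design.round_categories) > 1:
        round_effects[design.round_categories[0]] = 0.0
        for t in design.round_categories[1:]:
            round_effects[t] = float(beta_raw[idx])
            idx += 1

    return FitResult(
        covariate_names=list(spec.covariate_names),
        theta0=theta0,
        gamma=gamma,
        unit_effects=unit_effects,
        round_effects=round_effects,
        vcov=vcov_raw,
        param_names=list(design.colnames),
        n_obs=n,
        log_likelihood=float(np.sum(w * (y * eta - np.logaddexp(0.0, eta)))),
        converged=True,
        n_iter=n_iter,
        beta_std=beta,
        transform=A,
        ll_trace=ll_trace,
    )


# ---------------------------------------------------------------------------
# Cluster-robust covariance
# ---------------------------------------------------------------------------

def _meat(g: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, int]:
    """Sum of outer products of cluster-summed score contributions, CR1-scaled."""
    df = pd.DataFrame(g)
    sums = df.groupby(pd.Series(labels), sort=False).sum().to_numpy()
    G = sums.shape[0]
    if G < 2:
        raise ValueError("clustering dimension has a single cluster; variance undefined")
    return (G / (G - 1.0)) * (sums.T @ sums), G


def cluster_robust_vcov(
    fit: FitResult, design: Design, plan: ClusterPlan | None = None
) -> np.ndarray:
    """Two-way cluster-robust sandwich covariance (raw scale).

    Combines one-way sandwich estimators by inclusion-exclusion:
    V = V_unit + V_round - V_(unit x round), each with a CR1 small-sample
    factor G/(G-1).  Negative eigenvalues of the combined matrix (possible
    in finite samples) are truncated to zero with a logged warning.

    ``plan`` is accepted for interface completeness; the clustering labels
    themselves were captured by :func:`build_design`.
    """
    del plan  # labels live on the design
    X, y, w = design.X, design.y, design.w
    beta = fit.beta_std
    prob = logistic(X @ beta)
    g = X * (w * (y - prob))[:, None]

    lam = design.spec.ridge_penalty
    wp = w * prob * (1.0 - prob)
    H = X.T @ (X * wp[:, None]) + np.diag(lam * design.penalty_mask.astype(float))
    evals_h, evecs_h = _floored_eigh(H, lam if lam > 0 else 1e-8)
    bread = (evecs_h / evals_h) @ evecs_h.T

    inter = np.array(
        [f"{u}|{t}" for u, t in zip(design.unit_labels, design.round_labels)],
        dtype=object,
    )
    meat_u, _ = _meat(g, design.unit_labels)
    meat_r, _ = _meat(g, design.round_labels)
    meat_i, _ = _meat(g, inter)
    V = bread @ (meat_u + meat_r - meat_i) @ bread
    V = 0.5 * (V + V.T)

    # Directions in the exact null space of the design (e.g. unit-level
    # covariates under unit fixed effects) carry no sampling information: the
    # sandwich sees no score variation along them, yet the estimates there are
    # pinned only by the ridge normalization.  Restore the penalty-scale
    # variance 1/lambda for those directions so their intervals honestly
    # report "not identified by the data" instead of spuriously tight.
    if lam > 0:
        evals_x, evecs_x = np.linalg.eigh(X.T @ X)
        null = evecs_x[:, evals_x < 1e-10 * max(evals_x.max(), 1.0)]
        if null.shape[1]:
            V = V + (null @ null.T) / lam

    evals, evecs = np.linalg.eigh(V)
    if np.any(evals < 0):
        logger.warning(
            "two-way cluster vcov had %d negative eigenvalues (min %.3g); truncated to 0",
            int((evals < 0).sum()),
            float(evals.min()),
        )
        V = (evecs * np.clip(evals, 0.0, None)) @ evecs.T
    A = fit.transform
    Vr = A @ V @ A.T
    return 0.5 * (Vr + Vr.T)


def with_cluster_robust_vcov(
    fit: FitResult, design: Design, plan: ClusterPlan | None = None
) -> FitResult:
    """Return a copy of ``fit`` whose ``vcov`` is the two-way clustered one."""
    return dataclasses.replace(fit, vcov=cluster_robust_vcov(fit, design, plan))


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def _profile_vector(fit: FitResult, profile) -> np.ndarray:
    if isinstance(profile, dict):
        missing = [n for n in fit.covariate_names if n not in profile]
        if missing:
            raise ValueError(f"profile lacks covariates {missing}")
        x = np.array([float(profile[n]) for n in fit.covariate_names])
    else:
        x = np.asarray(profile, dtype=float)
        if x.shape != (len(fit.covariate_names),):
            raise ValueError(
                f"profile has shape {x.shape}, expected ({len(fit.covariate_names)},)"
            )
    return x


def predict_transition_probs(
    fit: FitResult, profile, alpha: float = 0.0, tau: float = 0.0
) -> tuple[float, float]:
    """Transition probabilities at a covariate profile (raw scale).

    Returns ``(p_no_to_yes, p_yes_to_yes)``: the probability of answering
    "yes" given a previous "no" uses theta0, given a previous "yes" uses
    theta1 = theta0 + gamma; both add the supplied unit effect ``alpha``
    and round effect ``tau``.
    """
    x = _profile_vector(fit, profile)
    x1 = np.concatenate([[1.0], x])
    lp0 = float(x1 @ fit.theta0) + alpha + tau
    lp1 = float(x1 @ fit.theta1) + alpha + tau
    return float(logistic(lp0)), float(logistic(lp1))
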