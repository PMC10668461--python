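"""Long-run analysis of the fitted two-state vaccine-intent chain.

Given fitted transition-model coefficients, this module builds the 2x2
transition probability matrix at a covariate profile, extracts its
stationary distribution by eigendecomposition (cross-checked against the
two-state closed form pi_yes = p01 / (p01 + p10)), constructs percentile
counterfactual scenarios (a target covariate at its weighted 1st/99th
percentile with everything else at the weighted median), and attaches
cluster-bootstrap percentile confidence intervals obtained by resampling
administrative units with replacement and refitting the model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel_model import (
    ClusterPlan,
    Design,
    FitResult,
    ModelSpec,
    build_design,
    fit_weighted_logit,
    predict_transition_probs,
)

logger = logging.getLogger("vaxdyn")

STATES = ("no", "yes")
MAX_BOOTSTRAP_FAILURE_FRACTION = 0.10


# ---------------------------------------------------------------------------
# Transition matrix and stationary distribution
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic 2x2 matrix; rows = previous answer, columns = current.

    State order is ("no", "yes"), so ``P[0, 1]`` is the probability a
    previously hesitant household switches to "yes".
    """

    P: np.ndarray

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=float)
        if P.shape != (2, 2):
            raise ValueError("transition matrix must be 2x2")
        if np.any(P < -1e-12) or np.any(P > 1 + 1e-12):
            raise ValueError("transition probabilities must lie in [0, 1]")
        if not np.allclose(P.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("rows of a transition matrix must sum to 1")
        object.__setattr__(self, "P", P)

    @property
    def p_no_to_yes(self) -> float:
        return float(self.P[0, 1])

    @property
    def p_yes_to_no(self) -> float:
        return float(self.P[1, 0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.P, index=list(STATES), columns=list(STATES))


@dataclass(frozen=True)
class StationaryDist:
    """Long-run distribution over ("no", "yes"); ``degenerate`` flags an
    absorbing chain whose stationary distribution is a point mass."""

    pi_no: float
    pi_yes: float
    degenerate: bool = False


def transition_matrix(
    fit: FitResult, profile, alpha: float = 0.0, tau: float = 0.0
) -> TransitionMatrix:
    """Transition matrix at a covariate profile from fitted coefficients."""
    p01, p11 = predict_transition_probs(fit, profile, alpha=alpha, tau=tau)
    return TransitionMatrix(np.array([[1.0 - p01, p01], [1.0 - p11, p11]]))


def stationary_distribution(P: TransitionMatrix | np.ndarray) -> StationaryDist:
    """Stationary distribution of a 2-state chain via eigendecomposition.

    Computes the left eigenvector of P for eigenvalue 1, normalized to sum
    to 1, and verifies it against the closed form
    pi_yes = p01 / (p01 + p10) to 1e-12.  An absorbing chain (an
    off-diagonal exactly 0) returns the exact degenerate distribution with
    ``degenerate=True``; a chain with both off-diagonals 0 (the identity)
    has no unique stationary distribution and raises.
    """
    if not isinstance(P, TransitionMatrix):
        P = TransitionMatrix(P)
    p01 = P.P[0, 1]
    p10 = P.P[1, 0]
    if p01 == 0.0 and p10 == 0.0:
        raise ValueError("identity chain: stationary distribution not unique")
    if p01 == 0.0:
        return StationaryDist(1.0, 0.0, degenerate=True)
    if p10 == 0.0:
        return StationaryDist(0.0, 1.0, degenerate=True)

    # Left eigenvector for eigenvalue 1.  A row-stochastic matrix has the
    # eigenvalue exactly 1, so the eigenvector is the null space of P^T - I.
    # That matrix is assembled from the off-diagonal entries (row sums are 1,
    # so the diagonal of P^T - I equals minus the opposite off-diagonal);
    # this avoids the cancellation in computing (1 - p) - 1 and keeps the
    # SVD null vector accurate even when the spectral gap is tiny.
    Q = np.array([[-p01, p10], [p01, -p10]])
    _, _, vt = np.linalg.svd(Q)
    v = vt[-1]
    pi = v / v.sum()

    pi_yes_closed = p01 / (p01 + p10)
    if abs(pi[1] - pi_yes_closed) > 1e-12:
        raise AssertionError(
            f"eigendecomposition ({pi[1]!r}) and closed form ({pi_yes_closed!r}) disagree"
        )
    return StationaryDist(float(pi[0]), float(pi[1]))


def persistence_summary(P: TransitionMatrix | np.ndarray) -> tuple[float, float]:
    """Diagonal of the transition matrix: (stay-yes, stay-no) probabilities.

    These are the round-to-round persistence of vaccine acceptance and of
    hesitancy, respectively.
    """
    if not isinstance(P, TransitionMatrix):
        P = TransitionMatrix(P)
    return float(P.P[1, 1]), float(P.P[0, 0])


# ---------------------------------------------------------------------------
# Counterfactual scenarios
# ---------------------------------------------------------------------------

def weighted_quantile(values, weights, q: float) -> float:
    """Nearest-rank weighted quantile: smallest v with F(v) >= q."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    order = np.argsort(values, kind="stable")
    v = values[order]
    cw = np.cumsum(weights[order])
    target = q * cw[-1]
    return float(v[np.searchsorted(cw, target, side="left")])


@dataclass(frozen=True)
class CounterfactualScenario:
    """A covariate profile with one target covariate pushed to a percentile.

    ``level`` is "low" (1st percentile), "high" (99th percentile) or
    "median"; all non-target covariates sit at their survey-weighted median
    over the estimation rows.  ``alpha``/``tau`` are the unit/round effects
    at which predictions are evaluated.
    """

    target_covariate: str
    level: str
    profile: dict
    alpha: float
    tau: float
    constant_target: bool = False

    @property
    def name(self) -> str:
        return f"{self.target_covariate}:{self.level}"


@dataclass(frozen=True)
class ScenarioResult:
    """Stationary yes-probability of a scenario with a bootstrap interval."""

    scenario: CounterfactualScenario
    point: float
    lo95: float
    hi95: float
    replicates: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class ScenarioDifference:
    """High-minus-low contrast for one target, in percentage points."""

    target_covariate: str
    diff_ppd: float
    lo95_ppd: float
    hi95_ppd: float


def median_profile_effects(fit: FitResult) -> tuple[float, float]:
    """The "median household" unit and round effects.

    Unit effect: median of the estimated unit effects (reference included at
    0); round effect: mean of the estimated round effects.  Both fall back
    to 0 when the model has no such fixed effects.
    """
    alpha = float(np.median(list(fit.unit_effects.values()))) if fit.unit_effects else 0.0
    tau = float(np.mean(list(fit.round_effects.values()))) if fit.round_effects else 0.0
    return alpha, tau


def make_scenarios(
    fit: FitResult,
    analysis_table: pd.DataFrame,
    targets: list[str],
    weight_column: str = "weight",
) -> list[CounterfactualScenario]:
    """Median / 1st-percentile / 99th-percentile scenarios per target.

    Percentiles are survey-weight-weighted over the estimation rows; a
    constant target covariate yields low == high and is flagged.
    """
    unknown = [t for t in targets if t not in fit.covariate_names]
    if unknown:
        raise ValueError(f"targets {unknown} not among model covariates")
    w = analysis_table[weight_column].to_numpy(dtype=float)
    medians = {
        name: weighted_quantile(analysis_table[name], w, 0.5)
        for name in fit.covariate_names
    }
    alpha, tau = median_profile_effects(fit)
    scenarios: list[CounterfactualScenario] = []
    for target in targets:
        col = analysis_table[target].to_numpy(dtype=float)
        lo = weighted_quantile(col, w, 0.01)
        hi = weighted_quantile(col, w, 0.99)
        constant = lo == hi
        if constant:
            logger.warning("target %s is (weighted-)constant: low == high", target)
        for level, value in (("median", medians[target]), ("low", lo), ("high", hi)):
            profile = dict(medians)
            profile[target] = value
            scenarios.append(
                CounterfactualScenario(target, level, profile, alpha, tau, constant)
            )
    return scenarios


def scenario_stationary_yes(fit: FitResult, scenario: CounterfactualScenario) -> float:
    """Stationary yes-probability of one scenario under fitted coefficients.

    The scenario's alpha/tau are recomputed from the supplied fit (median
    unit effect, mean round effect) so bootstrap refits use their own
    estimated fixed effects.
    """
    alpha, tau = median_profile_effects(fit)
    P = transition_matrix(fit, scenario.profile, alpha=alpha, tau=tau)
    return stationary_distribution(P).pi_yes


# ---------------------------------------------------------------------------
# Cluster bootstrap
# ---------------------------------------------------------------------------

def _nearest_rank_interval(reps: np.ndarray) -> tuple[float, float]:
    """Exact nearest-rank 2.5 / 97.5 percentile endpoints (order statistics)."""
    s = np.sort(reps)
    B = len(s)
    lo = s[max(int(np.ceil(0.025 * B)) - 1, 0)]
    hi = s[min(int(np.ceil(0.975 * B)) - 1, B - 1)]
    return float(lo), float(hi)


def _resample_units(
    analysis_table: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw administrative units with replacement; re-label duplicates.

    A unit drawn twice enters as two distinct clusters (and two distinct
    fixed effects), the standard cluster-bootstrap convention.
    """
    unit_ids = np.sort(analysis_table["unit_id"].unique())
    draw = rng.choice(unit_ids, size=len(unit_ids), replace=True)
    groups = {u: g for u, g in analysis_table.groupby("unit_id", sort=False)}
    parts = []
    for j, u in enumerate(draw):
        g = groups[u].copy()
        g["unit_id"] = f"{u}#{j}"
        parts.append(g)
    return pd.concat(parts, ignore_index=True)


def _warm_start(design_b: Design, fit: FitResult) -> np.ndarray:
    """Initial parameter vector for a bootstrap refit from the full-sample fit.

    Main-effect blocks carry over directly (resample standardization is close
    to the original); each relabelled unit cluster starts at its source
    unit's estimated effect.  Only an initialization — the refit converges to
    the resample's own optimum.
    """
    beta = np.zeros(design_b.X.shape[1])
    k = (2 if design_b.spec.include_lag_interaction else 1) * (1 + design_b.n_covariates)
    beta[:k] = fit.beta_std[:k]
    for j, name in enumerate(design_b.colnames):
        if name.startswith("alpha:"):
            source = name[len("alpha:"):].split("#")[0]
            beta[j] = fit.unit_effects.get(source, 0.0)
        elif name.startswith("tau:"):
            label = name[len("tau:"):]
            eff = fit.round_effects
            beta[j] = eff.get(label, eff.get(int(label) if label.isdigit() else label, 0.0))
    return beta


def bootstrap_scenarios(
    analysis_table: pd.DataFrame,
    spec: ModelSpec,
    scenarios: list[CounterfactualScenario],
    B: int = 1000,
    seed: int = 0,
    fit: FitResult | None = None,
) -> tuple[list[ScenarioResult], list[ScenarioDifference]]:
    """Cluster-bootstrap intervals for scenario stationary probabilities.

    Resamples administrative units with replacement B times, refits the
    transition model on each resample, and recomputes every scenario's
    stationary yes-probability.  Intervals are nearest-rank 2.5/97.5
    percentiles of the replicate values; for each target with both a "high"
    and a "low" scenario, the high-minus-low difference (in percentage
    points) gets its own percentile interval.  A resample whose fit fails is
    redrawn; more than 10% failures is an error.
    """
    if B < 2:
        raise ValueError("B must be at least 2")
    rng = np.random.default_rng(seed)
    if fit is None:
        design = build_design(analysis_table, spec)
        fit = fit_weighted_logit(design, spec)
    points = np.array([scenario_stationary_yes(fit, sc) for sc in scenarios])

    reps = np.empty((B, len(scenarios)))
    failures = 0
    max_failures = int(np.ceil(MAX_BOOTSTRAP_FAILURE_FRACTION * B))
    b = 0
    while b < B:
        table_b = _resample_units(analysis_table, rng)
        try:
            design_b = build_design(table_b, spec)
            fit_b = fit_weighted_logit(design_b, spec, beta_init=_warm_start(design_b, fit))
            reps[b] = [scenario_stationary_yes(fit_b, sc) for sc in scenarios]
        except Exception as exc:
            failures += 1
            logger.info("bootstrap resample failed (%s); redrawing", exc)
            if failures > max_failures:
                raise RuntimeError(
                    f"{failures} bootstrap resamples failed (> {max_failures} allowed); "
                    f"last error: {exc}"
                ) from exc
            continue
        b += 1
    if failures:
        logger.info("bootstrap: %d failed resamples redrawn", failures)

    results = []
    for j, sc in enumerate(scenarios):
        lo, hi = _nearest_rank_interval(reps[:, j])
        results.append(ScenarioResult(sc, float(points[j]), lo, hi, reps[:, j]))

    differences = []
    by_target: dict[str, dict[str, int]] = {}
    for j, sc in enumerate(scenarios):
        by_target.setdefault(sc.target_covariate, {})[sc.level] = j
    for target, levels in by_target.items():
        if "high" in levels and "low" in levels:
            d_point = 100.0 * (points[levels["high"]] - points[levels["low"]])
            d_reps = 100.0 * (reps[:, levels["high"]] - reps[:, levels["low"]])
            lo, hi = _nearest_rank_interval(d_reps)
            differences.append(ScenarioDifference(target, float(d_point), lo, hi))
    return results, differences


# ---------------------------------------------------------------------------
# Reporting helpers
# ---------------------------------------------------------------------------

def scenarios_frame(
    results: list[ScenarioResult], differences: list[ScenarioDifference]
) -> pd.DataFrame:
    """Flatten scenario results into the ``scenarios.csv`` layout."""
    rows = [
        {
            "scenario": r.scenario.name,
            "target": r.scenario.target_covariate,
            "level": r.scenario.level,
            "value": r.scenario.profile[r.scenario.target_covariate],
            "point": r.point,
            "lo95": r.lo95,
            "hi95": r.hi95,
        }
        for r in results
    ]
    df = pd.DataFrame(rows)
    diff_rows = [
        {
            "scenario": f"{d.target_covariate}:high-low",
            "target": d.target_covariate,
            "level": "high-low (ppd)",
            "value": np.nan,
            "point": d.diff_ppd,
            "lo95": d.lo95_ppd,
            "hi95": d.hi95_ppd,
        }
        for d in differences
    ]
    return pd.concat([df, pd.DataFrame(diff_rows)], ignore_index=True)


def plot_scenarios(results: list[ScenarioResult], path) -> None:
    """Bar chart of scenario stationary yes-probabilities with CI brackets."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = [r.scenario.name for r in results]
    points = [r.point for r in results]
    lower = [r.point - r.lo95 for r in results]
    upper = [r.hi95 - r.point for r in results]
    fig, ax = plt.subplots(figsize=(1.2 * len(results) + 2, 4))
    ax.bar(names, points, color="0.35")
    ax.errorbar(
        names, points, yerr=[lower, upper], fmt="none", ecolor="black", capsize=5
    )
    ax.set_ylabel('long-run Pr(answer "yes")')
    ax.set_ylim(0, 1)
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
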