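"""Synthetic toy country with a fully known vaccine-intent process.

Generates every input the analysis pipeline consumes — administrative
polygons, clustered households with a sampling-unit gazetteer, violence
events, misaligned electoral constituencies with vote shares, road
polylines — and a household panel whose responses are drawn from the
covariate-conditional two-state Markov process the pipeline is built to
estimate.  Because the generating coefficients, unit effects, round effects
and per-unit contextual values are all recorded in a :class:`SyntheticTruth`
manifest, parameter recovery and every downstream stage can be tested
without any external data.

Geometry is a planar Cartesian grid measured in km: the coordinate columns
are still called ``lon``/``lat`` so the files are schema-compatible with
real WGS84 inputs, but no projection machinery is involved.

The per-household generating model, with y=1 meaning the household says
"yes" to a free vaccine:

    Pr(y_it = 1) = logistic( x_i @ theta0 + y_{i,t-1} * (x_i @ gamma)
                             + alpha_k(i) + tau_t )

where x_i = [1, age, sex, urban, violence_count, competitiveness,
road_density] on the raw covariate scales, alpha_k is a per-unit intercept
(0 for the lexicographically first unit, the reference), and tau_t a
per-round intercept (0 in round 1).  Round-1 responses are drawn from the
household-specific stationary distribution so the chain starts at
equilibrium.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import LineString, box

from . import geo_harmonize as geo
from .geo_harmonize import (
    AdminUnit,
    Constituency,
    RoadSegment,
    competitiveness_from_shares,
    write_geojson,
)

#: fixed covariate order for x_i (after the implicit leading intercept)
COVARIATE_NAMES = (
    "age",
    "sex",
    "urban",
    "violence_count",
    "competitiveness",
    "road_density",
)

FIRST_SURVEY_DATE = "2021-06-01"
VIOLENCE_WINDOW_YEARS = 20


def logistic(z):
    return 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=float)))


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class WorldConfig:
    """Parameters of the synthetic world.

    Defaults describe the reference study conditions used throughout the
    test suite: a 5x5 grid of 10 km units, 2,000 households followed over 5
    survey rounds, moderate unit heterogeneity, and generating coefficients
    under which a median household transitions roughly like the headline
    two-state matrix (about 0.35 no->yes, 0.96 yes->yes) while violence
    depresses acceptance in both lag states.

    ``theta0`` and ``gamma`` each have length ``1 + len(covariate_names)``
    (leading intercept).  ``round_effects`` has length ``n_rounds`` with the
    first entry 0 (reference round); the reference unit's effect is 0 by
    construction.
    """

    n_units: int = 25
    grid_shape: tuple[int, int] = (5, 5)
    unit_size_km: float = 10.0
    n_households: int = 2000
    n_rounds: int = 5
    theta0: tuple[float, ...] = (-0.33, -0.010, 0.10, 0.20, -0.006, 0.80, 1.20)
    gamma: tuple[float, ...] = (4.11, -0.004, 0.00, 0.10, -0.006, 0.40, 0.60)
    unit_effect_sd: float = 0.3
    # round 1 never enters estimation (no lag) and round 2 is the estimation
    # reference, so both are 0 by default: the remaining entries are then
    # directly comparable to fitted round effects.
    round_effects: tuple[float, ...] = (0.0, 0.0, -0.10, 0.05, -0.05)
    event_intensity_range: tuple[float, float] = (0.0, 150.0)
    n_constituencies: int = 9
    attrition_rate: float = 0.05
    seed: int = 0
    covariate_names: tuple[str, ...] = COVARIATE_NAMES
    villages_per_unit: int = 3
    n_roads: int = 40
    urban_share: float = 0.35
    weight_sigma: float = 0.5  # lognormal sd of raw survey weights
    init_stationary: bool = True  # else round 1 ~ Bernoulli(0.5)

    def __post_init__(self) -> None:
        rows, cols = self.grid_shape
        if rows * cols != self.n_units:
            raise ValueError(
                f"grid_shape {self.grid_shape} inconsistent with n_units {self.n_units}"
            )
        if len(self.theta0) != len(self.gamma):
            raise ValueError("theta0 and gamma must have equal length")
        if len(self.theta0) != 1 + len(self.covariate_names):
            raise ValueError(
                "coefficient vectors must have length 1 + len(covariate_names)"
            )
        if len(self.round_effects) != self.n_rounds:
            raise ValueError("round_effects must have length n_rounds")
        if not 0.0 <= self.attrition_rate < 1.0:
            raise ValueError("attrition_rate must lie in [0, 1)")
        lo, hi = self.event_intensity_range
        if lo < 0 or hi < lo:
            raise ValueError("event_intensity_range must satisfy 0 <= low <= high")

    @property
    def domain_width_km(self) -> float:
        return self.grid_shape[1] * self.unit_size_km

    @property
    def domain_height_km(self) -> float:
        return self.grid_shape[0] * self.unit_size_km


@dataclass
class SyntheticTruth:
    """Everything the generator knows that an analyst would have to estimate."""

    covariate_names: list[str]
    theta0: list[float]
    gamma: list[float]
    unit_effects: dict[str, float]
    round_effects: dict[str, float]  # keyed by round number as str
    unit_context: dict[str, dict[str, float]]  # unit_id -> contextual values
    household_units: dict[str, str]  # household_id -> unit_id
    road_km_per_unit: dict[str, float]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class World:
    """Bundle of all generated artifacts plus the truth manifest."""

    config: WorldConfig
    units: list[AdminUnit]
    households: pd.DataFrame
    gazetteer: pd.DataFrame
    events: pd.DataFrame
    constituencies: list[Constituency]
    votes: pd.DataFrame
    roads: list[RoadSegment]
    panel: pd.DataFrame
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# Geography
# ---------------------------------------------------------------------------

def make_geography(config: WorldConfig) -> list[AdminUnit]:
    """Tile the rectangular domain with a rows x cols grid of square units.

    Unit ids are ``U001``..``Unnn`` in row-major order; each polygon carries
    its exact area in km².
    """
    rows, cols = config.grid_shape
    s = config.unit_size_km
    units = []
    k = 0
    for r in range(rows):
        for c in range(cols):
            k += 1
            poly = box(c * s, r * s, (c + 1) * s, (r + 1) * s)
            units.append(AdminUnit(f"U{k:03d}", poly, area_km2=s * s, level=2))
    return units


# ---------------------------------------------------------------------------
# Households and gazetteer
# ---------------------------------------------------------------------------

def make_households(
    config: WorldConfig, units: list[AdminUnit], rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str]]:
    """Create households clustered in named sampling units (villages).

    Each unit hosts ``villages_per_unit`` villages at uniform interior
    points; households pick a village uniformly.  Covariates: age ~ discrete
    uniform 18..90 (survey respondents are heads of household), sex ~
    Bernoulli(0.5), urban ~ Bernoulli(urban_share); survey weights are i.i.d.
    lognormal, normalized to mean exactly 1.

    Returns (households, gazetteer, village->unit map).
    """
    village_names: list[str] = []
    village_lon: list[float] = []
    village_lat: list[float] = []
    village_unit: dict[str, str] = {}
    for unit in units:
        minx, miny, maxx, maxy = unit.geometry.bounds
        for j in range(config.villages_per_unit):
            name = f"village {unit.unit_id.lower()} {j + 1}"
            # uniform interior point: margin keeps points off shared edges
            fx, fy = rng.uniform(0.05, 0.95, size=2)
            village_names.append(name)
            village_lon.append(minx + fx * (maxx - minx))
            village_lat.append(miny + fy * (maxy - miny))
            village_unit[name] = unit.unit_id
    gazetteer = pd.DataFrame(
        {
            "sampling_unit_name": village_names,
            "lon": village_lon,
            "lat": village_lat,
        }
    )

    n = config.n_households
    if n == 0:
        cols = ["household_id", "sampling_unit_name", "age", "sex", "urban", "weight"]
        return pd.DataFrame(columns=cols), gazetteer, village_unit
    village_idx = rng.integers(0, len(village_names), size=n)
    age = rng.integers(18, 91, size=n)
    sex = rng.integers(0, 2, size=n)
    urban = (rng.random(n) < config.urban_share).astype(int)
    weight = rng.lognormal(mean=0.0, sigma=config.weight_sigma, size=n)
    weight = weight / weight.mean()
    households = pd.DataFrame(
        {
            "household_id": [f"H{i + 1:05d}" for i in range(n)],
            "sampling_unit_name": [village_names[i] for i in village_idx],
            "age": age,
            "sex": sex,
            "urban": urban,
            "weight": weight,
        }
    )
    return households, gazetteer, village_unit


# ---------------------------------------------------------------------------
# Contextual sources
# ---------------------------------------------------------------------------

def simulate_events(
    config: WorldConfig, units: list[AdminUnit], rng: np.random.Generator
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Draw violence events with unit-specific Poisson intensity.

    Each unit gets an intensity uniform in ``event_intensity_range`` (events
    per unit over the whole 20-year pre-survey window); the count is Poisson,
    coordinates uniform in the unit, dates uniform in the window.

    Returns (events table, unit -> intensity map).
    """
    lo, hi = config.event_intensity_range
    start = pd.Timestamp(FIRST_SURVEY_DATE) - pd.DateOffset(years=VIOLENCE_WINDOW_YEARS)
    end = pd.Timestamp(FIRST_SURVEY_DATE)
    span_days = (end - start).days
    lons: list[float] = []
    lats: list[float] = []
    dates: list[str] = []
    intensities: dict[str, float] = {}
    for unit in units:
        lam = rng.uniform(lo, hi)
        intensities[unit.unit_id] = float(lam)
        count = int(rng.poisson(lam))
        minx, miny, maxx, maxy = unit.geometry.bounds
        if count:
            fx = rng.uniform(0.001, 0.999, size=count)
            fy = rng.uniform(0.001, 0.999, size=count)
            offs = rng.integers(0, span_days, size=count)
            lons.extend(minx + fx * (maxx - minx))
            lats.extend(miny + fy * (maxy - miny))
            dates.extend((start + pd.Timedelta(days=int(d))).date().isoformat() for d in offs)
    events = pd.DataFrame({"lon": lons, "lat": lats, "date": dates})
    return events, intensities


def _near_square_grid(n: int) -> tuple[int, int]:
    """Factor n into the (rows, cols) divisor pair closest to square."""
    best = (1, n)
    for r in range(1, int(np.sqrt(n)) + 1):
        if n % r == 0:
            best = (r, n // r)
    return best


def simulate_elections(
    config: WorldConfig, rng: np.random.Generator
) -> tuple[list[Constituency], pd.DataFrame]:
    """Partition the domain into constituencies misaligned with unit borders.

    Constituencies form a near-square grid whose interior break lines are
    shifted by 0.37 of a unit, so their borders never coincide with unit
    borders.  Each constituency holds a two-candidate race with a drawn
    competitiveness c in (0.05, 0.95): winner share (2 - c)/2, runner-up c/2.
    """
    rows, cols = _near_square_grid(config.n_constituencies)
    W, H = config.domain_width_km, config.domain_height_km
    shift = 0.37 * config.unit_size_km

    def breaks(n_cells: int, total: float) -> np.ndarray:
        b = np.linspace(0.0, total, n_cells + 1)
        b[1:-1] = np.clip(b[1:-1] + shift, 1e-9, total - 1e-9)
        return b

    xb, yb = breaks(cols, W), breaks(rows, H)
    constituencies: list[Constituency] = []
    vote_rows = []
    k = 0
    for r in range(rows):
        for c in range(cols):
            k += 1
            cid = f"C{k:03d}"
            geom = box(xb[c], yb[r], xb[c + 1], yb[r + 1])
            comp = float(rng.uniform(0.05, 0.95))
            winner = (2.0 - comp) / 2.0
            runner = comp / 2.0
            assert abs(competitiveness_from_shares(winner, runner) - comp) < 1e-12
            constituencies.append(Constituency(cid, geom, comp))
            vote_rows.append({"constituency_id": cid, "candidate_rank": 1, "vote_share": winner})
            vote_rows.append({"constituency_id": cid, "candidate_rank": 2, "vote_share": runner})
    return constituencies, pd.DataFrame(vote_rows)


def simulate_roads(
    config: WorldConfig, rng: np.random.Generator
) -> list[RoadSegment]:
    """Random multi-unit polylines with class labels.

    Each road is a 2-4 vertex polyline between random points of the domain,
    so most roads span several units; classes are drawn with probabilities
    0.4 / 0.3 / 0.3 for primary / secondary / other.
    """
    W, H = config.domain_width_km, config.domain_height_km
    roads: list[RoadSegment] = []
    classes = np.array(geo.ROAD_CLASSES)
    for _ in range(config.n_roads):
        n_pts = int(rng.integers(2, 5))
        xs = rng.uniform(0, W, size=n_pts)
        ys = rng.uniform(0, H, size=n_pts)
        geom = LineString(np.column_stack([xs, ys]))
        if geom.length <= 0:
            continue
        road_class = str(rng.choice(classes, p=[0.4, 0.3, 0.3]))
        roads.append(RoadSegment(geom, road_class))
    return roads


# ---------------------------------------------------------------------------
# Panel simulation
# ---------------------------------------------------------------------------

def _covariate_matrix(
    households: pd.DataFrame,
    household_units: dict[str, str],
    unit_context: dict[str, dict[str, float]],
    covariate_names: tuple[str, ...],
) -> np.ndarray:
    """Stack [1, covariates...] per household on raw scales."""
    n = len(households)
    X = np.ones((n, 1 + len(covariate_names)))
    ctx_cols = {name for ctx in unit_context.values() for name in ctx}
    for j, name in enumerate(covariate_names, start=1):
        if name in households.columns:
            X[:, j] = households[name].to_numpy(dtype=float)
        elif name in ctx_cols:
            units_of = households["household_id"].map(household_units)
            X[:, j] = [unit_context[u][name] for u in units_of]
        else:
            raise ValueError(f"covariate {name!r} found in neither households nor context")
    return X


def simulate_panel(
    config: WorldConfig,
    households: pd.DataFrame,
    household_units: dict[str, str],
    unit_context: dict[str, dict[str, float]],
    unit_effects: dict[str, float],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw panel responses from the two-state transition process.

    Round 1 is drawn from each household's stationary distribution at its
    covariate profile (with the round-1 effect), later rounds from
    logistic(x@theta0 + y_prev * x@gamma + alpha_k + tau_t).
    """
    n = len(households)
    if n == 0:
        return pd.DataFrame(columns=["household_id", "round", "response"])
    theta0 = np.asarray(config.theta0, dtype=float)
    gamma = np.asarray(config.gamma, dtype=float)
    X = _covariate_matrix(households, household_units, unit_context, config.covariate_names)
    alpha = households["household_id"].map(
        lambda h: unit_effects[household_units[h]]
    ).to_numpy(dtype=float)

    lp0_base = X @ theta0 + alpha
    lp_gamma = X @ gamma

    tau1 = config.round_effects[0]
    p01 = logistic(lp0_base + tau1)
    p11 = logistic(lp0_base + lp_gamma + tau1)
    p10 = 1.0 - p11
    if config.init_stationary:
        pi_yes = np.where(p01 + p10 > 0, p01 / (p01 + p10), 0.5)
    else:
        pi_yes = np.full(n, 0.5)

    responses = np.empty((n, config.n_rounds), dtype=int)
    responses[:, 0] = rng.random(n) < pi_yes
    for t in range(1, config.n_rounds):
        tau_t = config.round_effects[t]
        lp = lp0_base + responses[:, t - 1] * lp_gamma + tau_t
        responses[:, t] = rng.random(n) < logistic(lp)

    hh = households["household_id"].to_numpy()
    panel = pd.DataFrame(
        {
            "household_id": np.repeat(hh, config.n_rounds),
            "round": np.tile(np.arange(1, config.n_rounds + 1), n),
            "response": responses.reshape(-1),
        }
    )
    return panel


def apply_attrition(
    panel: pd.DataFrame, rate: float, seed: int | np.random.Generator
) -> pd.DataFrame:
    """Drop households permanently with per-round probability ``rate``.

    After each round every remaining household independently leaves the
    panel with probability ``rate`` (missing completely at random); all its
    later rows are removed.  Presence is therefore monotone: a household
    observed in round t is observed in all earlier rounds.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("attrition rate must lie in [0, 1)")
    if rate == 0.0 or len(panel) == 0:
        return panel.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rounds = np.sort(panel["round"].unique())
    hh = panel["household_id"].unique()
    # last round retained: 1 + number of consecutive survivals
    survive = rng.random((len(hh), len(rounds) - 1)) >= rate
    drops = np.argmin(survive, axis=1) + 1  # first failed survival
    drops[survive.all(axis=1)] = len(rounds)
    last_round = {h: rounds[d - 1] for h, d in zip(hh, drops)}
    keep = panel["round"] <= panel["household_id"].map(last_round)
    return panel.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Whole-world generation and serialization
# ---------------------------------------------------------------------------

def _draw_identified_unit_effects(
    unit_ids: list[str],
    ctx_matrix: np.ndarray,
    sd: float,
    rng: np.random.Generator,
) -> dict[str, float]:
    """Draw unit effects orthogonal to unit-level covariates, reference at 0.

    Draws N(0, sd) effects, pins the first (reference) unit to 0, then
    residualizes the rest against [1, covariates - reference covariates] and
    rescales the residuals back to standard deviation ``sd``.  This is the
    combination of unit heterogeneity the fixed-effects model can actually
    attribute to the units rather than to the unit-level covariates.
    """
    K = len(unit_ids)
    draws = rng.normal(0.0, sd, size=K)
    if sd == 0.0 or K < 2:
        return {uid: 0.0 for uid in unit_ids}
    alpha = draws - draws[0]
    C = np.column_stack([np.ones(K - 1), ctx_matrix[1:] - ctx_matrix[0]])
    coef, *_ = np.linalg.lstsq(C, alpha[1:], rcond=None)
    resid = alpha[1:] - C @ coef
    s = resid.std()
    if s > 0:
        resid = resid * (sd / s)
    return {unit_ids[0]: 0.0, **{u: float(a) for u, a in zip(unit_ids[1:], resid)}}

def generate_world(config: WorldConfig) -> World:
    """Generate geography, sources, context truth and panel in a fixed order.

    The per-unit contextual values used to drive the panel process are the
    *realized* harmonized values (actual event counts in the 20-year window,
    area-weighted competitiveness, clipped primary+secondary road density),
    so re-harmonizing the written files reproduces the generating covariates
    exactly.
    """
    rng = np.random.default_rng(config.seed)
    units = make_geography(config)
    households, gazetteer, village_unit = make_households(config, units, rng)
    events, _intensities = simulate_events(config, units, rng)
    constituencies, votes = simulate_elections(config, rng)
    roads = simulate_roads(config, rng)

    window = (
        (pd.Timestamp(FIRST_SURVEY_DATE) - pd.DateOffset(years=VIOLENCE_WINDOW_YEARS)).date().isoformat(),
        FIRST_SURVEY_DATE,
    )
    violence = geo.aggregate_event_counts(events, units, window)
    competitiveness, missing = geo.interpolate_competitiveness(constituencies, units)
    if missing:
        raise RuntimeError(f"synthetic constituencies failed to cover units {missing}")
    density = geo.road_density(roads, units)
    road_km = geo.road_length_per_unit(roads, units)

    unit_context = {
        u.unit_id: {
            "violence_count": float(violence.loc[u.unit_id]),
            "competitiveness": float(competitiveness.loc[u.unit_id]),
            "road_density": float(density.loc[u.unit_id]),
        }
        for u in units
    }

    # Unit effects are drawn in the model's identified parameterization:
    # the reference (first) unit is pinned to 0, and the remaining effects are
    # residualized against the unit-level covariates.  With unit fixed effects
    # in the model, unit-level covariate main effects are collinear with the
    # effect vector, so only this normalized combination is estimable; drawing
    # alpha outside it would make "true coefficients" undefined as estimands.
    unit_ids = sorted(u.unit_id for u in units)
    ctx_names = sorted(unit_context[unit_ids[0]])
    unit_effects = _draw_identified_unit_effects(
        unit_ids,
        np.array([[unit_context[u][c] for c in ctx_names] for u in unit_ids]),
        config.unit_effect_sd,
        rng,
    )

    household_units = {
        h: village_unit[v]
        for h, v in zip(households["household_id"], households["sampling_unit_name"])
    }
    panel = simulate_panel(config, households, household_units, unit_context, unit_effects, rng)
    panel = apply_attrition(panel, config.attrition_rate, rng)

    truth = SyntheticTruth(
        covariate_names=list(config.covariate_names),
        theta0=list(config.theta0),
        gamma=list(config.gamma),
        unit_effects=unit_effects,
        round_effects={str(t + 1): float(v) for t, v in enumerate(config.round_effects)},
        unit_context=unit_context,
        household_units=household_units,
        road_km_per_unit={k: float(v) for k, v in road_km.items()},
    )
    return World(
        config=config,
        units=units,
        households=households,
        gazetteer=gazetteer,
        events=events,
        constituencies=constituencies,
        votes=votes,
        roads=roads,
        panel=panel,
        truth=truth,
    )


def write_world(world: World, out_dir) -> dict[str, Path]:
    """Write every artifact to its canonical file; returns name -> path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["units"] = out / "units.geojson"
    write_geojson(
        (
            (u.geometry, {"unit_id": u.unit_id, "area_km2": u.area_km2, "level": u.level})
            for u in world.units
        ),
        paths["units"],
    )
    paths["constituencies"] = out / "constituencies.geojson"
    write_geojson(
        ((c.geometry, {"constituency_id": c.constituency_id}) for c in world.constituencies),
        paths["constituencies"],
    )
    paths["roads"] = out / "roads.geojson"
    write_geojson(
        ((r.geometry, {"road_class": r.road_class}) for r in world.roads),
        paths["roads"],
    )
    for name, df in [
        ("households", world.households),
        ("gazetteer", world.gazetteer),
        ("panel", world.panel),
        ("events", world.events),
        ("votes", world.votes),
    ]:
        paths[name] = out / f"{name}.csv"
        df.to_csv(paths[name], index=False)
    paths["truth"] = out / "truth.json"
    world.truth.to_json(paths["truth"])
    return paths


def analysis_table_from_truth(world: World) -> pd.DataFrame:
    """Estimation table built directly from the truth manifest.

    Bypasses file round-trips and spatial matching (household-unit links and
    unit context come straight from :class:`SyntheticTruth`); used for fast
    parameter-recovery studies.  Equivalent to harmonizing the written files.
    """
    context = pd.DataFrame(
        [{"unit_id": uid, **ctx} for uid, ctx in world.truth.unit_context.items()]
    )
    return geo.build_integrated_table(
        world.panel,
        world.households.drop(columns=["sampling_unit_name"]),
        world.truth.household_units,
        context,
    )
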