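"""Spatial harmonization of contextual data onto administrative units.

Survey households, violence events, election returns and road networks all
live on different geographic supports: named sampling locations, point
coordinates, constituency polygons and polylines.  This module transforms
each of them onto a single set of administrative-unit polygons so that
contextual covariates can be merged with household panel responses:

* :func:`geocode_sampling_units` — resolve sampling-unit names to coordinates
  through a gazetteer;
* :func:`assign_households_to_units` — point-in-polygon matching of household
  locations to units;
* :func:`aggregate_event_counts` — per-unit counts of point events inside a
  date window;
* :func:`interpolate_competitiveness` — area-weighted transfer of electoral
  competitiveness from constituency polygons to units;
* :func:`road_density` — clipped primary/secondary road length per unit area;
* :func:`build_integrated_table` — the long-format estimation table joining
  panel responses, their first-order lags, household covariates and unit
  covariates.

All coordinates are treated as planar.  Real longitude/latitude inputs are
handled planarly as well, which is a documented approximation adequate for
small administrative units away from the poles.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Polygon, mapping, shape

logger = logging.getLogger("vaxdyn")

ROAD_CLASSES = ("primary", "secondary", "other")
#: road classes that count toward road density
DENSITY_CLASSES = ("primary", "secondary")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AdminUnit:
    """An administrative polygon, the spatial support of the analysis.

    Parameters
    ----------
    unit_id : str
        Stable identifier; ties in spatial assignment break toward the
        lexicographically smallest id.
    geometry : shapely.Polygon
        Valid simple polygon in planar coordinates (km in synthetic mode).
    area_km2 : float
        Area in square kilometres, must be positive.
    level : int
        Administrative level (1 or 2); informational.
    """

    unit_id: str
    geometry: Polygon
    area_km2: float
    level: int = 2

    def __post_init__(self) -> None:
        if self.area_km2 <= 0:
            raise ValueError(f"unit {self.unit_id}: area_km2 must be positive")
        if not self.geometry.is_valid or self.geometry.is_empty:
            raise ValueError(f"unit {self.unit_id}: invalid polygon geometry")


@dataclass(frozen=True)
class Constituency:
    """Electoral constituency polygon with its Top-1 competitiveness.

    Competitiveness is one minus the winning vote margin (winner share minus
    runner-up share), clamped to [0, 1]: 1 means a razor-thin election, 0 an
    uncontested one.
    """

    constituency_id: str
    geometry: Polygon
    competitiveness: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.competitiveness <= 1.0:
            raise ValueError("competitiveness must lie in [0, 1]")


@dataclass(frozen=True)
class RoadSegment:
    """A polyline with a road class label."""

    geometry: LineString
    road_class: str

    def __post_init__(self) -> None:
        if self.road_class not in ROAD_CLASSES:
            raise ValueError(f"unknown road class {self.road_class!r}")
        if self.geometry.length <= 0:
            raise ValueError("road segment must have positive length")


def competitiveness_from_shares(winner_share: float, runner_up_share: float = 0.0) -> float:
    """Top-1 competitiveness: ``1 - (winner - runner-up)``, clamped to [0, 1].

    A 0.95/0.05 split gives 0.10; an exact tie gives 1; a single candidate
    with share 1.0 gives 0.
    """
    if winner_share < runner_up_share:
        raise ValueError("winner share must be >= runner-up share")
    return float(min(1.0, max(0.0, 1.0 - (winner_share - runner_up_share))))


# ---------------------------------------------------------------------------
# GeoJSON / CSV readers
# ---------------------------------------------------------------------------

def read_units(path) -> list[AdminUnit]:
    """Read administrative units from a GeoJSON FeatureCollection.

    Each feature must carry ``unit_id`` and ``area_km2`` properties
    (``level`` optional, default 2).
    """
    with open(path) as fh:
        gj = json.load(fh)
    units = []
    for feat in gj["features"]:
        props = feat["properties"]
        units.append(
            AdminUnit(
                unit_id=str(props["unit_id"]),
                geometry=shape(feat["geometry"]),
                area_km2=float(props["area_km2"]),
                level=int(props.get("level", 2)),
            )
        )
    return sorted(units, key=lambda u: u.unit_id)


def read_constituencies(geojson_path, votes_csv_path) -> list[Constituency]:
    """Read constituency polygons and derive competitiveness from vote shares.

    ``votes.csv`` holds one row per candidate: ``constituency_id,
    candidate_rank, vote_share``.  Competitiveness is computed from the two
    top-ranked candidates; a constituency with a single candidate has
    runner-up share 0.
    """
    with open(geojson_path) as fh:
        gj = json.load(fh)
    votes = pd.read_csv(votes_csv_path)
    comp: dict[str, float] = {}
    for cid, grp in votes.groupby("constituency_id"):
        grp = grp.sort_values("candidate_rank")
        shares = grp["vote_share"].to_numpy(dtype=float)
        runner = shares[1] if len(shares) > 1 else 0.0
        comp[str(cid)] = competitiveness_from_shares(shares[0], runner)
    out = []
    for feat in gj["features"]:
        cid = str(feat["properties"]["constituency_id"])
        if cid not in comp:
            raise ValueError(f"no vote shares for constituency {cid}")
        out.append(Constituency(cid, shape(feat["geometry"]), comp[cid]))
    return sorted(out, key=lambda c: c.constituency_id)


def read_roads(path) -> list[RoadSegment]:
    """Read road polylines from a GeoJSON FeatureCollection."""
    with open(path) as fh:
        gj = json.load(fh)
    return [
        RoadSegment(shape(f["geometry"]), str(f["properties"]["road_class"]))
        for f in gj["features"]
    ]


def read_events(path) -> pd.DataFrame:
    """Read a point event table (``lon, lat, date``) from CSV."""
    return pd.read_csv(path)


def write_geojson(features: Iterable[tuple[object, dict]], path) -> None:
    """Write (geometry, properties) pairs as a GeoJSON FeatureCollection."""
    fc = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "geometry": mapping(geom), "properties": props}
            for geom, props in features
        ],
    }
    with open(path, "w") as fh:
        json.dump(fc, fh, indent=1)


# ---------------------------------------------------------------------------
# Geocoding and point-in-polygon assignment
# ---------------------------------------------------------------------------

def _normalize_name(name: str) -> str:
    return " ".join(str(name).split()).casefold()


def geocode_sampling_units(
    names: Sequence[str], gazetteer: pd.DataFrame
) -> tuple[dict[str, tuple[float, float]], list[str]]:
    """Resolve sampling-unit names to coordinates via exact normalized match.

    Matching is case-insensitive and whitespace-normalized (leading/trailing
    stripped, internal runs collapsed).  Names absent from the gazetteer are
    returned in the rejection list, never silently dropped.

    Parameters
    ----------
    names : sequence of str
        Sampling-unit names to geocode (e.g. from the household table).
    gazetteer : DataFrame
        Columns ``sampling_unit_name, lon, lat`` with unique names.

    Returns
    -------
    (mapping, rejected)
        ``mapping`` maps each matched input name (verbatim) to ``(lon, lat)``;
        ``rejected`` lists the unmatched input names.

    Raises
    ------
    ValueError
        If the gazetteer contains duplicate (normalized) names.
    """
    keys = gazetteer["sampling_unit_name"].map(_normalize_name)
    if keys.duplicated().any():
        dups = sorted(keys[keys.duplicated()].unique())
        raise ValueError(f"duplicate gazetteer names after normalization: {dups}")
    lookup = {
        k: (float(lon), float(lat))
        for k, lon, lat in zip(keys, gazetteer["lon"], gazetteer["lat"])
    }
    matched: dict[str, tuple[float, float]] = {}
    rejected: list[str] = []
    for name in names:
        coords = lookup.get(_normalize_name(name))
        if coords is None:
            rejected.append(name)
        else:
            matched[name] = coords
    if rejected:
        logger.info("geocode: %d of %d names unmatched", len(rejected), len(names))
    return matched, rejected


def assign_points_to_units(
    lons: np.ndarray, lats: np.ndarray, units: Sequence[AdminUnit]
) -> list[str | None]:
    """Assign each point to the unit polygon covering it.

    Boundary points (covered by several units) go to the lexicographically
    smallest ``unit_id``; points outside every unit map to ``None``.
    """
    pts = shapely.points(np.asarray(lons, dtype=float), np.asarray(lats, dtype=float))
    assigned: list[str | None] = [None] * len(pts)
    # iterate units in id order so the first hit is the tie-break winner
    for unit in sorted(units, key=lambda u: u.unit_id):
        mask = shapely.covers(unit.geometry, pts)
        for i in np.flatnonzero(mask):
            if assigned[i] is None:
                assigned[i] = unit.unit_id
    return assigned


def assign_households_to_units(
    points: Mapping[str, tuple[float, float]], units: Sequence[AdminUnit]
) -> tuple[dict[str, str], list[str]]:
    """Match household/sampling-unit coordinates to administrative units.

    Parameters
    ----------
    points : mapping
        Keys are household or sampling-unit identifiers, values ``(lon, lat)``.
    units : sequence of AdminUnit

    Returns
    -------
    (mapping, rejected)
        ``mapping`` from identifier to ``unit_id``; identifiers whose point
        falls outside every unit are listed in ``rejected``.
    """
    ids = list(points)
    if not ids:
        return {}, []
    lons = np.array([points[i][0] for i in ids])
    lats = np.array([points[i][1] for i in ids])
    hits = assign_points_to_units(lons, lats, units)
    mapping_out = {i: u for i, u in zip(ids, hits) if u is not None}
    rejected = [i for i, u in zip(ids, hits) if u is None]
    if rejected:
        logger.info("assignment: %d points outside all units", len(rejected))
    return mapping_out, rejected


# ---------------------------------------------------------------------------
# Event aggregation
# ---------------------------------------------------------------------------

def aggregate_event_counts(
    events: pd.DataFrame,
    units: Sequence[AdminUnit],
    window: tuple[str, str],
) -> pd.Series:
    """Count point events per unit inside a half-open date window.

    An event is counted for unit *k* when its date lies in
    ``[window[0], window[1])`` and its point falls inside (or on the boundary
    of) the unit's polygon, with the same smallest-id tie-break as household
    assignment.  Units with no events get 0.

    Raises
    ------
    ValueError
        If the window is empty/inverted or any date fails to parse (the error
        lists the offending row indices).
    """
    start, end = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    if not start < end:
        raise ValueError(f"window start {start} must precede end {end}")
    index = pd.Index(sorted(u.unit_id for u in units), name="unit_id")
    counts = pd.Series(0, index=index, dtype=int, name="violence_count")
    if len(events) == 0:
        return counts
    dates = pd.to_datetime(events["date"], errors="coerce", format="mixed")
    bad = events.index[dates.isna()].tolist()
    if bad:
        raise ValueError(f"unparseable event dates at rows {bad}")
    in_window = (dates >= start) & (dates < end)
    sub = events.loc[in_window]
    if len(sub):
        hits = assign_points_to_units(
            sub["lon"].to_numpy(), sub["lat"].to_numpy(), units
        )
        for u in hits:
            if u is not None:
                counts.loc[u] += 1
    return counts


# ---------------------------------------------------------------------------
# Areal interpolation of competitiveness
# ---------------------------------------------------------------------------

def interpolate_competitiveness(
    constituencies: Sequence[Constituency],
    units: Sequence[AdminUnit],
) -> tuple[pd.Series, list[str]]:
    """Area-weighted average of constituency competitiveness per unit.

    For unit *k*, the value is sum_c w_kc * comp_c / sum_c w_kc with
    w_kc the area of the intersection of unit *k* and constituency *c*
    (the standard areal-interpolation rule for an intensive variable).
    Units overlapping no constituency get NaN and are reported.

    Returns
    -------
    (values, missing)
        ``values`` is a Series indexed by unit_id; ``missing`` lists unit ids
        with zero total overlap.
    """
    index = pd.Index(sorted(u.unit_id for u in units), name="unit_id")
    values = pd.Series(np.nan, index=index, name="competitiveness")
    missing: list[str] = []
    for unit in units:
        num = 0.0
        den = 0.0
        for c in constituencies:
            w = unit.geometry.intersection(c.geometry).area
            num += w * c.competitiveness
            den += w
        if den <= 0.0:
            missing.append(unit.unit_id)
        else:
            values.loc[unit.unit_id] = num / den
    if missing:
        logger.warning("competitiveness missing (zero overlap) for units %s", missing)
    return values, missing


# ---------------------------------------------------------------------------
# Road density
# ---------------------------------------------------------------------------

def road_length_per_unit(
    roads: Sequence[RoadSegment],
    units: Sequence[AdminUnit],
    classes: Sequence[str] = DENSITY_CLASSES,
) -> pd.Series:
    """Total clipped length (km) of the given road classes inside each unit."""
    index = pd.Index(sorted(u.unit_id for u in units), name="unit_id")
    lengths = pd.Series(0.0, index=index, name="road_km")
    for seg in roads:
        if seg.road_class not in classes:
            continue
        for unit in units:
            clipped = seg.geometry.intersection(unit.geometry)
            if not clipped.is_empty:
                lengths.loc[unit.unit_id] += clipped.length
    return lengths


def road_density(
    roads: Sequence[RoadSegment], units: Sequence[AdminUnit]
) -> pd.Series:
    """Primary + secondary road length per unit divided by unit area (km/km²).

    Segments of class ``other`` are excluded; a unit crossed by no counted
    road has density 0.
    """
    lengths = road_length_per_unit(roads, units)
    areas = pd.Series(
        {u.unit_id: u.area_km2 for u in units}, name="area_km2"
    ).reindex(lengths.index)
    out = lengths / areas
    out.name = "road_density"
    return out


# ---------------------------------------------------------------------------
# Context table and integrated analysis table
# ---------------------------------------------------------------------------

def build_context_table(
    units: Sequence[AdminUnit],
    violence_count: pd.Series,
    competitiveness: pd.Series,
    road_density_: pd.Series,
    extra: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble the per-unit contextual covariate table.

    One row per unit; raises if any harmonized value is missing (a unit with
    zero constituency overlap must be fixed upstream, not silently imputed).
    """
    index = pd.Index(sorted(u.unit_id for u in units), name="unit_id")
    ctx = pd.DataFrame(index=index)
    ctx["violence_count"] = violence_count.reindex(index)
    ctx["competitiveness"] = competitiveness.reindex(index)
    ctx["road_density"] = road_density_.reindex(index)
    if extra is not None:
        for col in extra.columns:
            ctx[col] = extra[col].reindex(index)
    if ctx.isna().any().any():
        bad = ctx.columns[ctx.isna().any()].tolist()
        raise ValueError(f"context table has missing values in columns {bad}")
    return ctx.reset_index()


def build_integrated_table(
    panel: pd.DataFrame,
    households: pd.DataFrame,
    household_units: Mapping[str, str],
    context: pd.DataFrame,
) -> pd.DataFrame:
    """Join panel responses, lags, household covariates and unit covariates.

    Produces the long-format estimation table: one row per household-round
    with an immediately preceding observed round, carrying ``response``,
    ``response_lag``, household covariates, the household's unit id, that
    unit's contextual covariates, and the survey weight.  Rows for
    households with no unit assignment, and rounds without a consecutive
    predecessor, are excluded; exclusion counts are logged and stored in
    ``result.attrs['exclusions']``.

    Parameters
    ----------
    panel : DataFrame
        Columns ``household_id, round, response``.
    households : DataFrame
        Columns ``household_id, age, sex, urban, weight`` (extra columns pass
        through).
    household_units : mapping
        household_id -> unit_id (households absent here are excluded).
    context : DataFrame
        Per-unit contextual covariates with a ``unit_id`` column.
    """
    panel = panel.sort_values(["household_id", "round"]).copy()
    n_rows = len(panel)

    unit_series = panel["household_id"].map(dict(household_units))
    no_unit = int(unit_series.isna().sum())
    panel = panel.loc[unit_series.notna()].copy()
    panel["unit_id"] = unit_series.loc[panel.index]

    grp = panel.groupby("household_id", sort=False)
    prev_round = grp["round"].shift(1)
    prev_resp = grp["response"].shift(1)
    consecutive = prev_round == panel["round"] - 1
    no_lag = int((~consecutive).sum())
    est = panel.loc[consecutive].copy()
    est["response_lag"] = prev_resp.loc[est.index].astype(int)

    est = est.merge(households, on="household_id", how="left", validate="m:1")
    est = est.merge(context, on="unit_id", how="left", validate="m:1")
    value_cols = [c for c in est.columns if c not in ("household_id", "unit_id")]
    missing = est[value_cols].isna().any(axis=1)
    n_missing = int(missing.sum())
    est = est.loc[~missing].reset_index(drop=True)

    est.attrs["exclusions"] = {
        "input_rows": n_rows,
        "no_unit_assignment": no_unit,
        "no_consecutive_lag": no_lag,
        "missing_covariates": n_missing,
        "estimation_rows": len(est),
    }
    logger.info("integrated table exclusions: %s", est.attrs["exclusions"])
    return est
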