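"""Synthetic studies with known parameters, end to end.

Generates everything the pipeline consumes — feeder layouts, ringing
sites, tag registries, canopy-height and vegetation-index rasters, road
networks, and a 12-month detection stream — from a hurdle generative
model that mirrors the fitted statistical model: per species × pair ×
season, presence is Bernoulli on the logit scale with multi-membership
feeder effects, and, given presence, a random subset of tagged birds
receives zero-truncated Poisson counts with feeder and tag effects.

Defaults emulate the field design: three ~0.5 km² networks along a
greenspace-fragmentation gradient, 17 feeders each at ~81 m mean
nearest-neighbour spacing, ~150 tags per network in a 2:1 blue:great tit
ratio, a September-to-August year in four seasons, and 2 m rasters.

The renderer guarantees an exact round trip: the per-pair-season count
table extracted from the rendered detections equals the truth table.  It
does so by placing each connection as a bout pair inside its own time
slot and separating a tag's consecutive slots by more than the 48 h
duration cutoff, so the only surviving consecutive-bout candidates are
the intended ones.  That bounds how many connections one tag can make in
one season (~40), and the simulator caps draws at that capacity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import poisson
from shapely.geometry import LineString

from feedernet.errors import ValidationError
from feedernet.io import SPECIES_LEVELS
from feedernet.landscape import build_pair_features
from feedernet.models import build_design
from feedernet.raster import Raster
from feedernet.seasons import STUDY_CALENDAR, SeasonCalendar

NETWORK_NAMES = ("low", "medium", "high")

#: Generating coefficients on the standardized-covariate scale, presence
#: (zero) part: positive vegetation effect, negative distance and
#: road-gap effects, seasonal offsets against a summer baseline and a
#: species contrast against blue tit.
DEFAULT_BETA_ZERO = {
    "intercept": -1.8,
    "veg_z": 0.8,
    "dist_z": -1.2,
    "ring_z": -0.5,
    "road_gap_1": -0.3,
    "road_gap_2": -0.5,
    "season_autumn": 0.8,
    "season_winter": 0.6,
    "season_spring": 0.8,
    "species_great_tit": -1.1,
}

#: Count (frequency) part on the log scale.
DEFAULT_BETA_COUNT = {
    "intercept": 1.3,
    "veg_z": 0.2,
    "dist_z": -0.3,
    "ring_z": -0.2,
    "road_gap_1": -0.2,
    "road_gap_2": -0.3,
    "season_autumn": -0.5,
    "season_winter": -0.5,
    "season_spring": 0.1,
    "species_great_tit": -0.1,
}


@dataclass
class SynthConfig:
    """All knobs of the synthetic study.  ``seed`` is mandatory for
    reproducibility; identical configs give identical outputs."""

    seed: int = 0
    n_networks: int = 3
    n_feeders: int = 17
    n_tags: int = 150  # per network
    blue_tit_fraction: float = 2.0 / 3.0  # 2:1 blue:great
    n_ringing_sites: int = 2
    area_side_m: float = 700.0  # ~0.5 km^2 per network
    margin_m: float = 30.0
    min_spacing_m: float = 40.0
    raster_res_m: float = 2.0
    n_veg_blobs: int = 25
    veg_scale: tuple = (1.6, 1.0, 0.6)  # per-network blob-count factors
    veg_base_height: float = 0.0
    index_base: float = -0.05
    n_roads: int = 6
    road_scale: tuple = (0.5, 0.75, 1.25)
    calendar: SeasonCalendar = STUDY_CALENDAR
    beta_zero: dict = field(default_factory=lambda: dict(DEFAULT_BETA_ZERO))
    beta_count: dict = field(default_factory=lambda: dict(DEFAULT_BETA_COUNT))
    sigma2_feeder_zero: float = 0.5
    sigma2_feeder_count: float = 0.3
    sigma2_tag: float = 0.3
    participation_mean: float = 2.0  # mean birds per present cell
    slow_fraction: float = 0.05  # extra >48 h transits, to exercise discards
    max_per_tag_season: int = 40  # renderer capacity, see module docstring
    max_duration_h: float = 48.0

    def __post_init__(self):
        for name in ("n_networks", "n_feeders", "n_tags", "n_ringing_sites"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.seed is None:
            raise ValidationError("seed is mandatory")


@dataclass
class SynthTruth:
    """Realized ground truth: the per-tag pair-season count table exactly
    as encoded into the rendered detections, plus the generating
    parameters and random-effect draws."""

    counts: pd.DataFrame  # network_id, feeder_a, feeder_b, season, tag_id, species, count
    params: dict
    ranef: dict

    @property
    def presence(self) -> pd.DataFrame:
        """Species × pair × season cells with at least one count."""
        if len(self.counts) == 0:
            return pd.DataFrame(
                columns=["network_id", "feeder_a", "feeder_b", "season",
                         "species", "presence"]
            )
        out = (
            self.counts.groupby(
                ["network_id", "feeder_a", "feeder_b", "season", "species"],
                as_index=False,
            )["count"]
            .sum()
        )
        out["presence"] = 1
        return out.drop(columns="count")

    def pair_season_counts(self) -> pd.DataFrame:
        """Per-pair-season totals (the round-trip comparison table)."""
        if len(self.counts) == 0:
            return pd.DataFrame(
                columns=["network_id", "feeder_a", "feeder_b", "season", "count"]
            )
        return (
            self.counts.groupby(
                ["network_id", "feeder_a", "feeder_b", "season"], as_index=False
            )["count"]
            .sum()
            .sort_values(["network_id", "feeder_a", "feeder_b", "season"])
            .reset_index(drop=True)
        )


@dataclass
class SynthStudy:
    """A complete rendered study: every input the pipeline reads."""

    config: SynthConfig
    stations: pd.DataFrame
    sites: pd.DataFrame
    tags: pd.DataFrame
    height: dict  # network_id -> Raster
    index: dict
    roads: dict  # network_id -> list[LineString]
    features: pd.DataFrame
    truth: SynthTruth
    detections: pd.DataFrame


def _network_ids(cfg: SynthConfig) -> list[str]:
    if cfg.n_networks <= len(NETWORK_NAMES):
        return list(NETWORK_NAMES[: cfg.n_networks])
    return [f"net{i}" for i in range(cfg.n_networks)]


def _scale(factors: tuple, i: int) -> float:
    return factors[i % len(factors)]


def generate_stations(cfg: SynthConfig, network_id: str, origin: float,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Feeder layout: uniform placement with a minimum-spacing rejection
    rule, tuned so the mean nearest-neighbour spacing lands near 81 m."""
    lo = origin + cfg.margin_m
    hi = origin + cfg.area_side_m - cfg.margin_m
    lo_y, hi_y = cfg.margin_m, cfg.area_side_m - cfg.margin_m
    pts = []
    attempts = 0
    while len(pts) < cfg.n_feeders:
        attempts += 1
        if attempts > 20000:
            raise ValidationError("could not place feeders with min spacing")
        x = rng.uniform(lo, hi)
        y = rng.uniform(lo_y, hi_y)
        if all(np.hypot(x - px, y - py) >= cfg.min_spacing_m for px, py in pts):
            pts.append((x, y))
    return pd.DataFrame(
        {
            "feeder_id": [f"{network_id}-F{i:02d}" for i in range(cfg.n_feeders)],
            "network_id": network_id,
            "x": [p[0] for p in pts],
            "y": [p[1] for p in pts],
        }
    )


def generate_landscape(
    cfg: SynthConfig, network_id: str, origin: float, rng: np.random.Generator,
    net_index: int = 0,
) -> tuple[Raster, Raster, list]:
    """Height and vegetation-index rasters plus straight road centrelines.

    Vegetation is laid down as smooth Gaussian canopy blobs so per-pair
    cover spans a wide range; the index co-varies with height so bare
    ground stays below the index threshold.  Per-network blob/road scale
    factors emulate the fragmentation gradient.
    """
    side = cfg.area_side_m
    n = int(round(side / cfg.raster_res_m))
    xs = origin + (np.arange(n) + 0.5) * cfg.raster_res_m
    ys = (n - np.arange(n) - 0.5) * cfg.raster_res_m  # row 0 = north
    gx, gy = np.meshgrid(xs, ys)

    height = np.full((n, n), cfg.veg_base_height, dtype=float)
    n_blobs = int(round(cfg.n_veg_blobs * _scale(cfg.veg_scale, net_index)))
    for _ in range(n_blobs):
        cx = rng.uniform(origin, origin + side)
        cy = rng.uniform(0, side)
        amp = rng.uniform(2.0, 15.0)
        sd = rng.uniform(15.0, 60.0)
        height += amp * np.exp(-((gx - cx) ** 2 + (gy - cy) ** 2) / (2 * sd * sd))

    index = (
        cfg.index_base
        + 0.8 * (1.0 - np.exp(-height))
        + rng.normal(0.0, 0.02, size=height.shape)
    )
    index = np.clip(index, -1.0, 1.0)

    roads = []
    n_roads = int(round(cfg.n_roads * _scale(cfg.road_scale, net_index)))
    for _ in range(n_roads):
        # residential street segments, not full transects: lengths chosen
        # so per-network road-gap totals fall in the low-hundreds range
        # reported for ~0.5 km^2 urban study areas
        angle = rng.uniform(0, np.pi)
        px = rng.uniform(origin + 0.1 * side, origin + 0.9 * side)
        py = rng.uniform(0.1 * side, 0.9 * side)
        dx, dy = np.cos(angle), np.sin(angle)
        L = rng.uniform(0.08, 0.22) * side  # half-length
        roads.append(
            LineString(
                [(px - L * dx, py - L * dy), (px + L * dx, py + L * dy)]
            )
        )

    h = Raster(height, x_ll=origin, y_ll=0.0, cellsize=cfg.raster_res_m)
    idx = Raster(index, x_ll=origin, y_ll=0.0, cellsize=cfg.raster_res_m)
    return h, idx, roads


def generate_sites(cfg: SynthConfig, stations: pd.DataFrame,
                   rng: np.random.Generator) -> pd.DataFrame:
    """Ringing sites: near a randomly chosen feeder (~15-25 m away)."""
    rows = []
    for net, group in stations.groupby("network_id"):
        pick = rng.choice(len(group), size=cfg.n_ringing_sites, replace=False)
        for j, k in enumerate(pick):
            st = group.iloc[k]
            ang = rng.uniform(0, 2 * np.pi)
            r = rng.uniform(15.0, 25.0)
            rows.append(
                {
                    "site_id": f"{net}-R{j}",
                    "network_id": net,
                    "x": st["x"] + r * np.cos(ang),
                    "y": st["y"] + r * np.sin(ang),
                }
            )
    return pd.DataFrame(rows)


def generate_tags(cfg: SynthConfig, sites: pd.DataFrame,
                  rng: np.random.Generator) -> pd.DataFrame:
    """Tag registry: per-network tags, 2:1 blue:great tit by default,
    ringed at one of the network's sites before the study year."""
    rows = []
    start = cfg.calendar.start
    for net, group in sites.groupby("network_id"):
        site_ids = group["site_id"].tolist()
        for i in range(cfg.n_tags):
            species = (
                SPECIES_LEVELS[0]
                if rng.random() < cfg.blue_tit_fraction
                else SPECIES_LEVELS[1]
            )
            rows.append(
                {
                    "tag_id": f"{net}-T{i:03d}",
                    "species": species,
                    "ringing_site_id": site_ids[int(rng.integers(len(site_ids)))],
                    "tag_date": (
                        start - pd.Timedelta(days=int(rng.integers(10, 80)))
                    ).date(),
                }
            )
    return pd.DataFrame(rows)


def _rztp(rng: np.random.Generator, lam: np.ndarray) -> np.ndarray:
    """Zero-truncated Poisson draws by inverse-cdf conditioning."""
    lam = np.asarray(lam, float)
    u = rng.uniform(size=lam.shape)
    cdf0 = poisson.cdf(0, lam)
    y = poisson.ppf(cdf0 + u * (1.0 - cdf0), lam)
    return np.maximum(y, 1.0).astype(int)


def simulate_connections(
    cfg: SynthConfig,
    features: pd.DataFrame,
    tags: pd.DataFrame,
    rng: np.random.Generator,
) -> SynthTruth:
    """Draw the hurdle ground truth on a computed pair-features table.

    Per species × pair × season cell: presence ~ Bernoulli on the logit
    scale with the zero-part coefficients and multi-membership feeder
    effects; for present cells, 1 + Poisson-distributed birds of that
    species participate, each with a zero-truncated Poisson count on the
    log scale with the count-part coefficients, its network's feeder
    effects and its own tag effect.  Per-tag-per-season totals are capped
    at the renderer capacity.
    """
    seasons = cfg.calendar.labels
    grid = (
        features.merge(pd.DataFrame({"season": seasons}), how="cross")
        .merge(pd.DataFrame({"species": list(SPECIES_LEVELS)}), how="cross")
        .reset_index(drop=True)
    )
    # standardize within network, as the fitted models do
    parts = []
    for net, g in grid.groupby("network_id", sort=True):
        X, _ = build_design(g)
        parts.append(X)
    X = pd.concat(parts).loc[grid.index]

    def eta(beta: dict) -> np.ndarray:
        e = np.full(len(grid), beta.get("intercept", 0.0))
        for name, b in beta.items():
            if name == "intercept":
                continue
            if name not in X.columns:
                raise ValidationError(f"unknown coefficient {name!r}")
            e += b * X[name].to_numpy()
        return e

    feeders = pd.unique(
        pd.concat([grid["feeder_a"], grid["feeder_b"]], ignore_index=True)
    )
    u_zero = pd.Series(
        rng.normal(0.0, np.sqrt(cfg.sigma2_feeder_zero), len(feeders)),
        index=feeders,
    )
    u_count = pd.Series(
        rng.normal(0.0, np.sqrt(cfg.sigma2_feeder_count), len(feeders)),
        index=feeders,
    )
    v_tag = pd.Series(
        rng.normal(0.0, np.sqrt(cfg.sigma2_tag), len(tags)),
        index=tags["tag_id"].to_numpy(),
    )

    eta_zero = (
        eta(cfg.beta_zero)
        + grid["feeder_a"].map(u_zero).to_numpy()
        + grid["feeder_b"].map(u_zero).to_numpy()
    )
    present = rng.uniform(size=len(grid)) < expit(eta_zero)

    eta_count_cell = (
        eta(cfg.beta_count)
        + grid["feeder_a"].map(u_count).to_numpy()
        + grid["feeder_b"].map(u_count).to_numpy()
    )

    # tags belong to the network whose prefix matches their id
    tags = tags.copy()
    tags["network_id"] = tags["tag_id"].str.rsplit("-", n=1).str[0]
    tags_by = {
        key: g["tag_id"].to_numpy()
        for key, g in tags.groupby(["network_id", "species"])
    }

    rows = []
    for i in np.flatnonzero(present):
        cell = grid.iloc[i]
        pool = tags_by.get((cell["network_id"], cell["species"]), np.array([]))
        if pool.size == 0:
            continue
        n_part = min(1 + rng.poisson(max(cfg.participation_mean - 1.0, 0.0)),
                     pool.size)
        chosen = rng.choice(pool, size=n_part, replace=False)
        lam = np.exp(
            np.clip(eta_count_cell[i] + v_tag[chosen].to_numpy(), -30, 30)
        )
        counts = _rztp(rng, lam)
        for tag_id, c in zip(chosen, counts):
            rows.append(
                {
                    "network_id": cell["network_id"],
                    "feeder_a": cell["feeder_a"],
                    "feeder_b": cell["feeder_b"],
                    "season": cell["season"],
                    "tag_id": tag_id,
                    "species": cell["species"],
                    "count": int(c),
                }
            )
    counts = pd.DataFrame(
        rows,
        columns=["network_id", "feeder_a", "feeder_b", "season", "tag_id",
                 "species", "count"],
    )

    # cap per-tag-per-season totals at the renderer capacity
    if len(counts):
        totals = counts.groupby(["tag_id", "season"])["count"].transform("sum")
        over = totals > cfg.max_per_tag_season
        if over.any():
            capped = counts.copy()
            for _, idx in counts[over].groupby(["tag_id", "season"]).groups.items():
                cum = counts.loc[idx, "count"].cumsum()
                allowed = (cfg.max_per_tag_season - (cum - counts.loc[idx, "count"])
                           ).clip(lower=0)
                capped.loc[idx, "count"] = np.minimum(
                    counts.loc[idx, "count"], allowed
                )
            counts = capped[capped["count"] > 0].reset_index(drop=True)

    params = {
        "beta_zero": dict(cfg.beta_zero),
        "beta_count": dict(cfg.beta_count),
        "sigma2_feeder_zero": cfg.sigma2_feeder_zero,
        "sigma2_feeder_count": cfg.sigma2_feeder_count,
        "sigma2_tag": cfg.sigma2_tag,
    }
    ranef = {"u_zero": u_zero, "u_count": u_count, "v_tag": v_tag}
    return SynthTruth(counts=counts, params=params, ranef=ranef)


def render_detections(
    truth: SynthTruth,
    stations: pd.DataFrame,
    calendar: SeasonCalendar,
    cfg: SynthConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Encode the truth counts into a raw detection stream.

    Each connection becomes a pair of visit bouts at the two feeders with
    an inter-bout gap below the duration cutoff; a tag's consecutive
    slots are separated by more than the cutoff so no unintended
    consecutive-bout candidate survives extraction.  Tags with no
    connections contribute nuisance single-feeder visits, and a
    configurable fraction of slow (>cutoff) transits is injected to
    exercise the discard path.
    """
    sec = pd.Timedelta(seconds=1)
    all_rows = []
    D = float(cfg.max_duration_h)  # duration cutoff; slot spacing exceeds it

    def emit_bout(tag_id, feeder_id, t0, n_reads):
        for k in range(n_reads):
            all_rows.append((tag_id, feeder_id, t0 + k * 20 * sec))
        return t0 + (n_reads - 1) * 20 * sec

    connecting_tags = set()
    if len(truth.counts):
        connecting_tags = set(truth.counts["tag_id"])
        for (tag_id, season), g in truth.counts.groupby(["tag_id", "season"]):
            start, end = calendar.bounds(season)
            season_h = (end - start).total_seconds() / 3600.0
            slots = []
            for _, row in g.iterrows():
                slots.extend([(row["feeder_a"], row["feeder_b"])] * row["count"])
            rng.shuffle(slots)
            n = len(slots)
            budget = season_h / n
            if budget < D + 2.75:
                raise ValidationError(
                    f"tag {tag_id} season {season}: {n} connections exceed "
                    "renderer capacity"
                )
            max_gap = float(np.clip(budget - (D + 2.0), 0.25, min(40.0, D - 8.0)))
            t = start + pd.Timedelta(minutes=float(rng.uniform(5, 60)))
            for fa, fb in slots:
                if rng.random() < 0.5:
                    fa, fb = fb, fa
                n_a = 1 + int(rng.poisson(2))
                n_b = 1 + int(rng.poisson(2))
                depart = emit_bout(tag_id, fa, t, n_a)
                gap_h = float(
                    np.exp(rng.uniform(np.log(1.0 / 60.0), np.log(max_gap)))
                )
                arrive = depart + pd.Timedelta(hours=gap_h)
                t_end = emit_bout(tag_id, fb, arrive, n_b)
                t = t_end + pd.Timedelta(
                    hours=D + 0.6 + float(rng.uniform(0.0, 0.4))
                )
            # optionally inject one slow (>cutoff) transit in leftover time
            if (
                rng.random() < cfg.slow_fraction
                and (end - t).total_seconds() / 3600.0 > 2.0 * D + 20.0
            ):
                fa, fb = slots[0]
                depart = emit_bout(tag_id, fa, t, 2)
                arrive = depart + pd.Timedelta(
                    hours=D + float(rng.uniform(1.0, 12.0))
                )
                emit_bout(tag_id, fb, arrive, 2)

    # nuisance same-feeder visits for tags that never connect
    feeders_by_net = {
        net: g["feeder_id"].tolist() for net, g in stations.groupby("network_id")
    }
    # note: connecting tags already carry nuisance re-reads inside bouts
    return _finish_detections(all_rows, truth, feeders_by_net, calendar, cfg, rng,
                              connecting_tags)


def _finish_detections(all_rows, truth, feeders_by_net, calendar, cfg, rng,
                       connecting_tags):
    start, end = calendar.start, calendar.end
    span_days = (end - start).days
    for net, feeders in feeders_by_net.items():
        for i in range(cfg.n_tags):
            tag_id = f"{net}-T{i:03d}"
            if tag_id in connecting_tags:
                continue
            if rng.random() < 0.5:  # some tagged birds never visit at all
                continue
            feeder = feeders[int(rng.integers(len(feeders)))]
            for _ in range(int(rng.integers(1, 6))):
                t0 = start + pd.Timedelta(
                    days=float(rng.uniform(0, span_days)),
                )
                for k in range(1 + int(rng.poisson(2))):
                    all_rows.append((tag_id, feeder, t0 + k * pd.Timedelta(seconds=20)))
    det = pd.DataFrame(all_rows, columns=["tag_id", "feeder_id", "timestamp"])
    det["timestamp"] = pd.to_datetime(det["timestamp"]).dt.floor("s")
    det = det.sort_values("timestamp", kind="stable").reset_index(drop=True)
    return det


def generate_study(cfg: SynthConfig) -> SynthStudy:
    """Generate a complete deterministic study from ``cfg``."""
    root = np.random.SeedSequence(cfg.seed)
    nets = _network_ids(cfg)
    streams = root.spawn(len(nets) + 3)
    net_rngs = [np.random.default_rng(s) for s in streams[: len(nets)]]
    rng_tags, rng_truth, rng_render = (
        np.random.default_rng(s) for s in streams[len(nets):]
    )

    stations_parts, height, index, roads = [], {}, {}, {}
    for i, (net, rng) in enumerate(zip(nets, net_rngs)):
        origin = i * 2.0 * cfg.area_side_m
        st = generate_stations(cfg, net, origin, rng)
        stations_parts.append(st)
        h, idx, rds = generate_landscape(cfg, net, origin, rng, net_index=i)
        height[net], index[net], roads[net] = h, idx, rds
    stations = pd.concat(stations_parts, ignore_index=True)
    sites = generate_sites(cfg, stations, rng_tags)
    tags = generate_tags(cfg, sites, rng_tags)

    features = build_pair_features(stations, sites, height, index, roads)
    truth = simulate_connections(cfg, features, tags, rng_truth)
    detections = render_detections(truth, stations, cfg.calendar, cfg, rng_render)
    return SynthStudy(
        config=cfg,
        stations=stations,
        sites=sites,
        tags=tags,
        height=height,
        index=index,
        roads=roads,
        features=features,
        truth=truth,
        detections=detections,
    )


def write_study(study: SynthStudy, outdir) -> None:
    """Write the full input bundle (CSV tables, .asc rasters, GeoJSON
    roads, detections) plus truth.json to ``outdir``."""
    import json
    from pathlib import Path

    from feedernet.io import write_table
    from feedernet.landscape import write_roads

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_table(study.stations, out / "stations.csv")
    write_table(study.sites, out / "ringing_sites.csv")
    write_table(study.tags, out / "tags.csv")
    write_table(study.detections, out / "detections.csv")
    write_table(study.features, out / "pair_features.csv")
    for net in study.height:
        study.height[net].write_ascii(out / f"height_{net}.asc")
        study.index[net].write_ascii(out / f"index_{net}.asc")
        write_roads(study.roads[net], out / f"roads_{net}.geojson")
    with open(out / "truth.json", "w") as fh:
        json.dump(
            {
                "params": study.truth.params,
                "counts": study.truth.counts.to_dict(orient="records"),
            },
            fh,
            indent=1,
        )
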