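"""Synthetic multi-herd GPS surveys with known ground truth.

The generator emulates the structure of a Sahelian cattle-collar survey:
several herds tracked at a 30-min fix interval over months, resident herds
tethered (resting) at night near a home village, transhumant herds making
phase-structured journeys (directed multi-day marches between long
stationary stops), isotropic GPS noise, random fix drop-out and collar
swaps, plus a concentric synthetic land-use map (homefields within ~1 km of
the village, bushfields out to ~3 km, rangelands and lowlands beyond) in a
fine and a coarse layer.

Overrides (night tethering, march phases) are applied to the *state
sequence*, not patched onto positions afterwards, so decoded-state recovery
against the stored truth remains a meaningful test.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon, box

from . import solar
from .emissions import sample_angles, sample_steps
from .geo import LocalProjection, wrap_angle
from .landuse import LandUseMap
from .model import HmmModel

# sd such that the 95% radial quantile of isotropic 2-D Gaussian noise is
# 10 m (the collars' advertised accuracy): r_p = sd * sqrt(-2 ln(1-p))
GPS_NOISE_SD_M = 10.0 / np.sqrt(-2.0 * np.log(0.05))

HOME_LAT, HOME_LON = 14.5, -16.5  # agropastoral study-area centre


@dataclass
class TranshumancePhase:
    """One scheduled journey phase: where the drove should be from when."""

    label: str
    start: dt.date
    target_km: tuple[float, float]  # (east, north) displacement from home


def default_schedule(start: dt.date) -> list[TranshumancePhase]:
    """A two-stop journey with return, scaled to a ~120-day survey window."""
    return [
        TranshumancePhase("agropastoral-1", start + dt.timedelta(days=25), (25.0, 5.0)),
        TranshumancePhase("pastoral", start + dt.timedelta(days=55), (45.0, 40.0)),
        TranshumancePhase("home-return", start + dt.timedelta(days=100), (0.0, 0.0)),
    ]


@dataclass
class SimConfig:
    """Survey-generator configuration; defaults are the study conditions."""

    n_herds: int = 3
    herd_types: tuple[str, ...] | None = None  # default alternates t/r
    start: dt.date = dt.date(2022, 3, 1)
    n_days: int = 120
    fix_interval_min: float = 30.0
    gps_noise_sd: float = GPS_NOISE_SD_M
    gap_rate: float = 0.02
    night_tether: bool = True
    transhumance_schedule: list[TranshumancePhase] | None = None
    collar_swap_herds: tuple[int, ...] = ()
    home_lat: float = HOME_LAT
    home_lon: float = HOME_LON
    seed: int = 0

    def __post_init__(self):
        if self.fix_interval_min <= 0:
            raise ValueError("fix_interval must be positive")
        if not 0.0 <= self.gap_rate < 1.0:
            raise ValueError("gap_rate must lie in [0, 1)")
        if self.n_days < 1:
            raise ValueError("span must be non-empty")
        if self.herd_types is None:
            self.herd_types = tuple(
                "transhumant" if i % 2 == 0 else "resident" for i in range(self.n_herds)
            )
        if len(self.herd_types) != self.n_herds:
            raise ValueError("one herd type per herd required")
        if any(t not in ("resident", "transhumant") for t in self.herd_types):
            raise ValueError("herd types must be resident or transhumant")
        if self.transhumance_schedule is None:
            self.transhumance_schedule = default_schedule(self.start)
        end = self.start + dt.timedelta(days=self.n_days)
        for ph in self.transhumance_schedule:
            if not self.start <= ph.start < end:
                raise ValueError(f"phase {ph.label!r} scheduled outside survey span")


@dataclass
class SyntheticSurvey:
    """Generated bundle: GPS + metadata + land use + per-fix ground truth."""

    gps: pd.DataFrame
    metadata: pd.DataFrame
    landuse: list[LandUseMap]
    legend: dict[str, str]
    truth: pd.DataFrame
    config: SimConfig
    n_generated: int = 0
    n_dropped_gaps: int = 0

    def write(self, outdir) -> None:
        import pathlib

        import yaml

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.gps.to_csv(out / "gps.csv", index=False)
        self.metadata.to_csv(out / "metadata.csv", index=False)
        self.truth.to_csv(out / "truth.csv", index=False)
        for layer in self.landuse:
            layer.to_geojson(out / f"landuse_{layer.resolution_tag}.geojson")
        with open(out / "legend.yaml", "w") as fh:
            yaml.safe_dump(self.legend, fh)


# ---------------------------------------------------------------------------
# elementary simulation operations


def simulate_states(model: HmmModel, n_steps: int, seed: int,
                    covariates: np.ndarray | None = None) -> np.ndarray:
    """Sample a latent state sequence: first state from Pi, then rows of
    Gamma (evaluated at each step's covariate) of the previous state."""
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(seed)
    pi0 = np.asarray(model.pi0, dtype=float)
    C = len(model.covariates)
    if C and covariates is None:
        raise ValueError("model has covariates but none were supplied")
    if C:
        Z = np.asarray(covariates, dtype=float).reshape(n_steps, C)
        gammas = model.transitions.matrices(Z)
    else:
        g = model.transitions.matrix()
        if np.any(g < 0) or not np.allclose(g.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition rows must be probability vectors")
        gammas = None
    states = np.empty(n_steps, dtype=np.int64)
    states[0] = rng.choice(model.n_states, p=pi0)
    for t in range(1, n_steps):
        row = gammas[t, states[t - 1]] if gammas is not None else g[states[t - 1]]
        states[t] = rng.choice(model.n_states, p=row)
    return states


def simulate_track(model: HmmModel, states: np.ndarray, start: tuple[float, float],
                   seed: int, initial_heading: float | None = None):
    """Correlated random walk conditional on a state sequence.

    Per step a length is drawn from the state's zero-inflated step law and a
    turning angle from its von Mises law; headings accumulate turning angles
    from an initial heading uniform on the circle.  The walk lives in a local
    azimuthal-equidistant frame centred on ``start`` and is returned as
    WGS84 (lat, lon) arrays of length ``len(states) + 1``.
    """
    states = np.asarray(states, dtype=int)
    if np.any(states < 0) or np.any(states >= model.n_states):
        raise ValueError("state sequence invalid for model")
    rng = np.random.default_rng(seed)
    n = states.size
    steps = np.empty(n)
    turns = np.empty(n)
    for s_idx, e in enumerate(model.emissions):
        m = states == s_idx
        k = int(m.sum())
        if k:
            steps[m] = sample_steps(rng, k, e.mu, e.sigma, e.zeta, model.step_family)
            turns[m] = sample_angles(rng, k, e.mu_angle, e.kappa)
    h0 = rng.uniform(-np.pi, np.pi) if initial_heading is None else initial_heading
    headings = wrap_angle(h0 + np.concatenate([[0.0], np.cumsum(turns[1:])]))
    x = np.concatenate([[0.0], np.cumsum(steps * np.sin(headings))])
    y = np.concatenate([[0.0], np.cumsum(steps * np.cos(headings))])
    proj = LocalProjection(start[0], start[1])
    return proj.inverse(x, y)


def add_gps_noise(lat, lon, sd: float, seed: int):
    """Isotropic Gaussian jitter of scale ``sd`` metres, independent per fix."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if sd == 0:
        return lat.copy(), lon.copy()
    rng = np.random.default_rng(seed)
    proj = LocalProjection(float(np.mean(lat)), float(np.mean(lon)))
    x, y = proj.forward(lat, lon)
    return proj.inverse(x + rng.normal(0, sd, lat.size), y + rng.normal(0, sd, lat.size))


# ---------------------------------------------------------------------------
# full survey


def _night_mask(timestamps: pd.DatetimeIndex, lat: float, lon: float,
                margin_h: float = 1.0) -> np.ndarray:
    """True where the clock is between sunset+margin and sunrise-margin."""
    out = np.zeros(len(timestamps), dtype=bool)
    margin = dt.timedelta(hours=margin_h)
    for date, grp in pd.Series(range(len(timestamps)), index=timestamps).groupby(
        timestamps.date
    ):
        rise, set_ = solar.sunrise_sunset_utc(date, lat, lon)
        ts = grp.index
        out[grp.to_numpy()] = (ts < rise - margin) | (ts >= set_ + margin)
    return out


def synthetic_temperature(timestamps: pd.DatetimeIndex, rng: np.random.Generator):
    """Collar temperature: daily sinusoid 25-45 degC peaking mid-afternoon."""
    hours = timestamps.hour + timestamps.minute / 60.0
    base = 35.0 - 10.0 * np.cos(2.0 * np.pi * (hours - 2.0) / 24.0)
    return np.asarray(base + rng.normal(0.0, 0.8, len(timestamps)))


def synthetic_landuse(home_lat: float = HOME_LAT, home_lon: float = HOME_LON
                      ) -> tuple[list[LandUseMap], dict[str, str]]:
    """Concentric synthetic land-use: a fine local layer and a coarse one."""
    proj = LocalProjection(home_lat, home_lon)

    def to_wgs(poly_m: Polygon) -> Polygon:
        xs, ys = np.array(poly_m.exterior.coords).T
        lat, lon = proj.inverse(xs, ys)
        shell = list(zip(lon, lat))
        holes = []
        for ring in poly_m.interiors:
            xs, ys = np.array(ring.coords).T
            la, lo = proj.inverse(xs, ys)
            holes.append(list(zip(lo, la)))
        return Polygon(shell, holes)

    km = 1000.0
    home_disc = Point(0, 0).buffer(1.0 * km, quad_segs=32)
    ring_1_3 = Point(0, 0).buffer(3.0 * km, quad_segs=32).difference(home_disc)
    east_half = box(0, -4 * km, 4 * km, 4 * km)
    fallow = box(1.2 * km, 1.2 * km, 2.0 * km, 2.0 * km)
    lowland = box(-3.8 * km, -3.8 * km, -2.5 * km, -2.2 * km)
    fine_extent = box(-5 * km, -5 * km, 5 * km, 5 * km)
    fine_range = fine_extent.difference(Point(0, 0).buffer(3.0 * km, quad_segs=32))

    fine_polys = [
        to_wgs(home_disc),
        to_wgs(ring_1_3.intersection(east_half)),
        to_wgs(ring_1_3.difference(east_half)),
        to_wgs(fallow),
        to_wgs(lowland),
        to_wgs(fine_range.difference(lowland)),
    ]
    fine_labels = [
        "homefield",
        "millet_cropland",
        "groundnut_cropland",
        "collective_fallow",
        "wet_lowland",
        "shrub_rangeland",
    ]
    coarse_polys = [
        to_wgs(box(-12 * km, -12 * km, 12 * km, 12 * km)),
        to_wgs(box(-160 * km, -160 * km, 160 * km, 160 * km)
               .difference(box(-12 * km, -12 * km, 12 * km, 12 * km))),
    ]
    coarse_labels = ["cropland_mosaic", "open_savannah"]
    legend = {
        "homefield": "homefields",
        "millet_cropland": "bushfields",
        "groundnut_cropland": "bushfields",
        "collective_fallow": "fallows",
        "wet_lowland": "lowlands",
        "shrub_rangeland": "rangelands",
        "cropland_mosaic": "bushfields",
        "open_savannah": "rangelands",
    }
    fine = LandUseMap(fine_polys, fine_labels, legend, priority=2, resolution_tag="fine")
    coarse = LandUseMap(coarse_polys, coarse_labels, legend, priority=1,
                        resolution_tag="coarse")
    return [fine, coarse], legend


def _travelling_state(model: HmmModel) -> int:
    return int(np.argmax([e.mu for e in model.emissions]))


def _resting_state(model: HmmModel) -> int:
    return int(np.argmin([e.mu for e in model.emissions]))


def _simulate_herd(config: SimConfig, model: HmmModel, herd_idx: int,
                   rng: np.random.Generator):
    """States + track for one herd, with tether/march overrides applied."""
    interval = dt.timedelta(minutes=config.fix_interval_min)
    n_fixes = int(config.n_days * 24 * 60 / config.fix_interval_min) + 1
    t0 = dt.datetime.combine(config.start, dt.time(0, 0))
    timestamps = pd.DatetimeIndex([t0 + i * interval for i in range(n_fixes)])
    n_steps = n_fixes - 1
    herd_type = config.herd_types[herd_idx]

    # latent states (steps are indexed by their origin fix)
    seed = int(rng.integers(2**31 - 1))
    states = simulate_states(model, n_steps, seed)
    night = _night_mask(timestamps[:-1], config.home_lat, config.home_lon)
    rest, travel = _resting_state(model), _travelling_state(model)
    if herd_type == "resident" and config.night_tether:
        states[night] = rest

    # anchors: where the herd should sit at each step, from the schedule
    proj = LocalProjection(config.home_lat, config.home_lon)
    anchors = np.zeros((n_steps, 2))
    phase = np.array(["home"] * n_steps, dtype=object)
    if herd_type == "transhumant":
        dates = timestamps[:-1].date
        for ph in config.transhumance_schedule:
            m = dates >= ph.start
            anchors[m] = np.array(ph.target_km) * 1000.0
            phase[m] = ph.label

    # walk: normal CRW near the anchor, directed march when far from it
    walk_rng = np.random.default_rng(int(rng.integers(2**31 - 1)))
    x = np.empty(n_fixes)
    y = np.empty(n_fixes)
    # herds start scattered around the village
    x[0], y[0] = walk_rng.normal(0.0, 300.0, 2)
    heading = walk_rng.uniform(-np.pi, np.pi)
    clamp_m = 1500.0
    for t in range(n_steps):
        dx, dy = anchors[t, 0] - x[t], anchors[t, 1] - y[t]
        dist_to_anchor = float(np.hypot(dx, dy))
        marching = dist_to_anchor > clamp_m
        if marching:
            states[t] = rest if night[t] else travel
        e = model.emissions[states[t]]
        step = float(sample_steps(walk_rng, 1, e.mu, e.sigma, e.zeta,
                                  model.step_family)[0])
        turn = float(sample_angles(walk_rng, 1, e.mu_angle, e.kappa)[0])
        if marching and not night[t]:
            # march by day straight at the target, with a little wander
            heading = float(np.arctan2(dx, dy) + walk_rng.vonmises(0.0, 40.0))
        elif dist_to_anchor > clamp_m * 0.8 and states[t] != rest:
            heading = float(np.arctan2(dx, dy) + walk_rng.vonmises(0.0, 4.0))
        else:
            heading = float(wrap_angle(heading + turn))
        x[t + 1] = x[t] + step * np.sin(heading)
        y[t + 1] = y[t] + step * np.cos(heading)
    lat, lon = proj.inverse(x, y)

    fix_phase = np.concatenate([phase, phase[-1:]])
    fix_state = np.concatenate([states, states[-1:]])
    temp = synthetic_temperature(timestamps, walk_rng)
    dop = np.round(np.exp(walk_rng.normal(np.log(1.15), 0.25, n_fixes)), 3)
    return timestamps, lat, lon, fix_state, fix_phase, temp, dop


def simulate_survey(config: SimConfig, model: HmmModel) -> SyntheticSurvey:
    """Generate a full survey bundle; byte-identical for identical seeds."""
    root = np.random.default_rng(config.seed)
    gps_rows, truth_rows, meta_rows = [], [], []
    n_generated = n_dropped = 0
    for h in range(config.n_herds):
        herd_rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 1000 + h])
        )
        ts, lat, lon, st, ph, temp, dop = _simulate_herd(config, model, h, herd_rng)
        lat, lon = add_gps_noise(
            lat, lon, config.gps_noise_sd, int(herd_rng.integers(2**31 - 1))
        )
        n = len(ts)
        n_generated += n
        keep = np.ones(n, dtype=bool)
        if config.gap_rate > 0:
            keep[1:-1] = herd_rng.uniform(size=n - 2) >= config.gap_rate
        n_dropped += int((~keep).sum())

        animal = f"A{h:02d}"
        herd = f"H{h:02d}"
        collars = [f"C{h:02d}a"]
        end_ts = ts[-1] + dt.timedelta(minutes=config.fix_interval_min)
        if h in config.collar_swap_herds:
            collars.append(f"C{h:02d}b")
            swap_at = ts[n // 2]
            periods = [(ts[0], swap_at), (swap_at, end_ts)]
        else:
            periods = [(ts[0], end_ts)]
        collar_per_fix = np.array(
            [collars[-1] if (len(periods) > 1 and t >= periods[1][0]) else collars[0]
             for t in ts],
            dtype=object,
        )
        for collar, (p0, p1) in zip(collars, periods):
            meta_rows.append(
                dict(collar_id=collar, animal_id=animal, herd_id=herd,
                     herd_type=config.herd_types[h],
                     start_utc=p0.isoformat(), end_utc=p1.isoformat())
            )
        sub = pd.DataFrame(
            dict(
                collar_id=collar_per_fix[keep],
                timestamp_utc=[t.isoformat() for t in ts[keep]],
                lat=np.round(lat[keep], 7),
                lon=np.round(lon[keep], 7),
                dop=dop[keep],
                temperature_c=np.round(temp[keep], 2),
            )
        )
        gps_rows.append(sub)
        truth_rows.append(
            pd.DataFrame(
                dict(
                    collar_id=collar_per_fix[keep],
                    animal_id=animal,
                    timestamp_utc=[t.isoformat() for t in ts[keep]],
                    true_state=st[keep],
                    phase=ph[keep],
                )
            )
        )
    maps, legend = synthetic_landuse(config.home_lat, config.home_lon)
    del root  # seed hierarchy is per herd; nothing else is random
    return SyntheticSurvey(
        gps=pd.concat(gps_rows, ignore_index=True),
        metadata=pd.DataFrame(meta_rows),
        landuse=maps,
        legend=legend,
        truth=pd.concat(truth_rows, ignore_index=True),
        config=config,
        n_generated=n_generated,
        n_dropped_gaps=n_dropped,
    )
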