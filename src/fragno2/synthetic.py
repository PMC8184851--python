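"""Synthetic station panels, land-use rasters and controlling variables.

The generator emulates the study conditions of a Chinese national monitoring
panel: 145 stations with daily NO2 from 2015-01-01 through 2020-05-01, annual
and weekly periodicity plus linear meteorology dependence and AR(1) noise,
a lockdown beginning 2020-01-24 that multiplicatively suppresses NO2, and a
categorical land-use raster per station with tunable fragmentation. The
lockdown suppression fraction s_i of station i is a known (ground-truth)
logit-linear function of the station's six fragmentation covariates, so the
downstream association models admit parameter-recovery tests.

Rasters are produced by seeded cluster growth: each class receives a number
of seed cells that interpolates from one (compact blocks) to its full cell
quota (near-random scatter) as ``fragmentation_level`` goes 0 -> 1, and
regions are grown from the seeds until every class meets its quota.
"""

from __future__ import annotations

import dataclasses
import heapq
import json
from dataclasses import dataclass
from datetime import date
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from fragno2.landscape import (
    FragmentationProfile,
    LandUseRaster,
    fragmentation_profile,
    read_ascii_grid,
    write_ascii_grid,
)

CONTROL_COLUMNS = ("pop", "aqi", "pm25", "pm10", "o3", "so2", "co", "tem", "hum", "wind")
PANEL_COLUMNS = ("station_id", "date", "no2", "temperature", "humidity", "wind_speed")

#: reference meteorology means; meteorology enters the NO2 law centred on
#: these so that zero effect coefficients give an exactly deterministic curve
MET_REFERENCE = (15.0, 65.0, 2.5)


class ConfigurationError(ValueError):
    """Raised for invalid scenario configurations."""


def _as_date(d) -> date:
    if isinstance(d, date):
        return d
    return pd.Timestamp(d).date()


@dataclass
class ScenarioConfig:
    """Parameters of a synthetic scenario.

    ``class_proportions`` is indexed by class code, i.e. (background,
    residential, commercial, industrial, transportation, public).
    ``suppression_betas`` act on the six standardized fragmentation
    covariates (ind_ed, pub_ed, ind_lsi, pub_lsi, uf_ai, uf_np) on the logit
    scale of the lockdown suppression fraction. An optional pre-lockdown
    suppression (``pre_suppression_*``, default off) lets scenarios carry a
    fragmentation signal before the lockdown as well.
    """

    n_stations: int = 145
    history_start: date = date(2015, 1, 1)
    forecast_start: date = date(2020, 1, 1)
    lockdown_date: date = date(2020, 1, 24)
    end_date: date = date(2020, 5, 1)
    baseline_level: float = 35.0
    annual_amplitude: float = 12.0
    weekly_amplitude: float = 3.0
    ar_coefficient: float = 0.6
    noise_sd: float = 4.0
    met_effect_coeffs: tuple[float, float, float] = (-0.2, 0.03, -2.0)
    suppression_base: float = 0.3
    suppression_betas: tuple[float, ...] = (-0.2, 0.15, 0.15, -0.2, -0.25, -0.1)
    pre_suppression_base: float = 0.0
    pre_suppression_betas: tuple[float, ...] = (0.0,) * 6
    suppression_link: str = "logit"
    raster_rows: int = 64
    raster_cols: int = 64
    cell_size: float = 100.0
    class_proportions: tuple[float, ...] = (0.35, 0.22, 0.08, 0.12, 0.08, 0.15)
    fragmentation_level: float | tuple[float, ...] = 0.35
    fragmentation_range: tuple[float, float] | None = (0.1, 0.8)
    proportion_jitter: float = 60.0
    buffer_radius: float = 3000.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.history_start = _as_date(self.history_start)
        self.forecast_start = _as_date(self.forecast_start)
        self.lockdown_date = _as_date(self.lockdown_date)
        self.end_date = _as_date(self.end_date)
        self.validate()

    def validate(self) -> None:
        if self.n_stations < 1:
            raise ConfigurationError("n_stations must be >= 1")
        if not (self.history_start < self.forecast_start <= self.lockdown_date < self.end_date):
            raise ConfigurationError(
                "dates must satisfy history_start < forecast_start <= lockdown_date < end_date"
            )
        props = np.asarray(self.class_proportions, dtype=float)
        if props.size != 6 or (props < 0).any() or abs(props.sum() - 1.0) > 1e-9:
            raise ConfigurationError("class_proportions must be 6 nonnegative values summing to 1")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not -1 < self.ar_coefficient < 1:
            raise ConfigurationError("ar_coefficient must be in (-1, 1)")
        if not 0 <= self.suppression_base < 1 or not 0 <= self.pre_suppression_base < 1:
            raise ConfigurationError("suppression bases must be in [0, 1)")
        if len(self.suppression_betas) != 6 or len(self.pre_suppression_betas) != 6:
            raise ConfigurationError("suppression betas must have 6 entries")
        if self.suppression_link not in ("logit", "log"):
            raise ConfigurationError("suppression_link must be 'logit' or 'log'")
        frag = np.atleast_1d(np.asarray(self.fragmentation_level, dtype=float))
        if frag.size not in (1, 6) or (frag < 0).any() or (frag > 1).any():
            raise ConfigurationError(
                "fragmentation_level must be a scalar or 6-vector in [0, 1]"
            )
        if self.raster_rows < 8 or self.raster_cols < 8:
            raise ConfigurationError("raster dimensions must be >= 8x8")
        if self.cell_size <= 0:
            raise ConfigurationError("cell_size must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k in ("history_start", "forecast_start", "lockdown_date", "end_date"):
            d[k] = getattr(self, k).isoformat()
        return d


@dataclass
class StationPanel:
    """Per-station daily observed series with contiguous calendar index."""

    station_id: str
    dates: pd.DatetimeIndex
    no2_observed: np.ndarray
    temperature: np.ndarray
    humidity: np.ndarray
    wind_speed: np.ndarray

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        n = len(self.dates)
        for name in ("no2_observed", "temperature", "humidity", "wind_speed"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} length does not match dates")
            setattr(self, name, arr)
        if n > 1:
            gaps = np.diff(self.dates.values).astype("timedelta64[D]")
            if not (gaps == np.timedelta64(1, "D")).all():
                raise ValueError("dates must be contiguous daily")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "station_id": self.station_id,
                "date": self.dates.strftime("%Y-%m-%d"),
                "no2": self.no2_observed,
                "temperature": self.temperature,
                "humidity": self.humidity,
                "wind_speed": self.wind_speed,
            }
        )


@dataclass
class Scenario:
    """A self-consistent synthetic bundle with ground truth."""

    config: ScenarioConfig
    station_ids: list[str]
    panels: list[StationPanel]
    rasters: dict[str, LandUseRaster]
    profiles: dict[str, FragmentationProfile]
    controls: pd.DataFrame
    suppression: pd.DataFrame  # ground truth: station_id, s_during, s_before
    counterfactual: dict[str, np.ndarray]  # noise-free/unsuppressed mean path

    @property
    def profile_frame(self) -> pd.DataFrame:
        rows = [{"station_id": sid, **p.as_dict()} for sid, p in self.profiles.items()]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Raster generation
# ---------------------------------------------------------------------------

def _quotas(proportions: np.ndarray, n_cells: int) -> np.ndarray:
    """Largest-remainder apportionment of cells to classes."""
    raw = proportions * n_cells
    counts = np.floor(raw).astype(int)
    rem = n_cells - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:rem]] += 1
    return counts


def generate_landuse_raster(config: ScenarioConfig, station_seed: int) -> LandUseRaster:
    """Grow a categorical raster matching ``class_proportions`` with
    fragmentation controlled by ``fragmentation_level``.

    Each class with a nonzero quota receives ``1 + round(f_c * (quota - 1))``
    seed cells (``fragmentation_level`` may be a scalar or one value per
    class); regions grow from the seeds (randomised rook frontier) until
    quotas are exhausted, and stranded quota falls back to random unassigned
    cells. f = 0 gives one compact block per class; f = 1 makes every cell a
    seed, i.e. a random scatter.
    """
    config.validate()
    rng = np.random.default_rng(station_seed)
    rows, cols = config.raster_rows, config.raster_cols
    n_cells = rows * cols
    props = np.asarray(config.class_proportions, dtype=float)
    quotas = _quotas(props, n_cells)
    frag = np.atleast_1d(np.asarray(config.fragmentation_level, dtype=float))
    frag = np.full(6, frag[0]) if frag.size == 1 else frag

    grid = np.full((rows, cols), -9, dtype=int)  # -9 = unassigned sentinel
    remaining = quotas.copy()

    # seed placement
    all_cells = rng.permutation(n_cells)
    cursor = 0
    seeds: list[list[tuple[int, int]]] = [[] for _ in range(6)]
    for c in range(6):
        if quotas[c] == 0:
            continue
        k = 1 + int(round(frag[c] * (quotas[c] - 1)))
        placed = 0
        while placed < k and cursor < n_cells:
            idx = all_cells[cursor]
            cursor += 1
            r, cc = divmod(int(idx), cols)
            if grid[r, cc] != -9:
                continue
            grid[r, cc] = c
            remaining[c] -= 1
            placed += 1
            seeds[c].append((r, cc))

    frontiers: list[list[tuple[float, int, int]]] = [[] for _ in range(6)]

    def push_neighbors(c: int, r: int, cc: int) -> None:
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            nr, nc = r + dr, cc + dc
            if 0 <= nr < rows and 0 <= nc < cols and grid[nr, nc] == -9:
                heapq.heappush(frontiers[c], (rng.random(), nr, nc))

    for c in range(6):
        for r, cc in seeds[c]:
            push_neighbors(c, r, cc)

    unassigned_pool = list(all_cells[cursor:])
    pool_pos = 0
    active = [c for c in range(6) if remaining[c] > 0]
    while active:
        weights = np.array([remaining[c] for c in active], dtype=float)
        c = active[rng.choice(len(active), p=weights / weights.sum())]
        r = cc = -1
        while frontiers[c]:
            _, rr, ccc = heapq.heappop(frontiers[c])
            if grid[rr, ccc] == -9:
                r, cc = rr, ccc
                break
        if r < 0:  # stranded quota: random unassigned cell
            while pool_pos < len(unassigned_pool):
                idx = unassigned_pool[pool_pos]
                pool_pos += 1
                rr, ccc = divmod(int(idx), cols)
                if grid[rr, ccc] == -9:
                    r, cc = rr, ccc
                    break
            if r < 0:
                flat = np.flatnonzero(grid.ravel() == -9)
                rr, ccc = divmod(int(flat[0]), cols)
                r, cc = rr, ccc
        grid[r, cc] = c
        remaining[c] -= 1
        push_neighbors(c, r, cc)
        active = [c for c in range(6) if remaining[c] > 0]

    assert (grid != -9).all()
    return LandUseRaster(grid=grid, cell_size=config.cell_size, nodata=-1)


# ---------------------------------------------------------------------------
# Panel generation
# ---------------------------------------------------------------------------

def _standardize_profiles(profiles: Sequence[FragmentationProfile]) -> np.ndarray:
    """Column-standardize the six covariates across stations; NaN -> 0."""
    x = np.array([[p.as_dict()[c] for c in FragmentationProfile.COLUMNS] for p in profiles])
    mu = np.nanmean(x, axis=0)
    sd = np.nanstd(x, axis=0)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    return np.nan_to_num(z, nan=0.0)


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def suppression_fractions(
    profiles: Sequence[FragmentationProfile],
    base: float,
    betas: Sequence[float],
    link: str = "logit",
) -> np.ndarray:
    """Ground-truth suppression fraction s_i of each station.

    ``link='logit'`` (default): logit(s_i) = logit(base) + betas . z_i.
    ``link='log'``: s_i = base * exp(betas . z_i), capped at 0.95; this keeps
    log(s) exactly linear in the standardized covariates over the whole range,
    matching the log-link association models without logit saturation.
    """
    if base == 0.0:
        return np.zeros(len(profiles))
    z = _standardize_profiles(profiles)
    shift = z @ np.asarray(betas, dtype=float)
    if link == "log":
        return np.minimum(base * np.exp(shift), 0.95)
    eta = _logit(base) + shift
    return 1.0 / (1.0 + np.exp(-eta))


def _simulate_meteorology(n: int, day_index: np.ndarray, rng: np.random.Generator):
    tem = 15.0 - 10.0 * np.cos(2 * np.pi * day_index / 365.25) + rng.normal(0, 2.0, n)
    hum = np.clip(
        65.0 + 15.0 * np.sin(2 * np.pi * day_index / 365.25 + 1.0) + rng.normal(0, 8.0, n),
        5.0, 100.0,
    )
    wind = 0.5 + rng.gamma(2.0, 1.0, n)
    return tem, hum, wind


def deterministic_no2(config: ScenarioConfig, day_index: np.ndarray) -> np.ndarray:
    """The noise-free seasonal NO2 curve (no meteorology, no suppression)."""
    annual = config.annual_amplitude * np.cos(2 * np.pi * day_index / 365.25)
    weekly = config.weekly_amplitude * np.sin(2 * np.pi * (day_index % 7) / 7.0)
    return config.baseline_level + annual + weekly


def generate_no2_panel(
    config: ScenarioConfig,
    profiles: Sequence[FragmentationProfile],
    seed: int,
) -> tuple[list[StationPanel], dict[str, np.ndarray]]:
    """Generate one StationPanel per profile plus ground-truth suppression.

    NO2 = baseline + annual sinusoid + weekly sinusoid + linear meteorology
    effects (centred on reference means) + AR(1) noise, truncated at 0; the
    whole series is multiplied by (1 - s_i) from the lockdown date onward
    (and by (1 - s_pre,i) on [forecast_start, lockdown_date) when a
    pre-lockdown suppression is configured).

    Returns ``(panels, truth)`` with ``truth`` holding arrays ``s_during``,
    ``s_before`` and the per-station unsuppressed mean paths.
    """
    if len(profiles) == 0:
        raise ValueError("profiles must be nonempty")
    config.validate()
    rng = np.random.default_rng(seed)
    dates = pd.date_range(config.history_start, config.end_date, freq="D")
    n = len(dates)
    day_index = np.arange(n, dtype=float)
    lockdown = pd.Timestamp(config.lockdown_date)
    fc_start = pd.Timestamp(config.forecast_start)
    during = np.asarray(dates >= lockdown)
    before = np.asarray((dates >= fc_start) & (dates < lockdown))

    s_during = suppression_fractions(
        profiles, config.suppression_base, config.suppression_betas,
        link=config.suppression_link,
    )
    s_before = suppression_fractions(
        profiles, config.pre_suppression_base, config.pre_suppression_betas,
        link=config.suppression_link,
    )
    base_curve = deterministic_no2(config, day_index)
    c_tem, c_hum, c_wind = config.met_effect_coeffs
    ref_tem, ref_hum, ref_wind = MET_REFERENCE

    panels: list[StationPanel] = []
    mean_paths = np.empty((len(profiles), n))
    for i in range(len(profiles)):
        tem, hum, wind = _simulate_meteorology(n, day_index, rng)
        mean = (
            base_curve
            + c_tem * (tem - ref_tem)
            + c_hum * (hum - ref_hum)
            + c_wind * (wind - ref_wind)
        )
        if config.noise_sd > 0:
            innov = rng.normal(0, config.noise_sd, n)
            noise = np.empty(n)
            noise[0] = innov[0]
            for t in range(1, n):
                noise[t] = config.ar_coefficient * noise[t - 1] + innov[t]
        else:
            noise = np.zeros(n)
        y = np.maximum(mean + noise, 0.0)
        factor = np.ones(n)
        factor[before] = 1.0 - s_before[i]
        factor[during] = 1.0 - s_during[i]
        panels.append(
            StationPanel(
                station_id=f"S{i + 1:03d}",
                dates=dates,
                no2_observed=y * factor,
                temperature=tem,
                humidity=hum,
                wind_speed=wind,
            )
        )
        mean_paths[i] = np.maximum(mean, 0.0)
    truth = {"s_during": s_during, "s_before": s_before, "mean_paths": mean_paths}
    return panels, truth


# ---------------------------------------------------------------------------
# Controls and the full scenario
# ---------------------------------------------------------------------------

def _generate_controls(
    config: ScenarioConfig,
    panels: Sequence[StationPanel],
    profiles: Sequence[FragmentationProfile],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-station controlling variables.

    Pollutants and population get log-normal marginals (strictly positive,
    right-tailed, as in ambient data); meteorology columns are the panel
    means over the evaluation window. A latent standardized suppression
    signal u_i loads mildly on the pollutant columns so that confounder
    adjustment in the association models is actually exercised.
    """
    z = _standardize_profiles(profiles)
    u = z @ np.asarray(config.suppression_betas, dtype=float)
    su = float(np.std(u))
    if su > 0:
        u = u / su
    n = len(profiles)
    fc_start = pd.Timestamp(config.forecast_start)
    rows = []
    for i, panel in enumerate(panels):
        mask = np.asarray(panel.dates >= fc_start)
        rows.append(
            {
                "station_id": panel.station_id,
                "pop": float(np.exp(rng.normal(11.0, 0.5) + 0.2 * u[i])),
                "aqi": float(np.exp(rng.normal(4.2, 0.25) + 0.15 * u[i])),
                "pm25": float(np.exp(rng.normal(3.6, 0.3) + 0.15 * u[i])),
                "pm10": float(np.exp(rng.normal(4.1, 0.3) + 0.15 * u[i])),
                "o3": float(np.exp(rng.normal(4.0, 0.25) - 0.1 * u[i])),
                "so2": float(np.exp(rng.normal(2.6, 0.4) + 0.1 * u[i])),
                "co": float(np.exp(rng.normal(0.0, 0.3) + 0.1 * u[i])),
                "tem": float(panel.temperature[mask].mean()),
                "hum": float(panel.humidity[mask].mean()),
                "wind": float(panel.wind_speed[mask].mean()),
            }
        )
    return pd.DataFrame(rows, columns=("station_id",) + CONTROL_COLUMNS)


def generate_scenario(config: ScenarioConfig) -> Scenario:
    """Generate a self-consistent bundle: rasters, fragmentation profiles,
    NO2 panels whose lockdown suppression is tied to the profiles, controls,
    and the ground truth needed for recovery tests.

    Per-station and per-class fragmentation levels are drawn independently
    from ``fragmentation_range`` (when set) and class proportions receive
    mild Dirichlet jitter, so the six covariates vary across stations and
    are not collapsed onto a single latent fragmentation axis.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    station_ids = [f"S{i + 1:03d}" for i in range(config.n_stations)]

    if config.fragmentation_range is not None:
        lo, hi = config.fragmentation_range
        frag_levels = rng.uniform(lo, hi, size=(config.n_stations, 6))
    else:
        base = np.atleast_1d(np.asarray(config.fragmentation_level, dtype=float))
        frag_levels = np.tile(np.full(6, base[0]) if base.size == 1 else base,
                              (config.n_stations, 1))
    props = np.asarray(config.class_proportions, dtype=float)

    rasters: dict[str, LandUseRaster] = {}
    profiles: list[FragmentationProfile] = []
    center = (config.raster_rows // 2, config.raster_cols // 2)
    for i, sid in enumerate(station_ids):
        if config.proportion_jitter and config.proportion_jitter > 0:
            p_i = rng.dirichlet(np.maximum(props * config.proportion_jitter, 1e-3))
        else:
            p_i = props
        station_cfg = dataclasses.replace(
            config,
            fragmentation_level=tuple(frag_levels[i]),
            class_proportions=tuple(p_i),
            fragmentation_range=None,
            proportion_jitter=0.0,
        )
        station_seed = int(rng.integers(0, 2**31 - 1))
        raster = generate_landuse_raster(station_cfg, station_seed)
        rasters[sid] = raster
        profiles.append(fragmentation_profile(raster, center, config.buffer_radius))

    panel_seed = int(rng.integers(0, 2**31 - 1))
    panels, truth = generate_no2_panel(config, profiles, panel_seed)
    controls = _generate_controls(config, panels, profiles, rng)
    suppression = pd.DataFrame(
        {
            "station_id": station_ids,
            "s_during": truth["s_during"],
            "s_before": truth["s_before"],
        }
    )
    return Scenario(
        config=config,
        station_ids=station_ids,
        panels=panels,
        rasters=rasters,
        profiles=dict(zip(station_ids, profiles)),
        controls=controls,
        suppression=suppression,
        counterfactual={sid: truth["mean_paths"][i] for i, sid in enumerate(station_ids)},
    )


# ---------------------------------------------------------------------------
# Bundle I/O
# ---------------------------------------------------------------------------

def write_scenario(scenario: Scenario, out_dir) -> dict[str, Path]:
    """Write the bundle: panels.csv, controls.csv, ground_truth.csv, one
    ASCII grid per station, and the scenario config as JSON."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover
        raise OSError(f"cannot create scenario directory {out}: {exc}") from exc
    paths: dict[str, Path] = {}
    panel_frame = pd.concat([p.to_frame() for p in scenario.panels], ignore_index=True)
    paths["panels"] = out / "panels.csv"
    panel_frame.to_csv(paths["panels"], index=False, float_format="%.10g")
    paths["controls"] = out / "controls.csv"
    scenario.controls.to_csv(paths["controls"], index=False, float_format="%.10g")
    paths["ground_truth"] = out / "ground_truth.csv"
    scenario.suppression.to_csv(paths["ground_truth"], index=False, float_format="%.10g")
    raster_dir = out / "rasters"
    raster_dir.mkdir(exist_ok=True)
    for sid, raster in scenario.rasters.items():
        write_ascii_grid(raster, raster_dir / f"{sid}.asc")
    paths["rasters"] = raster_dir
    paths["config"] = out / "scenario_config.json"
    paths["config"].write_text(json.dumps(scenario.config.to_dict(), indent=2) + "\n")
    return paths


def read_panels(path) -> list[StationPanel]:
    """Read the long-format panels CSV back into StationPanel objects."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"panel CSV not found: {path}")
    frame = pd.read_csv(path, parse_dates=["date"])
    panels = []
    for sid, grp in frame.groupby("station_id", sort=True):
        grp = grp.sort_values("date")
        panels.append(
            StationPanel(
                station_id=str(sid),
                dates=pd.DatetimeIndex(grp["date"]),
                no2_observed=grp["no2"].to_numpy(),
                temperature=grp["temperature"].to_numpy(),
                humidity=grp["humidity"].to_numpy(),
                wind_speed=grp["wind_speed"].to_numpy(),
            )
        )
    return panels


def read_controls(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"controls CSV not found: {path}")
    frame = pd.read_csv(path)
    frame["station_id"] = frame["station_id"].astype(str)
    return frame


def read_rasters(raster_dir) -> dict[str, LandUseRaster]:
    raster_dir = Path(raster_dir)
    if not raster_dir.is_dir():
        raise FileNotFoundError(f"raster directory not found: {raster_dir}")
    out = {}
    for p in sorted(raster_dir.glob("*.asc")):
        out[p.stem] = read_ascii_grid(p)
    if not out:
        raise FileNotFoundError(f"no .asc rasters in {raster_dir}")
    return out
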