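"""Synthetic-data generators for every input of the thermal-niche pipeline.

The generators produce, with known ground truth: tethered-flight temperature
traces (thorax / abdomen / environment), thermogram frame stacks around those
traces, site x species abundance matrices with planted indicator species,
pitfall capture schedules with a planted day/night split, and 5-minute
ground-temperature sensor logs with a diel cycle.  Defaults mirror the field
study the pipeline is designed for: 3 habitats x 3 sites, 5-day activity
sampling split at 7:00/18:00, 12-day sensor logs, and >=40 s of continuous
flight per individual.  Every generator is seeded and returns (or writes) a
truth sidecar holding the exact parameters used, so downstream estimators can
be tested by round-trip rather than re-derivation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .thermography import FlightWindow, FrameStack, ROISpec, TemperatureTrace

__all__ = [
    "SpeciesProfile",
    "TraceSimConfig",
    "StackGeometry",
    "CommunitySimConfig",
    "CaptureSimConfig",
    "SensorSimConfig",
    "FlightTraceSet",
    "simulate_flight_trace",
    "simulate_frame_stack",
    "simulate_community",
    "simulate_captures",
    "simulate_sensor_log",
    "default_species_pool",
    "load_species_reference",
]

MECHANISMS = ("APHT", "AAHT", "NONE")
ACTIVITIES = ("diurnal", "ENC")
HABITATS = ("native_forest", "agroforestry", "open_pasture")

#: fraction of thoracic excess temperature appearing on the abdomen, by
#: mechanism: APHT retains heat in the thorax, AAHT pumps it to the abdomen.
ABDOMEN_EXCESS_FRACTION = {"APHT": 0.1, "AAHT": 0.8, "NONE": 0.35}


def _require_finite(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not math.isfinite(float(value)):
            raise ValueError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class SpeciesProfile:
    """Ground-truth physiology and ecology of one simulated species.

    ``endothermy_true`` is the asymptotic thorax-minus-environment excess
    temperature (degC) during flight; ``slope_*_true`` are the linear
    temperature trends (degC/s) after take-off; ``mechanism_true`` controls
    how much thoracic heat shows up on the abdomen.
    """

    name: str
    activity_true: str = "diurnal"
    habitat_true: str = "native_forest"
    mass_mean: float = 0.3
    mass_sd: float = 0.05
    endothermy_true: float = 4.0
    warmup_amplitude: float = 4.0
    warmup_rate: float = 0.5
    slope_th_true: float = 0.0
    slope_abd_true: float = 0.0
    mechanism_true: str = "NONE"
    noise_sd: float = 0.3

    def __post_init__(self) -> None:
        _require_finite(mass_mean=self.mass_mean, mass_sd=self.mass_sd,
                        endothermy_true=self.endothermy_true,
                        warmup_amplitude=self.warmup_amplitude,
                        warmup_rate=self.warmup_rate,
                        slope_th_true=self.slope_th_true,
                        slope_abd_true=self.slope_abd_true,
                        noise_sd=self.noise_sd)
        if self.mass_mean <= 0:
            raise ValueError("mass_mean must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.endothermy_true < 0:
            raise ValueError("endothermy_true must be non-negative")
        if self.activity_true not in ACTIVITIES:
            raise ValueError(f"activity_true must be one of {ACTIVITIES}")
        if self.mechanism_true not in MECHANISMS:
            raise ValueError(f"mechanism_true must be one of {MECHANISMS}")
        if self.mechanism_true == "APHT":
            if not (self.slope_th_true > 0 and abs(self.slope_abd_true) <= 0.25 * self.slope_th_true):
                raise ValueError("APHT requires slope_th_true > 0 and near-zero slope_abd_true")
        if self.mechanism_true == "AAHT":
            if not (self.slope_th_true > 0 and self.slope_abd_true > 0):
                raise ValueError("AAHT requires positive thorax and abdomen slopes")


@dataclass(frozen=True)
class TraceSimConfig:
    """Sampling layout of one simulated flight recording.

    ``duration`` is seconds of continuous flight *after* take-off (the trace
    spans [0, takeoff_time + duration]); >=40 s keeps the flight analysable.
    ``frame_rate`` defaults to 25 Hz, a typical thermal-video rate.
    """

    duration: float = 45.0
    frame_rate: float = 25.0
    takeoff_time: float = 5.0
    t_env_base: float = 25.0
    env_drift: float = 0.0  # degC/s linear drift of the background
    seed: int = 0

    def __post_init__(self) -> None:
        _require_finite(duration=self.duration, frame_rate=self.frame_rate,
                        takeoff_time=self.takeoff_time, t_env_base=self.t_env_base,
                        env_drift=self.env_drift)
        if self.duration < 40.0:
            raise ValueError("duration must be >= 40 s of continuous flight")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.takeoff_time < 0:
            raise ValueError("takeoff_time must be non-negative")

    @property
    def times(self) -> np.ndarray:
        n = int(round((self.takeoff_time + self.duration) * self.frame_rate)) + 1
        return np.arange(n, dtype=float) / self.frame_rate


@dataclass(frozen=True)
class FlightTraceSet:
    """Simulated thorax/abdomen/environment traces plus their ground truth."""

    t_th: TemperatureTrace
    t_abd: TemperatureTrace
    t_env: TemperatureTrace
    window: FlightWindow
    truth: dict

    def traces(self) -> tuple[TemperatureTrace, TemperatureTrace, TemperatureTrace]:
        return self.t_th, self.t_abd, self.t_env


def simulate_flight_trace(profile: SpeciesProfile, cfg: TraceSimConfig) -> FlightTraceSet:
    """Simulate one tethered flight.

    Environment: t_env_base + linear drift + N(0, noise_sd) per frame.
    Thorax:      environment + endothermy*(1 - exp(-warmup_rate * t)) and,
                 after take-off, + slope_th_true * (t - takeoff).
    Abdomen:     same structure with the mechanism-dependent excess fraction
                 and slope_abd_true.

    Noise is i.i.d. Gaussian per frame and per trace -- the simplest model
    that exercises the downstream estimators.
    """
    rng = np.random.default_rng(cfg.seed)
    t = cfg.times
    flight = np.clip(t - cfg.takeoff_time, 0.0, None)

    env_clean = cfg.t_env_base + cfg.env_drift * t
    warmup = 1.0 - np.exp(-profile.warmup_rate * t)
    th_excess = profile.endothermy_true * warmup + profile.slope_th_true * flight
    abd_frac = ABDOMEN_EXCESS_FRACTION[profile.mechanism_true]
    abd_excess = abd_frac * profile.endothermy_true * warmup + profile.slope_abd_true * flight

    noise = rng.normal(0.0, profile.noise_sd, size=(3, t.size)) if profile.noise_sd > 0 \
        else np.zeros((3, t.size))
    th = env_clean + th_excess + noise[0]
    abd = env_clean + abd_excess + noise[1]
    env = env_clean + noise[2]

    window = FlightWindow(takeoff_time=cfg.takeoff_time, end_time=float(t[-1]),
                          qualifies=(float(t[-1]) - cfg.takeoff_time) >= 40.0 - 1e-9)
    mask = window.mask(t)
    truth = {
        **{f"profile_{k}": v for k, v in asdict(profile).items()},
        **{f"cfg_{k}": v for k, v in asdict(cfg).items()},
        "abdomen_excess_fraction": abd_frac,
        # analytic mean excess over the flight window of the noise-free signal
        "expected_endothermy": float(np.mean(th_excess[mask])),
        "n_frames_in_window": int(mask.sum()),
    }
    return FlightTraceSet(
        t_th=TemperatureTrace("thorax", t, th),
        t_abd=TemperatureTrace("abdomen", t, abd),
        t_env=TemperatureTrace("environment", t, env),
        window=window,
        truth=truth,
    )


@dataclass(frozen=True)
class StackGeometry:
    """Frame geometry and ROI placement for simulated thermogram stacks."""

    rows: int = 60
    cols: int = 80
    centers: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {"thorax": (20, 20), "abdomen": (20, 40),
                                 "environment": (45, 60)})
    jitter_px: int = 0
    patch_spread: float = 2.0  # degC below the patch maximum for other pixels

    def rois(self) -> list[ROISpec]:
        return [ROISpec(label, r, c) for label, (r, c) in self.centers.items()]


def simulate_frame_stack(traces: FlightTraceSet | Sequence[TemperatureTrace],
                         geometry: StackGeometry = StackGeometry(),
                         seed: int = 0) -> tuple[FrameStack, list[ROISpec]]:
    """Embed a trace triplet into a synthetic thermogram frame stack.

    Each frame is background (the environment trace value) plus three
    disjoint 3x3 patches whose per-pixel values are <= the nominal trace
    value, the patch *maximum* equalling the trace value at that frame --
    matching the max-over-ROI extraction rule.  ``jitter_px`` shifts each
    patch center by up to that many pixels per frame; a 1-px jitter is
    absorbed by the 3x3 max window.
    """
    trio = traces.traces() if isinstance(traces, FlightTraceSet) else tuple(traces)
    labels = [tr.roi_label for tr in trio]
    if sorted(labels) != sorted(geometry.centers):
        raise ValueError("trace labels must match geometry ROI centers")
    base_times = trio[0].times
    for tr in trio[1:]:
        if not np.array_equal(tr.times, base_times):
            raise ValueError("traces must share a time base")

    rois = geometry.rois()
    margin = geometry.jitter_px
    for roi in rois:
        r, c = roi.center_row, roi.center_col
        if not (1 + margin <= r <= geometry.rows - 2 - margin
                and 1 + margin <= c <= geometry.cols - 2 - margin):
            raise ValueError(f"ROI {roi.label!r} (with jitter envelope) outside frame")
    for i, a in enumerate(rois):
        for b in rois[i + 1:]:
            if abs(a.center_row - b.center_row) < 3 + 2 * margin and \
               abs(a.center_col - b.center_col) < 3 + 2 * margin:
                raise ValueError(f"ROIs {a.label!r} and {b.label!r} overlap")

    rng = np.random.default_rng(seed)
    env = next(tr for tr in trio if tr.roi_label == "environment")
    n = base_times.size
    frames = np.broadcast_to(env.values[:, None, None],
                             (n, geometry.rows, geometry.cols)).copy()
    by_label = {tr.roi_label: tr for tr in trio}
    for label, (r, c) in geometry.centers.items():
        vals = by_label[label].values
        offsets = rng.uniform(0.0, geometry.patch_spread, size=(n, 3, 3))
        # the patch center carries the exact nominal value, so the maximum
        # stays inside the nominal 3x3 window under jitter of <= 1 px
        offsets[:, 1, 1] = 0.0
        patch = vals[:, None, None] - offsets
        if margin:
            for k in range(n):
                dr = int(rng.integers(-margin, margin + 1))
                dc = int(rng.integers(-margin, margin + 1))
                rr, cc = r + dr, c + dc
                win = frames[k, rr - 1:rr + 2, cc - 1:cc + 2]
                np.maximum(win, patch[k], out=win)
        else:
            win = frames[:, r - 1:r + 2, c - 1:c + 2]
            np.maximum(win, patch, out=win)
    return FrameStack(frames=frames, frame_times=base_times.copy()), rois


# ---------------------------------------------------------------------------
# community / captures / sensor generators
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CommunitySimConfig:
    """Layout of a simulated site x species abundance survey.

    Counts are negative-binomial around a per-species x habitat mean:
    ``home_mean`` in the species' own habitat, ``home_mean * cross_factor``
    elsewhere; ``dispersion`` is the NB size parameter (smaller = noisier).
    """

    species_pool: Sequence[SpeciesProfile] = ()
    habitats: Sequence[str] = HABITATS
    sites_per_habitat: int = 3
    home_mean: float = 30.0
    cross_factor: float = 0.05
    dispersion: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sites_per_habitat < 2:
            raise ValueError("sites_per_habitat must be >= 2")
        if len(self.habitats) < 2:
            raise ValueError("at least 2 habitats required")
        if self.home_mean <= 0 or self.dispersion <= 0:
            raise ValueError("home_mean and dispersion must be positive")


def simulate_community(cfg: CommunitySimConfig) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Simulate an abundance survey.

    Returns ``(counts, habitat_of_site, truth)`` where ``counts`` is a
    site x species integer DataFrame, ``habitat_of_site`` maps site -> habitat
    and ``truth`` records each species' home habitat and planted means.
    """
    pool = list(cfg.species_pool) or default_species_pool()
    rng = np.random.default_rng(cfg.seed)
    sites, site_hab = [], []
    for hab in cfg.habitats:
        for s in range(cfg.sites_per_habitat):
            sites.append(f"{hab}_site{s + 1}")
            site_hab.append(hab)
    habitat_of_site = pd.Series(site_hab, index=pd.Index(sites, name="site"),
                                name="habitat")
    counts = pd.DataFrame(0, index=habitat_of_site.index,
                          columns=[p.name for p in pool], dtype=int)
    truth_rows = []
    for p in pool:
        for site, hab in habitat_of_site.items():
            mean = cfg.home_mean if hab == p.habitat_true else cfg.home_mean * cfg.cross_factor
            # NB via gamma-Poisson mixture: mean m, size k
            lam = rng.gamma(cfg.dispersion, mean / cfg.dispersion)
            counts.loc[site, p.name] = int(rng.poisson(lam))
        truth_rows.append({"species": p.name, "habitat_true": p.habitat_true,
                           "home_mean": cfg.home_mean,
                           "cross_mean": cfg.home_mean * cfg.cross_factor})
    return counts, habitat_of_site, pd.DataFrame(truth_rows)


@dataclass(frozen=True)
class CaptureSimConfig:
    """Layout of a simulated day/night pitfall sampling campaign."""

    days: int = 5
    period_boundaries: tuple[int, int] = (7, 18)  # local clock hours
    total_captures: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.days < 1:
            raise ValueError("days must be >= 1")
        if self.total_captures < 1:
            raise ValueError("total_captures must be >= 1")
        b0, b1 = self.period_boundaries
        if not (0 <= b0 < b1 <= 24):
            raise ValueError("period boundaries must satisfy 0 <= start < end <= 24")


def simulate_captures(cfg: CaptureSimConfig,
                      species_pool: Sequence[SpeciesProfile] = (),
                      diurnal_fraction: Optional[Mapping[str, float]] = None,
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate timestamped pitfall captures over ``cfg.days`` full days.

    Per species the number of period-1 (daytime) captures is binomial with
    that species' ``diurnal_fraction`` (default 0.85 for diurnal truth, 0.15
    for evening/nocturnal/crepuscular); capture times are uniform within the
    period.  Returns ``(captures, truth)`` with ``captures`` holding
    ``species,timestamp`` rows.
    """
    pool = list(species_pool) or default_species_pool()
    rng = np.random.default_rng(cfg.seed)
    b0, b1 = cfg.period_boundaries
    day_hours = b1 - b0
    night_hours = 24 - day_hours
    start = pd.Timestamp("2015-11-01")
    rows, truth_rows = [], []
    for p in pool:
        frac = None if diurnal_fraction is None else diurnal_fraction.get(p.name)
        if frac is None:
            frac = 0.85 if p.activity_true == "diurnal" else 0.15
        if not (0.0 <= frac <= 1.0):
            raise ValueError("diurnal_fraction must be in [0, 1]")
        n1 = int(rng.binomial(cfg.total_captures, frac))
        n2 = cfg.total_captures - n1
        for n, in_day in ((n1, True), (n2, False)):
            days = rng.integers(0, cfg.days, size=n)
            u = rng.uniform(0.0, 1.0, size=n)
            if in_day:
                hours = b0 + u * day_hours
            else:
                hours = (b1 + u * night_hours) % 24.0
            for d, h in zip(days, hours):
                rows.append({"species": p.name,
                             "timestamp": start + pd.Timedelta(days=int(d))
                             + pd.Timedelta(hours=float(h))})
        truth_rows.append({"species": p.name, "diurnal_fraction": frac,
                           "activity_true": p.activity_true,
                           "n_period1": n1, "n_period2": n2})
    captures = pd.DataFrame(rows).sort_values("timestamp").reset_index(drop=True)
    return captures, pd.DataFrame(truth_rows)


@dataclass(frozen=True)
class SensorSimConfig:
    """Layout of a simulated ground-temperature logger record.

    The diel cycle is a cosine peaking at 13:00 (mid-day window) with
    ``diel_amplitude`` = half the peak-to-trough range, so the day maximum is
    ``diel_mean + diel_amplitude`` and the night minimum is
    ``diel_mean - diel_amplitude``.
    """

    days: int = 12
    interval_minutes: int = 5
    diel_mean: float = 24.0
    diel_amplitude: float = 6.0
    noise_sd: float = 0.2
    peak_hour: float = 13.0
    site: str = "site1"
    habitat: str = "native_forest"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.days < 1:
            raise ValueError("days must be >= 1")
        if self.interval_minutes <= 0 or 1440 % self.interval_minutes != 0:
            raise ValueError("interval_minutes must divide 1440")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def simulate_sensor_log(cfg: SensorSimConfig) -> tuple[pd.DataFrame, dict]:
    """Simulate a fixed-interval sensor log with a sinusoidal diel cycle.

    Returns ``(log, truth)``; ``log`` has ``timestamp,temp_c,site,habitat``
    columns and ``truth`` contains the analytic (noise-free) day/night
    statistics over the exact sample grid.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.days * (1440 // cfg.interval_minutes)
    start = pd.Timestamp("2015-10-01")
    timestamps = start + pd.to_timedelta(np.arange(n) * cfg.interval_minutes, unit="m")
    hours = (np.arange(n) * cfg.interval_minutes / 60.0) % 24.0
    clean = cfg.diel_mean + cfg.diel_amplitude * np.cos(
        2.0 * np.pi * (hours - cfg.peak_hour) / 24.0)
    temps = clean + (rng.normal(0.0, cfg.noise_sd, size=n) if cfg.noise_sd > 0 else 0.0)
    log = pd.DataFrame({"timestamp": timestamps, "temp_c": temps,
                        "site": cfg.site, "habitat": cfg.habitat})
    day = (hours >= 7.0) & (hours < 18.0)
    truth = {
        "day_mean": float(clean[day].mean()), "day_max": float(clean[day].max()),
        "day_min": float(clean[day].min()), "night_mean": float(clean[~day].mean()),
        "night_max": float(clean[~day].max()), "night_min": float(clean[~day].min()),
    }
    truth["amplitude"] = truth["day_max"] - truth["night_min"]
    return log, truth


# ---------------------------------------------------------------------------
# default species pool from the bundled reference table
# ---------------------------------------------------------------------------

def load_species_reference() -> pd.DataFrame:
    """Published thermal-niche summary table for 17 Atlantic-forest dung
    beetle species (per-species means and SDs of mass, endothermy and the
    three flight slopes, plus the slope-pair rank-test statistics)."""
    from importlib.resources import files

    path = files("thermoniche.data").joinpath("species_reference.csv")
    with path.open("rb") as fh:
        return pd.read_csv(fh)


def default_species_pool() -> list[SpeciesProfile]:
    """Species pool whose ground truth mirrors the bundled reference table."""
    ref = load_species_reference()
    pool = []
    for row in ref.itertuples(index=False):
        sth, sabd = float(row.slope_th), float(row.slope_abd)
        if row.P_th_abd < 0.05 and sth > 0 and row.P_abd_env >= 0.05:
            mech, sabd_true = "APHT", 0.0
        elif row.P_th_abd >= 0.05 and sth > 0 and sabd > 0 and row.P_abd_env < 0.05:
            mech, sabd_true = "AAHT", sabd
        else:
            mech, sabd_true = "NONE", sabd
        pool.append(SpeciesProfile(
            name=row.species, activity_true=row.activity, habitat_true=row.habitat,
            mass_mean=float(row.mass_mean_g), mass_sd=float(row.mass_sd_g),
            endothermy_true=float(row.endothermy_mean_c),
            warmup_amplitude=float(row.endothermy_mean_c), warmup_rate=0.5,
            slope_th_true=sth, slope_abd_true=sabd_true, mechanism_true=mech,
            noise_sd=0.3))
    return pool
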