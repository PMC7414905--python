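"""Per-individual flight physiology and species-level thermoregulation calls.

For each qualifying flight (>= 40 s continuous) this module computes:

* **endothermy** (excess temperature): mean thorax-minus-environment
  temperature over the flight window, the classical measure of how far a
  flying insect holds its thorax above ambient;
* **sT_th, sT_abd, sT_env**: ordinary-least-squares slopes (degC/s) of the
  thorax, abdomen and environment traces over [take-off, take-off + 40 s];
* **slope difference** sT_th - sT_abd, a proxy for how much thoracic heat is
  *not* transferred to the abdomen.

At the species level the pairs of slope samples (thorax vs abdomen, abdomen
vs environment) are compared with Kruskal-Wallis H tests, and the rule table
below turns the outcomes into a physiological thermoregulation mechanism:

* **APHT** (abdominal passive heat transfer, heat retained in the thorax):
  thorax and abdomen slopes differ, the mean thorax slope is positive, and
  abdomen and environment slopes are similar.
* **AAHT** (abdominal active heat transfer, heat pumped to the abdomen via
  hemolymph): thorax and abdomen slopes are similar and both positive, and
  abdomen and environment slopes differ.
* anything else is **UNDEFINED** (no efficient physiological mechanism).

"Similar" means Kruskal-Wallis P >= alpha (default 0.05).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .thermography import FlightWindow, TemperatureTrace

__all__ = [
    "FlightTraces",
    "IndividualPhysiology",
    "SlopeComparison",
    "SpeciesMechanismCall",
    "compute_endothermy",
    "fit_slope",
    "compare_slope_pair",
    "classify_mechanism",
    "classify_from_summary",
    "mechanism_from_rule",
    "slope_difference",
    "compute_individual_physiology",
    "species_mechanism_table",
    "SLOPE_WINDOW_SECONDS",
]

logger = logging.getLogger(__name__)

#: slopes are fitted from take-off to this many seconds into continuous flight
SLOPE_WINDOW_SECONDS = 40.0


@dataclass(frozen=True)
class FlightTraces:
    """Aligned thorax/abdomen/environment traces for one qualifying flight."""

    individual_id: str
    species: str
    mass: float
    activity: str
    habitat: str
    window: FlightWindow
    t_th: TemperatureTrace
    t_abd: TemperatureTrace
    t_env: TemperatureTrace

    def __post_init__(self) -> None:
        if not self.window.qualifies:
            raise ValueError("flight window does not meet the >= 40 s filter")
        for tr in (self.t_abd, self.t_env):
            if not np.array_equal(tr.times, self.t_th.times):
                raise ValueError("traces must share a common time base")


@dataclass(frozen=True)
class IndividualPhysiology:
    """Fitted thermal-niche variables for one individual's flight."""

    individual_id: str
    species: str
    mass: float
    endothermy: float
    slope_th: float
    slope_abd: float
    slope_env: float

    @property
    def slope_diff(self) -> float:
        return self.slope_th - self.slope_abd


@dataclass(frozen=True)
class SlopeComparison:
    """Kruskal-Wallis comparison of one slope pair for one species."""

    pair: str  # 'th_vs_abd' or 'abd_vs_env'
    H: float
    df: int
    P: float
    similar: bool  # P >= alpha


@dataclass(frozen=True)
class SpeciesMechanismCall:
    """Species-level thermoregulation-mechanism call with its evidence."""

    species: str
    n: int
    mean_slope_th: float
    mean_slope_abd: float
    sign_th: str
    sign_abd: str
    cmp_th_abd: SlopeComparison
    cmp_abd_env: SlopeComparison
    mechanism: str
    alpha: float


def compute_endothermy(ft: FlightTraces) -> float:
    """Mean thorax-minus-environment temperature over the flight window."""
    mask = ft.window.mask(ft.t_th.times)
    if not mask.any():
        raise ValueError("no samples inside the flight window")
    return float(np.mean(ft.t_th.values[mask] - ft.t_env.values[mask]))


def fit_slope(trace: TemperatureTrace, window: FlightWindow,
              max_span: float = SLOPE_WINDOW_SECONDS) -> float:
    """OLS slope (degC/s) of a trace over [take-off, take-off + max_span]."""
    t0 = window.takeoff_time
    t1 = min(window.end_time, t0 + max_span)
    mask = (trace.times >= t0 - 1e-9) & (trace.times <= t1 + 1e-9)
    t = trace.times[mask]
    y = trace.values[mask]
    if t.size < 3:
        raise ValueError("need >= 3 samples inside the slope window")
    if np.ptp(t) == 0:
        raise ValueError("degenerate time axis (all sample times equal)")
    tc = t - t.mean()
    return float(np.dot(tc, y - y.mean()) / np.dot(tc, tc))


def compare_slope_pair(group_a: Sequence[float], group_b: Sequence[float],
                       alpha: float = 0.05, pair: str = "") -> SlopeComparison:
    """Tie-corrected Kruskal-Wallis H test between two groups of slopes.

    If every value in both groups is identical the statistic is undefined;
    by convention H=0, P=1 (the groups are trivially similar) and the event
    is logged.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        logger.warning("all slope values identical in pair %r; H set to 0", pair)
        return SlopeComparison(pair=pair, H=0.0, df=1, P=1.0, similar=True)
    h, p = stats.kruskal(a, b)
    return SlopeComparison(pair=pair, H=float(h), df=1, P=float(p),
                           similar=bool(p >= alpha))


def mechanism_from_rule(th_abd_similar: bool, abd_env_similar: bool,
                        mean_slope_th: float, mean_slope_abd: float) -> str:
    """Pure rule table mapping slope-pair evidence to a mechanism label."""
    if (not th_abd_similar) and mean_slope_th > 0 and abd_env_similar:
        return "APHT"
    if th_abd_similar and mean_slope_th > 0 and mean_slope_abd > 0 \
            and not abd_env_similar:
        return "AAHT"
    return "UNDEFINED"


def classify_from_summary(mean_slope_th: float, mean_slope_abd: float,
                          p_th_abd: float, p_abd_env: float,
                          alpha: float = 0.05) -> str:
    """Mechanism call from summary-level inputs (mean slopes + pair P values),
    e.g. a published species table rather than raw per-individual slopes."""
    return mechanism_from_rule(p_th_abd >= alpha, p_abd_env >= alpha,
                               mean_slope_th, mean_slope_abd)


def classify_mechanism(species: str,
                       slopes_th: Sequence[float],
                       slopes_abd: Sequence[float],
                       slopes_env: Sequence[float],
                       alpha: float = 0.05) -> SpeciesMechanismCall:
    """Classify one species' thermoregulation mechanism from individual slopes."""
    th = np.asarray(slopes_th, dtype=float)
    abd = np.asarray(slopes_abd, dtype=float)
    env = np.asarray(slopes_env, dtype=float)
    if not (th.size == abd.size == env.size):
        raise ValueError("slope vectors must have one entry per individual")
    if th.size < 2:
        raise ValueError("need >= 2 individuals with all three slopes")
    cmp_th_abd = compare_slope_pair(th, abd, alpha=alpha, pair="th_vs_abd")
    cmp_abd_env = compare_slope_pair(abd, env, alpha=alpha, pair="abd_vs_env")
    mean_th = float(th.mean())
    mean_abd = float(abd.mean())
    mechanism = mechanism_from_rule(cmp_th_abd.similar, cmp_abd_env.similar,
                                    mean_th, mean_abd)
    return SpeciesMechanismCall(
        species=species, n=int(th.size), mean_slope_th=mean_th,
        mean_slope_abd=mean_abd,
        sign_th="+" if mean_th > 0 else "-",
        sign_abd="+" if mean_abd > 0 else "-",
        cmp_th_abd=cmp_th_abd, cmp_abd_env=cmp_abd_env,
        mechanism=mechanism, alpha=alpha)


def slope_difference(slope_th: float, slope_abd: float) -> float:
    """sT_th - sT_abd: larger values mean less heat moved to the abdomen."""
    return slope_th - slope_abd


def compute_individual_physiology(ft: FlightTraces,
                                  slope_window: float = SLOPE_WINDOW_SECONDS
                                  ) -> IndividualPhysiology:
    """All fitted thermal-niche variables for one qualifying flight."""
    return IndividualPhysiology(
        individual_id=ft.individual_id, species=ft.species, mass=ft.mass,
        endothermy=compute_endothermy(ft),
        slope_th=fit_slope(ft.t_th, ft.window, slope_window),
        slope_abd=fit_slope(ft.t_abd, ft.window, slope_window),
        slope_env=fit_slope(ft.t_env, ft.window, slope_window))


def species_mechanism_table(physiology: pd.DataFrame,
                            alpha: float = 0.05) -> pd.DataFrame:
    """Species-level mechanism calls from a per-individual physiology table.

    ``physiology`` needs columns ``species, slope_th, slope_abd, slope_env``;
    species with fewer than 2 individuals are reported with mechanism
    ``UNDEFINED`` and NaN test statistics.
    """
    rows = []
    for species, grp in physiology.groupby("species", sort=True):
        if len(grp) < 2:
            logger.warning("species %r has < 2 individuals; mechanism undefined",
                           species)
            rows.append({"species": species, "n": len(grp),
                         "mean_slope_th": grp["slope_th"].mean(),
                         "mean_slope_abd": grp["slope_abd"].mean(),
                         "H_th_abd": np.nan, "P_th_abd": np.nan,
                         "H_abd_env": np.nan, "P_abd_env": np.nan,
                         "mechanism": "UNDEFINED", "alpha": alpha})
            continue
        call = classify_mechanism(species, grp["slope_th"], grp["slope_abd"],
                                  grp["slope_env"], alpha=alpha)
        rows.append({"species": species, "n": call.n,
                     "mean_slope_th": call.mean_slope_th,
                     "mean_slope_abd": call.mean_slope_abd,
                     "H_th_abd": call.cmp_th_abd.H, "P_th_abd": call.cmp_th_abd.P,
                     "H_abd_env": call.cmp_abd_env.H, "P_abd_env": call.cmp_abd_env.P,
                     "mechanism": call.mechanism, "alpha": alpha})
    return pd.DataFrame(rows)
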