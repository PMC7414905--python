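"""Habitat affinity (IndVal) and daily-activity classification.

The indicator value of species *i* for habitat *j* is

    IndVal_ij = A_ij * B_ij * 100

with the Dufrene-Legendre definitions: specificity
``A_ij = mean abundance of i over the sites of j / sum over habitats of
those means`` and fidelity ``B_ij = fraction of habitat-j sites where i
occurs``.  Significance is assessed by permuting the site -> habitat
assignment and comparing each observed value with the permutation
distribution of the species' *maximum* IndVal (add-one estimator).  Species
scoring > 70% with P < 0.05 are indicator species; 45-70% with P < 0.05 are
detector species.

Daily activity is classified from two-period capture counts (7:00-18:00 vs
18:00-7:00, the second period spanning midnight): a species is diurnal when
>= 60% of its captures fall in period 1, evening/nocturnal/crepuscular (ENC)
when >= 60% fall in period 2, with a literature fallback for species with
too few captures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceMatrix",
    "IndValResult",
    "CaptureTable",
    "ActivityCall",
    "indval",
    "categorize_indval",
    "classify_activity",
    "captures_to_table",
    "INDICATOR_THRESHOLD",
    "DETECTOR_RANGE",
    "ACTIVITY_THRESHOLD",
]

logger = logging.getLogger(__name__)

INDICATOR_THRESHOLD = 70.0  # strict: IndVal must exceed this
DETECTOR_RANGE = (45.0, 70.0)  # closed interval
ACTIVITY_THRESHOLD = 0.60
DEFAULT_PERIOD_BOUNDARIES = (7, 18)


@dataclass(frozen=True)
class AbundanceMatrix:
    """Site x species count matrix with a site -> habitat mapping."""

    counts: pd.DataFrame  # rows = sites, columns = species, integer counts
    habitat_of_site: pd.Series  # index = sites

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.habitat_of_site.index):
            raise ValueError("counts rows and habitat_of_site must share the same sites")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("abundances must be non-negative")
        if self.habitat_of_site.nunique() < 2:
            raise ValueError("at least 2 habitats required")

    @property
    def habitats(self) -> list[str]:
        return sorted(self.habitat_of_site.unique())

    @classmethod
    def from_csv(cls, path) -> "AbundanceMatrix":
        """Read a CSV with one row per site, a ``habitat`` column and one
        column per species."""
        df = pd.read_csv(path, index_col=0, comment="#")
        if "habitat" not in df.columns:
            raise ValueError("abundance CSV needs a 'habitat' column")
        habitat = df.pop("habitat")
        return cls(counts=df.astype(int), habitat_of_site=habitat)


@dataclass(frozen=True)
class IndValResult:
    species: str
    habitat: str
    A: float  # specificity in [0, 1]
    B: float  # fidelity in [0, 1]
    indval: float  # percent in [0, 100]
    P_perm: float
    category: str  # indicator / detector / none


def _indval_components(counts: np.ndarray, group_index: np.ndarray,
                       n_groups: int) -> tuple[np.ndarray, np.ndarray]:
    """(A, B) matrices of shape (n_groups, n_species) for a label assignment."""
    n_sites, n_species = counts.shape
    sums = np.zeros((n_groups, n_species))
    occ = np.zeros((n_groups, n_species))
    np.add.at(sums, group_index, counts)
    np.add.at(occ, group_index, counts > 0)
    group_sizes = np.bincount(group_index, minlength=n_groups).astype(float)
    means = sums / group_sizes[:, None]
    total = means.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(total > 0, means / np.where(total > 0, total, 1.0), 0.0)
    b = occ / group_sizes[:, None]
    return a, b


def indval(matrix: AbundanceMatrix, n_permutations: int = 999,
           seed: Optional[int] = None, alpha: float = 0.05) -> pd.DataFrame:
    """IndVal of every species for every habitat, with permutation P values.

    The permutation null reassigns the site -> habitat labels uniformly at
    random; for each species the null statistic is its maximum IndVal over
    habitats, and ``P = (1 + #{null max >= observed}) / (1 + n_permutations)``.
    Species with zero total abundance get IndVal 0, category 'none' and are
    logged.
    """
    counts = matrix.counts.to_numpy(dtype=float)
    species = matrix.counts.columns
    habitats = matrix.habitats
    hab_index = pd.Categorical(matrix.habitat_of_site, categories=habitats).codes
    n_groups = len(habitats)
    if np.bincount(hab_index, minlength=n_groups).min() < 1:
        raise ValueError("every habitat needs at least one site")

    a, b = _indval_components(counts, hab_index, n_groups)
    iv = a * b * 100.0

    zero_total = counts.sum(axis=0) == 0
    if zero_total.any():
        logger.warning("%d species have zero total abundance; IndVal set to 0",
                       int(zero_total.sum()))

    rng = np.random.default_rng(seed)
    exceed = np.zeros((n_groups, counts.shape[1]))
    labels = hab_index.copy()
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        pa, pb = _indval_components(counts, perm, n_groups)
        null_max = (pa * pb * 100.0).max(axis=0)  # per species
        exceed += null_max[None, :] >= iv - 1e-12
    p_perm = (1.0 + exceed) / (1.0 + n_permutations)

    rows = []
    for j, hab in enumerate(habitats):
        for i, sp in enumerate(species):
            value = 0.0 if zero_total[i] else float(iv[j, i])
            p = 1.0 if zero_total[i] else float(p_perm[j, i])
            rows.append({
                "species": sp, "habitat": hab,
                "A": 0.0 if zero_total[i] else float(a[j, i]),
                "B": float(b[j, i]), "indval": value, "P_perm": p,
                "category": "none" if zero_total[i]
                else categorize_indval(value, p, alpha=alpha),
            })
    return pd.DataFrame(rows)


def categorize_indval(indval_pct: float, p_perm: float,
                      alpha: float = 0.05,
                      indicator_threshold: float = INDICATOR_THRESHOLD,
                      detector_range: tuple[float, float] = DETECTOR_RANGE) -> str:
    """indicator (> 70%, P < alpha), detector ([45, 70]%, P < alpha), or none."""
    if not (0.0 <= indval_pct <= 100.0):
        raise ValueError("indval must be in [0, 100]")
    if p_perm < alpha:
        if indval_pct > indicator_threshold:
            return "indicator"
        if detector_range[0] <= indval_pct <= detector_range[1]:
            return "detector"
    return "none"


@dataclass(frozen=True)
class CaptureTable:
    """Per-species capture counts in the two daily periods."""

    species: str
    period1: int  # 7:00-18:00
    period2: int  # 18:00-7:00 (spans midnight)

    def __post_init__(self) -> None:
        if self.period1 < 0 or self.period2 < 0:
            raise ValueError("capture counts must be non-negative")

    @property
    def total(self) -> int:
        return self.period1 + self.period2


@dataclass(frozen=True)
class ActivityCall:
    species: str
    fraction_P1: float
    call: str  # diurnal / ENC / unresolved
    source: str  # sampling / literature / none


def classify_activity(table: CaptureTable, min_captures: int = 25,
                      literature: Optional[Mapping[str, str]] = None,
                      threshold: float = ACTIVITY_THRESHOLD) -> ActivityCall:
    """Apply the >= 60% rule, falling back to a literature label.

    The fallback triggers when the species has fewer than ``min_captures``
    captures or when neither period reaches the threshold.
    """
    total = table.total
    frac = table.period1 / total if total else float("nan")
    if total >= min_captures:
        if frac >= threshold - 1e-12:
            return ActivityCall(table.species, frac, "diurnal", "sampling")
        if (1.0 - frac) >= threshold - 1e-12:
            return ActivityCall(table.species, frac, "ENC", "sampling")
    lit = (literature or {}).get(table.species)
    if lit is not None:
        return ActivityCall(table.species, frac, lit, "literature")
    return ActivityCall(table.species, frac, "unresolved", "none")


def captures_to_table(captures: pd.DataFrame,
                      boundaries: tuple[int, int] = DEFAULT_PERIOD_BOUNDARIES
                      ) -> list[CaptureTable]:
    """Bin timestamped captures into the two half-open clock periods.

    Period 1 is [start, end) by local clock; period 2 is the complement and
    spans midnight.  ``captures`` needs ``species`` and ``timestamp`` columns.
    """
    ts = pd.to_datetime(captures["timestamp"])
    hours = ts.dt.hour + ts.dt.minute / 60.0 + ts.dt.second / 3600.0
    b0, b1 = boundaries
    in_p1 = (hours >= b0) & (hours < b1)
    out = []
    for sp, grp in captures.assign(_p1=in_p1).groupby("species", sort=True):
        p1 = int(grp["_p1"].sum())
        out.append(CaptureTable(species=sp, period1=p1, period2=len(grp) - p1))
    return out
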