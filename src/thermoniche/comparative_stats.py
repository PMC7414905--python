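"""Comparative models for the thermal-niche variables.

For each response (endothermy, thorax slope, abdomen slope, their
difference, minimum tethered-flapping temperature) the comparative design is
a linear mixed-effects model

    response ~ habitat * activity + mass + (1 | species)

fitted by REML, with sum-to-zero factor contrasts so that type-III Wald
chi-square tests of each term are meaningful.  Endothermy is log-transformed
(it is right-skewed); non-positive values cannot enter the log response and
are dropped with a logged count.  Post-hoc cell comparisons use estimated
marginal means at the mean of the mass covariate with Tukey
(studentized-range) adjustment.  Body mass across habitat/activity groups is
compared with tie-corrected Kruskal-Wallis H tests followed by Conover-Iman
rank post-hocs.  No multiple-testing correction is applied across responses
by default; Holm adjustment of the Conover table is available behind a flag.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.formula.api as smf

__all__ = [
    "MixedModelFit",
    "KWResult",
    "fit_mixed_model",
    "anova_type3",
    "tukey_contrasts",
    "kruskal_conover",
    "correlate",
]

logger = logging.getLogger(__name__)


@dataclass
class MixedModelFit:
    """Fitted mixed model plus the metadata needed for downstream tables."""

    result: object  # statsmodels MixedLMResults
    formula: str
    data: pd.DataFrame
    response: str
    log_transform: bool
    n_dropped: int = 0
    singular: bool = False

    @property
    def fe_params(self) -> pd.Series:
        return self.result.fe_params

    def fe_cov(self) -> np.ndarray:
        k = len(self.result.fe_params)
        return np.asarray(self.result.cov_params())[:k, :k]


def fit_mixed_model(data: pd.DataFrame, response: str,
                    log_transform: bool = False) -> MixedModelFit:
    """Fit ``response ~ habitat * activity + mass + (1 | species)`` by REML.

    ``data`` needs columns ``species, habitat, activity, mass`` plus the
    response.  With ``log_transform`` the response becomes
    ``log(response)``; rows with non-positive response are excluded (their
    count is logged and stored on the returned fit).  A random-intercept
    variance estimated at (or collapsing to) zero is reported as a singular
    fit via a warning, not a failure.
    """
    for col in ("species", "habitat", "activity", "mass", response):
        if col not in data.columns:
            raise ValueError(f"missing column {col!r}")
        if col != "mass" and col != response and data[col].isna().any():
            raise ValueError(f"missing values in {col!r}")
    if data["habitat"].nunique() < 2 or data["activity"].nunique() < 2:
        raise ValueError("habitat and activity each need >= 2 levels")
    if data["species"].nunique() < 2:
        raise ValueError("need >= 2 species for a species random intercept")

    df = data.copy()
    n_dropped = 0
    yname = response
    if log_transform:
        bad = df[response] <= 0
        n_dropped = int(bad.sum())
        if n_dropped:
            logger.warning("dropping %d non-positive %s values from the log fit",
                           n_dropped, response)
            df = df[~bad]
        yname = f"_log_{response}"
        df[yname] = np.log(df[response])

    formula = f"{yname} ~ C(habitat, Sum) * C(activity, Sum) + mass"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, df, groups=df["species"])
        result = model.fit(reml=True)
    singular = bool(np.asarray(result.cov_re).min() < 1e-8)
    if singular:
        warnings.warn("random-intercept variance is ~0 (singular fit); "
                      "fixed effects equal the OLS solution", UserWarning,
                      stacklevel=2)
    return MixedModelFit(result=result, formula=formula, data=df,
                         response=response, log_transform=log_transform,
                         n_dropped=n_dropped, singular=singular)


def anova_type3(fit: MixedModelFit) -> pd.DataFrame:
    """Type-III Wald chi-square ANOVA table of the fixed-effect terms.

    For each non-intercept term, chi2 = b' V^-1 b over that term's
    coefficients (meaningful because the factors use sum-to-zero contrasts),
    with a chi-square reference on the term's df.
    """
    di = fit.result.model.data.design_info
    beta = np.asarray(fit.fe_params)
    cov = fit.fe_cov()
    rows = []
    for term, sl in di.term_name_slices.items():
        if term == "Intercept":
            continue
        b = beta[sl]
        v = cov[sl, sl]
        try:
            chi2 = float(b @ np.linalg.solve(v, b))
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"rank-deficient design for term {term!r}") from exc
        df_term = b.size
        rows.append({"term": _pretty_term(term), "Chisq": chi2, "df": df_term,
                     "P": float(stats.chi2.sf(chi2, df_term))})
    return pd.DataFrame(rows)


def _pretty_term(term: str) -> str:
    return (term.replace("C(habitat, Sum)", "habitat")
            .replace("C(activity, Sum)", "activity"))


def _cell_grid(fit: MixedModelFit) -> pd.DataFrame:
    habs = sorted(fit.data["habitat"].unique())
    acts = sorted(fit.data["activity"].unique())
    grid = pd.DataFrame([(h, a) for h in habs for a in acts],
                        columns=["habitat", "activity"])
    grid["mass"] = fit.data["mass"].mean()
    return grid


def _emm(fit: MixedModelFit) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Estimated marginal means per habitat x activity cell at mean mass."""
    from patsy import build_design_matrices

    grid = _cell_grid(fit)
    di = fit.result.model.data.design_info
    (dm,) = build_design_matrices([di], grid)
    x = np.asarray(dm)
    beta = np.asarray(fit.fe_params)
    cov = fit.fe_cov()
    emm = x @ beta
    emm_cov = x @ cov @ x.T
    grid = grid.assign(emmean=emm)
    return grid, emm, emm_cov


def tukey_contrasts(fit: MixedModelFit, within: str = "activity") -> pd.DataFrame:
    """Pairwise Tukey-adjusted contrasts of cell marginal means.

    ``within='activity'`` compares habitats separately within each activity
    level (families of size n_habitats); ``within='habitat'`` compares the
    two activity levels within each habitat.  The statistic is the contrast
    divided by its standard error, compared against the studentized-range
    distribution with the family's number of means and large-sample
    (normal) degrees of freedom.
    """
    if within not in ("activity", "habitat"):
        raise ValueError("within must be 'activity' or 'habitat'")
    grid, emm, emm_cov = _emm(fit)
    other = "habitat" if within == "activity" else "activity"
    rows = []
    for level, sub in grid.groupby(within, sort=True):
        idx = sub.index.to_numpy()
        if len(idx) < 2:
            raise ValueError(f"empty or singleton cell family at {within}={level!r}")
        k = len(idx)
        for i, j in combinations(range(k), 2):
            a, b = idx[i], idx[j]
            diff = float(emm[a] - emm[b])
            se = float(np.sqrt(emm_cov[a, a] + emm_cov[b, b] - 2.0 * emm_cov[a, b]))
            t = diff / se
            p = float(stats.studentized_range.sf(abs(t) * np.sqrt(2.0), k, np.inf))
            rows.append({
                within: level,
                "contrast": f"{grid.loc[a, other]} - {grid.loc[b, other]}",
                "E": diff, "t": t, "P": p})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class KWResult:
    H: float
    df: int
    P: float


def kruskal_conover(values: Sequence[float], groups: Sequence,
                    p_adjust: Optional[str] = None
                    ) -> tuple[KWResult, pd.DataFrame]:
    """Kruskal-Wallis H test plus Conover-Iman pairwise rank post-hocs.

    The Conover statistic for groups i, j is

        t = (Rbar_i - Rbar_j) / sqrt(S^2 * (N - 1 - H)/(N - k) * (1/n_i + 1/n_j))

    with pooled rank variance S^2 = (sum R^2 - N (N+1)^2 / 4) / (N - 1) and a
    t reference on N - k df.  P values are two-sided and unadjusted by
    default (no multiplicity correction across comparisons); ``p_adjust='holm'``
    applies a Holm step-down.
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if y.shape != g.shape:
        raise ValueError("values and groups must be the same length")
    levels = pd.unique(g)
    if len(levels) < 2:
        raise ValueError("need >= 2 groups")
    samples = [y[g == lv] for lv in levels]
    if any(len(s) < 2 for s in samples):
        raise ValueError("each group needs n >= 2")
    if np.ptp(y) == 0:
        raise ValueError("all values identical; rank tests undefined")

    h, p = stats.kruskal(*samples)
    n = y.size
    k = len(levels)
    kw = KWResult(H=float(h), df=k - 1, P=float(p))

    ranks = stats.rankdata(y)
    s2 = (np.sum(ranks ** 2) - n * (n + 1.0) ** 2 / 4.0) / (n - 1.0)
    scale = s2 * (n - 1.0 - h) / (n - k)
    rbar = {lv: ranks[g == lv].mean() for lv in levels}
    sizes = {lv: int((g == lv).sum()) for lv in levels}
    dof = n - k
    rows = []
    for a, b in combinations(levels, 2):
        se = np.sqrt(scale * (1.0 / sizes[a] + 1.0 / sizes[b]))
        t = (rbar[a] - rbar[b]) / se if se > 0 else 0.0
        rows.append({"group_a": a, "group_b": b, "t": float(t), "df": dof,
                     "P": float(2.0 * stats.t.sf(abs(t), dof)) if se > 0 else 1.0})
    table = pd.DataFrame(rows)
    if p_adjust is not None:
        if p_adjust != "holm":
            raise ValueError("only 'holm' adjustment is supported")
        from statsmodels.stats.multitest import multipletests

        table["P"] = multipletests(table["P"], method="holm")[1]
    return kw, table


def correlate(data: pd.DataFrame,
              pairs: Sequence[tuple[str, str]]) -> pd.DataFrame:
    """Pearson correlation for each named pair of columns."""
    rows = []
    for a, b in pairs:
        sub = data[[a, b]].dropna()
        if len(sub) < 3:
            raise ValueError(f"need >= 3 paired observations for ({a}, {b})")
        r, p = stats.pearsonr(sub[a], sub[b])
        rows.append({"var_a": a, "var_b": b, "r": float(r), "P": float(p),
                     "n": len(sub)})
    return pd.DataFrame(rows)
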