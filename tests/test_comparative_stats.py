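"""Mixed model, type-III Wald ANOVA, Tukey contrasts, Kruskal-Wallis +
Conover post-hocs and correlations."""

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import statsmodels.formula.api as smf

from thermoniche.comparative_stats import (anova_type3, correlate,
                                           fit_mixed_model, kruskal_conover,
                                           tukey_contrasts)

HABITATS = ["native_forest", "agroforestry", "open_pasture"]
ACTIVITIES = ["diurnal", "ENC"]


def balanced_design(n_per_species=5, species_per_cell=1, seed=0,
                    shared_residuals=False):
    """Species-level habitat x activity design with within-species replicates."""
    rng = np.random.default_rng(seed)
    rows = []
    resid = rng.normal(0, 1.0, n_per_species)
    mass_vals = np.linspace(0.1, 0.5, n_per_species)
    sp = 0
    for h in HABITATS:
        for a in ACTIVITIES:
            for _ in range(species_per_cell):
                e = resid if shared_residuals else rng.normal(0, 1.0, n_per_species)
                for i in range(n_per_species):
                    rows.append({"species": f"sp{sp}", "habitat": h,
                                 "activity": a, "mass": mass_vals[i],
                                 "endothermy": 3.0 + e[i]})
                sp += 1
    return pd.DataFrame(rows)


class TestMixedModel:
    def test_zero_variance_limit_equals_ols(self):
        """With identical residual patterns across species the random
        intercept collapses to zero and the fixed effects equal OLS."""
        df = balanced_design(species_per_cell=2, shared_residuals=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_mixed_model(df, "endothermy")
        ols = smf.ols(fit.formula, fit.data).fit()
        np.testing.assert_allclose(np.asarray(fit.fe_params),
                                   np.asarray(ols.params), atol=1e-6)

    def test_log_transform_drops_nonpositive(self):
        df = balanced_design(seed=3)
        df.loc[df.index[:2], "endothermy"] = -0.5
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_mixed_model(df, "endothermy", log_transform=True)
        assert fit.n_dropped == 2
        assert len(fit.data) == len(df) - 2

    def test_missing_levels_rejected(self):
        df = balanced_design()
        with pytest.raises(ValueError):
            fit_mixed_model(df[df.habitat == "native_forest"], "endothermy")


class TestAnovaType3:
    def test_one_df_term_is_squared_z(self):
        """For the single-df activity term the Wald chi-square equals the
        squared coefficient z-score."""
        df = balanced_design(species_per_cell=3, seed=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_mixed_model(df, "endothermy")
        table = anova_type3(fit).set_index("term")
        idx = [i for i, name in enumerate(fit.fe_params.index)
               if "activity" in name and ":" not in name]
        assert len(idx) == 1
        beta = fit.fe_params.iloc[idx[0]]
        se = np.sqrt(fit.fe_cov()[idx[0], idx[0]])
        assert table.loc["activity", "Chisq"] == pytest.approx(
            (beta / se) ** 2, rel=1e-9)
        assert table.loc["activity", "df"] == 1
        assert table.loc["habitat:activity", "df"] == 2

    def test_terms_present(self):
        df = balanced_design(species_per_cell=2, seed=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = anova_type3(fit_mixed_model(df, "endothermy"))
        assert set(table["term"]) == {"habitat", "activity",
                                      "habitat:activity", "mass"}
        assert (table["Chisq"] >= 0).all()


class TestTukeyContrasts:
    def fit(self, seed=0):
        df = balanced_design(species_per_cell=2, seed=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return fit_mixed_model(df, "endothermy")

    def test_two_group_family_equals_unadjusted(self):
        """Within a habitat the activity family has k=2 means, so the Tukey
        p-value reduces to the unadjusted two-sided normal p."""
        table = tukey_contrasts(self.fit(), within="habitat")
        for row in table.itertuples():
            assert row.P == pytest.approx(2 * stats.norm.sf(abs(row.t)),
                                          rel=1e-6)

    def test_contrast_estimates_are_consistent(self):
        """Pairwise differences within a family satisfy d(ab)+d(bc)=d(ac)."""
        table = tukey_contrasts(self.fit(), within="activity")
        for _, fam in table.groupby("activity"):
            d = {tuple(r.contrast.split(" - ")): r.E for r in fam.itertuples()}
            (ab, bc, ac) = (d[("agroforestry", "native_forest")],
                            d[("native_forest", "open_pasture")],
                            d[("agroforestry", "open_pasture")])
            assert ab + bc == pytest.approx(ac, abs=1e-9)

    def test_adjusted_p_not_smaller_than_unadjusted(self):
        table = tukey_contrasts(self.fit(seed=5), within="activity")
        for row in table.itertuples():
            assert row.P >= 2 * stats.norm.sf(abs(row.t)) - 1e-12


def conover_oracle(values, groups):
    """Independent Conover-Iman computation from the definitional formula,
    using plain-python midranks."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        mid = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    levels = list(dict.fromkeys(groups))
    n = len(values)
    k = len(levels)
    by = {lv: [ranks[i] for i in range(n) if groups[i] == lv] for lv in levels}
    # tie-corrected H from the rank sums
    correction = 1.0
    ties = {}
    for v in values:
        ties[v] = ties.get(v, 0) + 1
    t_sum = sum(t ** 3 - t for t in ties.values())
    correction = 1.0 - t_sum / (n ** 3 - n)
    h = (12.0 / (n * (n + 1)) * sum(sum(r) ** 2 / len(r) for r in by.values())
         - 3 * (n + 1)) / correction
    s2 = (sum(r * r for r in ranks) - n * (n + 1) ** 2 / 4.0) / (n - 1)
    out = {}
    for a, b in combinations(levels, 2):
        na, nb = len(by[a]), len(by[b])
        se = (s2 * (n - 1 - h) / (n - k) * (1 / na + 1 / nb)) ** 0.5
        out[(a, b)] = (sum(by[a]) / na - sum(by[b]) / nb) / se
    return h, out


class TestKruskalConover:
    def test_hand_computed_h(self):
        kw, _ = kruskal_conover([1, 2, 3, 4, 5, 6],
                                ["a", "a", "a", "b", "b", "b"])
        assert kw.H == pytest.approx(3.857142857, abs=1e-6)
        assert kw.df == 1

    def test_three_identical_groups(self):
        values = [1, 2, 3] * 3
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        kw, table = kruskal_conover(values, groups)
        assert kw.H == pytest.approx(0.0, abs=1e-12)
        assert table["P"].to_numpy() == pytest.approx(1.0, abs=1e-9)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_matches_independent_oracle(self, seed):
        rng = np.random.default_rng(seed)
        sizes = rng.integers(3, 8, size=3)
        values, groups = [], []
        for g, size in zip("abc", sizes):
            values += [float(x) for x in rng.integers(0, 12, size)]
            groups += [g] * size
        if len(set(values)) == 1:
            values[0] += 1.0
        kw, table = kruskal_conover(values, groups)
        h_oracle, t_oracle = conover_oracle(values, groups)
        assert kw.H == pytest.approx(h_oracle, abs=1e-9)
        for row in table.itertuples():
            assert row.t == pytest.approx(t_oracle[(row.group_a, row.group_b)],
                                          abs=1e-9)

    @given(st.integers(0, 500))
    def test_h_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(size=12)
        groups = np.repeat(["a", "b", "c"], 4)
        kw1, _ = kruskal_conover(values, groups)
        kw2, _ = kruskal_conover(np.exp(values), groups)
        assert kw1.H == pytest.approx(kw2.H, abs=1e-9)

    def test_unadjusted_by_default_holm_optional(self):
        rng = np.random.default_rng(0)
        values = np.concatenate([rng.normal(0, 1, 8), rng.normal(2, 1, 8),
                                 rng.normal(4, 1, 8)])
        groups = np.repeat(["a", "b", "c"], 8)
        _, plain = kruskal_conover(values, groups)
        _, holm = kruskal_conover(values, groups, p_adjust="holm")
        assert (holm["P"] >= plain["P"] - 1e-12).all()

    def test_all_identical_values_rejected(self):
        with pytest.raises(ValueError):
            kruskal_conover([1.0] * 6, ["a"] * 3 + ["b"] * 3)


class TestCorrelate:
    def test_trivial_cases(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]})
        df["same"] = df["x"]
        df["neg"] = -df["x"]
        out = correlate(df, [("x", "same"), ("x", "neg")])
        assert out["r"].tolist() == pytest.approx([1.0, -1.0])

    def test_bivariate_normal_recovery(self):
        rho = 0.59
        rng = np.random.default_rng(1)
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=2000)
        df = pd.DataFrame(z, columns=["a", "b"])
        out = correlate(df, [("a", "b")])
        se = (1 - rho ** 2) / np.sqrt(2000)
        assert out["r"].iloc[0] == pytest.approx(rho, abs=4 * se)

    def test_too_few_observations_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]})
        with pytest.raises(ValueError):
            correlate(df, [("a", "b")])
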