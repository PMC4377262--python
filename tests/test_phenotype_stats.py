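"""Trait aggregation, PERMANOVA (one- and two-way), survival summaries."""

import numpy as np
import pandas as pd
import pytest

from margin_adapt import (CgeNecrosisConfig, RtePhenotypeConfig,
                          mean_max_growth, permanova_one_way,
                          permanova_two_way, simulate_cge_necrosis,
                          simulate_rte_phenotypes, survival_summary)
from margin_adapt.phenotype_stats import UnbalancedDesignError


class TestMeanMaxGrowth:
    def test_identical_values(self):
        assert mean_max_growth([3.0] * 10) == pytest.approx(3.0)

    def test_top_k_of_range(self):
        assert mean_max_growth(range(1, 21), k=10) == pytest.approx(15.5)

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        vals = rng.random(25)
        assert mean_max_growth(vals) == mean_max_growth(vals[::-1])

    def test_short_measurement_warns(self):
        with pytest.warns(UserWarning, match="using all"):
            assert mean_max_growth([1.0, 2.0], k=10) == pytest.approx(1.5)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            mean_max_growth([-1.0, 2.0])


def _balanced_frame(rng, n_per_cell=10, effects=(0, 0, 0)):
    a_eff, b_eff, ab_eff = effects
    rows = []
    for i, origin in enumerate(("shallow", "mesophotic")):
        for j, depth in enumerate(("shallow", "mesophotic")):
            mu = a_eff * i + b_eff * j + ab_eff * i * j
            for k in range(n_per_cell):
                rows.append({
                    "individual": f"{origin[:2]}{depth[:2]}{k}",
                    "sample": origin, "origin_depth": origin,
                    "treatment_depth": depth, "trait": "growth_mm",
                    "value": mu + rng.normal(),
                })
    return pd.DataFrame(rows)


class TestTwoWay:
    def test_equals_classical_anova(self):
        """Euclidean-distance pseudo-F coincides with the parametric two-way
        ANOVA F on balanced designs (statsmodels oracle)."""
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        rng = np.random.default_rng(10)
        for _ in range(5):
            df = _balanced_frame(rng, effects=rng.normal(size=3))
            res = permanova_two_way(df, n_perm=49, seed=1)
            fit = smf.ols(
                "value ~ C(origin_depth) * C(treatment_depth)", data=df).fit()
            table = sm.stats.anova_lm(fit, typ=1)
            ours = res.table["pseudo_F"].to_numpy()[:3]
            # statsmodels orders main effects first, interaction third
            theirs = table["F"].to_numpy()[:3]
            assert np.allclose(np.sort(ours), np.sort(theirs), atol=1e-10)
            assert res.table.loc["total", "SS"] == pytest.approx(
                res.table["SS"][:4].sum(), abs=1e-9)

    def test_constant_response_degenerate(self):
        df = _balanced_frame(np.random.default_rng(0))
        df["value"] = 5.0
        res = permanova_two_way(df, n_perm=99, seed=2)
        assert res.degenerate
        assert (res.table["pseudo_F"].dropna() == 0).all()
        assert (res.table["p_perm"].dropna() == 1).all()

    def test_shift_scale_invariance(self):
        rng = np.random.default_rng(3)
        df = _balanced_frame(rng, effects=(1.0, 0.5, 2.0))
        r1 = permanova_two_way(df, n_perm=199, seed=7)
        df2 = df.assign(value=df["value"] * 3.5 + 100.0)
        r2 = permanova_two_way(df2, n_perm=199, seed=7)
        assert np.allclose(r1.table["pseudo_F"].dropna(),
                           r2.table["pseudo_F"].dropna(), atol=1e-9)
        assert np.allclose(r1.table["p_perm"].dropna(),
                           r2.table["p_perm"].dropna())

    def test_empty_cell_refused(self):
        df = _balanced_frame(np.random.default_rng(1))
        df = df[~((df.origin_depth == "shallow")
                  & (df.treatment_depth == "mesophotic"))]
        with pytest.raises(UnbalancedDesignError, match="empty design cell"):
            permanova_two_way(df, n_perm=9, seed=0)

    def test_unbalanced_refused(self):
        df = _balanced_frame(np.random.default_rng(1))
        with pytest.raises(UnbalancedDesignError, match="unbalanced"):
            permanova_two_way(df.iloc[:-1], n_perm=9, seed=0)

    def test_interaction_detected_at_study_size(self):
        """A 3-SD interaction is detected in the default 10-per-cell design."""
        cfg = RtePhenotypeConfig()
        pheno = simulate_rte_phenotypes(cfg, seed=5)
        res = permanova_two_way(pheno, n_perm=999, seed=6)
        assert res.table.loc["origin_depth x treatment_depth", "p_perm"] < 0.01


class TestOneWay:
    def test_identical_groups(self):
        df = pd.DataFrame({
            "individual": [f"i{k}" for k in range(8)],
            "sample": ["A"] * 4 + ["B"] * 4,
            "origin_depth": ["shallow"] * 4 + ["mesophotic"] * 4,
            "treatment_depth": ["shallow"] * 8,
            "trait": "growth_mm",
            "value": [1.0, 2.0, 3.0, 4.0] * 2,
        })
        res = permanova_one_way(df, n_perm=99, seed=0)
        assert res.table.loc["origin_depth", "pseudo_F"] == pytest.approx(0.0)
        assert res.table.loc["origin_depth", "p_perm"] == 1.0

    def test_maximal_separation_at_study_size(self):
        rng = np.random.default_rng(12)
        df = pd.DataFrame({
            "individual": [f"i{k}" for k in range(48)],
            "sample": ["RI-20"] * 24 + ["RI-40"] * 24,
            "origin_depth": ["shallow"] * 24 + ["mesophotic"] * 24,
            "treatment_depth": ["shallow"] * 48,
            "trait": "necrosis_pct",
            "value": np.concatenate([rng.normal(10, 1, 24),
                                     rng.normal(20, 1, 24)]),
        })
        res = permanova_one_way(df, trait="necrosis_pct", n_perm=999, seed=1)
        assert res.table.loc["origin_depth", "p_perm"] == pytest.approx(1 / 1000)

    def test_equals_classical_f(self):
        from scipy.stats import f_oneway
        rng = np.random.default_rng(4)
        df = pd.DataFrame({
            "individual": [f"i{k}" for k in range(30)],
            "sample": ["A"] * 15 + ["B"] * 15,
            "origin_depth": ["shallow"] * 15 + ["mesophotic"] * 15,
            "treatment_depth": ["shallow"] * 30,
            "trait": "growth_mm",
            "value": rng.normal(size=30),
        })
        res = permanova_one_way(df, n_perm=49, seed=3)
        f_ref = f_oneway(df["value"][:15], df["value"][15:]).statistic
        assert res.table.loc["origin_depth", "pseudo_F"] == \
            pytest.approx(f_ref, abs=1e-10)

    def test_null_p_values_uniform(self):
        """Permutation p under the null is ~Uniform(0,1) (KS check)."""
        from scipy.stats import kstest
        rng = np.random.default_rng(9)
        pvals = []
        for _ in range(400):
            df = pd.DataFrame({
                "individual": [f"i{k}" for k in range(24)],
                "sample": ["A"] * 12 + ["B"] * 12,
                "origin_depth": ["shallow"] * 12 + ["mesophotic"] * 12,
                "treatment_depth": ["shallow"] * 24,
                "trait": "growth_mm",
                "value": rng.normal(size=24),
            })
            res = permanova_one_way(df, n_perm=199,
                                    seed=int(rng.integers(2**31 - 1)))
            pvals.append(res.table.loc["origin_depth", "p_perm"])
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_small_level_refused(self):
        df = pd.DataFrame({
            "individual": ["a", "b", "c"],
            "sample": ["A", "A", "B"],
            "origin_depth": ["shallow", "shallow", "mesophotic"],
            "treatment_depth": ["shallow"] * 3,
            "trait": "growth_mm",
            "value": [1.0, 2.0, 3.0],
        })
        with pytest.raises(UnbalancedDesignError):
            permanova_one_way(df, n_perm=9, seed=0)


class TestSurvival:
    def test_study_like_percentages(self):
        cfg = CgeNecrosisConfig()
        pheno = simulate_cge_necrosis(cfg, seed=3)
        summ = survival_summary(pheno).set_index("sample")
        # 24 colonies per origin; shallow buffers, mesophotic suffers
        assert (summ["n_colonies"] == 24).all()
        assert summ.loc["RI-20", "survival_pct"] > summ.loc["RI-40", "survival_pct"]

    def test_exact_fraction(self):
        rows = []
        for i in range(24):
            rows.append({"individual": f"c{i}", "sample": "S",
                         "origin_depth": "shallow",
                         "treatment_depth": "shallow",
                         "trait": "necrosis_pct",
                         "value": 100.0 if i < 4 else 0.0, "time": 1})
        from margin_adapt.genotype_io import PhenotypeTable
        summ = survival_summary(PhenotypeTable(pd.DataFrame(rows)))
        assert summ["survival_pct"][0] == pytest.approx(100 * 20 / 24)
        assert summ["never_necrosed_pct"][0] == pytest.approx(100 * 20 / 24)

    def test_all_zero_records(self):
        rows = [{"individual": f"c{i}", "sample": "S",
                 "origin_depth": "shallow", "treatment_depth": "shallow",
                 "trait": "necrosis_pct", "value": 0.0, "time": t}
                for i in range(5) for t in (0, 1)]
        from margin_adapt.genotype_io import PhenotypeTable
        summ = survival_summary(PhenotypeTable(pd.DataFrame(rows)))
        assert summ["never_necrosed_pct"][0] == 100.0

    def test_empty_rejected(self):
        from margin_adapt.genotype_io import PhenotypeTable
        t = PhenotypeTable(pd.DataFrame({
            "individual": ["a"], "sample": ["S"],
            "origin_depth": ["shallow"], "treatment_depth": ["shallow"],
            "trait": ["growth_mm"], "value": [1.0]}))
        with pytest.raises(ValueError, match="no necrosis"):
            survival_summary(t)
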