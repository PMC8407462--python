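import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from gutstruct import host, synthetic


def hypergeom_tail_oracle(N, K, n, k):
    """Direct pmf summation over the support."""
    def pmf(x):
        return (math.comb(K, x) * math.comb(N - K, n - x)) / math.comb(N, n)
    lo, hi = max(0, n - (N - K)), min(K, n)
    upper = sum(pmf(x) for x in range(k, hi + 1))
    lower = sum(pmf(x) for x in range(lo, k + 1))
    return upper, lower


class TestHypergeomTails:
    def test_extreme_enrichment_hand_value(self):
        p_enr, _ = host.hypergeom_tails(20, 10, 5, 5)
        assert p_enr == pytest.approx(252 / 15504)

    def test_central_value_has_fat_tails(self):
        p_enr, p_dep = host.hypergeom_tails(100, 50, 10, 5)
        assert p_enr > 0.5 and p_dep > 0.5

    def test_ubiquitous_asv_degenerate(self):
        p_enr, p_dep = host.hypergeom_tails(50, 50, 10, 10)
        assert p_enr == pytest.approx(1.0) and p_dep == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(40):
            N = int(rng.integers(10, 60))
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            k = int(rng.integers(max(0, n - (N - K)), min(K, n) + 1))
            got = host.hypergeom_tails(N, K, n, k)
            want = hypergeom_tail_oracle(N, K, n, k)
            assert got[0] == pytest.approx(want[0], abs=1e-12)
            assert got[1] == pytest.approx(want[1], abs=1e-12)

    def test_pmf_sums_to_one(self):
        # upper tail at the smallest support value covers everything
        p_enr, _ = host.hypergeom_tails(30, 12, 8, 0)
        assert p_enr == pytest.approx(1.0)


class TestPrevalenceEnrichment:
    def test_enriched_group_flagged_positive(self):
        rng = np.random.default_rng(1)
        n = 300
        groups = pd.Series(["old"] * 150 + ["young"] * 150)
        present = np.concatenate([rng.random(150) < 0.8,
                                  rng.random(150) < 0.2])
        presence = pd.DataFrame({"asv1": present,
                                 "asv2": rng.random(n) < 0.5})
        screen = host.prevalence_enrichment(presence, groups, alpha=0.1)
        call = screen.set_index(["asv", "group"]).loc[("asv1", "old"), "direction"]
        assert call == "+"
        assert screen.set_index(["asv", "group"]).loc[("asv1", "young"),
                                                      "direction"] == "-"

    def test_null_respects_fdr(self):
        rng = np.random.default_rng(2)
        presence = pd.DataFrame(rng.random((400, 30)) < 0.5)
        presence.columns = [f"a{i}" for i in range(30)]
        groups = pd.Series(rng.choice(["g1", "g2", "g3"], size=400))
        screen = host.prevalence_enrichment(presence, groups, alpha=0.1)
        assert (screen["direction"] != "").mean() < 0.05

    def test_empty_group_rejected(self):
        presence = pd.DataFrame({"a": [True, False]})
        groups = pd.Series(["g1", None])
        with pytest.raises(ValueError):
            host.prevalence_enrichment(presence, groups)

    def test_direction_matrix_shape(self):
        presence = pd.DataFrame({"a": [True, False] * 10, "b": [True] * 20})
        groups = pd.Series(["x"] * 10 + ["y"] * 10)
        mat = host.direction_matrix(host.prevalence_enrichment(presence, groups))
        assert mat.shape == (2, 2)


class TestWinsorizeIqr:
    def test_no_outliers_unchanged(self):
        x = np.arange(1, 10, dtype=float)
        assert np.array_equal(host.winsorize_iqr(x), x)

    def test_type7_quartile_hand_example(self):
        x = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 100], float)
        out = host.winsorize_iqr(x)
        # Q1=3.25, Q3=7.75, IQR=4.5 -> upper cutoff 14.5
        assert out[-1] == pytest.approx(14.5)
        assert np.array_equal(out[:-1], x[:-1])

    def test_constant_vector_unchanged(self):
        x = np.full(6, 3.0)
        assert np.array_equal(host.winsorize_iqr(x), x)

    @given(st.lists(st.floats(min_value=-1e6, max_value=1e6), min_size=4,
                    max_size=50))
    @settings(max_examples=100, deadline=None)
    def test_projection_property(self, values):
        # winsorization is a clip: output stays inside the cutoffs, values
        # already inside are untouched, and a second pass is the identity
        # whenever clipping left the quartiles unchanged (the rule is not
        # idempotent when >25% of the mass sits in the tails)
        x = np.asarray(values, float)
        q1, q3 = np.percentile(x, [25, 75])
        lo, hi = q1 - 1.5 * (q3 - q1), q3 + 1.5 * (q3 - q1)
        once = host.winsorize_iqr(values)
        assert ((once >= lo - 1e-9) & (once <= hi + 1e-9)).all()
        inside = (x >= lo) & (x <= hi)
        assert np.array_equal(once[inside], x[inside])
        p1, p3 = np.percentile(once, [25, 75])
        if np.isclose(p1, q1) and np.isclose(p3, q3):
            assert np.allclose(host.winsorize_iqr(once), once)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            host.winsorize_iqr([1, 2, 3])


def _counts_with_abundance(rng, n=200, m=5):
    """Counts with a large background column so every focal ASV has a
    genuinely varying relative abundance."""
    counts = pd.DataFrame(rng.poisson(rng.lognormal(3, 1, size=(n, m))) + 1,
                          columns=[f"a{i}" for i in range(m)],
                          index=[f"s{i}" for i in range(n)])
    counts["bg"] = rng.integers(500, 2000, size=n)
    return counts


class TestAssociate:
    def test_perfect_linear_relationship(self):
        rng = np.random.default_rng(3)
        counts = _counts_with_abundance(rng, n=10)
        logab = host.log_abundance(counts)
        factors = pd.DataFrame({"f": 2.0 * logab["a0"]})
        res = host.associate(counts, factors, winsorize=False)
        row = res.table.set_index("asv").loc["a0"]
        assert row["beta"] == pytest.approx(2.0, rel=1e-9)
        assert row["p"] < 1e-12

    def test_f_equals_squared_t(self):
        rng = np.random.default_rng(4)
        counts = _counts_with_abundance(rng, n=60, m=1)
        logab = host.log_abundance(counts)["a0"]
        y = 0.3 * logab + rng.normal(size=60)
        res = host.associate(counts, pd.DataFrame({"f": y}), winsorize=False)
        slope, _, _, p_t, _ = stats.linregress(logab, y)
        row = res.table.set_index("asv").loc["a0"]
        assert row["beta"] == pytest.approx(slope, rel=1e-9)
        assert row["p"] == pytest.approx(p_t, rel=1e-8)

    def test_parameter_recovery_and_ci_coverage(self):
        # y = 0.5 x + N(0,1): the slope estimate is unbiased and its 95%
        # interval covers the truth at the nominal rate
        rng = np.random.default_rng(5)
        counts = _counts_with_abundance(rng, n=500, m=1)[["a0", "bg"]]
        x = host.log_abundance(counts)["a0"]
        betas, covered = [], []
        for _ in range(500):
            y = 0.5 * x + rng.normal(size=500)
            res = host.associate(counts[["a0", "bg"]], pd.DataFrame({"f": y}, index=counts.index),
                                 winsorize=False)
            row = res.table.set_index("asv").loc["a0"]
            se = abs(row["beta"]) / np.sqrt(row["F"])
            betas.append(row["beta"])
            half = stats.t.ppf(0.975, 498) * se
            covered.append(abs(row["beta"] - 0.5) <= half)
        assert np.mean(betas) == pytest.approx(0.5, abs=0.05)
        assert np.mean(covered) == pytest.approx(0.95, abs=0.03)

    def test_age_conditioning_triggers_partial_f(self):
        rng = np.random.default_rng(6)
        n = 300
        counts = _counts_with_abundance(rng, n=n, m=1)
        x = host.log_abundance(counts)["a0"]
        age = pd.Series(3.0 * x + rng.normal(0, 0.5, size=n), index=counts.index)
        factor = pd.DataFrame({"f": 0.5 * age + rng.normal(size=n)},
                              index=counts.index)
        res = host.associate(counts, factor, age=age, winsorize=False)
        tab = res.table.set_index("asv")
        assert bool(tab.loc["a0", "age_adjusted"])
        # age absorbs the abundance signal: the partial effect is weak
        res_no_age = host.associate(counts, factor, winsorize=False)
        assert tab.loc["a0", "p"] > res_no_age.table.set_index("asv").loc["a0", "p"]

    def test_zero_variance_factor_excluded(self):
        rng = np.random.default_rng(7)
        counts = _counts_with_abundance(rng, n=50, m=1)
        factors = pd.DataFrame({"flat": np.ones(50)}, index=counts.index)
        res = host.associate(counts, factors, winsorize=False)
        assert len(res.table) == 0

    def test_female_only_effect_detected_only_in_female_stratum(self):
        spec = synthetic.CohortSpec(
            n_samples=600, n_asvs=60, n_clusters=0, seed=11,
            effect_table=[("ASV_0023", "bmi", 0.8, ("sex", "female"))])
        counts, tax, tree, meta, truth = synthetic.generate_cohort(spec)
        by_sex = {}
        for sex in ("female", "male"):
            idx = meta.index[meta["sex"] == sex]
            res = host.associate(counts.loc[idx], meta.loc[idx, ["bmi"]],
                                 fdr=0.2)
            tab = res.table.set_index("asv")
            by_sex[sex] = tab.loc["ASV_0023", "q"]
        assert by_sex["female"] < 0.2
        assert by_sex["male"] > 0.2


class TestDietPca:
    def test_dominant_column_drives_pc1(self):
        rng = np.random.default_rng(8)
        n = 200
        shared = rng.normal(size=n)
        df = pd.DataFrame({"big": 3 * shared + 0.1 * rng.normal(size=n),
                           "echo": 2 * shared + 0.1 * rng.normal(size=n),
                           "noise1": rng.normal(size=n),
                           "noise2": rng.normal(size=n)})
        pca = host.diet_pca(df)
        assert abs(pca.loadings.loc["big", "PC1"]) > 0.5

    def test_recovers_planted_two_factor_subspace(self):
        rng = np.random.default_rng(9)
        n = 400
        f1, f2 = rng.normal(size=n), rng.normal(size=n)
        cols = {}
        loads = rng.uniform(-1, 1, size=(10, 2))
        for j in range(10):
            cols[f"v{j}"] = (2.0 * loads[j, 0] * f1 + 2.0 * loads[j, 1] * f2
                             + 0.3 * rng.normal(size=n))
        pca = host.diet_pca(pd.DataFrame(cols))
        # principal angle between recovered and planted score subspaces
        A = np.column_stack([f1, f2])
        B = pca.scores[["PC1", "PC2"]].to_numpy()
        qa, _ = np.linalg.qr(A - A.mean(0))
        qb, _ = np.linalg.qr(B - B.mean(0))
        angles = np.degrees(np.arccos(np.clip(
            np.linalg.svd(qa.T @ qb)[1], -1, 1)))
        assert angles.max() < 5.0

    def test_variance_explained_sums_to_one(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame(rng.normal(size=(50, 6)))
        pca = host.diet_pca(df)
        assert pca.variance_explained.sum() == pytest.approx(1.0)
        assert (np.diff(pca.variance_explained) <= 1e-12).all()

    def test_constant_column_dropped(self, caplog):
        rng = np.random.default_rng(11)
        df = pd.DataFrame({"a": rng.normal(size=30), "b": np.ones(30),
                           "c": rng.normal(size=30)})
        with caplog.at_level("WARNING", logger="gutstruct"):
            pca = host.diet_pca(df)
        assert "b" not in pca.loadings.index

    def test_sign_convention(self):
        rng = np.random.default_rng(12)
        df = pd.DataFrame(rng.normal(size=(80, 5)))
        pca = host.diet_pca(df)
        for col in pca.loadings.columns:
            v = pca.loadings[col]
            assert v.iloc[np.argmax(np.abs(v.to_numpy()))] > 0


class TestAgeCorrelations:
    def test_monotone_richness_gives_rho_one(self):
        n = 40
        age = pd.Series(np.linspace(20, 80, n))
        richness = pd.Series(np.arange(n))
        sex = pd.Series(["female"] * 20 + ["male"] * 20)
        out = host.age_diversity_correlation(richness, age, sex)
        assert np.allclose(out["rho"], 1.0)

    def test_planted_positive_trend_detected(self):
        rng = np.random.default_rng(13)
        n = 300
        age = pd.Series(rng.uniform(20, 80, size=n))
        richness = pd.Series((0.5 * age + rng.normal(0, 8, size=n)).round())
        sex = pd.Series(rng.choice(["female", "male"], size=n))
        out = host.age_diversity_correlation(richness, age, sex).set_index("stratum")
        assert out.loc["all", "rho"] > 0
        assert out.loc["all", "p"] < 0.05

    def test_age_abundance_rank_invariance(self):
        rng = np.random.default_rng(14)
        counts = _counts_with_abundance(rng, n=100, m=3)
        age = pd.Series(rng.uniform(20, 80, size=100), index=counts.index)
        r1 = host.age_abundance_correlation(counts, age)
        r2 = host.age_abundance_correlation(counts, np.exp(age / 20))
        assert np.allclose(r1["rho"], r2["rho"])

    def test_planted_age_effect_detected(self):
        spec = synthetic.CohortSpec(
            n_samples=500, n_asvs=60, n_clusters=0, seed=15,
            effect_table=[("ASV_0010", "age", 0.6)])
        counts, tax, tree, meta, truth = synthetic.generate_cohort(spec)
        out = host.age_abundance_correlation(counts, meta["age"], fdr=0.2)
        row = out.set_index("asv").loc["ASV_0010"]
        assert row["rho"] > 0 and bool(row["significant"])
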