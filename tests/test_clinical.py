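"""Cohort-comparison statistics: Fisher exact, Mann-Whitney, Kruskal-Wallis,
Spearman, and the support-vector vs non-support-vector partition."""

import itertools

import numpy as np
import pytest
from scipy import stats

from wmvpa.clinical import (ContingencyTable2x2, febrile_contingency,
                            fisher_exact_2x2, kruskal_wallis, mann_whitney_u,
                            sv_vs_nonsv_comparison,
                            weighting_covariate_correlation)
from _oracles import fisher_exact_enumeration_oracle


class TestFisherExact:
    def test_male_febrile_table_published_p(self, male_clinical):
        """4/11 favorable vs 4/8 non-favorable with febrile history: p = 0.66."""
        table = febrile_contingency(male_clinical)
        assert (table.a, table.b, table.c, table.d) == (4, 4, 7, 4)
        assert round(fisher_exact_2x2(table), 2) == 0.66

    def test_symmetric_table_p_one(self):
        assert fisher_exact_2x2(ContingencyTable2x2(1, 1, 1, 1)) == 1.0

    def test_matches_enumeration_oracle_on_small_tables(self):
        for a, b, c, d in itertools.product(range(5), repeat=4):
            if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
                continue
            ours = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))
            oracle = fisher_exact_enumeration_oracle(a, b, c, d)
            assert ours == pytest.approx(oracle, rel=1e-7), (a, b, c, d)

    def test_monotone_toward_independence(self):
        # moving counts toward proportionality cannot decrease the p-value
        p_strong = fisher_exact_2x2(ContingencyTable2x2(8, 0, 0, 8))
        p_weaker = fisher_exact_2x2(ContingencyTable2x2(6, 2, 2, 6))
        p_indep = fisher_exact_2x2(ContingencyTable2x2(4, 4, 4, 4))
        assert p_strong <= p_weaker <= p_indep

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 2, 3, 4)


class TestMannWhitney:
    def test_identical_groups_p_one_approx_backend(self):
        g = [1.0, 2.0, 3.0, 4.0, 5.0]
        u, p, backend = mann_whitney_u(g, g)
        assert backend == "asymptotic"  # ties force the approximation
        assert u == 12.5
        assert p == 1.0

    def test_disjoint_groups_exact_p(self):
        """Fully separated samples of 5 vs 5: U = 25, exact p = 2/252."""
        u, p, backend = mann_whitney_u([6, 7, 8, 9, 10], [1, 2, 3, 4, 5])
        assert backend == "exact"
        assert u == 25.0
        assert p == pytest.approx(2 / 252)

    def test_u_statistics_sum_identity(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=7), rng.normal(size=9)
        ua, _, _ = mann_whitney_u(a, b)
        ub, _, _ = mann_whitney_u(b, a)
        assert ua + ub == len(a) * len(b)

    def test_large_samples_use_asymptotic_backend(self):
        rng = np.random.default_rng(1)
        _, p, backend = mann_whitney_u(rng.normal(size=30), rng.normal(size=30))
        assert backend == "asymptotic" and 0.0 <= p <= 1.0

    def test_published_table_comparisons_non_significant(self, male_clinical,
                                                         female_clinical):
        """Smoke check of the study's group comparisons: no clinical
        characteristic separates favorable from non-favorable outcomes."""
        for clin in (male_clinical, female_clinical):
            fo = clin[clin.label == 1]
            nfo = clin[clin.label == -1]
            for char in ("age_at_onset", "age_at_mri", "age_at_surgery",
                         "seizure_freq_per_month", "followup_months"):
                _, p, _ = mann_whitney_u(fo[char], nfo[char])
                assert p > 0.05, char

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestKruskalWallis:
    def test_identical_constant_groups(self):
        h, p = kruskal_wallis([[3.0, 3.0], [3.0, 3.0], [3.0, 3.0]])
        assert h == 0.0 and p == 1.0

    def test_two_groups_equals_squared_standardized_u(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=6), rng.normal(size=8)  # continuous: no ties
        h, _ = kruskal_wallis([a, b])
        u, _, _ = mann_whitney_u(a, b)
        mean = len(a) * len(b) / 2.0
        sd = np.sqrt(len(a) * len(b) * (len(a) + len(b) + 1) / 12.0)
        assert h == pytest.approx(((u - mean) / sd) ** 2)

    def test_group_order_invariance(self):
        groups = [[1.0, 2.0], [3.0, 5.0], [4.0, 8.0, 9.0]]
        h1, _ = kruskal_wallis(groups)
        h2, _ = kruskal_wallis(groups[::-1])
        assert h1 == pytest.approx(h2)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0], []])


class TestWeightingCorrelation:
    def test_perfect_monotone_correlations(self):
        w = np.array([0.1, 0.4, 0.2, 0.9, 0.6])
        rho, _ = weighting_covariate_correlation(w, w)
        assert rho == pytest.approx(1.0)
        rho, _ = weighting_covariate_correlation(w, -w)
        assert rho == pytest.approx(-1.0)

    def test_null_false_positive_rate_at_nominal_level(self):
        """Independent weighting and covariate at n = 19: ~5% of 1000
        replicates reach p < 0.05."""
        rng = np.random.default_rng(3)
        hits = 0
        for _ in range(1000):
            w = rng.normal(size=19)
            c = rng.normal(size=19)
            _, p = weighting_covariate_correlation(w, c)
            hits += p < 0.05
        assert 0.03 <= hits / 1000 <= 0.07

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            weighting_covariate_correlation(np.ones(5), np.arange(5.0))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            weighting_covariate_correlation(np.ones(3), np.ones(4))


class TestSvVsNonSv:
    def _clinical(self, n, rng):
        import pandas as pd
        return pd.DataFrame({
            "subject_id": [f"S{i}" for i in range(n)],
            "label": [1] * (n // 2) + [-1] * (n - n // 2),
            "age_at_onset": rng.integers(1, 40, n),
            "followup_months": rng.integers(12, 48, n),
            "seizure_freq_per_month": rng.integers(1, 30, n),
        })

    def test_group_sizes_sum_to_n(self):
        rng = np.random.default_rng(4)
        clin = self._clinical(12, rng)
        alpha = rng.random(12) * (rng.random(12) > 0.3)
        out = sv_vs_nonsv_comparison(alpha, clin)
        sizes = out[["SV_FO", "SV_NonFO", "NonSV_FO", "NonSV_NonFO"]].iloc[0]
        assert sizes.sum() == 12

    def test_all_support_vectors_reported_degenerate(self):
        rng = np.random.default_rng(5)
        clin = self._clinical(8, rng)
        out = sv_vs_nonsv_comparison(np.ones(8) * 0.5, clin)
        # two occupied cells (SV_FO, SV_NonFO) still allow a comparison;
        # a truly degenerate single-cell partition reports no p-value
        clin_single = clin.copy()
        clin_single["label"] = 1
        out2 = sv_vs_nonsv_comparison(np.ones(8) * 0.5, clin_single)
        assert out2.degenerate.all()
        assert out2.p.isna().all()
        assert not out.degenerate.any()

    def test_null_p_values_are_uniform_across_seeds(self):
        """Covariates independent of the imaging data give uniform
        Kruskal-Wallis p-values across simulated cohorts."""
        from wmvpa import (CohortSpec, HyperparameterGrid, build_dataset,
                           default_mask, final_model, generate_cohort)
        grid = HyperparameterGrid(C_values=(1.0,), k_values=(10,))
        pvals = []
        for seed in range(40):
            spec = CohortSpec(grid_shape=(8, 8, 8), n_positive=5, n_negative=5,
                              effects=[], noise_sd=0.05, seed=seed)
            volumes, clinical = generate_cohort(spec)
            ds = build_dataset(volumes, default_mask(volumes), clinical)
            model, _, _ = final_model(ds, grid)
            out = sv_vs_nonsv_comparison(model.alpha, ds.clinical,
                                         characteristics=("seizure_freq_per_month",))
            if not out.degenerate.iloc[0]:
                pvals.append(out.p.iloc[0])
        assert len(pvals) >= 20
        assert stats.kstest(pvals, "uniform").pvalue > 0.01
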