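"""Tests for the group-statistics layer."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mitoquant import reference
from mitoquant.stats import (
    anova_tukey,
    backtransform_lsmean,
    fit_group_model,
    t_test_gated,
)


class TestGatedTTest:
    def test_identical_samples_not_significant(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = t_test_gated(a, a.copy(), side="greater")
        assert res.pvalue >= 0.5
        assert not res.significant

    def test_gates_recorded(self):
        rng = np.random.default_rng(0)
        res = t_test_gated(rng.normal(0, 1, 20), rng.normal(0, 1, 20), side="greater")
        assert 0 <= res.shapiro_p[0] <= 1 and 0 <= res.levene_p <= 1
        assert res.normality_ok and res.equal_variance_ok

    def test_power_on_shifted_groups(self):
        # N(2,1) vs N(0,1), n=20/group, one-sided: essentially always detected
        rng = np.random.default_rng(1)
        hits = sum(
            t_test_gated(rng.normal(2, 1, 20), rng.normal(0, 1, 20), "greater").pvalue
            < 0.05
            for _ in range(100)
        )
        assert hits >= 99

    def test_matches_scipy_pooled_t(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1, 15)
        res = t_test_gated(a, b, side="less")
        ref = sps.ttest_ind(a, b, equal_var=True, alternative="less")
        assert res.pvalue == pytest.approx(ref.pvalue)

    def test_zero_variance_convention(self):
        a = np.full(5, 3.0)
        res = t_test_gated(a, a.copy(), side="greater")
        assert res.pvalue == 1.0 and res.note is not None

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            t_test_gated([1.0, 2.0], [1.0, 2.0, 3.0], side="greater")


class TestAnovaTukey:
    def test_identical_groups(self):
        g = {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0], "c": [1.0, 2.0, 3.0]}
        res = anova_tukey(g)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert (res.pairwise["p_adj"] > 0.99).all()

    def test_two_groups_tukey_equals_pooled_t(self):
        # with k = 2 the studentized range collapses to q = sqrt(2)|t|, so the
        # Tukey p equals the two-sided pooled-variance t-test p
        rng = np.random.default_rng(3)
        for _ in range(10):
            a, b = rng.normal(0, 1, 9), rng.normal(0.8, 1, 4)
            res = anova_tukey({"a": a, "b": b})
            t_two_sided = sps.ttest_ind(a, b, equal_var=True).pvalue
            assert res.pairwise["p_adj"].iloc[0] == pytest.approx(t_two_sided, rel=1e-6)

    def test_power_at_study_sample_sizes(self):
        # 5 SD separation at n = 9 vs 4 (the respirometry group sizes)
        rng = np.random.default_rng(4)
        hits = sum(
            anova_tukey({"a": rng.normal(0, 1, 9), "b": rng.normal(5, 1, 4)}).pvalue
            < 0.05
            for _ in range(100)
        )
        assert hits >= 99

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            anova_tukey({"only": np.arange(4.0)})

    def test_degenerate_variance_reported(self):
        res = anova_tukey({"a": [1.0, 1.0], "b": [2.0, 2.0]})
        assert res.degenerate and res.pvalue == 0.0


class TestBacktransform:
    def test_log_link_reference_sizes(self):
        # exponentiating the printed size-model lsmeans reproduces the
        # reported group mean mitochondrial sizes
        assert backtransform_lsmean(-0.235) == pytest.approx(0.79, abs=0.005)
        assert backtransform_lsmean(-0.352) == pytest.approx(0.70, abs=0.005)

    def test_zero_maps_to_one(self):
        assert backtransform_lsmean(0.0) == 1.0

    def test_identity_link(self):
        assert backtransform_lsmean(2.5, link="identity") == 2.5


class TestReferenceContrastArithmetic:
    @pytest.mark.parametrize(
        "lsmeans,contrasts",
        [
            (reference.DENSITY_LSMEANS, reference.DENSITY_CONTRASTS),
            (reference.SIZE_LSMEANS, reference.SIZE_CONTRASTS),
        ],
        ids=["density", "size"],
    )
    def test_contrast_is_difference_of_lsmeans(self, lsmeans, contrasts):
        # every printed contrast equals the difference of its two printed
        # lsmeans, within the rounding of the published tables
        for c1, c2, printed in contrasts:
            diff = lsmeans[c1] - lsmeans[c2]
            assert diff == pytest.approx(printed, abs=0.011), (c1, c2)


class TestFitGroupModel:
    def _tidy(self, cell_means, n_sections=4, n_animals=2, rng=None, family="poisson"):
        rng = rng or np.random.default_rng(0)
        rows = []
        for (group, cell_type), mu in cell_means.items():
            for a in range(n_animals):
                for s in range(n_sections):
                    if family == "poisson":
                        val = rng.poisson(mu)
                    else:
                        val = rng.gamma(shape=20.0, scale=mu / 20.0)
                    rows.append(
                        {
                            "value": val,
                            "group": group,
                            "cell_type": cell_type,
                            "animal_id": f"{group}-a{a}",
                            "section_id": f"{group}-a{a}-s{s}",
                        }
                    )
        return pd.DataFrame(rows)

    def test_saturated_log_link_case(self):
        # one observation per design cell: the lsmean is log of the observation
        df = pd.DataFrame(
            {
                "value": [10, 20],
                "group": ["g1", "g1"],
                "cell_type": ["astro", "neuro"],
            }
        )
        comp = fit_group_model(df, family="poisson_log", n_boot=0)
        assert comp.lsmeans["g1:astro"] == pytest.approx(np.log(10), abs=1e-6)
        assert comp.back_transformed["g1:neuro"] == pytest.approx(20.0, rel=1e-6)

    def test_contrast_equals_lsmean_difference(self):
        rng = np.random.default_rng(5)
        df = self._tidy({("g1", "astro"): 40, ("g1", "neuro"): 25,
                         ("g2", "astro"): 30, ("g2", "neuro"): 35}, rng=rng)
        comp = fit_group_model(df, family="poisson_log", n_boot=50, seed=1)
        for _, row in comp.contrasts.iterrows():
            c1, c2 = row["contrast"].split(" - ")
            assert row["estimate"] == pytest.approx(
                comp.lsmeans[c1] - comp.lsmeans[c2], abs=1e-12
            )

    def test_poisson_lsmean_recovery(self):
        # programmed cell means recovered on the log scale within 2 SE in the
        # vast majority of simulated datasets
        means = {("g1", "astro"): 60, ("g1", "neuro"): 35}
        rng = np.random.default_rng(6)
        ok = total = 0
        for _ in range(60):
            df = self._tidy(means, n_sections=5, n_animals=3, rng=rng)
            comp = fit_group_model(df, family="poisson_log", n_boot=0)
            for (g, ct), mu in means.items():
                cell = f"{g}:{ct}"
                total += 1
                ok += abs(comp.lsmeans[cell] - np.log(mu)) <= 2 * comp.lsmean_se[cell]
        assert ok / total >= 0.9

    def test_poisson_with_area_offset_gives_log_density(self):
        df = pd.DataFrame(
            {
                "value": [50, 100],
                "area": [10.0, 20.0],
                "group": ["g", "g"],
                "cell_type": ["astro", "neuro"],
            }
        )
        comp = fit_group_model(df, family="poisson_log", offset_area="area", n_boot=0)
        # both cells have density 5 per area unit
        assert comp.lsmeans["g:astro"] == pytest.approx(np.log(5.0), abs=1e-6)
        assert comp.lsmeans["g:neuro"] == pytest.approx(np.log(5.0), abs=1e-6)

    def test_gamma_family(self):
        rng = np.random.default_rng(7)
        df = self._tidy({("g1", "astro"): 0.8, ("g1", "neuro"): 0.7},
                        n_sections=10, n_animals=3, rng=rng, family="gamma")
        comp = fit_group_model(df, family="gamma_log", n_boot=0)
        assert comp.back_transformed["g1:astro"] == pytest.approx(0.8, rel=0.1)

    def test_poisson_requires_integer_counts(self):
        df = pd.DataFrame(
            {"value": [1.5, 2.5], "group": ["g", "g"], "cell_type": ["a", "n"]}
        )
        with pytest.raises(ValueError, match="integer"):
            fit_group_model(df, family="poisson_log")

    def test_missing_cell_reported(self):
        df = pd.DataFrame(
            {
                "value": [5, 6, 7],
                "group": ["g1", "g1", "g2"],
                "cell_type": ["astro", "neuro", "astro"],
            }
        )
        comp = fit_group_model(df, family="poisson_log", n_boot=0)
        assert "g2:neuro" in comp.missing_cells
        assert not any("g2:neuro" in c for c in comp.contrasts["contrast"])

    def test_cluster_bootstrap_inflates_se_under_animal_effects(self):
        # strong animal-level heterogeneity: bootstrap SE exceeds the naive
        # independence SE from the GLM covariance
        rng = np.random.default_rng(8)
        rows = []
        for g, ct_mu in [("g1", 40)]:
            for a in range(4):
                for ct in ("astro", "neuro"):
                    animal_mu = ct_mu * rng.lognormal(0, 0.5)
                    for s in range(4):
                        rows.append(
                            {
                                "value": rng.poisson(animal_mu),
                                "group": g,
                                "cell_type": ct,
                                "animal_id": f"a{a}",
                                "section_id": f"a{a}-{ct}-s{s}",
                            }
                        )
        df = pd.DataFrame(rows)
        naive = fit_group_model(df, family="poisson_log", n_boot=0)
        boot = fit_group_model(df, family="poisson_log", n_boot=200, seed=2)
        assert boot.contrasts["se"].iloc[0] >= naive.contrasts["se"].iloc[0]
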