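"""Plot means, genotype/year ANOVA, heritability, correlation, jackknife."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ionkernel as ik
from conftest import toy_two_way


def _seed_table(values_by_plot: dict, element="Ca") -> pd.DataFrame:
    rows = []
    for (line, year, block), seeds in values_by_plot.items():
        for i, v in enumerate(seeds):
            rows.append({"sample_id": f"{line}{year}{block}_{i}",
                         "line": line, "year": year, "block": block,
                         element: v})
    return pd.DataFrame(rows)


class TestPlotMeans:
    def test_arithmetic(self):
        t = _seed_table({("A", "2010", 1): [2.0, 4.0]})
        pm = ik.compute_plot_means(t, ["Ca"])
        assert pm["Ca"].iloc[0] == 3.0

    def test_exclusions_drop_lines(self, effects3):
        design = ik.FieldDesign(n_lines=26, seeds_per_plot=(4, 4))
        samples, _ = ik.generate_field_experiment(design, effects3, seed=0)
        pm = ik.compute_plot_means(samples, ["Ca"],
                                   exclude_lines=("IL14H", "HP301", "P39"))
        assert pm["line"].nunique() == 23

    def test_single_seed_identity_and_nan_skipped(self):
        t = _seed_table({("A", "2010", 1): [5.0],
                         ("B", "2010", 1): [np.nan, 7.0]})
        pm = ik.compute_plot_means(t, ["Ca"])
        assert pm.set_index("line")["Ca"].to_dict() == {"A": 5.0, "B": 7.0}

    def test_empty_plots_dropped(self):
        t = _seed_table({("A", "2010", 1): [np.nan, np.nan],
                         ("B", "2010", 1): [1.0]})
        pm = ik.compute_plot_means(t, ["Ca"])
        assert pm["line"].tolist() == ["B"]


class TestGenotypeYearModel:
    def test_detects_line_effect(self):
        cells = {(f"L{i}", y): 10 + i for i in range(4)
                 for y in ("2010", "2011")}
        df = toy_two_way(cells, reps=3, noise_sd=0.1, seed=1)
        res = ik.fit_genotype_year_model(df, "y")
        assert res.pvalue["line"] < 1e-6
        assert res.pvalue["year"] > 0.01

    def test_single_year_falls_back_to_line_model(self):
        cells = {(f"L{i}", "2010"): 10 + i for i in range(4)}
        df = toy_two_way(cells, reps=3, noise_sd=0.1, seed=2)
        res = ik.fit_genotype_year_model(df, "y")
        assert "year" not in res.terms

    def test_needs_two_lines(self):
        df = toy_two_way({("A", "2010"): 1.0}, reps=3)
        with pytest.raises(ValueError, match="2 lines"):
            ik.fit_genotype_year_model(df, "y")


class TestHeritability:
    def test_noiseless_limit_is_one(self):
        cells = {(f"L{i}", y): 10.0 + i for i in range(5)
                 for y in ("2010", "2011")}
        df = toy_two_way(cells, reps=3, noise_sd=0.0)
        for scope in ("2010", "combined"):
            h = ik.estimate_heritability(df, "y", scope)
            assert h.h2 == pytest.approx(1.0)

    def test_no_genetic_variance_clamps_to_zero(self):
        # identical line means; block-to-block noise only
        rng = np.random.default_rng(3)
        cells = {(f"L{i}", y): 10.0 for i in range(3)
                 for y in ("2010", "2011")}
        h2s = []
        for s in range(20):
            df = toy_two_way(cells, reps=4, noise_sd=1.0, seed=s)
            h2s.append(ik.estimate_heritability(df, "y", "combined").h2)
        assert np.mean(h2s) < 0.25
        assert all(0.0 <= h <= 1.0 for h in h2s)

    def test_additive_mode_parameter_recovery(self):
        """Mean estimate approaches the analytic ratio over replicates."""
        eff = ik.EffectModel(
            effects={"Ca": ik.ElementEffect(mean_ppm=100, var_g=0.6,
                                            var_y=0.1, var_gy=0.2,
                                            var_plot=0.2, var_e=0.5)},
            mode="additive")
        design = ik.FieldDesign(n_lines=23, seeds_per_plot=(5, 5),
                                line_names=None)
        target = eff.analytic_h2("Ca", 2, [6, 5], 5)
        ests = []
        for s in range(30):
            samples, _ = ik.generate_field_experiment(design, eff, seed=s)
            pm = ik.compute_plot_means(samples, ["Ca"])
            ests.append(ik.estimate_heritability(pm, "Ca", "combined").h2)
        assert np.mean(ests) == pytest.approx(target, abs=0.06)

    def test_unreplicated_design_directs_to_jackknife(self):
        df = toy_two_way({(f"L{i}", y): 10.0 + i for i in range(3)
                          for y in ("2010", "2011")}, reps=1)
        with pytest.raises(ValueError, match="jackknife"):
            ik.estimate_heritability(df, "y", "combined")

    def test_more_noise_lowers_h2(self):
        cells = {(f"L{i}", y): 10.0 + i for i in range(8)
                 for y in ("2010", "2011")}
        lo = toy_two_way(cells, reps=4, noise_sd=0.5, seed=9)
        hi = toy_two_way(cells, reps=4, noise_sd=5.0, seed=9)
        assert (ik.estimate_heritability(hi, "y", "combined").h2
                < ik.estimate_heritability(lo, "y", "combined").h2)


class TestYearCorrelation:
    def _pm(self, y1, y2):
        rows = []
        for i, (a, b) in enumerate(zip(y1, y2)):
            rows.append({"line": f"L{i}", "year": "2010", "block": 1, "Ca": a})
            rows.append({"line": f"L{i}", "year": "2011", "block": 1, "Ca": b})
        return pd.DataFrame(rows)

    def test_identity_and_antisymmetry(self):
        y1 = [1.0, 2, 3, 4, 5]
        r, _, n = ik.year_correlation(self._pm(y1, y1), "Ca")
        assert r == pytest.approx(1.0)
        y2 = [-v for v in y1]
        r2, _, _ = ik.year_correlation(self._pm(y1, y2), "Ca")
        assert r2 == pytest.approx(-1.0)

    def test_matches_closed_form_pearson(self):
        y1 = np.array([3.0, 7, 1, 9, 4])
        y2 = np.array([2.0, 6, 2, 7, 8])
        r, p, n = ik.year_correlation(self._pm(y1, y2), "Ca")
        a, b = y1 - y1.mean(), y2 - y2.mean()
        expected = (a @ b) / np.sqrt((a @ a) * (b @ b))
        assert r == pytest.approx(expected, abs=1e-12)
        assert n == 5

    def test_too_few_shared_lines_flagged(self):
        pm = self._pm([1.0, 2], [2.0, 3])
        r, p, n = ik.year_correlation(pm, "Ca")
        assert np.isnan(r) and n == 2


class TestJackknife:
    def test_single_seed_plots_make_identical_datasets(self):
        rng = np.random.default_rng(5)
        plots = {(f"L{i}", y, b): [10.0 + i + rng.normal(0, 0.5)]
                 for i in range(6) for y in ("2010", "2011")
                 for b in (1, 2, 3)}
        t = _seed_table(plots)
        jk = ik.jackknife_single_seed(t, ["Ca"], n_datasets=20, seed=1)["Ca"]
        assert np.ptp(jk.pvalues) == 0.0
        assert np.ptp(jk.h2) == 0.0
        assert jk.p5 == jk.pvalues[0]
        assert jk.h2_5 == jk.h2[0]
        # and they equal the one possible dataset's statistics
        res = ik.fit_genotype_year_model(t, "Ca")
        assert jk.p5 == pytest.approx(res.pvalue["line"], rel=1e-12)

    def test_determinism(self, effects3, small_design):
        samples, _ = ik.generate_field_experiment(small_design, effects3,
                                                  seed=6)
        a = ik.jackknife_single_seed(samples, ["Ca"], n_datasets=10, seed=3)
        b = ik.jackknife_single_seed(samples, ["Ca"], n_datasets=10, seed=3)
        assert np.array_equal(a["Ca"].pvalues, b["Ca"].pvalues)
        assert np.array_equal(a["Ca"].h2, b["Ca"].h2)
        c = ik.jackknife_single_seed(samples, ["Ca"], n_datasets=10, seed=4)
        assert not np.array_equal(a["Ca"].pvalues, c["Ca"].pvalues)

    def test_jackknife_h2_below_plot_mean_h2(self, effects3, nam_design):
        """Single-seed heritability runs below the plot-mean estimate."""
        samples, _ = ik.generate_field_experiment(nam_design, effects3,
                                                  seed=7)
        pm = ik.compute_plot_means(samples, ["Ca"])
        h_pm = ik.estimate_heritability(pm, "Ca", "combined").h2
        jk = ik.jackknife_single_seed(samples, ["Ca"], n_datasets=30,
                                      seed=8)["Ca"]
        assert jk.h2_5 < h_pm

    def test_empty_table_raises(self):
        with pytest.raises(ValueError, match="no plots"):
            ik.jackknife_single_seed(
                pd.DataFrame(columns=["line", "year", "block", "Ca"]),
                ["Ca"])


def test_nam_summary_table_shape(effects3, small_design):
    samples, _ = ik.generate_field_experiment(small_design, effects3, seed=9)
    pm = ik.compute_plot_means(samples, ["Ca", "Zn", "Cu"])
    out = ik.nam_summary_table(samples, pm, ["Ca", "Zn", "Cu"],
                               n_jackknife=5, jackknife_seed=1)
    assert len(out) == 3
    for col in ("p_geno", "p_year", "p_gxy", "h2_year1", "h2_year2",
                "h2_both", "corr", "jk5_p", "jk5_h2"):
        assert col in out.columns
    assert out[["h2_year1", "h2_year2", "h2_both", "jk5_h2"]].apply(
        lambda c: c.between(0, 1)).all().all()


def test_bonferroni_cutoff_default():
    cfg = ik.PipelineConfig()
    assert len(cfg.elements) == 20
    assert cfg.alpha_adjusted == pytest.approx(0.0005)
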