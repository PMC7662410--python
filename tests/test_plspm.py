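import numpy as np
import pandas as pd
import pytest

from ansrecall import (PathModelSpec, align_indicator_signs, bootstrap_paths,
                       default_model, fit_plspm, goodness_of_fit,
                       permutation_group_test)
from ansrecall.plspm import PLSPMFit
from tests.conftest import DEFAULT_BETAS, make_table

TWO_BLOCK = PathModelSpec(blocks={"X": ("x",), "Y": ("y",)},
                          edges=(("X", "Y"),))


def two_block_frame(r=0.5, n=300, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    y = r * x + np.sqrt(1 - r * r) * rng.standard_normal(n)
    return pd.DataFrame({"x": x, "y": y})


class TestSpec:
    def test_default_blocks(self):
        spec = default_model()
        assert spec.blocks["Vagal"] == ("hf", "pnn50", "rmssd")
        assert spec.blocks["Sympathetic"] == ("lf", "sdnn", "ns_scr",
                                              "mean_scl")
        assert spec.blocks["ANS"] == ("lf_hf", "avnn")
        assert spec.endogenous == ("ANS", "Recall")
        assert spec.predecessors("ANS") == ("Sympathetic", "Vagal")

    def test_duplicate_mv_rejected(self):
        with pytest.raises(ValueError, match="more than one block"):
            PathModelSpec(blocks={"A": ("x",), "B": ("x",)},
                          edges=(("A", "B"),))

    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            PathModelSpec(blocks={"A": ("x",), "B": ("y",)},
                          edges=(("A", "B"), ("B", "A")))

    def test_unknown_lv_rejected(self):
        with pytest.raises(ValueError, match="unknown LV"):
            PathModelSpec(blocks={"A": ("x",)}, edges=(("A", "Z"),))

    def test_isolated_lv_rejected(self):
        with pytest.raises(ValueError, match="not part"):
            PathModelSpec(blocks={"A": ("x",), "B": ("y",), "C": ("z",)},
                          edges=(("A", "B"),))

    def test_json_round_trip(self):
        spec = default_model()
        assert PathModelSpec.from_jsonable(spec.to_jsonable()) == spec


class TestAlign:
    def test_flips_inverted_mv(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(200)
        df = pd.DataFrame({"a": x, "b": -x,
                           "c": x + 0.1 * rng.standard_normal(200),
                           "y": rng.standard_normal(200)})
        spec = PathModelSpec(blocks={"L": ("a", "b", "c"), "Y": ("y",)},
                             edges=(("L", "Y"),))
        aligned, flips = align_indicator_signs(df, spec)
        assert flips == {"a": False, "b": True, "c": False, "y": False}
        corr = aligned[["a", "b", "c"]].corr().to_numpy()
        assert np.all(corr >= 0)

    def test_consistent_block_untouched(self, model):
        table = make_table(n=200, loadings=0.9, noise_sd=0.3)
        aligned, flips = align_indicator_signs(table, model)
        assert not any(flips.values())
        pd.testing.assert_frame_equal(
            aligned[list(model.all_mvs())], table[list(model.all_mvs())])

    def test_constant_column_rejected(self, model):
        table = make_table(n=50)
        table["sdnn"] = 1.0
        with pytest.raises(ValueError, match="zero-variance"):
            align_indicator_signs(table, model)


class TestFit:
    def test_closed_form_two_block(self):
        df = two_block_frame(r=0.5, n=300, seed=0)
        fit = fit_plspm(df, TWO_BLOCK)
        r = np.corrcoef(df["x"], df["y"])[0, 1]
        assert fit.path_coefficients[("X", "Y")] == pytest.approx(r,
                                                                  abs=1e-9)
        assert fit.r_squared["Y"] == pytest.approx(r * r, abs=1e-9)

    def test_two_block_equivalence_many_datasets(self):
        for seed in range(50):
            rng = np.random.default_rng(seed)
            df = two_block_frame(r=rng.uniform(-0.9, 0.9), n=60, seed=seed)
            fit = fit_plspm(df, TWO_BLOCK)
            r = np.corrcoef(df["x"], df["y"])[0, 1]
            assert fit.path_coefficients[("X", "Y")] == pytest.approx(
                r, abs=1e-9)

    def test_unit_variance_scores(self, model):
        table = make_table(n=400, loadings=0.8, noise_sd=0.5, seed=2)
        fit = fit_plspm(table, model)
        for lv in model.blocks:
            assert fit.lv_scores[lv].var(ddof=1) == pytest.approx(1.0,
                                                                  abs=1e-9)

    def test_single_predictor_identity(self, model):
        table = make_table(n=400, loadings=0.8, noise_sd=0.5, seed=3)
        fit = fit_plspm(table, model)
        r = np.corrcoef(fit.lv_scores["ANS"], fit.lv_scores["Recall"])[0, 1]
        assert fit.path_coefficients[("ANS", "Recall")] == pytest.approx(
            r, abs=1e-9)

    def test_gof_identity(self, model):
        table = make_table(n=400, loadings=0.8, noise_sd=0.5, seed=4)
        fit = fit_plspm(table, model)
        mean_comm = np.mean(list(fit.communalities.values()))
        mean_r2 = np.mean(list(fit.r_squared.values()))
        assert fit.gof ** 2 == pytest.approx(mean_comm * mean_r2, abs=1e-12)
        assert goodness_of_fit(fit) == pytest.approx(fit.gof, abs=1e-15)

    def test_parameter_recovery_noiseless(self, model):
        table = make_table(n=1000, seed=7)
        aligned, _ = align_indicator_signs(table, model)
        fit = fit_plspm(aligned, model)
        for edge, truth in DEFAULT_BETAS.items():
            assert fit.path_coefficients[edge] == pytest.approx(truth,
                                                                abs=0.05)

    def test_null_betas_near_zero(self, model):
        table = make_table(betas={e: 0.0 for e in DEFAULT_BETAS}, n=1000,
                           seed=8)
        aligned, _ = align_indicator_signs(table, model)
        fit = fit_plspm(aligned, model)
        for edge in DEFAULT_BETAS:
            assert abs(fit.path_coefficients[edge]) <= 0.08

    @pytest.mark.parametrize("scheme", ["path", "centroid", "factorial"])
    def test_inner_schemes_agree_on_clean_data(self, model, scheme):
        table = make_table(n=800, loadings=0.9, noise_sd=0.2, seed=9)
        aligned, _ = align_indicator_signs(table, model)
        fit = fit_plspm(aligned, model, scheme=scheme)
        assert fit.converged
        assert fit.path_coefficients[("Sympathetic", "ANS")] \
            == pytest.approx(0.6, abs=0.12)

    def test_sign_flip_consistency(self, model):
        """Negating an MV in a multi-MV block changes nothing after align."""
        table = make_table(n=300, loadings=0.9, noise_sd=0.3, seed=11)
        aligned, _ = align_indicator_signs(table, model)
        ref = fit_plspm(aligned, model)
        for mv in ("lf", "sdnn", "hf", "rmssd", "lf_hf", "avnn"):
            mutated = table.copy()
            mutated[mv] = -mutated[mv]
            re_aligned, flips = align_indicator_signs(mutated, model)
            fit = fit_plspm(re_aligned, model)
            for edge, b in ref.path_coefficients.items():
                assert fit.path_coefficients[edge] == pytest.approx(
                    b, abs=1e-9), (mv, edge)
            for m, lo in ref.loadings.items():
                assert abs(fit.loadings[m]) == pytest.approx(abs(lo),
                                                             abs=1e-9)

    def test_zero_variance_rejected(self, model):
        table = make_table(n=100)
        table["avnn"] = 5.0
        with pytest.raises(ValueError, match="zero-variance"):
            fit_plspm(table, model)

    def test_missing_values_rejected(self, model):
        table = make_table(n=100)
        table.loc[3, "lf"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            fit_plspm(table, model)

    def test_too_few_rows_rejected(self, model):
        with pytest.raises(ValueError, match="rows"):
            fit_plspm(make_table(n=100).head(3), model)

    def test_unknown_scheme_rejected(self, model):
        with pytest.raises(ValueError, match="scheme"):
            fit_plspm(make_table(n=100), model, scheme="spaghetti")


class TestGoF:
    def _dummy_fit(self, communalities, r_squared):
        return PLSPMFit(spec=TWO_BLOCK, outer_weights={}, loadings={},
                        lv_scores=pd.DataFrame(),
                        path_coefficients={}, r_squared=r_squared,
                        communalities=communalities, gof=0.0, n_iterations=1,
                        converged=True, n_rows=10)

    def test_perfect_fit_bound(self, model):
        table = make_table(betas={("Sympathetic", "ANS"): 1.0,
                                  ("Vagal", "ANS"): 0.0,
                                  ("ANS", "Recall"): 1.0}, n=500, seed=12)
        fit = fit_plspm(table, model)
        assert fit.gof == pytest.approx(1.0, abs=1e-6)

    def test_direct_formula(self):
        fit = self._dummy_fit({"a": 0.64, "b": 0.64}, {"Y": 0.25})
        assert goodness_of_fit(fit) == pytest.approx(0.4, abs=1e-12)

    def test_no_endogenous_rejected(self):
        fit = self._dummy_fit({"a": 0.5}, {})
        with pytest.raises(ValueError, match="endogenous"):
            goodness_of_fit(fit)

    def test_unconverged_rejected(self):
        fit = self._dummy_fit({"a": 0.5}, {"Y": 0.5})
        fit.converged = False
        with pytest.raises(ValueError, match="converge"):
            goodness_of_fit(fit)


class TestBootstrap:
    def test_small_n_boot_rejected(self, model):
        with pytest.raises(ValueError, match="n_boot"):
            bootstrap_paths(make_table(n=50), model, n_boot=10)

    def test_strong_effect_significant(self, model):
        table = make_table(n=500, seed=13)
        result = bootstrap_paths(table, model, n_boot=200, seed=1)
        edge = result["edges"][("Sympathetic", "ANS")]
        assert edge["significant"]
        assert edge["ci_low"] > 0
        assert edge["p_value"] <= 0.05

    def test_null_effect_not_significant(self, model):
        table = make_table(betas={("Sympathetic", "ANS"): 0.5,
                                  ("Vagal", "ANS"): -0.5,
                                  ("ANS", "Recall"): 0.0}, n=400, seed=14)
        result = bootstrap_paths(table, model, n_boot=200, seed=1)
        edge = result["edges"][("ANS", "Recall")]
        assert edge["ci_low"] < 0 < edge["ci_high"]


class TestPermutation:
    def test_small_n_perm_rejected(self, model):
        table = make_table(n=60)
        with pytest.raises(ValueError, match="n_perm"):
            permutation_group_test(table, model, table["gender"], n_perm=10)

    def test_tiny_group_rejected(self, model):
        table = make_table(n=60)
        labels = ["A"] * 58 + ["B"] * 2
        with pytest.raises(ValueError, match="at least 3"):
            permutation_group_test(table, model, labels, n_perm=99)

    def test_separated_groups_detected(self, model):
        a = make_table(betas={("Sympathetic", "ANS"): 0.6,
                              ("Vagal", "ANS"): -0.3,
                              ("ANS", "Recall"): 0.3}, n=200, seed=15)
        b = make_table(betas={("Sympathetic", "ANS"): -0.6,
                              ("Vagal", "ANS"): -0.3,
                              ("ANS", "Recall"): 0.3}, n=200, seed=16)
        table = pd.concat([a, b], ignore_index=True)
        labels = ["A"] * 200 + ["B"] * 200
        comp = permutation_group_test(table, model, labels, n_perm=199,
                                      seed=2)
        assert comp.edges[("Sympathetic", "ANS")]["p_value"] < 0.01

    def test_p_value_formula(self, model):
        table = make_table(n=80, seed=17)
        comp = permutation_group_test(table, model, table["gender"],
                                      n_perm=99, seed=3)
        for stats in comp.edges.values():
            p = stats["p_value"]
            assert 1 / 100 <= p <= 1.0
            # p is on the (1 + k) / (1 + n_perm) grid
            assert (p * 100) == pytest.approx(round(p * 100), abs=1e-9)

    def test_null_p_values_roughly_uniform(self, model):
        """KS test over replicate null p-values (reduced replicate count)."""
        from scipy import stats
        pvals = []
        for rep in range(120):
            table = make_table(n=40, seed=1000 + rep)
            comp = permutation_group_test(table, model, table["gender"],
                                          n_perm=99, seed=rep)
            pvals.append(comp.edges[("Sympathetic", "ANS")]["p_value"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01
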