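"""Invariance filter, nested ANOVA, stability subsets, selection, clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pdxsig import qpcr, signature
from pdxsig.config import SelectionConfig, SimulationConfig
from pdxsig.synthetic import simulate_ct_table


def small_matrix(values, models, responses=None):
    genes = [f"g{i}" for i in range(values.shape[0])]
    samples = [f"s{i}" for i in range(values.shape[1])]
    info = pd.DataFrame({"model": models}, index=samples)
    if responses is not None:
        info["response"] = responses
    return qpcr.ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        sample_info=info,
    )


class TestInvarianceFilter:
    def test_constant_and_single_model_removed(self):
        vals = np.array([
            [5.0, 5.0, 5.0, 5.0],   # invariant (constant)
            [0.0, 0.0, 0.0, 0.0],   # invariant (never detected)
            [2.0, 3.0, 0.0, 0.0],   # expressed in model A only
            [1.0, 2.0, 3.0, 4.0],   # informative
        ])
        m = small_matrix(vals, ["A", "A", "B", "B"])
        retained, log = signature.invariance_filter(m)
        assert retained == ["g3"]
        reasons = log.set_index("gene")["reason"].to_dict()
        assert reasons == {"g0": "invariant", "g1": "invariant", "g2": "single-model"}

    def test_default_panel_keeps_42_of_57(self, expression_matrix):
        retained, log = signature.invariance_filter(expression_matrix)
        assert len(retained) == 42
        assert len(log) == 15


class TestPreprocess:
    def test_rows_standardized(self, expression_matrix, selection_config):
        retained, _ = signature.invariance_filter(expression_matrix)
        z = signature.preprocess(expression_matrix, selection_config, genes=retained)
        assert np.allclose(z.mean(axis=1), 0, atol=1e-10)
        assert np.allclose(z.std(axis=1, ddof=1), 1, atol=1e-10)

    def test_constant_gene_errors(self, selection_config):
        m = small_matrix(np.array([[2.0, 2.0, 2.0, 2.0]]), ["A", "A", "B", "B"])
        with pytest.raises(ValueError, match="zero-variance"):
            signature.preprocess(m, selection_config)

    def test_monotone_per_gene(self, selection_config):
        m = small_matrix(np.array([[0.0, 1.0, 4.0, 9.0]]), ["A", "A", "B", "B"])
        z = signature.preprocess(m, selection_config)
        assert z.iloc[0].is_monotonic_increasing


def nested_anova_oracle(y, response, model):
    """Brute-force sums-of-squares decomposition, written from the definition."""
    y = np.asarray(y, float)
    response = np.asarray(response)
    model = np.asarray(model)
    grand = y.mean()
    ss_resp = ss_model = 0.0
    b_total = 0
    for level in set(response):
        yl = y[response == level]
        ss_resp += len(yl) * (yl.mean() - grand) ** 2
        for m in set(model[response == level]):
            ym = y[(response == level) & (model == m)]
            ss_model += len(ym) * (ym.mean() - yl.mean()) ** 2
            b_total += 1
    a = len(set(response))
    df1, df2 = a - 1, b_total - a
    F = (ss_resp / df1) / (ss_model / df2)
    return F, stats.f.sf(F, df1, df2)


class TestNestedAnova:
    def test_all_equal_degenerate(self):
        f, p = signature.nested_anova([1.0] * 8, ["R"] * 4 + ["N"] * 4,
                                      ["a", "a", "b", "b", "c", "c", "d", "d"])
        assert f == 0.0
        assert p == 1.0

    def test_strong_response_effect(self):
        rng = np.random.default_rng(1)
        model = np.repeat(["a", "b", "c", "d"], 3)
        response = np.repeat(["R", "R", "N", "N"], 3)
        y = np.where(response == "R", 3.0, -3.0) + rng.normal(0, 0.1, 12)
        _, p = signature.nested_anova(y, response, model)
        assert p < 0.01

    def test_matches_bruteforce_oracle(self):
        """Vectorized F equals the definitional SS decomposition on random grids."""
        rng = np.random.default_rng(2)
        for reps, n_models in itertools.product([2, 3], [4, 6]):
            model = np.repeat([f"m{i}" for i in range(n_models)], reps)
            response = np.where(np.arange(len(model)) < len(model) // 2, "R", "N")
            y = rng.normal(size=len(model))
            f1, p1 = signature.nested_anova(y, response, model)
            f2, p2 = nested_anova_oracle(y, response, model)
            assert f1 == pytest.approx(f2, rel=1e-10)
            assert p1 == pytest.approx(p2, rel=1e-10)

    def test_unbalanced_design_matches_oracle(self):
        rng = np.random.default_rng(3)
        model = np.array(["a"] * 3 + ["b"] * 5 + ["c"] * 2 + ["d"] * 4)
        response = np.array(["R"] * 8 + ["N"] * 6)
        y = rng.normal(size=len(model))
        f1, p1 = signature.nested_anova(y, response, model)
        f2, p2 = nested_anova_oracle(y, response, model)
        assert f1 == pytest.approx(f2, rel=1e-10)

    def test_reduces_to_anova_on_model_means(self):
        """Balanced nested F equals one-way ANOVA computed on the model means."""
        rng = np.random.default_rng(4)
        model = np.repeat([f"m{i}" for i in range(6)], 4)
        response = np.where(np.arange(24) < 12, "R", "N")
        y = rng.normal(size=24)
        f1, _ = signature.nested_anova(y, response, model)
        means = pd.DataFrame({"y": y, "m": model, "r": response}).groupby("m").agg(
            y=("y", "mean"), r=("r", "first"))
        f2 = stats.f_oneway(means.loc[means["r"] == "R", "y"],
                            means.loc[means["r"] == "N", "y"]).statistic
        assert f1 == pytest.approx(f2, rel=1e-10)

    def test_single_model_per_level_rejected(self):
        with pytest.raises(ValueError, match="single model"):
            signature.nested_anova([1, 2, 3, 4], ["R", "R", "N", "N"], ["a", "a", "b", "b"])

    def test_model_in_two_levels_rejected(self):
        with pytest.raises(ValueError):
            signature.nested_anova(
                [1, 2, 3, 4, 5, 6, 7, 8],
                ["R", "R", "R", "N", "N", "N", "R", "N"],
                ["a", "a", "b", "b", "c", "c", "b", "a"],
            )


class TestStabilitySubsets:
    def test_sizes_and_composition(self, expression_matrix):
        cfg = SelectionConfig(seed=5)
        subsets = signature.stability_subsets(expression_matrix.sample_info, cfg)
        assert len(subsets) == 30
        models = expression_matrix.sample_info["model"]
        for sub in subsets:
            assert len(sub) == models.nunique() * 3
            per_model = models.reindex(sub).value_counts()
            assert (per_model == 3).all()
            assert len(set(sub)) == len(sub)  # without replacement

    def test_seed_reproducible(self, expression_matrix):
        cfg = SelectionConfig(seed=5)
        s1 = signature.stability_subsets(expression_matrix.sample_info, cfg)
        s2 = signature.stability_subsets(expression_matrix.sample_info, cfg)
        assert s1 == s2

    def test_full_data_when_subset_equals_pool(self, expression_matrix):
        info = expression_matrix.sample_info.groupby("model").head(3)
        cfg = SelectionConfig(seed=5, n_subsets=4)
        subsets = signature.stability_subsets(info, cfg)
        for sub in subsets:
            assert sorted(sub) == sorted(info.index)


class TestSelection:
    def test_determinism(self, expression_matrix):
        cfg = SelectionConfig(seed=9)
        r1 = signature.select_signature(expression_matrix, cfg)
        r2 = signature.select_signature(expression_matrix, cfg)
        pd.testing.assert_frame_equal(r1.per_gene, r2.per_gene)
        assert r1.selected == r2.selected

    def test_selected_requires_full_consensus_and_adjusted_p(self, expression_matrix):
        res = signature.select_signature(expression_matrix, SelectionConfig(seed=9))
        sel = res.per_gene[res.per_gene["selected"]]
        assert (sel["p_adj"] < 0.05).all()
        assert (sel["consensus_count"] == 30).all()

    def test_selection_shrinks_with_alpha(self, expression_matrix):
        loose = signature.select_signature(expression_matrix, SelectionConfig(seed=9, alpha=0.05))
        tight = signature.select_signature(expression_matrix, SelectionConfig(seed=9, alpha=0.001))
        assert set(tight.selected) <= set(loose.selected)

    def test_planted_directions_reported(self, expression_matrix):
        res = signature.select_signature(expression_matrix, SelectionConfig(seed=9))
        planted_dir = {"MCL1": "up_in_responders", "VIM": "down_in_responders",
                       "PROM1": "down_in_responders", "CD24": "up_in_responders"}
        for g, d in planted_dir.items():
            assert res.per_gene.loc[g, "direction"] == d


class TestClustering:
    def test_distance_matrix_properties(self, expression_matrix, selection_config):
        retained, _ = signature.invariance_filter(expression_matrix)
        z = signature.preprocess(expression_matrix, selection_config, genes=retained)
        d = signature.spearman_distance(z.iloc[:10])
        arr = d.to_numpy()
        assert np.allclose(arr, arr.T)
        assert np.allclose(np.diag(arr), 0)
        assert arr.min() >= -1e-12 and arr.max() <= 2 + 1e-12

    def test_identical_profiles_merge_first(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=6)
        vals = np.column_stack([base, base, base + rng.normal(0, 5, 6), rng.normal(size=6)])
        z = pd.DataFrame(vals, index=[f"g{i}" for i in range(6)],
                         columns=["s1", "s2", "s3", "s4"])
        d = signature.spearman_distance(z)
        assert d.loc["s1", "s2"] == pytest.approx(0.0, abs=1e-12)

    def test_strong_signature_reproduces_response_partition(self, expression_matrix):
        cfg = SimulationConfig(seed=21, planted_genes=tuple(
            (g, d, 4.0) for g, d, _ in SimulationConfig().planted_genes))
        sim = simulate_ct_table(cfg)
        m = qpcr.build_expression_matrix(sim.table, sim.sample_model, sim.model_response,
                                         sim.reference_samples)
        res = signature.select_signature(m, SelectionConfig(seed=9))
        clus = signature.cluster_samples(res, genes=[g for g, _, _ in cfg.planted_genes])
        resp = m.sample_info["response"].reindex(clus.labels.index)
        tab = pd.crosstab(clus.labels, resp).to_numpy()
        # each cluster is pure for one response class
        assert (tab == 0).sum() == 2

    def test_heatmap_export_round_trip(self, expression_matrix, tmp_path):
        res = signature.select_signature(expression_matrix, SelectionConfig(seed=9))
        genes = list(res.per_gene.sort_values("p_raw").index[:6])
        out = tmp_path / "heatmap.png"
        ordered = signature.export_heatmap(res, out, genes=genes)
        assert out.exists()
        back = pd.read_csv(tmp_path / "heatmap.tsv", sep="\t", index_col=0)
        assert np.allclose(back.to_numpy(), ordered.to_numpy())
        assert list(back.index) == list(ordered.index)
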