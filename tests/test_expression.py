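import numpy as np
import pandas as pd
import pytest
from scipy import stats

from exvivopharm import synthetic
from exvivopharm.expression import (
    ExpressionError,
    delta_ct_quant,
    differential_panel,
    genorm_rank,
    genorm_stability,
    load_panel_fixture,
    normalization_factor,
    normalize_card,
    relative_quantity,
)


def ct_frame(ct_by_gene_sample, role="target", replicates=1):
    rows = []
    for gene, by_sample in ct_by_gene_sample.items():
        for sample, ct in by_sample.items():
            for rep in range(1, replicates + 1):
                rows.append(
                    {"sample_id": sample, "class": "A", "gene": gene, "role": role,
                     "replicate": rep, "ct": ct}
                )
    return pd.DataFrame(rows)


def random_rq(n_genes, n_samples, seed=0, sigma=0.5):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.lognormal(0, sigma, size=(n_genes, n_samples)),
        index=[f"G{i}" for i in range(n_genes)],
        columns=[f"S{j}" for j in range(n_samples)],
    )


class TestRelativeQuantity:
    def test_minimal_ct_sample_has_rq_one(self):
        rq = relative_quantity(ct_frame({"G1": {"S1": 24.0, "S2": 26.0}}))
        assert rq.loc["G1", "S1"] == pytest.approx(1.0)

    def test_one_cycle_above_minimum_halves(self):
        rq = relative_quantity(ct_frame({"G1": {"S1": 24.0, "S2": 25.0}}))
        assert rq.loc["G1", "S2"] == pytest.approx(0.5)

    def test_3p32_cycles_is_tenth(self):
        rq = relative_quantity(ct_frame({"G1": {"S1": 24.0, "S2": 27.32}}))
        assert rq.loc["G1", "S2"] == pytest.approx(0.1, abs=1e-3)

    def test_replicates_are_averaged(self):
        frame = pd.DataFrame(
            [
                {"sample_id": "S1", "class": "A", "gene": "G1", "role": "target", "replicate": 1, "ct": 24.0},
                {"sample_id": "S1", "class": "A", "gene": "G1", "role": "target", "replicate": 2, "ct": 26.0},
                {"sample_id": "S2", "class": "A", "gene": "G1", "role": "target", "replicate": 1, "ct": 25.0},
                {"sample_id": "S2", "class": "A", "gene": "G1", "role": "target", "replicate": 2, "ct": np.nan},
            ]
        )
        rq = relative_quantity(frame)
        # S1 mean 25, S2 mean 25 (NaN skipped): both at the minimum
        assert rq.loc["G1", "S1"] == pytest.approx(1.0)
        assert rq.loc["G1", "S2"] == pytest.approx(1.0)

    def test_all_undetermined_gene_errors(self):
        frame = ct_frame({"G1": {"S1": np.nan, "S2": np.nan}})
        with pytest.raises(ExpressionError, match="G1"):
            relative_quantity(frame)

    def test_bad_efficiency(self):
        with pytest.raises(ExpressionError):
            relative_quantity(ct_frame({"G1": {"S1": 24.0}}), efficiency=1.0)


class TestGenormStability:
    def test_constant_ratio_pair_has_zero_m(self):
        rq = random_rq(1, 10, seed=1)
        refs = pd.DataFrame({"S%d" % j: [rq.iloc[0, j], 3 * rq.iloc[0, j]] for j in range(10)},
                            index=["R1", "R2"])
        m = genorm_stability(refs)
        assert m["R1"] == pytest.approx(0.0, abs=1e-12)
        assert m["R2"] == pytest.approx(0.0, abs=1e-12)

    def test_three_identical_references(self):
        base = random_rq(1, 8, seed=2).iloc[0]
        refs = pd.DataFrame([base, base, base], index=["R1", "R2", "R3"])
        assert np.allclose(genorm_stability(refs), 0.0, atol=1e-12)

    def test_m_grows_with_noise(self):
        # Spearman oracle: noisier reference -> larger M, monotonically
        rng = np.random.default_rng(3)
        base = pd.Series(rng.lognormal(0, 0.2, 40), index=[f"S{j}" for j in range(40)])
        ms = []
        for sigma in (0.05, 0.15, 0.4, 0.9):
            noisy = base * rng.lognormal(0, sigma, 40)
            refs = pd.DataFrame([base, base * 1.7, noisy], index=["R1", "R2", "R3"])
            ms.append(genorm_stability(refs)["R3"])
        assert stats.spearmanr(ms, [0.05, 0.15, 0.4, 0.9]).statistic == 1.0

    def test_reference_relabeling_symmetry(self):
        refs = random_rq(3, 12, seed=4)
        refs.index = ["R1", "R2", "R3"]
        m = genorm_stability(refs)
        m_rev = genorm_stability(refs.iloc[::-1])
        for name in refs.index:
            assert m[name] == pytest.approx(m_rev[name])

    def test_sample_permutation_invariance(self):
        refs = random_rq(3, 12, seed=5)
        perm = refs.iloc[:, ::-1]
        assert np.allclose(genorm_stability(refs), genorm_stability(perm))

    def test_requires_two_references(self):
        with pytest.raises(ExpressionError):
            genorm_stability(random_rq(1, 5))

    def test_iterative_ranking_drops_noisiest_first(self):
        rng = np.random.default_rng(6)
        base = pd.Series(rng.lognormal(0, 0.2, 30))
        refs = pd.DataFrame(
            [base, base * rng.lognormal(0, 0.05, 30), base * rng.lognormal(0, 1.5, 30)],
            index=["stable", "mild", "wild"],
        )
        order = genorm_rank(refs)
        assert order[0][0] == "wild"


class TestNormalizationFactor:
    @pytest.mark.parametrize(
        "refs,expected", [((1, 1, 1), 1.0), ((0.25, 1, 4), 1.0), ((0.5, 0.5, 0.5), 0.5)]
    )
    def test_geometric_mean(self, refs, expected):
        frame = pd.DataFrame({"S1": refs}, index=["R1", "R2", "R3"])
        assert normalization_factor(frame)["S1"] == pytest.approx(expected)

    def test_missing_reference_names_sample(self):
        frame = pd.DataFrame({"S1": [1.0, np.nan]}, index=["R1", "R2"])
        with pytest.raises(ExpressionError, match="S1"):
            normalization_factor(frame)


class TestNormalizeCard:
    def test_constant_gene_maps_to_zero(self):
        rq = pd.DataFrame({"S1": [2.0], "S2": [2.0], "S3": [2.0]}, index=["G1"])
        nf = pd.Series(1.0, index=rq.columns)
        out = normalize_card(rq, nf)
        assert np.allclose(out.values.loc["G1"], 0.0)

    def test_per_gene_median_is_zero(self):
        rq = random_rq(30, 9, seed=7)
        nf = pd.Series(1.0, index=rq.columns)
        med = normalize_card(rq, nf).values.median(axis=1)
        assert np.allclose(med, 0.0, atol=1e-12)

    def test_per_gene_median_zero_even_sample_count(self):
        rq = random_rq(30, 10, seed=8)
        nf = pd.Series(1.0, index=rq.columns)
        med = normalize_card(rq, nf).values.median(axis=1)
        assert np.allclose(med, 0.0, atol=1e-12)

    def test_sample_scaling_absorbed_by_nf(self):
        target = random_rq(20, 8, seed=9)
        refs = random_rq(3, 8, seed=10)
        base = normalize_card(target, normalization_factor(refs)).values
        scaled_t, scaled_r = target.copy(), refs.copy()
        scaled_t["S3"] *= 37.0
        scaled_r["S3"] *= 37.0
        scaled = normalize_card(scaled_t, normalization_factor(scaled_r)).values
        assert np.allclose(base.to_numpy(), scaled.to_numpy())

    def test_doubling_one_cell_shifts_it_by_one_log2(self):
        rq = random_rq(5, 200, seed=11)
        nf = pd.Series(1.0, index=rq.columns)
        base = normalize_card(rq, nf).values
        bumped = rq.copy()
        bumped.loc["G2", "S17"] *= 2.0
        out = normalize_card(bumped, nf).values
        delta = (out - base).to_numpy()
        i, j = rq.index.get_loc("G2"), rq.columns.get_loc("S17")
        assert out.loc["G2", "S17"] - base.loc["G2", "S17"] == pytest.approx(1.0, abs=0.05)
        others = np.delete(delta[i], j)
        assert np.max(np.abs(others)) < 0.05
        assert np.allclose(np.delete(delta, i, axis=0), 0.0)

    def test_zero_rq_rejected(self):
        rq = pd.DataFrame({"S1": [0.0], "S2": [1.0]}, index=["G1"])
        with pytest.raises(ExpressionError):
            normalize_card(rq, pd.Series(1.0, index=rq.columns))

    def test_mostly_missing_gene_dropped(self):
        rq = random_rq(3, 4, seed=12)
        rq.loc["G1", ["S0", "S1", "S2"]] = np.nan
        out = normalize_card(rq, pd.Series(1.0, index=rq.columns))
        assert out.dropped_genes == ["G1"]
        assert "G1" not in out.values.index


class TestDifferentialPanel:
    @staticmethod
    def run_panel(seed, effect_genes, ct_sd=0.3, n_per_class=5):
        classes = {f"R{i}": "Responder" for i in range(n_per_class)}
        classes.update({f"N{i}": "NonResponder" for i in range(n_per_class)})
        params = synthetic.ExpressionParams(seed=seed, ct_sd=ct_sd, effect_genes=effect_genes)
        ct = synthetic.generate_ct_table(classes, params)
        rq = relative_quantity(ct)
        refs = list(params.reference_genes)
        nf = normalization_factor(rq.loc[refs])
        matrix = normalize_card(rq.drop(index=refs), nf)
        labels = ct.drop_duplicates("sample_id").set_index("sample_id")["class"]
        return differential_panel(matrix, labels)

    def test_planted_gene_ranks_first(self):
        result = self.run_panel(0, {"BIRC5": 2.0})
        assert result.iloc[0]["gene"] == "BIRC5"
        assert result.iloc[0]["log2_diff"] > 1.0  # NonResponder minus Responder

    def test_fdr_monotone_nondecreasing_with_rank(self):
        result = self.run_panel(1, {"BIRC5": 2.0, "BIRC3": 1.0})
        assert (np.diff(result["fdr"].cummax()) >= -1e-15).all()
        assert ((result["p"] > 0) & (result["p"] <= 1)).all()

    def test_zero_variance_zero_difference_gene_gets_p_one(self):
        rq = pd.DataFrame(
            {"S1": [1.0, 1.0], "S2": [1.0, 2.0], "S3": [1.0, 1.5], "S4": [1.0, 2.5]},
            index=["flat", "vary"],
        )
        matrix = normalize_card(rq, pd.Series(1.0, index=rq.columns))
        labels = pd.Series(["A", "A", "B", "B"], index=rq.columns)
        result = differential_panel(matrix, labels).set_index("gene")
        assert result.loc["flat", "p"] == 1.0

    def test_single_class_errors(self):
        rq = random_rq(4, 6, seed=13)
        matrix = normalize_card(rq, pd.Series(1.0, index=rq.columns))
        labels = pd.Series("A", index=rq.columns)
        with pytest.raises(ExpressionError):
            differential_panel(matrix, labels)

    def test_null_panel_p_uniform(self):
        # no planted effects: pooled per-gene p-values should look U(0,1)
        ps = []
        for seed in range(8):
            ps.extend(self.run_panel(seed, {}, n_per_class=5)["p"].tolist())
        assert stats.kstest(ps, "uniform").pvalue > 1e-4


class TestDeltaCt:
    @pytest.mark.parametrize("dct,expected", [(0, 1.0), (1, 0.5), (-2, 4.0)])
    def test_powers_of_two(self, dct, expected):
        assert delta_ct_quant(24.0 + dct, 24.0) == pytest.approx(expected)

    def test_undetermined_propagates_missing(self):
        assert np.isnan(delta_ct_quant(np.nan, 24.0))
        assert np.isnan(delta_ct_quant(24.0, np.nan))

    def test_vectorized(self):
        out = delta_ct_quant(np.array([24.0, 25.0]), np.array([24.0, 24.0]))
        assert out == pytest.approx([1.0, 0.5])


def test_panel_fixture_has_92_targets_and_3_references():
    panel = load_panel_fixture()
    assert (panel["role"] == "target").sum() == 92
    assert list(panel.loc[panel["role"] == "reference", "gene"]) == ["ACTB", "TBP", "HMBS"]
    assert {"BIRC5", "BIRC3", "TNF"} <= set(panel.loc[panel["status"] == "reported", "gene"])
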