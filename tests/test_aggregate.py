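import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from exondiff.aggregate import (
    DEFAULT_MC_REPS,
    DEFAULT_MC_SEED,
    NullTable,
    bh_adjust,
    call_genes,
    gene_median_score,
    gene_null_pvalue,
    get_null_table,
    null_tail,
    score_genes,
    signed_log_p,
)

# small Monte Carlo tables keep the unit suite fast; the full-size default
# tables are exercised by the pipeline tests
MC = dict(mc_reps=200_000, mc_seed=DEFAULT_MC_SEED)


class TestSignedLogP:
    def test_least_significant_p_maps_to_zero(self):
        assert signed_log_p(1.0, 2.3) == 0.0

    def test_definition(self):
        assert signed_log_p(math.exp(-3), -1.0) == pytest.approx(-3.0)

    def test_zero_fold_change_contributes_zero(self):
        assert signed_log_p(0.5, 0.0) == 0.0

    def test_p_zero_clamped(self):
        s = signed_log_p(0.0, 1.0)
        assert s == pytest.approx(-math.log(1e-300))

    @given(
        p=st.floats(1e-12, 1.0),
        x=st.floats(-10, 10, allow_nan=False),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_sign_follows_fold_change(self, p, x):
        s = signed_log_p(p, x)
        assert np.sign(s) == np.sign(x) * (1.0 if p < 1.0 else 0.0)


class TestGeneMedianScore:
    @pytest.mark.parametrize(
        "scores,expected",
        [([2, 3, 10], 3.0), ([1, 2, 3, 4], 2.5), ([-5, 0.1, 4], 0.1)],
    )
    def test_median_convention(self, scores, expected):
        assert gene_median_score(scores) == pytest.approx(expected)

    def test_mean_aggregator(self):
        assert gene_median_score([1, 2, 9], aggregator="mean") == pytest.approx(4.0)

    def test_single_exon_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            gene_median_score([3.0])


class TestNullTail:
    @pytest.mark.parametrize("n", [1, 2, 3, 4, 7, 10])
    def test_tail_at_zero_is_one(self, n):
        assert null_tail(n, 0.0, **MC) == pytest.approx(1.0)

    def test_n1_is_laplace_tail(self):
        assert null_tail(1, 2.0) == pytest.approx(math.exp(-2), rel=1e-12)

    def test_n3_closed_form_spot_value(self):
        q = math.exp(-1) / 2
        expected = 2 * (3 * q**2 * (1 - q) + q**3)
        assert null_tail(3, 1.0) == pytest.approx(expected, rel=1e-12)
        assert null_tail(3, 1.0) == pytest.approx(0.17811, abs=5e-5)

    @pytest.mark.parametrize("n", list(range(2, 51, 7)) + [49, 50])
    def test_strictly_decreasing_in_t(self, n):
        reps = dict(mc_reps=100_000, mc_seed=DEFAULT_MC_SEED)
        ts = [0.25, 0.5, 1.0, 2.0]
        vals = [null_tail(n, t, **reps) for t in ts]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_negative_t_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            null_tail(3, -0.5)

    def test_even_n_matches_monte_carlo_oracle(self):
        # independent draw with a different generator seed
        rng = np.random.default_rng(977)
        med = np.abs(np.median(rng.laplace(size=(500_000, 4)), axis=1))
        for t in (0.5, 1.0, 2.0):
            emp = (med >= t).mean()
            se = math.sqrt(emp * (1 - emp) / med.size)
            assert null_tail(4, t) == pytest.approx(emp, abs=4 * se)

    def test_cache_file_reloads_bit_exact(self, tmp_path):
        tab = get_null_table(6, **MC, cache_dir=tmp_path)
        path = tmp_path / f"null_n6_reps{MC['mc_reps']}_seed{MC['mc_seed']}.json"
        assert path.exists()
        tab2 = NullTable.from_json(path)
        np.testing.assert_array_equal(tab.t_grid, tab2.t_grid)
        np.testing.assert_array_equal(tab.log_tail_grid, tab2.log_tail_grid)
        assert tab.ext_slope == tab2.ext_slope


class TestGeneNullPvalue:
    def test_zero_score_gives_one(self):
        assert gene_null_pvalue(0.0, 5) == pytest.approx(1.0)

    def test_n1_self_consistency(self):
        # with a single score the null tail is the Laplace tail, i.e. the
        # back-transformed magnitude itself
        for m in (0.3, 1.7, -2.5):
            assert gene_null_pvalue(m, 1) == pytest.approx(math.exp(-abs(m)), rel=1e-12)

    def test_sign_symmetry(self):
        assert gene_null_pvalue(-1.8, 7) == gene_null_pvalue(1.8, 7)


class TestBHAdjust:
    def test_step_up_example(self):
        adj = bh_adjust([0.01, 0.02, 0.04])
        np.testing.assert_allclose(adj, [0.03, 0.03, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_ones_stay_one(self):
        assert (bh_adjust([1.0, 1.0, 1.0]) == 1.0).all()

    def test_matches_brute_force_oracle(self):
        def oracle(p):
            p = np.asarray(p, float)
            n = len(p)
            order = np.argsort(p, kind="mergesort")
            adj = np.empty(n)
            running = 1.0
            for rank in range(n, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * n / rank)
                adj[i] = running
            return adj

        rng = np.random.default_rng(99)
        for _ in range(1000):
            p = rng.random(rng.integers(1, 40))
            np.testing.assert_allclose(bh_adjust(p), oracle(p), atol=1e-12)


class TestScoreGenes:
    @staticmethod
    def exon_frame(gene_results):
        rows = []
        for gene, entries in gene_results.items():
            for x, p in entries:
                rows.append({"gene_id": gene, "x": x, "p": p})
        return pd.DataFrame(rows)

    def test_back_transform_consistency(self):
        df = self.exon_frame({"G1": [(1.0, 0.01)] * 4, "G2": [(0.1, 0.9)] * 3})
        scores = score_genes(df, **MC)
        g1 = scores.set_index("gene_id").loc["G1"]
        assert g1["median_p"] == pytest.approx(0.01)
        assert g1["median_p"] == pytest.approx(math.exp(-abs(g1["score_m"])), rel=1e-12)

    def test_alternating_signs_cancel(self):
        df = self.exon_frame(
            {
                "Gmix": [(1.0, 0.001), (-1.0, 0.001), (1.0, 0.001), (-1.0, 0.001)],
                "Gup": [(1.0, 0.001)] * 4,
            }
        )
        scores = score_genes(df, **MC).set_index("gene_id")
        assert abs(scores.loc["Gmix", "score_m"]) < 1e-9
        assert scores.loc["Gmix", "final_score"] > 0.9
        assert scores.loc["Gup", "final_score"] < 0.05

    def test_final_score_is_max_rule(self):
        rng = np.random.default_rng(12)
        df = self.exon_frame(
            {f"G{i}": [(rng.normal(), rng.random()) for _ in range(3)] for i in range(30)}
        )
        scores = score_genes(df, **MC)
        np.testing.assert_allclose(
            scores["final_score"], np.maximum(scores["median_p"], scores["fdr"])
        )
        assert (scores["fdr"] >= scores["null_p"] - 1e-15).all()

    def test_flipping_all_signs_preserves_significance(self):
        rng = np.random.default_rng(13)
        df = self.exon_frame(
            {f"G{i}": [(rng.normal(1), rng.random() ** 2) for _ in range(5)] for i in range(20)}
        )
        flipped = df.assign(x=-df["x"])
        a = score_genes(df, **MC).set_index("gene_id")
        b = score_genes(flipped, **MC).set_index("gene_id")
        np.testing.assert_allclose(a["score_m"], -b["score_m"])
        np.testing.assert_allclose(a["null_p"], b["null_p"])
        np.testing.assert_allclose(a["fdr"], b["fdr"])
        np.testing.assert_allclose(a["final_score"], b["final_score"])

    def test_improving_exon_pvalues_never_raises_null_p(self):
        base = self.exon_frame({"G1": [(1.0, p) for p in (0.2, 0.1, 0.05, 0.3, 0.4)]})
        better = base.assign(p=base["p"] / 2)
        a = score_genes(base, **MC)["null_p"].iloc[0]
        b = score_genes(better, **MC)["null_p"].iloc[0]
        assert b <= a

    def test_null_inputs_give_uniform_null_p(self):
        from scipy import stats

        for seed in (1, 2, 3):
            rng = np.random.default_rng(seed)
            rows = []
            for i in range(5000):
                n = rng.integers(2, 13)
                rows.append(
                    pd.DataFrame(
                        {
                            "gene_id": f"G{i:05d}",
                            "x": rng.choice([-1.0, 1.0], size=n),
                            "p": rng.random(n),
                        }
                    )
                )
            df = pd.concat(rows, ignore_index=True)
            scores = score_genes(df)  # full-size default tables
            ks = stats.kstest(scores["null_p"], "uniform")
            assert ks.pvalue > 0.01


class TestCallGenes:
    @staticmethod
    def scores(**overrides):
        base = {
            "gene_id": ["G1"],
            "n_exons": [6],
            "median_log2fc": [1.0],
            "score_m": [6.9],
            "median_p": [0.001],
            "null_p": [1e-6],
            "fdr": [0.01],
            "final_score": [0.01],
        }
        base.update({k: [v] for k, v in overrides.items()})
        return pd.DataFrame(base)

    def test_passing_gene_called(self):
        out = call_genes(self.scores())
        assert bool(out["called"].iloc[0])

    def test_too_few_exons_not_called(self):
        out = call_genes(self.scores(n_exons=4))
        assert not bool(out["called"].iloc[0])

    def test_small_fold_change_not_called(self):
        out = call_genes(self.scores(median_log2fc=math.log2(1.2)))
        assert not bool(out["called"].iloc[0])

    def test_median_p_criterion_skippable_for_gene_based(self):
        out = call_genes(self.scores(median_p=0.2, final_score=0.01))
        assert not bool(out["called"].iloc[0])
        out2 = call_genes(self.scores(median_p=0.2, final_score=0.01), median_p_max=None)
        assert bool(out2["called"].iloc[0])
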