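"""Expression normalization and signature scoring."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import clonedyn as cd


def de_table(n_sig=30, n_nonsig=10, seed=5):
    rng = np.random.default_rng(seed)
    genes = [f"G{i:03d}" for i in range(n_sig + n_nonsig)]
    lfc = np.linspace(3.0, -3.0, n_sig + n_nonsig)
    padj = np.concatenate([np.full(n_sig, 0.001), np.full(n_nonsig, 0.5)])
    rng.shuffle(padj)  # significance not tied to rank
    order = np.argsort(-lfc)
    return pd.DataFrame({"gene": genes, "log2fc": lfc, "padj": padj}).iloc[order]


class TestNormalize:
    def test_row_centering(self):
        E = pd.DataFrame({"s1": [2.0], "s2": [4.0], "s3": [6.0]}, index=["g"])
        out = cd.normalize_expression(E)
        assert np.allclose(out.loc["G"], [-2.0, 0.0, 2.0])

    def test_constant_row_zeroed_and_idempotent(self):
        E = pd.DataFrame({"s1": [5.0, 1.0], "s2": [5.0, 3.0]}, index=["a", "b"])
        once = cd.normalize_expression(E)
        assert np.allclose(once.loc["A"], 0.0)
        twice = cd.normalize_expression(once)
        assert np.allclose(once.to_numpy(), twice.to_numpy())
        assert np.allclose(once.sum(axis=1), 0.0)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            cd.normalize_expression(pd.DataFrame({"s1": [1.0]}, index=["g"]))


class TestMakeSignature:
    def test_top_n_each_direction(self):
        de = pd.DataFrame(
            {
                "gene": list("abcde"),
                "log2fc": [3.0, 2.0, 0.0, -2.0, -3.0],
                "padj": [0.01] * 5,
            }
        )
        sig = cd.make_signature(de, top_n=2)
        assert set(sig.index) == {"A", "B", "D", "E"}

    def test_nonsignificant_extreme_excluded(self):
        de = pd.DataFrame(
            {
                "gene": ["hot", "a", "b", "c"],
                "log2fc": [9.0, 1.0, 0.5, -1.0],
                "padj": [0.9, 0.01, 0.01, 0.01],
            }
        )
        sig = cd.make_signature(de, top_n=2)
        assert "HOT" not in sig.index

    def test_all_significant_kept_with_none(self):
        de = de_table()
        sig = cd.make_signature(de, top_n=None)
        assert len(sig) == (de["padj"] < 0.05).sum()

    def test_empty_after_filter_raises(self):
        de = pd.DataFrame({"gene": ["a"], "log2fc": [1.0], "padj": [0.9]})
        with pytest.raises(ValueError, match="filter"):
            cd.make_signature(de)


class TestScoreSamples:
    def make_eprime(self, vectors):
        E = pd.DataFrame(vectors, index=["g1", "g2", "g3", "g4"])
        return cd.normalize_expression(E)

    def test_proportional_sample_scores_one(self):
        sig = pd.Series([2.0, 1.0, -1.0, -2.0], index=["g1", "g2", "g3", "g4"])
        Ep = pd.DataFrame({"s1": 3.0 * sig, "s2": -3.0 * sig})
        scores = cd.score_samples(Ep, sig)
        assert scores["s1"] == pytest.approx(1.0)
        assert scores["s2"] == pytest.approx(-1.0)

    def test_worked_four_gene_case(self):
        """Pearson of (2,1,-1,-2) with (1.0,0.8,-0.2,-1.6): r = 0.9522."""
        sig = pd.Series([2.0, 1.0, -1.0, -2.0], index=["g1", "g2", "g3", "g4"])
        Ep = pd.DataFrame({"s": [1.0, 0.8, -0.2, -1.6]},
                          index=["g1", "g2", "g3", "g4"])
        oracle = sps.pearsonr([2, 1, -1, -2], [1.0, 0.8, -0.2, -1.6]).statistic
        assert oracle == pytest.approx(0.95216, abs=1e-4)
        assert cd.score_samples(Ep, sig)["s"] == pytest.approx(oracle)

    def test_zero_variance_sample_is_nan(self):
        sig = pd.Series([2.0, 1.0, -1.0], index=["g1", "g2", "g3"])
        Ep = pd.DataFrame({"s": [0.5, 0.5, 0.5]}, index=["g1", "g2", "g3"])
        with pytest.warns(UserWarning, match="zero variance"):
            scores = cd.score_samples(Ep, sig)
        assert np.isnan(scores["s"])

    def test_score_invariances(self, rng):
        """Per-gene offsets in E and positive signature rescaling are nulled."""
        genes = [f"g{i}" for i in range(20)]
        sig = pd.Series(rng.normal(size=20), index=genes)
        E = pd.DataFrame(rng.normal(size=(20, 6)), index=genes,
                         columns=[f"s{i}" for i in range(6)])
        base = cd.score_samples(cd.normalize_expression(E), sig)
        shifted = cd.score_samples(
            cd.normalize_expression(E.add(pd.Series(rng.normal(size=20),
                                                    index=genes), axis=0)),
            sig * 7.3,
        )
        assert np.allclose(base, shifted)

    def test_planted_signature_ranks_by_dose(self, rng):
        """Samples built as c*sig + noise rank by their dose c."""
        genes = [f"g{i}" for i in range(120)]
        sig = pd.Series(rng.normal(size=120), index=genes)
        doses = np.linspace(-2, 2, 15)
        noise_scale = sig.std() / 2  # signal-to-noise 2
        Ep = pd.DataFrame(
            {f"s{i}": c * sig + rng.normal(0, noise_scale, 120)
             for i, c in enumerate(doses)},
            index=genes,
        )
        scores = cd.score_samples(Ep, sig)
        rho = sps.spearmanr(doses, scores).statistic
        assert rho >= 0.9


class TestCytolytic:
    def test_equal_tpm(self):
        E = pd.DataFrame({"s": [np.log2(4.0), np.log2(4.0)]},
                         index=["GZMA", "PRF1"])
        assert cd.cytolytic_score(E)["s"] == pytest.approx(4.01)

    def test_geometric_mean(self):
        E = pd.DataFrame({"s": [np.log2(4.0), np.log2(16.0)]},
                         index=["GZMA", "PRF1"])
        assert cd.cytolytic_score(E)["s"] == pytest.approx(
            np.sqrt(4.01 * 16.01)
        )

    def test_zero_tpm_floor(self):
        E = pd.DataFrame({"s": [-np.inf, -np.inf]}, index=["GZMA", "PRF1"])
        assert cd.cytolytic_score(E)["s"] == pytest.approx(0.01)

    def test_missing_gene_named(self):
        E = pd.DataFrame({"s": [1.0]}, index=["GZMA"])
        with pytest.raises(KeyError, match="PRF1"):
            cd.cytolytic_score(E)


class TestAssociateAndRobustness:
    def test_identical_groups_null(self):
        scores = pd.Series([0.3] * 6, index=[f"s{i}" for i in range(6)])
        labels = pd.Series(["R"] * 3 + ["NR"] * 3, index=scores.index)
        res = cd.associate_scores(scores, labels, mode="two_group_t")
        assert res["statistic"] == 0.0
        assert res["pvalue"] == 1.0

    def test_perfect_pearson(self):
        scores = pd.Series([0.1, 0.2, 0.3, 0.4], index=list("abcd"))
        res = cd.associate_scores(scores, scores * 2 + 1, mode="pearson")
        assert res["statistic"] == pytest.approx(1.0)

    def test_small_de_collapses_grid(self, rng):
        de = de_table(n_sig=30)
        genes = de["gene"].str.upper()
        Ep = pd.DataFrame(rng.normal(size=(len(genes), 5)),
                          index=genes, columns=[f"s{i}" for i in range(5)])
        Ep = cd.normalize_expression(Ep)
        scores, _ = cd.robustness_grid(de, Ep, grid=(200, None))
        assert np.allclose(scores["200"], scores["all"])

    def test_planted_cohort_is_sign_consistent(self, rng):
        de = de_table(n_sig=400, n_nonsig=50, seed=11)
        sig_all = cd.make_signature(de, top_n=None)
        doses = np.concatenate([np.linspace(0.5, 2, 5), -np.linspace(0.5, 2, 5)])
        Ep = pd.DataFrame(
            {f"s{i}": c * sig_all + rng.normal(0, 0.3, len(sig_all))
             for i, c in enumerate(doses)},
            index=sig_all.index,
        )
        scores, consistency = cd.robustness_grid(de, Ep, grid=(200, 400, None))
        assert consistency == 1.0

    def test_grid_of_one_matches_plain_scoring(self, rng):
        de = de_table()
        sig = cd.make_signature(de, top_n=200)
        Ep = pd.DataFrame(rng.normal(size=(40, 4)),
                          index=de["gene"].str.upper(),
                          columns=list("wxyz"))
        Ep = cd.normalize_expression(Ep)
        grid_scores, _ = cd.robustness_grid(de, Ep, grid=(200,))
        assert np.allclose(grid_scores["200"], cd.score_samples(Ep, sig))


class TestSignatureOnSimulatedCohorts:
    @staticmethod
    def _intrinsic_signature(gene_truth):
        res = gene_truth[gene_truth["block"] == "intrinsic"]
        de = pd.DataFrame(
            {"gene": list(res.index), "log2fc": 0.4 * res["slope"].to_numpy(),
             "padj": np.full(len(res), 1e-4)}
        )
        return cd.make_signature(de, top_n=200)

    def test_resistance_scores_higher_in_responders(self):
        """On-treatment responders carry more resistant clones and score
        higher for the intrinsic-resistance signature (5 seeds)."""
        hits = 0
        for seed in range(1, 6):
            sim = cd.simulate_experiment(seed=seed)
            E, gt = cd.simulate_expression(sim, n_genes=300, seed=seed,
                                           return_truth=True)
            scores = cd.score_samples(cd.normalize_expression(E),
                                      self._intrinsic_signature(gt))
            meta = sim.meta.set_index("sample")
            ctrl = meta.loc[meta["arm"] == "IgG", "size_end"]
            treated = meta.loc[meta["arm"] != "IgG", "size_end"]
            calls = cd.classify_response(treated, ctrl)["label"]
            r = scores[calls.index[calls == "responder"]].mean()
            n = scores[calls.index[calls == "non_responder"]].mean()
            hits += r > n
        assert hits >= 4

    def test_scores_correlate_with_cytolytic_activity(self):
        """Signature scores track GZMA/PRF1 cytolytic activity positively."""
        hits = 0
        for seed in range(1, 6):
            sim = cd.simulate_experiment(seed=seed)
            E, gt = cd.simulate_expression(sim, n_genes=300, seed=seed,
                                           return_truth=True)
            scores = cd.score_samples(cd.normalize_expression(E),
                                      self._intrinsic_signature(gt))
            cyt = cd.cytolytic_score(E)
            res = cd.associate_scores(scores, np.log(cyt), mode="pearson")
            hits += res["statistic"] > 0
        assert hits >= 4


class TestSimulatedExpression:
    def test_immune_block_tracks_host_effect(self):
        sim = cd.simulate_experiment(seed=3)
        E = cd.simulate_expression(sim, n_genes=300, seed=3)
        h = sim.meta.set_index("sample")["mouse"].map(sim.truth.host_effect)
        imm = E.loc[E.index.str.startswith("IMM")].mean(axis=0)
        r = sps.pearsonr(imm, h.loc[imm.index]).statistic
        assert r > 0.8

    def test_resistant_block_monotone_in_resistant_fraction(self):
        sim = cd.simulate_experiment(seed=3)
        E = cd.simulate_expression(sim, n_genes=300, seed=3)
        res_clusters = sim.config.resistant_clusters
        is_res = sim.truth.clone_cluster.isin(res_clusters)
        rf = sim.truth.harvest_freq.loc[is_res].sum(axis=0)
        res_mean = E.loc[E.index.str.startswith("RES")].mean(axis=0)
        lo, hi = rf.idxmin(), rf.idxmax()
        assert res_mean[hi] > res_mean[lo]

    def test_too_few_genes_rejected(self):
        sim = cd.simulate_experiment(cd.SimConfig(
            mice_per_arm={"IgG": 2, "antiPD1": 2, "antiCTLA4": 2}), seed=0)
        with pytest.raises(ValueError, match="n_genes"):
            cd.simulate_expression(sim, n_genes=10)
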