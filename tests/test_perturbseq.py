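import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from perturbdecode import perturbseq as ps
from perturbdecode.perturbseq import GASignature
from perturbdecode.simulate import PerturbseqSimConfig, simulate_perturbseq


def _adata(x, genes=None, cells=None, obs=None):
    x = np.asarray(x)
    genes = genes or [f"g{i}" for i in range(x.shape[1])]
    cells = cells or [f"c{i}" for i in range(x.shape[0])]
    obs = obs if obs is not None else pd.DataFrame(index=cells)
    obs.index = pd.Index(cells)
    return ad.AnnData(X=x.astype(float), obs=obs,
                      var=pd.DataFrame(index=pd.Index(genes)))


class TestAssignPerturbations:
    def _guides(self, rows, names=("T1_sg1", "T2_sg1", "NTC_sg1")):
        g = _adata(rows, genes=list(names))
        g.var["target"] = [n.split("_sg")[0] for n in names]
        return g

    def test_singlet_assigned_to_target(self):
        g = self._guides([[12, 0, 0]])
        out = ps.assign_perturbations(g, min_umi=3)
        assert out.iloc[0].tolist() == ["T1", "T1_sg1", "singlet"]

    def test_two_guides_is_multiplet(self):
        g = self._guides([[12, 9, 0]])
        out = ps.assign_perturbations(g, min_umi=3)
        assert out.iloc[0]["status"] == "multiplet"

    def test_subthreshold_guides_ignored(self):
        # second guide below min_umi is background, not a multiplet
        g = self._guides([[12, 2, 0], [1, 2, 0]])
        out = ps.assign_perturbations(g, min_umi=3)
        assert out.iloc[0]["status"] == "singlet"
        assert out.iloc[1]["status"] == "unassigned"

    def test_ntc_maps_to_control_label(self):
        g = self._guides([[0, 0, 8]])
        assert ps.assign_perturbations(g).iloc[0]["perturbation"] == "NTC"

    def test_min_umi_validation(self):
        with pytest.raises(ValueError):
            ps.assign_perturbations(self._guides([[1, 0, 0]]), min_umi=0)

    def test_multiplet_fraction_matches_binomial_oracle(self):
        """Called multiplet fraction within 2 s.e. of the planted rate."""
        cfg = PerturbseqSimConfig(seed=21, multiplet_rate=0.1)
        _, guides, _, truth = simulate_perturbseq(cfg)
        out = ps.assign_perturbations(guides, min_umi=3)
        n = guides.n_obs
        frac = (out["status"] == "multiplet").mean()
        se = np.sqrt(0.1 * 0.9 / n)
        assert abs(frac - 0.1) <= 2 * se + 0.01  # +1% slack for capture noise


class TestNormalize:
    def test_zero_count_is_zero(self):
        norm = ps.normalize(_adata([[0, 10]]), scale=1e4)
        assert norm.X[0, 0] == 0.0

    def test_tp10k_arithmetic(self):
        # count 10 of cell total 100 at tp10k -> log2(1 + 1000)
        x = np.array([[10] + [90] + [0] * 8])
        norm = ps.normalize(_adata(x), scale=1e4, log_base=2)
        assert norm.X[0, 0] == pytest.approx(np.log2(1 + 1000.0))

    def test_order_statistics_preserved_within_cell(self, rng):
        x = rng.integers(0, 40, (5, 30))
        norm = ps.normalize(_adata(x), scale=1e4)
        for i in range(5):
            assert (np.argsort(x[i], kind="stable")
                    == np.argsort(norm.X[i], kind="stable")).all()

    def test_zero_total_cells_dropped(self):
        norm = ps.normalize(_adata([[0, 0], [3, 1]]))
        assert norm.n_obs == 1

    def test_scale_validation(self):
        with pytest.raises(ValueError):
            ps.normalize(_adata([[1]]), scale=0)


class TestPseudobulk:
    def test_six_profiles_per_guide(self, assigned):
        counts, meta = assigned
        one = meta[meta["guide"] == meta["guide"].iloc[0]]
        pb = ps.make_pseudobulk(counts[meta["guide"] == meta["guide"].iloc[0]],
                                one, keys=("guide", "condition", "batch"))
        assert pb.n_obs == 6  # 2 conditions x 3 batches

    def test_count_conservation(self, assigned):
        counts, meta = assigned
        pb = ps.make_pseudobulk(counts, meta, keys=("perturbation", "condition", "batch"))
        assert pb.X.sum() == pytest.approx(np.asarray(counts.X).sum())

    def test_single_cell_group_equals_cell(self):
        obs = pd.DataFrame({"grp": ["a"]})
        adata = _adata([[3, 7, 1]], obs=obs)
        pb = ps.make_pseudobulk(adata, adata.obs, keys=("grp",))
        np.testing.assert_array_equal(pb.X[0], [3, 7, 1])

    def test_empty_groups_raise(self):
        adata = _adata([[1]], obs=pd.DataFrame({"grp": ["a"]}))
        with pytest.raises(ValueError):
            ps.make_pseudobulk(adata, adata.obs.iloc[:0], keys=("grp",))


class TestZScores:
    def _pb(self, profiles, guides, conditions, batches, mode="mean_norm"):
        obs = pd.DataFrame({"guide": guides, "condition": conditions, "batch": batches})
        pb = _adata(profiles, obs=obs)
        pb.uns["mode"] = mode
        return pb

    def test_identical_to_control_gives_zero(self):
        prof = np.tile([1.0, 2.0, 3.0], (4, 1))
        pb = self._pb(prof[:2], ["k", "k"], ["mono", "co"], ["b1", "b1"])
        ctrl = self._pb(prof[:2], ["NTC", "NTC"], ["mono", "co"], ["b1", "b1"])
        z = ps.sgrna_zscore(pb, ctrl)
        np.testing.assert_allclose(z.loc["k"], 0.0)

    def test_single_stratum_equals_difference(self):
        pb = self._pb([[5.0, 1.0]], ["k"], ["mono"], ["b1"])
        ctrl = self._pb([[2.0, 4.0]], ["NTC"], ["mono"], ["b1"])
        z = ps.sgrna_zscore(pb, ctrl)
        np.testing.assert_allclose(z.loc["k"], [3.0, -3.0])

    def test_matches_brute_force_double_loop(self, rng):
        """Z_k equals the explicit (1/JI) double sum on a random 3-batch
        2-condition instance with all strata observed."""
        J, I, G = 3, 2, 7
        strata = [(c, b) for c in ("mono", "co") for b in ("b1", "b2", "b3")]
        prof_k = rng.normal(size=(J * I, G))
        prof_c = rng.normal(size=(J * I, G))
        pb = self._pb(prof_k, ["k"] * 6, [s[0] for s in strata], [s[1] for s in strata])
        ctrl = self._pb(prof_c, ["NTC"] * 6, [s[0] for s in strata],
                        [s[1] for s in strata])
        z = ps.sgrna_zscore(pb, ctrl)
        brute = np.zeros(G)
        for i in range(J * I):
            brute += prof_k[i] - prof_c[i]
        brute /= J * I
        np.testing.assert_allclose(z.loc["k"], brute, atol=1e-12)

    def test_missing_control_stratum_raises(self):
        pb = self._pb([[1.0]], ["k"], ["co"], ["b1"])
        ctrl = self._pb([[1.0]], ["NTC"], ["mono"], ["b1"])
        with pytest.raises(ValueError, match="control profile"):
            ps.sgrna_zscore(pb, ctrl)

    def test_requires_mean_norm_mode(self):
        pb = self._pb([[1.0]], ["k"], ["mono"], ["b1"], mode="sum")
        with pytest.raises(ValueError, match="mean-normalized"):
            ps.sgrna_zscore(pb, pb)


class TestConcordance:
    def test_duplicated_row_has_unit_correlation(self, rng):
        z = pd.DataFrame(rng.normal(size=(3, 20)), index=["a_sg1", "a_sg2", "b_sg1"])
        z.loc["a_sg2"] = z.loc["a_sg1"]
        res = ps.concordance(z, {"a_sg1": "a", "a_sg2": "a", "b_sg1": "b"})
        pair = res["pairs"].query("stratum == 'same'")
        assert pair["r"].iloc[0] == pytest.approx(1.0)

    def test_constant_row_excluded(self, rng):
        z = pd.DataFrame(rng.normal(size=(3, 10)), index=["a_sg1", "a_sg2", "b_sg1"])
        z.loc["b_sg1"] = 0.0
        res = ps.concordance(z, {"a_sg1": "a", "a_sg2": "a", "b_sg1": "b"})
        assert set(res["pairs"]["stratum"]) == {"same"}

    def test_planted_effects_stratify(self, assigned, perturbseq_sim):
        """Same-target pairs correlate above different-target and NTC pairs."""
        counts, meta = assigned
        z = ps.guide_zscores(counts, meta)
        gt = meta.groupby("guide")["perturbation"].first().to_dict()
        res = ps.concordance(z, gt)
        assert res["median_r"]["same"] > res["median_r"]["different"]
        assert res["p_same_vs_different"] < 0.01
        assert abs(res["median_r"]["ntc"]) < res["median_r"]["same"]
        assert res["p_same_vs_ntc"] < 0.01


class TestSignatures:
    def _de(self, genes, fdr, lfc):
        return pd.DataFrame({"log2fc": lfc, "p": fdr, "fdr": fdr},
                            index=pd.Index(genes, name="gene"))

    def test_empty_significant_set(self):
        de = self._de(["a", "b"], [0.5, 0.9], [1.0, -1.0])
        sig = ps.extract_ga_signature(de, de, "T")
        assert not sig.up and not sig.down

    def test_gene_significant_in_one_condition_included(self):
        # the coculture-only behavior: significant only in co still enters
        mono = self._de(["a"], [0.9], [0.1])
        co = self._de(["a"], [0.001], [2.0])
        sig = ps.extract_ga_signature(mono, co, "T")
        assert "a" in sig.up

    def test_conflicts_resolved_by_smaller_fdr(self):
        mono = self._de(["a"], [0.001], [1.0])
        co = self._de(["a"], [0.0001], [-1.0])
        sig = ps.extract_ga_signature(mono, co, "T")
        assert "a" in sig.down and "a" in sig.conflicts

    def test_mismatched_universes_raise(self):
        with pytest.raises(ValueError):
            ps.extract_ga_signature(self._de(["a"], [1], [0]),
                                    self._de(["b"], [1], [0]), "T")

    def test_planted_recovery_jaccard(self, assigned, perturbseq_sim):
        _, _, _, _, truth = perturbseq_sim
        counts, meta = assigned
        target = sorted(truth.effects)[0]
        sig = ps.run_target_de(counts, meta, target, fdr=0.01)
        planted = truth.effects[target]["up"] | truth.effects[target]["down"]
        rec = set(sig.up) | set(sig.down)
        assert len(planted & rec) / len(planted | rec) >= 0.6

    def test_up_down_overlap_rejected(self):
        with pytest.raises(ValueError):
            GASignature(target="T", up=frozenset({"a"}), down=frozenset({"a"}))


class TestScoreSignature:
    def test_single_up_gene_is_zscore(self, rng):
        x = rng.normal(2, 1, (30, 3))
        norm = _adata(x)
        norm.uns["scale"] = 1e4
        sig = GASignature(target="T", up=frozenset({"g1"}))
        s = ps.score_signature(norm, sig)
        expect = (x[:, 1] - x[:, 1].mean()) / x[:, 1].std()
        np.testing.assert_allclose(s.to_numpy(), expect, atol=1e-12)

    def test_up_equals_down_cancels(self, rng):
        x = rng.normal(size=(20, 4))
        norm = _adata(x)
        sig_up = GASignature(target="T", up=frozenset({"g0", "g1"}))
        sig_both = GASignature(target="U", up=frozenset({"g0", "g1"}),
                               down=frozenset({"g2", "g3"}))
        sig_mirror = GASignature(target="V", up=frozenset({"g2", "g3"}))
        s = ps.score_signature(norm, sig_both)
        np.testing.assert_allclose(
            s.to_numpy(),
            ps.score_signature(norm, sig_up).to_numpy()
            - ps.score_signature(norm, sig_mirror).to_numpy(), atol=1e-12)

    def test_no_genes_present_raises(self, rng):
        norm = _adata(rng.normal(size=(5, 2)))
        with pytest.raises(ValueError, match="no signature genes"):
            ps.score_signature(norm, GASignature(target="T", up=frozenset({"zz"})))

    def test_perturbed_cells_score_higher(self, assigned, perturbseq_sim):
        _, _, _, _, truth = perturbseq_sim
        counts, meta = assigned
        target = sorted(truth.effects)[0]
        sig = GASignature(target=target,
                          up=frozenset(truth.effects[target]["up"]),
                          down=frozenset(truth.effects[target]["down"]))
        norm = ps.normalize(counts)
        s = ps.score_signature(norm, sig)
        perturbed = s[meta.index[meta["perturbation"] == target]]
        control = s[meta.index[meta["perturbation"] == "NTC"]]
        assert stats.ttest_ind(perturbed, control, alternative="greater").pvalue < 0.05


class TestConditionResponse:
    def test_planted_program_recovered(self, assigned, perturbseq_sim):
        _, _, _, _, truth = perturbseq_sim
        counts, meta = assigned
        res = ps.condition_response(counts, meta, fdr=0.01)
        planted_up = truth.condition_program["up"]
        found = res["co_up"]
        assert found, "no co-UP genes recovered"
        precision = len(found & planted_up) / len(found)
        assert precision >= 0.8

    def test_threshold_is_strict(self):
        de = pd.DataFrame({"log2fc": [0.25, 0.26], "p": [1e-6, 1e-6],
                           "fdr": [1e-6, 1e-6]},
                          index=pd.Index(["at", "above"], name="gene"))
        co_up = set(de.index[(de.fdr < 0.01) & (de.log2fc > 0.25)])
        assert co_up == {"above"}  # the boundary gene is excluded

    def test_missing_condition_raises(self, assigned):
        counts, meta = assigned
        mono = meta[meta["condition"] == "mono"]
        with pytest.raises(ValueError):
            ps.condition_response(counts[(meta["condition"] == "mono").to_numpy()], mono)


class TestLoocv:
    def test_needs_three_guides(self, assigned):
        counts, meta = assigned
        bad = meta.copy()
        bad.loc[bad["perturbation"] == "G0000", "guide"] = "G0000_sg1"
        with pytest.raises(ValueError, match="guides"):
            ps.loocv_sgrna(counts, bad, "G0000")

    def test_auroc_matches_rank_sum(self, assigned, perturbseq_sim):
        _, _, _, _, truth = perturbseq_sim
        counts, meta = assigned
        target = sorted(truth.effects)[0]
        res = ps.loocv_sgrna(counts, meta, target)
        assert len(res) == 3
        assert ((res["auroc"] >= 0) & (res["auroc"] <= 1)).all()
        # strong planted effects: every held-out guide is recognized
        assert res["auroc"].mean() > 0.8
        assert (res["t_p"] < 0.05).all()
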