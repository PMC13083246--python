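import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from perturbdecode import spatial as sp
from perturbdecode.simulate import (
    InSituSimConfig,
    simulate_fov_confounded,
    simulate_gxe_cells,
    simulate_insitu,
)


def _adata(x, genes=None, obs=None):
    x = np.asarray(x)
    genes = genes or [f"g{i}" for i in range(x.shape[1])]
    cells = [f"c{i}" for i in range(x.shape[0])]
    obs = obs if obs is not None else pd.DataFrame(index=cells)
    obs.index = pd.Index(cells)
    return ad.AnnData(X=x.astype(float), obs=obs,
                      var=pd.DataFrame(index=pd.Index(genes)))


class TestZonation:
    def test_single_orf_degenerate(self, rng):
        meta = pd.DataFrame({
            "x": rng.uniform(0, 100, 30), "y": rng.uniform(0, 100, 30),
            "cell_type": "cancer", "tumor": "t", "orf": "A",
        })
        res = sp.zonation_test(meta, n_perm=49, seed=0)
        assert res["statistic"].iloc[0] == pytest.approx(1.0)
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_p_never_below_permutation_floor(self, rng):
        meta = pd.DataFrame({
            "x": rng.uniform(0, 100, 60), "y": rng.uniform(0, 100, 60),
            "cell_type": "cancer", "tumor": "t",
            "orf": ["A"] * 30 + ["B"] * 30,
        })
        meta.loc[meta.orf == "A", "x"] = rng.uniform(0, 5, 30)  # extreme clustering
        res = sp.zonation_test(meta, n_perm=99, seed=0)
        assert (res["p"] >= 1.0 / 100).all()

    def test_planted_clones_detected(self, insitu_sim):
        _, _, meta, _, _, _ = insitu_sim
        res = sp.zonation_test(meta, n_perm=199, seed=0)
        ok = res.dropna(subset=["p"])
        assert (ok["p"] < 0.05).all()

    def test_small_orfs_skipped(self, rng):
        meta = pd.DataFrame({
            "x": rng.uniform(0, 100, 31), "y": rng.uniform(0, 100, 31),
            "cell_type": "cancer", "tumor": "t",
            "orf": ["A"] * 30 + ["B"],
        })
        res = sp.zonation_test(meta, n_perm=49, seed=0)
        assert np.isnan(res.loc[res.orf == "B", "p"]).all()


class TestSpatialGA:
    def _confounded(self, seed=0):
        counts, meta, true_genes = simulate_fov_confounded(seed=seed)
        meta = meta.rename(columns={"orf": "orf_indicator"})
        return counts, meta, true_genes

    def test_planted_effects_recovered(self, insitu_sim):
        _, counts, meta, truth, _, _ = insitu_sim
        mask = ((meta.cell_type == "cancer") & meta.orf.isin(["ORF1", "CTRL"])).to_numpy()
        m2 = meta[mask].copy()
        m2["orf_indicator"] = (m2["orf"] == "ORF1").astype(int)
        de = sp.spatial_ga(counts[mask], m2, fdr=0.1)
        planted = truth.effects["ORF1"]["up"] | truth.effects["ORF1"]["down"]
        sig = set(de.index[de["fdr"] < 0.1])
        assert len(sig & planted) / len(planted) >= 0.8

    def test_fov_confounded_gene_controlled(self):
        """A gene driven by FOV identity rather than the perturbation is
        flagged by the FOV-blind hurdle model but not the mixed model."""
        counts, meta, true_genes = self._confounded(3)
        null_genes = [g for g in counts.var_names if g not in true_genes]
        de_mix = sp.spatial_ga(counts, meta, fdr=0.1)
        de_hur = sp.hurdle_ga(counts, meta, fdr=0.1)
        fp_mix = (de_mix.loc[de_mix.index.isin(null_genes), "fdr"] < 0.1).mean()
        fp_hur = (de_hur.loc[de_hur.index.isin(null_genes), "fdr"] < 0.1).mean()
        assert fp_hur > fp_mix

    def test_zero_variance_gene_excluded(self, rng):
        x = rng.poisson(5.0, (60, 3)).astype(float)
        x[:, 1] = 0.0  # never detected -> zero variance after normalization
        obs = pd.DataFrame({
            "fov": ["f1"] * 30 + ["f2"] * 30,
            "orf_indicator": rng.integers(0, 2, 60),
            "complexity": (x > 0).sum(axis=1),
        })
        adata = _adata(x, obs=obs)
        de = sp.spatial_ga(adata, adata.obs)
        assert "g1" in de.attrs["excluded"]

    def test_invariant_to_per_fov_shift(self, rng):
        """Adding a constant per-FOV (multiplicative) shift is absorbed by
        the random intercept: the ORF estimate barely moves."""
        n = 240
        obs = pd.DataFrame({
            "fov": np.repeat([f"f{i}" for i in range(8)], 30),
            "orf_indicator": rng.integers(0, 2, n),
            "complexity": rng.integers(50, 80, n),
        })
        base = rng.poisson(20.0, (n, 4)).astype(float)
        adata = _adata(base, obs=obs)
        de0 = sp.spatial_ga(adata, obs)
        shift = {f"f{i}": 2.0 ** rng.normal(0, 1) for i in range(8)}
        shifted = base * np.array([shift[f] for f in obs["fov"]])[:, None]
        de1 = sp.spatial_ga(_adata(shifted, obs=obs.copy()), obs)
        # TPM normalization makes a global per-FOV factor vanish exactly
        np.testing.assert_allclose(de0["log2fc"], de1["log2fc"], atol=0.05)

    def test_single_fov_falls_back_to_ols(self, rng, caplog):
        obs = pd.DataFrame({
            "fov": ["f1"] * 40,
            "orf_indicator": rng.integers(0, 2, 40),
            "complexity": rng.integers(10, 30, 40),
        })
        adata = _adata(rng.poisson(8.0, (40, 3)), obs=obs)
        with caplog.at_level("WARNING"):
            de = sp.spatial_ga(adata, obs)
        assert "single FOV" in caplog.text
        assert len(de) == 3


class TestHurdle:
    def test_detection_only_gene_significant(self, rng):
        n = 200
        orf = np.array([0] * 100 + [1] * 100)
        x = np.zeros((n, 1))
        x[orf == 1, 0] = rng.poisson(3.0, 100) + 1  # expressed in ORF cells only
        obs = pd.DataFrame({"orf_indicator": orf, "complexity": np.ones(n) * 10})
        de = sp.hurdle_ga(_adata(x, obs=obs), obs)
        assert de["p"].iloc[0] < 1e-4

    def test_all_zero_gene_flagged_single_part(self, rng):
        x = np.zeros((50, 1))
        obs = pd.DataFrame({"orf_indicator": rng.integers(0, 2, 50),
                            "complexity": np.ones(50)})
        de = sp.hurdle_ga(_adata(x, obs=obs), obs)
        assert de["flag"].iloc[0] == "single_part"

    def test_null_type_one_error_in_band(self, rng):
        n_cells, n_genes = 300, 120
        mu = np.exp(rng.normal(0.5, 0.8, n_genes))
        counts = rng.negative_binomial(2, 2 / (2 + mu[None, :]),
                                       size=(n_cells, n_genes))
        obs = pd.DataFrame({"orf_indicator": rng.integers(0, 2, n_cells),
                            "complexity": (counts > 0).sum(axis=1)})
        de = sp.hurdle_ga(_adata(counts, obs=obs), obs)
        rate = (de["p"] < 0.05).mean()
        assert 0.0 <= rate <= 0.1  # loose single-replicate band


class TestMicroFov:
    def test_abundances_sum_to_one(self, insitu_sim):
        _, counts, meta, _, _, _ = insitu_sim
        mf = sp.make_micro_fovs(counts, meta, mode="tile", tile_size=250.0)
        sums = mf.abundance.sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)

    def test_pure_tile_has_unit_abundance(self, rng):
        meta = pd.DataFrame({
            "x": rng.uniform(0, 99, 40), "y": rng.uniform(0, 99, 40),
            "tumor": "t", "cell_type": "cancer", "orf": "A",
        }, index=[f"c{i}" for i in range(40)])
        counts = _adata(rng.poisson(5.0, (40, 6)), obs=meta)
        mf = sp.make_micro_fovs(counts, meta, mode="tile", tile_size=100.0)
        assert (mf.abundance["A"] == 1.0).all()

    def test_tile_tally_matches_geometry_oracle(self, rng):
        n = 300
        meta = pd.DataFrame({
            "x": rng.uniform(0, 500, n), "y": rng.uniform(0, 500, n),
            "tumor": "t", "cell_type": "cancer",
            "orf": rng.choice(["A", "B"], n),
        }, index=[f"c{i}" for i in range(n)])
        counts = _adata(rng.poisson(5.0, (n, 4)), obs=meta)
        mf = sp.make_micro_fovs(counts, meta, mode="tile", tile_size=100.0)
        # brute-force point-in-tile assignment
        for mfov in mf.abundance.index:
            _, tile = mfov.split("|")
            tx, ty = map(int, tile.split("_"))
            inside = meta[(meta.x // 100 == tx) & (meta.y // 100 == ty)]
            for orf in ("A", "B"):
                expect = (inside["orf"] == orf).mean()
                assert mf.abundance.loc[mfov, orf] == pytest.approx(expect)
        # conservation: every cell lands in exactly one tile
        assert mf.cells.value_counts().sum() == n

    def test_sparse_cell_types_excluded_from_profiles(self, insitu_sim):
        _, counts, meta, _, _, _ = insitu_sim
        mf = sp.make_micro_fovs(counts, meta, mode="tile", tile_size=100.0,
                                min_cells=5)
        cells = mf.cells
        for mfov in mf.profiles["Tcell"].index:
            members = cells.index[(cells == mfov)
                                  & (meta["cell_type"] == "Tcell")]
            assert len(members) >= 5


class TestPmcp:
    def test_expression_equal_abundance_gives_rho_one(self, rng):
        from perturbdecode.spatial import MicroFOVTable

        n = 30
        ab = pd.DataFrame({"A": np.linspace(0.1, 0.9, n),
                           "B": rng.uniform(0, 1, n)},
                          index=[f"m{i}" for i in range(n)])
        prof = pd.DataFrame({"gene1": ab["A"].to_numpy()}, index=ab.index)
        mf = MicroFOVTable(abundance=ab, profiles={"T": prof},
                           cells=pd.Series(dtype=object),
                           n_cancer=pd.Series(10, index=ab.index))
        res = sp.pmcp(mf, "T", "A")
        assert res.loc["gene1", "rho"] == pytest.approx(1.0)

    def test_matches_brute_force_partial_correlation(self, rng):
        """partial_spearman equals rank -> OLS residual -> Pearson by hand."""
        for _ in range(20):
            n = rng.integers(15, 40)
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            z = rng.normal(size=(n, 3))
            rho, p = sp.partial_spearman(x, y, z)
            rx, ry = stats.rankdata(x), stats.rankdata(y)
            rz = np.column_stack([np.ones(n)] + [stats.rankdata(c) for c in z.T])
            ex = rx - rz @ np.linalg.lstsq(rz, rx, rcond=None)[0]
            ey = ry - rz @ np.linalg.lstsq(rz, ry, rcond=None)[0]
            expect = np.corrcoef(ex, ey)[0, 1]
            assert abs(rho - expect) < 1e-10

    def test_constant_abundance_raises(self, rng):
        from perturbdecode.spatial import MicroFOVTable

        ab = pd.DataFrame({"A": np.full(15, 0.5)}, index=[f"m{i}" for i in range(15)])
        prof = pd.DataFrame({"g": rng.normal(size=15)}, index=ab.index)
        mf = MicroFOVTable(abundance=ab, profiles={"T": prof},
                           cells=pd.Series(dtype=object),
                           n_cancer=pd.Series(10, index=ab.index))
        with pytest.raises(ValueError, match="constant abundance"):
            sp.pmcp(mf, "T", "A")

    def test_planted_programs_recovered(self):
        cfg = InSituSimConfig(seed=5, fovs_per_tumor=6, cells_per_fov=300)
        counts, meta, truth, _, _ = simulate_insitu(cfg)
        mf = sp.make_micro_fovs(counts, meta, mode="neighborhood", k=10)
        tp = fp = fn = 0
        for orf in ["ORF1", "ORF2", "ORF3", "ORF4"]:
            res = sp.pmcp(mf, "Tcell", orf, fdr=0.1)
            found = set(res.index[(res["fdr"] < 0.1) & (res["rho"] > 0)])
            planted = truth.pmcp_genes[("Tcell", orf)]
            tp += len(found & planted)
            fp += len(found - planted)
            fn += len(planted - found)
        assert tp / (tp + fp) >= 0.8
        assert tp / (tp + fn) >= 0.8


class TestGxe:
    def test_parameter_recovery_single_fit(self):
        df = simulate_gxe_cells(beta_interaction=1.0, seed=0)
        fit = sp._mixed_fit(df, "y ~ complexity + x + L1 + x:L1 + L2 + x:L2", "fov")
        assert fit.params["x:L1"] == pytest.approx(1.0, abs=0.3)
        assert abs(fit.params["x:L2"]) < 0.3

    def test_constant_ligand_dropped(self, rng, caplog):
        n = 120
        obs = pd.DataFrame({
            "fov": np.repeat([f"f{i}" for i in range(4)], 30),
            "orf_indicator": rng.integers(0, 2, n),
            "complexity": rng.integers(40, 60, n),
        })
        counts = _adata(rng.poisson(6.0, (n, 5)), obs=obs)
        lh = pd.DataFrame({"ligA": np.ones(n),
                           "ligB": rng.integers(0, 2, n).astype(float)},
                          index=obs.index)
        with caplog.at_level("WARNING"):
            res = sp.gxe(counts, obs, ["g0"], lh)
        assert "constant" in caplog.text
        assert not res.empty
        assert not res["term"].str.contains("ligA").any()


class TestLotoCv:
    def test_spatial_beats_nonspatial_under_confounding(self):
        counts, meta, _ = simulate_fov_confounded(seed=1)
        meta = meta.rename(columns={"orf": "orf_indicator"})
        res = sp.loto_cv(counts, meta, fdr=0.1)
        mean = res.groupby("variant")["auroc"].mean()
        assert mean["spatial"] > mean["nonspatial_only"]

    def test_needs_two_tumors(self, rng):
        obs = pd.DataFrame({
            "tumor": ["t1"] * 20, "fov": ["f1"] * 20,
            "orf_indicator": rng.integers(0, 2, 20),
            "complexity": np.ones(20) * 5,
        })
        counts = _adata(rng.poisson(5.0, (20, 3)), obs=obs)
        with pytest.raises(ValueError):
            sp.loto_cv(counts, obs)
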