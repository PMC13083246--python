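"""Spatial perturbation statistics: clonal zonation permutation tests,
spatially aware GA signatures (mixed models with an FOV random intercept),
a scRNA-seq hurdle baseline, leave-one-tumor-out validation, micro-FOV
pseudobulks with perturbation abundances, perturbation multicellular
programs (partial Spearman) and gene-environment interaction models.

The zonation statistic is the mean, over cancer cells carrying a given ORF,
of the fraction of same-ORF cells among their k nearest cancer-cell
neighbors; its null is obtained by permuting ORF labels across the cancer
cells of the same slide, which is exactly exchangeable under no zonation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import sparse, stats
from sklearn.neighbors import NearestNeighbors

from .insitu import log_tpm
from .utils import auroc, bh_fdr

log = logging.getLogger(__name__)

LN2 = np.log(2.0)


def _dense(x):
    return np.asarray(x.todense()) if sparse.issparse(x) else np.asarray(x)


# ---------------------------------------------------------------------------
# zonation


def zonation_test(meta: pd.DataFrame, n_perm: int = 999, k: int = 10,
                  seed: int = 0, min_cells: int = 2,
                  slide_col: str = "tumor") -> pd.DataFrame:
    """Empirical permutation test of clonal zonation per ORF per slide.

    ``meta`` needs cell_type, orf, x, y and the slide column. Only cancer
    cells with an ORF call enter. p = (1 + #{null >= obs}) / (1 + n_perm),
    never below 1/(n_perm + 1). ORFs with fewer than ``min_cells`` cells are
    skipped and reported with NaN p.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for slide, sub in meta.groupby(slide_col, sort=True):
        cancer = sub[(sub["cell_type"] == "cancer") & (sub["orf"] != "none")]
        labels = cancer["orf"].to_numpy()
        uniq = np.unique(labels)
        if len(cancer) < min_cells + 1:
            continue
        k_eff = min(k, len(cancer) - 1)
        nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(cancer[["x", "y"]])
        _, idx = nn.kneighbors(cancer[["x", "y"]])
        neigh = idx[:, 1:]

        def orf_stats(lab):
            same = lab[neigh] == lab[:, None]
            frac = same.mean(axis=1)
            return {o: frac[lab == o].mean() for o in uniq}

        obs = orf_stats(labels)
        null = {o: np.empty(n_perm) for o in uniq}
        for p_i in range(n_perm):
            perm = rng.permutation(labels)
            st = orf_stats(perm)
            for o in uniq:
                null[o][p_i] = st[o]
        for o in uniq:
            n_o = int((labels == o).sum())
            if n_o < min_cells:
                log.warning("slide %s ORF %s has %d cells; skipped", slide, o, n_o)
                rows.append((slide, o, n_o, np.nan, np.nan, np.nan))
                continue
            nv = null[o][~np.isnan(null[o])]
            p = (1.0 + np.sum(nv >= obs[o])) / (1.0 + len(nv))
            rows.append((slide, o, n_o, obs[o], nv.mean(), p))
    return pd.DataFrame(rows, columns=[slide_col, "orf", "n_cells", "statistic",
                                       "null_mean", "p"])


# ---------------------------------------------------------------------------
# mixed-model GA signatures


def _mixed_fit(df: pd.DataFrame, formula: str, groups: str):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, df, groups=df[groups])
        try:
            fit = model.fit(reml=True, method="lbfgs")
        except Exception:
            fit = model.fit(reml=True, method="powell")
    return fit


def _wald_p(fit, term: str, df_t: int) -> tuple[float, float, float]:
    beta = fit.params[term]
    se = fit.bse[term]
    if not np.isfinite(se) or se <= 0:
        return beta, np.inf, 1.0
    t = beta / se
    return beta, se, float(2.0 * stats.t.sf(abs(t), df_t))


def spatial_ga(counts: ad.AnnData, meta: pd.DataFrame, fdr: float = 0.1,
               orf_col: str = "orf_indicator") -> pd.DataFrame:
    """Spatially aware GA signature via per-gene linear mixed models.

    Model per gene: ``expr ~ (1|FOV) + ORF + complexity`` on log2(1+TPM)
    values, fit by REML; the ORF fixed effect is Wald-tested against a t
    reference with between-within degrees of freedom, then BH-corrected.
    ``meta`` needs ``fov``, ``complexity`` and a 0/1 column ``orf_col``.
    With a single FOV the random intercept is dropped (loud warning) and an
    OLS fit is used instead.
    """
    vals = log_tpm(counts)
    n_fov = meta["fov"].nunique()
    single_fov = n_fov < 2
    if single_fov:
        log.warning("single FOV: falling back to a fixed-effects (OLS) model")
    rows, excluded = [], []
    df_t = max(len(meta) - 3 - n_fov, 1)
    for j, gene in enumerate(counts.var_names):
        y = vals[:, j]
        if y.std() == 0:
            excluded.append(gene)
            continue
        df = pd.DataFrame({"y": y, "orf": meta[orf_col].to_numpy(float),
                           "complexity": meta["complexity"].to_numpy(float),
                           "fov": meta["fov"].to_numpy()})
        if single_fov:
            fit = sm.OLS(df["y"], sm.add_constant(df[["orf", "complexity"]])).fit()
            beta, se = fit.params["orf"], fit.bse["orf"]
            p = float(2.0 * stats.t.sf(abs(beta / se), fit.df_resid)) if se > 0 else 1.0
        else:
            fit = _mixed_fit(df, "y ~ orf + complexity", "fov")
            beta, se, p = _wald_p(fit, "orf", df_t)
        rows.append((gene, beta, se, p))
    out = pd.DataFrame(rows, columns=["gene", "log2fc", "se", "p"]).set_index("gene")
    out["fdr"] = bh_fdr(out["p"].to_numpy()) if len(out) else []
    out.attrs["excluded"] = excluded
    out.attrs["fdr_threshold"] = fdr
    return out


def hurdle_ga(counts: ad.AnnData, meta: pd.DataFrame, fdr: float = 0.1,
              orf_col: str = "orf_indicator") -> pd.DataFrame:
    """Nonspatial hurdle baseline (two-part scRNA-seq model).

    Per gene: a detection part (logistic regression of expression > 0 on
    ORF + complexity, likelihood-ratio chi-square on the ORF term) and a
    positive part (OLS of log expression among expressing cells, squared t
    as chi-square); the two chi-squares combine on 2 df. All-zero and
    all-positive genes fall back to the single available part (flagged).
    """
    vals = log_tpm(counts)
    x_orf = meta[orf_col].to_numpy(float)
    comp = meta["complexity"].to_numpy(float)
    comp = (comp - comp.mean()) / max(comp.std(), 1e-12)
    rows = []
    for j, gene in enumerate(counts.var_names):
        y = vals[:, j]
        detected = y > 0
        chi2, dof, lfc, flagged = 0.0, 0, 0.0, ""
        if 0 < detected.sum() < len(y):
            xfull = np.column_stack([np.ones(len(y)), comp, x_orf])
            xnull = xfull[:, :2]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    full = sm.GLM(detected.astype(float), xfull,
                                  family=sm.families.Binomial()).fit(maxiter=50)
                    nullf = sm.GLM(detected.astype(float), xnull,
                                   family=sm.families.Binomial()).fit(maxiter=50)
                    chi2 += max(0.0, nullf.deviance - full.deviance)
                    dof += 1
                except Exception:
                    flagged = "detection_failed"
        else:
            flagged = "single_part"
        pos = detected
        if pos.sum() >= 4 and len(np.unique(x_orf[pos])) == 2:
            xpos = np.column_stack([np.ones(pos.sum()), comp[pos], x_orf[pos]])
            fit = sm.OLS(y[pos], xpos).fit()
            if fit.bse[2] > 0 and np.isfinite(fit.bse[2]):
                chi2 += (fit.params[2] / fit.bse[2]) ** 2
                dof += 1
                lfc = fit.params[2]
        elif not flagged:
            flagged = "single_part"
        p = float(stats.chi2.sf(chi2, dof)) if dof else 1.0
        rows.append((gene, lfc, p, flagged))
    out = pd.DataFrame(rows, columns=["gene", "log2fc", "p", "flag"]).set_index("gene")
    out["fdr"] = bh_fdr(out["p"].to_numpy()) if len(out) else []
    out.attrs["fdr_threshold"] = fdr
    return out


# ---------------------------------------------------------------------------
# leave-one-tumor-out crossvalidation


def _signed_sets(de: pd.DataFrame, genes) -> tuple[set, set]:
    sub = de.loc[de.index.isin(genes)]
    return set(sub.index[sub.log2fc > 0]), set(sub.index[sub.log2fc <= 0])


def _score_cells(vals: np.ndarray, genes: pd.Index, up: set, down: set) -> np.ndarray:
    gi = {g: i for i, g in enumerate(genes)}

    def zmean(gs):
        cols = []
        for g in gs:
            v = vals[:, gi[g]]
            if v.std() > 0:
                cols.append((v - v.mean()) / v.std())
        return np.mean(cols, axis=0) if cols else np.zeros(len(vals))

    return zmean(up) - zmean(down)


def loto_cv(counts: ad.AnnData, meta: pd.DataFrame, fdr: float = 0.1,
            orf_col: str = "orf_indicator", min_genes: int = 5) -> pd.DataFrame:
    """Leave-one-tumor-out comparison of spatial vs nonspatial signatures.

    Per fold, the mixed-model (spatial) and hurdle (nonspatial) GA analyses
    run on the training tumors; the spatially supported signature is the
    mixed-model-significant gene set, the nonspatial-only signature the
    hurdle-significant genes the mixed model does not support. Both are
    scored on the held-out tumor's ORF versus control cells and summarized
    as AUROCs. Folds whose held-out tumor lacks ORF or control cells are
    skipped.
    """
    tumors = sorted(meta["tumor"].unique())
    if len(tumors) < 2:
        raise ValueError("need >= 2 tumors")
    rows = []
    for held in tumors:
        train = (meta["tumor"] != held).to_numpy()
        test = ~train
        mtest = meta[test]
        if mtest[orf_col].nunique() < 2:
            log.warning("held-out tumor %s lacks both ORF classes; fold skipped", held)
            continue
        de_sp = spatial_ga(counts[train], meta[train], fdr=fdr, orf_col=orf_col)
        de_h = hurdle_ga(counts[train], meta[train], fdr=fdr, orf_col=orf_col)
        sp_genes = set(de_sp.index[de_sp.fdr < fdr])
        h_genes = set(de_h.index[de_h.fdr < fdr])
        nonspatial_only = h_genes - sp_genes
        if len(sp_genes) < min_genes:
            sp_genes = set(de_sp.nsmallest(min_genes, "p").index)
        if len(nonspatial_only) < min_genes:
            extra = de_h.loc[~de_h.index.isin(sp_genes)].nsmallest(min_genes, "p").index
            nonspatial_only = nonspatial_only | set(extra)
        vals = log_tpm(counts[test])
        pos = (mtest[orf_col] == 1).to_numpy()
        for variant, genes_, de_ in (("spatial", sp_genes, de_sp),
                                     ("nonspatial_only", nonspatial_only, de_h)):
            up, down = _signed_sets(de_, genes_)
            s = _score_cells(vals, counts.var_names, up, down)
            rows.append((held, variant, auroc(s[pos], s[~pos]), len(genes_)))
    return pd.DataFrame(rows, columns=["held_out", "variant", "auroc", "n_genes"])


# ---------------------------------------------------------------------------
# micro-FOVs


@dataclass
class MicroFOVTable:
    """Micro-FOV pseudobulks and perturbation abundances."""

    abundance: pd.DataFrame  # micro-FOV x ORF fractions (over called cancer cells)
    profiles: dict  # cell_type -> DataFrame (micro-FOV x gene mean log TPM)
    cells: pd.Series  # cell_id -> micro-FOV id (tile mode; every cell in <= 1 tile)
    n_cancer: pd.Series  # micro-FOV -> number of called cancer cells


def make_micro_fovs(counts: ad.AnnData, meta: pd.DataFrame, mode: str = "tile",
                    tile_size: float = 100.0, k: int = 10,
                    min_cells: int = 3) -> MicroFOVTable:
    """Partition cells into micro-FOVs and tabulate abundances and profiles.

    Tile mode: square tiles of ``tile_size`` microns per slide; each cell
    belongs to exactly one tile. Perturbation abundance in a tile is the
    fraction of its ORF-called cancer cells carrying each label (fractions
    sum to 1 when every cancer cell has a call). Cell-type pseudobulk
    profiles (mean log2 TPM) are reported only for tiles holding at least
    ``min_cells`` cells of that type.

    Neighborhood mode: each non-cancer readout cell gets a window of its
    ``k`` nearest cancer cells; abundance is computed in that window and the
    profile row is the readout cell's own expression.
    """
    if not {"x", "y", "cell_type", "orf"} <= set(meta.columns):
        raise ValueError("meta needs x, y, cell_type and orf columns")
    vals = log_tpm(counts)
    genes = counts.var_names
    if mode == "tile":
        tile_ids = (meta["tumor"].astype(str) + "|"
                    + (meta["x"] // tile_size).astype(int).astype(str) + "_"
                    + (meta["y"] // tile_size).astype(int).astype(str))
        cells = pd.Series(tile_ids.to_numpy(), index=meta.index, name="micro_fov")
        cancer = meta[(meta["cell_type"] == "cancer") & (meta["orf"] != "none")]
        ab = (pd.crosstab(cells.loc[cancer.index], cancer["orf"])
              .pipe(lambda d: d.div(d.sum(axis=1), axis=0)))
        n_cancer = cells.loc[cancer.index].value_counts().reindex(ab.index).fillna(0)
        profiles = {}
        for ct in meta["cell_type"].unique():
            sub = meta.index[meta["cell_type"] == ct]
            df = pd.DataFrame(vals[meta.index.get_indexer(sub)], index=sub, columns=genes)
            grouped = df.groupby(cells.loc[sub]).agg("mean")
            sizes = cells.loc[sub].value_counts()
            keep = sizes.index[sizes >= min_cells]
            profiles[ct] = grouped.loc[grouped.index.intersection(keep)]
        return MicroFOVTable(abundance=ab, profiles=profiles, cells=cells,
                             n_cancer=n_cancer.astype(int))
    if mode == "neighborhood":
        cancer = meta[(meta["cell_type"] == "cancer") & (meta["orf"] != "none")]
        readout = meta[meta["cell_type"] != "cancer"]
        ab_rows = {}
        for tumor, sub in readout.groupby("tumor", sort=False):
            csub = cancer[cancer["tumor"] == tumor]
            if len(csub) < k:
                continue
            nn = NearestNeighbors(n_neighbors=k).fit(csub[["x", "y"]])
            _, idx = nn.kneighbors(sub[["x", "y"]])
            corf = csub["orf"].to_numpy()
            for row, cid in zip(idx, sub.index):
                labs, cnt = np.unique(corf[row], return_counts=True)
                ab_rows[cid] = dict(zip(labs, cnt / k))
        ab = pd.DataFrame(ab_rows).T.fillna(0.0)
        profiles = {}
        for ct in readout["cell_type"].unique():
            ids = readout.index[readout["cell_type"] == ct].intersection(ab.index)
            profiles[ct] = pd.DataFrame(vals[meta.index.get_indexer(ids)],
                                        index=ids, columns=genes)
        cells = pd.Series(ab.index, index=ab.index, name="micro_fov")
        return MicroFOVTable(abundance=ab, profiles=profiles, cells=cells,
                             n_cancer=pd.Series(k, index=ab.index))
    raise ValueError(f"unknown micro-FOV mode {mode!r}")


# ---------------------------------------------------------------------------
# perturbation multicellular programs


def partial_spearman(x: np.ndarray, y: np.ndarray, covars: np.ndarray) -> tuple[float, float]:
    """Partial Spearman correlation of x and y given covariates.

    Rank-transform everything, regress x and y on [1, covars] by least
    squares, correlate the residuals; p from the t approximation with
    n - 2 - #covariates degrees of freedom.
    """
    n = len(x)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rz = np.column_stack([np.ones(n)] + [stats.rankdata(c) for c in covars.T])
    bx, *_ = np.linalg.lstsq(rz, rx, rcond=None)
    by, *_ = np.linalg.lstsq(rz, ry, rcond=None)
    ex, ey = rx - rz @ bx, ry - rz @ by
    sx, sy = ex.std(), ey.std()
    if sx == 0 or sy == 0:
        return np.nan, np.nan
    rho = float(np.clip((ex * ey).mean() / (sx * sy), -1.0, 1.0))
    dof = n - 2 - covars.shape[1]
    if dof < 1 or abs(rho) == 1.0:
        return rho, 0.0 if abs(rho) == 1.0 else np.nan
    t = rho * np.sqrt(dof / (1.0 - rho**2))
    return rho, float(2.0 * stats.t.sf(abs(t), dof))


def pmcp(microfovs: MicroFOVTable, cell_type: str, orf: str,
         fdr: float = 0.1, control_label: str = "CTRL") -> pd.DataFrame:
    """Perturbation multicellular program for one (cell type, ORF) pair.

    Per gene: partial Spearman correlation of the cell type's micro-FOV
    pseudobulk expression with the ORF's perturbation abundance, controlling
    for the abundances of all other ORFs; BH within the gene family.
    """
    prof = microfovs.profiles.get(cell_type)
    if prof is None or len(prof) < 10:
        raise ValueError(f"need >= 10 micro-FOVs with cell type {cell_type!r}")
    common = prof.index.intersection(microfovs.abundance.index)
    prof = prof.loc[common]
    ab = microfovs.abundance.loc[common]
    if orf not in ab.columns:
        raise ValueError(f"no abundance column for ORF {orf!r}")
    x = ab[orf].to_numpy(float)
    if np.std(x) == 0:
        raise ValueError(f"constant abundance for ORF {orf!r}; correlation undefined")
    others = [c for c in ab.columns if c not in (orf, control_label)]
    covars = ab[others].to_numpy(float) if others else np.empty((len(ab), 0))
    covars = covars[:, covars.std(axis=0) > 0]
    rows = []
    for gene in prof.columns:
        rho, p = partial_spearman(x, prof[gene].to_numpy(float), covars)
        rows.append((gene, rho, p))
    out = pd.DataFrame(rows, columns=["gene", "rho", "p"]).set_index("gene")
    ok = out["p"].notna()
    out["fdr"] = np.nan
    out.loc[ok, "fdr"] = bh_fdr(out.loc[ok, "p"].to_numpy())
    out.attrs["cell_type"] = cell_type
    out.attrs["orf"] = orf
    out.attrs["fdr_threshold"] = fdr
    return out


# ---------------------------------------------------------------------------
# gene-environment interactions


def ligand_high_indicators(counts: ad.AnnData, meta: pd.DataFrame,
                           ligands, micro_fov: pd.Series) -> pd.DataFrame:
    """Per-cell indicators of above-median micro-FOV ligand expression.

    Each ligand's expression is averaged per micro-FOV (over all member
    cells); a micro-FOV is ligand-high when that mean exceeds the median
    across micro-FOVs. Indicators are broadcast back to cells.
    """
    vals = log_tpm(counts)
    gi = {g: i for i, g in enumerate(counts.var_names)}
    out = pd.DataFrame(index=meta.index)
    for lg in ligands:
        if lg not in gi:
            raise ValueError(f"ligand {lg!r} not in panel")
        per_cell = pd.Series(vals[:, gi[lg]], index=meta.index)
        per_mfov = per_cell.groupby(micro_fov.loc[meta.index]).mean()
        high = per_mfov > per_mfov.median()
        out[lg] = micro_fov.loc[meta.index].map(high).astype(float)
    return out


def gxe(counts: ad.AnnData, meta: pd.DataFrame, genes, ligand_high: pd.DataFrame,
        orf_col: str = "orf_indicator", p_threshold: float = 0.01) -> pd.DataFrame:
    """Gene-environment interaction mixed models.

    Per response gene: ``y ~ (1|FOV) + complexity + x + sum_i L_i +
    sum_i L_i:x`` where x is the ORF indicator and L_i the ligand-high
    indicators; REML fit, Wald t tests. Constant (aliased) ligand
    indicators are dropped with a warning; interactions are only reported
    where both factor levels are observed. Rows are (gene, term).
    """
    vals = log_tpm(counts)
    gidx = {g: i for i, g in enumerate(counts.var_names)}
    ligands = []
    for lg in ligand_high.columns:
        if ligand_high[lg].nunique() < 2:
            log.warning("ligand indicator %s is constant; dropped", lg)
            continue
        ligands.append(lg)
    rows = []
    for gene in genes:
        j = gidx.get(gene)
        if j is None:
            raise ValueError(f"gene {gene!r} not in panel")
        df = pd.DataFrame({
            "y": vals[:, j],
            "x": meta[orf_col].to_numpy(float),
            "complexity": meta["complexity"].to_numpy(float),
            "fov": meta["fov"].to_numpy(),
        }, index=meta.index)
        terms = ["complexity", "x"]
        for li, lg in enumerate(ligands):
            col = f"L{li + 1}"
            df[col] = ligand_high[lg].to_numpy(float)
            terms += [col, f"x:{col}"]
        formula = "y ~ " + " + ".join(terms)
        fit = _mixed_fit(df, formula, "fov")
        df_t = max(len(df) - len(terms) - 2 - meta["fov"].nunique(), 1)
        for li, lg in enumerate(ligands):
            col = f"L{li + 1}"
            for term, label in ((col, f"ligand_{lg}"), (f"x:{col}", f"interaction_{lg}")):
                if term.startswith("x:") and df.groupby([col])["x"].nunique().min() < 2:
                    continue  # interaction inestimable: a level lacks both x classes
                beta, se, p = _wald_p(fit, term, df_t)
                rows.append((gene, label, beta, se, p))
        beta, se, p = _wald_p(fit, "x", df_t)
        rows.append((gene, "orf", beta, se, p))
    out = pd.DataFrame(rows, columns=["gene", "term", "estimate", "se", "p"])
    out["significant"] = out["p"] < p_threshold
    return out
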