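"""Dissociated Perturb-seq analysis: guide assignment, normalization,
pseudobulk differential expression, GA signatures, sgRNA z-scores,
concordance strata and leave-one-sgRNA-out crossvalidation.

Conventions mirrored from the screen design: cells carrying exactly one
guide above the UMI cutoff are assigned that guide's target (multiplets are
excluded), control cells carry non-targeting (NTC) guides, pseudobulk
profiles are keyed by (guide-or-target, condition, batch) so a two-condition
three-batch design yields six profiles per sgRNA, and GA signatures are the
genes differentially expressed versus control at FDR < 0.01 in either
condition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse, stats

from .nbglm import make_design, nb_glm_de
from .utils import auroc, bh_fdr  # noqa: F401  (bh_fdr re-exported for callers)

log = logging.getLogger(__name__)

LN2 = np.log(2.0)


@dataclass(frozen=True)
class GASignature:
    """Up/down gene sets attached to one perturbation target."""

    target: str
    up: frozenset = frozenset()
    down: frozenset = frozenset()
    fdr_threshold: float = 0.01
    conflicts: frozenset = frozenset()
    source: str = ""

    def __post_init__(self):
        if set(self.up) & set(self.down):
            raise ValueError("up and down sets overlap")


def _dense(x) -> np.ndarray:
    return np.asarray(x.todense()) if sparse.issparse(x) else np.asarray(x)


# ---------------------------------------------------------------------------
# guide assignment


def assign_perturbations(guide_counts: ad.AnnData, min_umi: int = 3,
                         guide_to_target: dict | None = None) -> pd.DataFrame:
    """Assign each cell its perturbation from the guide-count matrix.

    Guides below ``min_umi`` UMIs are treated as technical background. Cells
    with exactly one surviving guide get that guide's target (NTC guides map
    to the ``"NTC"`` label); cells with none are ``unassigned`` and cells
    with two or more are ``multiplet`` — both are excluded downstream.

    Returns a frame indexed like the cells with ``perturbation``, ``guide``
    and ``status`` columns.
    """
    if min_umi < 1:
        raise ValueError("min_umi must be >= 1")
    if guide_to_target is None:
        if "target" in guide_counts.var:
            guide_to_target = guide_counts.var["target"].to_dict()
        else:
            guide_to_target = {g: g.split("_sg")[0] for g in guide_counts.var_names}
    x = _dense(guide_counts.X)
    passing = x >= min_umi
    n_pass = passing.sum(axis=1)
    guides = np.asarray(guide_counts.var_names)

    pert = np.full(guide_counts.n_obs, "unassigned", dtype=object)
    guide_col = np.full(guide_counts.n_obs, "", dtype=object)
    status = np.full(guide_counts.n_obs, "unassigned", dtype=object)
    singlet = n_pass == 1
    idx = np.argmax(passing[singlet], axis=1)
    guide_col[singlet] = guides[idx]
    pert[singlet] = [guide_to_target[g] for g in guides[idx]]
    status[singlet] = "singlet"
    status[n_pass >= 2] = "multiplet"
    pert[n_pass >= 2] = "multiplet"
    return pd.DataFrame(
        {"perturbation": pert, "guide": guide_col, "status": status},
        index=guide_counts.obs_names.copy(),
    )


# ---------------------------------------------------------------------------
# normalization


def normalize(counts: ad.AnnData, scale: float = 1e4, log_base: float = 2.0) -> ad.AnnData:
    """Scale counts to ``scale`` transcripts per cell and log1p-transform.

    value = log(1 + scale * count / cell_total) / log(log_base). Cells with
    zero total counts are dropped with a warning.
    """
    if scale <= 0:
        raise ValueError("scale must be > 0")
    if counts.n_obs == 0 or counts.n_vars == 0:
        raise ValueError("empty count matrix")
    x = _dense(counts.X).astype(float)
    totals = x.sum(axis=1)
    keep = totals > 0
    if not keep.all():
        log.warning("dropping %d cells with zero total counts", (~keep).sum())
        x, totals = x[keep], totals[keep]
    vals = np.log1p(scale * x / totals[:, None]) / np.log(log_base)
    out = ad.AnnData(X=vals, obs=counts.obs[keep].copy(), var=counts.var.copy())
    out.uns["scale"] = scale
    out.uns["log_base"] = log_base
    return out


# ---------------------------------------------------------------------------
# pseudobulk


def make_pseudobulk(counts: ad.AnnData, meta: pd.DataFrame,
                    keys: tuple[str, ...] = ("perturbation", "condition", "batch"),
                    mode: str = "sum", scale: float = 1e5,
                    log_base: float = 2.0) -> ad.AnnData:
    """Aggregate cells into pseudobulk profiles per observed key combination.

    ``mode="sum"`` sums raw counts (the DE input); ``mode="mean_norm"``
    averages log1p-transformed per-cell profiles at the given scale (the
    z-score input, tp100k by default).
    """
    if mode not in ("sum", "mean_norm"):
        raise ValueError(f"unknown mode {mode!r}")
    common = counts.obs_names.intersection(meta.index)
    sub = counts[common]
    m = meta.loc[common, list(keys)]
    groups = m.groupby(list(keys), observed=True, sort=True)
    if len(groups) == 0:
        raise ValueError("no pseudobulk groups (empty metadata?)")
    if mode == "sum":
        x = _dense(sub.X).astype(float)
    else:
        x = _dense(normalize(sub, scale=scale, log_base=log_base).X)
    profiles, rows = [], []
    for key, gidx in groups.indices.items():
        key = key if isinstance(key, tuple) else (key,)
        block = x[gidx]
        profiles.append(block.sum(axis=0) if mode == "sum" else block.mean(axis=0))
        rows.append((*key, len(gidx)))
    obs = pd.DataFrame(rows, columns=[*keys, "n_cells"])
    obs.index = pd.Index(["|".join(map(str, r[:-1])) for r in rows], name="group")
    pb = ad.AnnData(X=np.vstack(profiles), obs=obs, var=counts.var.copy())
    pb.uns["mode"] = mode
    return pb


# ---------------------------------------------------------------------------
# differential expression and signatures


def test_de(pseudobulk: ad.AnnData, group_var: str, ref, alt,
            covariates: tuple[str, ...] = ("batch",)) -> pd.DataFrame:
    """NB GLM differential expression between two pseudobulk groups.

    Fits ``y ~ covariates + group`` per gene with a log library-size offset
    and returns the DE table for alt vs ref (positive log2fc = higher in
    ``alt``).
    """
    if pseudobulk.uns.get("mode") != "sum":
        raise ValueError("test_de requires count-sum pseudobulk profiles")
    meta = pseudobulk.obs
    mask = meta[group_var].isin([ref, alt])
    for lv in (ref, alt):
        if (meta[group_var] == lv).sum() < 2:
            raise ValueError(f"need >= 2 pseudobulk samples at level {lv!r}")
    counts = pd.DataFrame(_dense(pseudobulk.X)[mask.to_numpy()],
                          index=meta.index[mask], columns=pseudobulk.var_names)
    design = make_design(meta[mask], group_var, ref, alt, covariates=covariates)
    de = nb_glm_de(counts.round().astype(int), design, "group")
    de.attrs["contrast"] = f"{group_var}: {alt} vs {ref}"
    return de


def extract_ga_signature(de_mono: pd.DataFrame, de_co: pd.DataFrame, target: str,
                         fdr: float = 0.01) -> GASignature:
    """GA signature: genes significant in either condition at the FDR cut.

    A gene up in one condition and down in the other is resolved toward the
    condition with the smaller FDR and recorded in ``conflicts``.
    """
    if not set(de_mono.index) == set(de_co.index):
        raise ValueError("DE tables must share the same gene universe")
    up, down, conflicts = set(), set(), set()
    for gene in de_mono.index:
        calls = []
        for tab in (de_mono, de_co):
            row = tab.loc[gene]
            if row["fdr"] < fdr and row["log2fc"] != 0:
                calls.append((np.sign(row["log2fc"]), row["fdr"]))
        if not calls:
            continue
        signs = {s for s, _ in calls}
        if len(signs) == 2:
            conflicts.add(gene)
            sign = min(calls, key=lambda c: c[1])[0]
        else:
            sign = signs.pop()
        (up if sign > 0 else down).add(gene)
    if conflicts:
        log.warning("signature %s: %d genes with conflicting directions", target, len(conflicts))
    return GASignature(target=target, up=frozenset(up), down=frozenset(down),
                       fdr_threshold=fdr, conflicts=frozenset(conflicts),
                       source="mono|co")


# ---------------------------------------------------------------------------
# sgRNA z-scores and concordance


def sgrna_zscore(pseudobulk: ad.AnnData, controls: ad.AnnData,
                 guide_col: str = "guide") -> pd.DataFrame:
    """Per-sgRNA expression shift versus matched control pseudobulks.

    ``Z_k`` is the average over the (batch j, condition i) strata observed
    for sgRNA k of ``P_kji - C_ji``, computed on mean log1p tp100k profiles
    — the deviation from control while controlling for batch. ``controls``
    is a mean-normalized pseudobulk of the control (NTC) cells keyed by
    (condition, batch). Strata with no cells for sgRNA k are skipped and the
    divisor adjusted; a stratum lacking a control profile is an error.
    NTC guides themselves may appear in ``pseudobulk`` and receive z-scores
    against the pooled control like any other guide.
    """
    for pb in (pseudobulk, controls):
        if pb.uns.get("mode") != "mean_norm":
            raise ValueError("sgrna_zscore requires mean-normalized pseudobulk profiles")
    obs = pseudobulk.obs
    x = _dense(pseudobulk.X)
    strata_cols = [c for c in ("condition", "batch") if c in obs.columns]
    cx = _dense(controls.X)
    control_profiles = {
        tuple(row[c] for c in strata_cols): cx[i]
        for i, (_, row) in enumerate(controls.obs.iterrows())
    }
    zrows, names = [], []
    for k in obs[guide_col].unique():
        idx = np.flatnonzero((obs[guide_col] == k).to_numpy())
        diffs = []
        for i in idx:
            key = tuple(obs.iloc[i][c] for c in strata_cols)
            if key not in control_profiles:
                raise ValueError(f"no control profile for stratum {key} required by sgRNA {k!r}")
            diffs.append(x[i] - control_profiles[key])
        zrows.append(np.mean(diffs, axis=0))
        names.append(k)
    z = pd.DataFrame(zrows, index=pd.Index(names, name="sgrna"),
                     columns=pseudobulk.var_names)
    if not np.isfinite(z.to_numpy()).all():
        raise ValueError("non-finite z-scores")
    return z


def guide_zscores(counts: ad.AnnData, meta: pd.DataFrame,
                  control: str = "NTC") -> pd.DataFrame:
    """Convenience wrapper: z-scores for every guide (including NTC guides)
    against the pooled control cells, on mean log1p tp100k profiles."""
    pb = make_pseudobulk(counts, meta, keys=("guide", "condition", "batch"),
                         mode="mean_norm")
    ctrl_mask = (meta["perturbation"] == control).to_numpy()
    pb_ctrl = make_pseudobulk(counts[ctrl_mask], meta[ctrl_mask],
                              keys=("condition", "batch"), mode="mean_norm")
    return sgrna_zscore(pb, pb_ctrl, guide_col="guide")


def concordance(z: pd.DataFrame, guide_to_target: dict) -> dict:
    """Pairwise sgRNA z-score Pearson correlations, stratified.

    Strata: pairs targeting the same gene, pairs targeting different genes,
    and NTC-NTC pairs; rank-sum tests compare same-vs-different and
    same-vs-NTC. Constant (zero-variance) z rows are excluded with a log
    message.
    """
    zv = z.to_numpy()
    keep = zv.std(axis=1) > 0
    if not keep.all():
        log.warning("excluding %d constant z-score rows from concordance", (~keep).sum())
    z = z[keep]
    names = list(z.index)
    corr = np.corrcoef(z.to_numpy())
    rows = []
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            ta, tb = guide_to_target[names[a]], guide_to_target[names[b]]
            if ta == "NTC" and tb == "NTC":
                stratum = "ntc"
            elif ta == tb:
                stratum = "same"
            elif "NTC" in (ta, tb):
                continue
            else:
                stratum = "different"
            rows.append((names[a], names[b], corr[a, b], stratum))
    pairs = pd.DataFrame(rows, columns=["guide_a", "guide_b", "r", "stratum"])
    res = {"pairs": pairs,
           "median_r": pairs.groupby("stratum")["r"].median().to_dict()}
    same = pairs.loc[pairs.stratum == "same", "r"]
    diff = pairs.loc[pairs.stratum == "different", "r"]
    ntc = pairs.loc[pairs.stratum == "ntc", "r"]
    if len(same) and len(diff):
        res["p_same_vs_different"] = float(
            stats.ranksums(same, diff, alternative="greater").pvalue)
    if len(same) and len(ntc):
        res["p_same_vs_ntc"] = float(stats.ranksums(same, ntc, alternative="greater").pvalue)
    return res


# ---------------------------------------------------------------------------
# signature scoring and crossvalidation


def score_signature(norm: ad.AnnData, sig: GASignature) -> pd.Series:
    """Per-cell signature score on a normalized matrix.

    Each signature gene is z-scored across cells; the score is the mean over
    up genes minus the mean over down genes. Genes absent from the matrix
    (or with zero variance) are skipped and counted in ``.attrs``.
    """
    x = _dense(norm.X)
    gidx = {g: i for i, g in enumerate(norm.var_names)}
    missing = 0

    def _zmean(genes_set):
        nonlocal missing
        cols = []
        for g in genes_set:
            j = gidx.get(g)
            if j is None:
                missing += 1
                continue
            v = x[:, j]
            sd = v.std()
            if sd == 0:
                missing += 1
                continue
            cols.append((v - v.mean()) / sd)
        return np.mean(cols, axis=0) if cols else np.zeros(norm.n_obs)

    present = (set(sig.up) | set(sig.down)) & set(gidx)
    if not present:
        raise ValueError(f"no signature genes of {sig.target!r} present in the matrix")
    score = _zmean(sig.up) - _zmean(sig.down)
    out = pd.Series(score, index=norm.obs_names, name=f"{sig.target}_score")
    out.attrs["missing_genes"] = missing
    return out


def _signature_from_cells(counts, meta, case_mask, control_mask, fdr,
                          target, min_genes, covariates):
    """Derive a GA signature contrasting case cells with control cells.

    Falls back to the ``min_genes`` genes with smallest p (signed by their
    fold change) when fewer pass the FDR cut, so scoring is always defined.
    """
    sub_meta = meta.copy()
    sub_meta["grp"] = np.where(case_mask, "case", np.where(control_mask, "ctrl", "other"))
    use = sub_meta["grp"] != "other"
    pb = make_pseudobulk(counts[use.to_numpy()], sub_meta[use],
                         keys=("grp", *covariates), mode="sum")
    de = test_de(pb, "grp", "ctrl", "case", covariates=covariates)
    sig_up = set(de.index[(de.fdr < fdr) & (de.log2fc > 0)])
    sig_dn = set(de.index[(de.fdr < fdr) & (de.log2fc < 0)])
    if len(sig_up) + len(sig_dn) < min_genes:
        top = de.nsmallest(min_genes, "p")
        sig_up = set(top.index[top.log2fc > 0])
        sig_dn = set(top.index[top.log2fc <= 0])
    return GASignature(target=target, up=frozenset(sig_up), down=frozenset(sig_dn),
                       fdr_threshold=fdr, source="loocv")


def loocv_sgrna(counts: ad.AnnData, meta: pd.DataFrame, target: str,
                fdr: float = 0.01, min_genes: int = 10,
                covariates: tuple[str, ...] = ("condition", "batch")) -> pd.DataFrame:
    """Leave-one-sgRNA-out crossvalidation for one target.

    For each held-out guide, the GA signature is re-derived from the
    target's remaining guides versus control cells, scored on the held-out
    and control cells, and evaluated with a one-sided t-test and the AUROC
    of the score as a univariate classifier.

    ``meta`` must carry ``guide`` and ``perturbation`` columns (from
    :func:`assign_perturbations`) plus the covariates.
    """
    guides = sorted(meta.loc[meta["perturbation"] == target, "guide"].unique())
    guides = [g for g in guides if g]
    if len(guides) < 3:
        raise ValueError(f"need >= 3 guides for target {target!r}, found {len(guides)}")
    ctrl_mask = (meta["perturbation"] == "NTC").to_numpy()
    norm = normalize(counts, scale=1e4, log_base=2.0)
    rows = []
    for left_out in guides:
        train_mask = ((meta["perturbation"] == target) & (meta["guide"] != left_out)).to_numpy()
        sig = _signature_from_cells(counts, meta, train_mask, ctrl_mask, fdr,
                                    target, min_genes, covariates)
        scores = score_signature(norm, sig)
        held = scores[meta.index[(meta["guide"] == left_out).to_numpy()]]
        ctrl = scores[meta.index[ctrl_mask]]
        t_p = float(stats.ttest_ind(held, ctrl, alternative="greater").pvalue)
        rows.append((left_out, t_p, auroc(held, ctrl), len(sig.up), len(sig.down)))
    return pd.DataFrame(rows, columns=["left_out", "t_p", "auroc", "n_up", "n_down"])


# ---------------------------------------------------------------------------
# condition response


def condition_response(counts: ad.AnnData, meta: pd.DataFrame, fdr: float = 0.01,
                       lfc: float = 0.25, control: str = "NTC") -> dict:
    """Coculture-response genes from control (NTC) cells only.

    DE of coculture versus monoculture control pseudobulks with a batch
    covariate; co-UP requires fdr < ``fdr`` and log2fc strictly > ``lfc``,
    co-DOWN the mirror image.
    """
    ntc = meta["perturbation"] == control
    conds = set(meta.loc[ntc, "condition"])
    if not {"mono", "co"} <= conds:
        raise ValueError(f"control cells must be present in both conditions, found {conds}")
    pb = make_pseudobulk(counts[ntc.to_numpy()], meta[ntc],
                         keys=("condition", "batch"), mode="sum")
    de = test_de(pb, "condition", "mono", "co", covariates=("batch",))
    co_up = set(de.index[(de.fdr < fdr) & (de.log2fc > lfc)])
    co_down = set(de.index[(de.fdr < fdr) & (de.log2fc < -lfc)])
    return {"co_up": co_up, "co_down": co_down, "de": de}


def run_target_de(counts: ad.AnnData, meta: pd.DataFrame, target: str,
                  fdr: float = 0.01, control: str = "NTC") -> GASignature:
    """Per-condition DE of one target versus control, folded into a GA signature."""
    des = {}
    for condition in ("mono", "co"):
        mask = ((meta["condition"] == condition)
                & meta["perturbation"].isin([target, control])).to_numpy()
        pb = make_pseudobulk(counts[mask], meta[mask],
                             keys=("perturbation", "batch"), mode="sum")
        des[condition] = test_de(pb, "perturbation", control, target, covariates=("batch",))
    return extract_ga_signature(des["mono"], des["co"], target, fdr=fdr)
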