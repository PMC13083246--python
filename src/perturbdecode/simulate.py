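"""Synthetic Perturb-seq and in situ Perturb-seq data with planted ground truth.

Two generators emulate the statistical structure the analyses assume:

* :func:`simulate_perturbseq` — dissociated CRISPRa Perturb-seq: NB counts
  with per-batch multiplicative gene factors, singlet/multiplet guide
  capture, two culture conditions sharing a planted condition-response
  program, and per-target gene-activation effect vectors (the target gene
  itself is elevated, mimicking on-target CRISPRa).
* :func:`simulate_insitu` — spatial in situ Perturb-seq: cell-type mixtures
  on FOV grids, spatially clustered ORF clones (nearest clone seed with a
  Gaussian distance-decayed assignment), neighborhood pMCP effects in
  non-cancer cells exposed to ORF-bearing cancer cells, and a planted
  ligand-conditional interaction for one "receptor" ORF.

Every planted effect is returned in a :class:`TruthTables` so downstream
recovery can be scored against ground truth alone.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

from . import io as pdio

LN2 = np.log(2.0)


# ---------------------------------------------------------------------------
# configs


@dataclass
class PerturbseqSimConfig:
    """Study-scale defaults scaled to desk size.

    The real screen used ~4 sgRNAs per target across 61 targets plus 32 NTC
    guides, two culture conditions and three sequencing batches (hence six
    pseudobulk profiles per sgRNA); the defaults keep that design shape at a
    size where every analysis runs in seconds.
    """

    n_genes: int = 400
    n_targets: int = 8
    n_ntc_guides: int = 6
    guides_per_target: int = 3
    cells_per_guide: int = 36
    n_batches: int = 3
    conditions: tuple[str, ...] = ("mono", "co")
    baseline_mean_log: float = 1.0  # ~2k UMIs/cell over the 400-gene panel
    dispersion: float = 2.0
    effect_size_log2fc: float = 1.0
    effect_genes_per_target: int = 30
    frac_sensitizing: float = 0.5
    coculture_program_size: int = 20
    batch_sd_log: float = 0.15
    multiplet_rate: float = 0.05
    seed: int = 0

    def __post_init__(self):
        for name in ("n_genes", "n_targets", "n_ntc_guides", "guides_per_target",
                     "cells_per_guide", "n_batches"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("frac_sensitizing", "multiplet_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.effect_genes_per_target > self.n_genes:
            raise ValueError("effect_genes_per_target cannot exceed n_genes")
        if len(self.conditions) < 1:
            raise ValueError("need at least one condition")


@dataclass
class InSituSimConfig:
    """Defaults shaped after a four-tumor in situ screen at desk scale."""

    n_tumors: int = 4
    fovs_per_tumor: int = 4
    cells_per_fov: int = 250
    fov_size: float = 500.0  # microns; FOVs tiled on a grid per tumor
    cell_type_props: dict = field(
        default_factory=lambda: {"cancer": 0.6, "Tcell": 0.2, "fibroblast": 0.2}
    )
    n_orfs: int = 4
    clone_seeds_per_orf: int = 2
    clone_bandwidth: float = 80.0  # microns
    orf_effect_genes: int = 10
    orf_effect_size: float = 1.0  # log2FC of planted cancer-cell GA effects
    pmcp_genes_per_pair: int = 4
    pmcp_effect_size: float = 1.0  # log2FC in exposed non-cancer cells
    pmcp_k: int = 10
    pmcp_min_frac: float = 0.3
    gxe_genes: int = 4
    gxe_effect_size: float = 1.0
    n_ligands: int = 2
    panel_size: int = 120
    baseline_mean_log: float = 0.5
    dispersion: float = 2.0
    correlated_clones: bool = False
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.cell_type_props.values()) - 1.0) > 1e-9:
            raise ValueError("cell_type_props must sum to 1")
        if self.clone_bandwidth <= 0:
            raise ValueError("clone_bandwidth must be > 0")
        if "cancer" not in self.cell_type_props:
            raise ValueError("cell_type_props must include a 'cancer' type")
        for name in ("n_tumors", "fovs_per_tumor", "cells_per_fov", "n_orfs",
                     "clone_seeds_per_orf", "panel_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class TruthTables:
    """Planted ground truth for scoring downstream recovery."""

    effects: dict = field(default_factory=dict)  # target -> {"up": set, "down": set}
    hit_class: dict = field(default_factory=dict)  # target -> sensitizing|resistance|neutral
    condition_program: dict = field(default_factory=dict)  # {"up": set, "down": set}
    regulatory_edges: set = field(default_factory=set)  # {(src, dst, sign)}
    cell_guides: dict = field(default_factory=dict)  # cell_id -> tuple of true guides
    cell_orf: dict = field(default_factory=dict)  # cell_id -> true ORF label
    pmcp_genes: dict = field(default_factory=dict)  # (cell_type, orf) -> set of genes
    exposed_cells: dict = field(default_factory=dict)  # orf -> set of exposed cell ids
    gxe: dict = field(default_factory=dict)  # {"orf":, "genes":, "ligands":, "beta": {ligand: coef}}

    def __post_init__(self):
        classes = set(self.hit_class.values())
        if not classes <= {"sensitizing", "resistance", "neutral"}:
            raise ValueError(f"unknown hit class in {classes}")

    def to_json(self) -> str:
        def _enc(o):
            if isinstance(o, (set, frozenset)):
                return sorted(o)
            raise TypeError(type(o))

        d = dataclasses.asdict(self)
        d["regulatory_edges"] = sorted(list(e) for e in self.regulatory_edges)
        d["pmcp_genes"] = {f"{ct}|{orf}": sorted(g) for (ct, orf), g in self.pmcp_genes.items()}
        return json.dumps(d, default=_enc, indent=1)


def _nb_draw(rng, mean, size):
    """NB with mean mu and size r: Var = mu + mu^2/r."""
    mean = np.clip(mean, 1e-12, None)
    return rng.negative_binomial(size, size / (size + mean))


# ---------------------------------------------------------------------------
# dissociated Perturb-seq


def simulate_perturbseq(cfg: PerturbseqSimConfig):
    """Simulate a dissociated CRISPRa Perturb-seq experiment.

    Returns ``(counts, guide_counts, meta, truth)`` where ``counts`` and
    ``guide_counts`` are cells x genes / cells x guides AnnData objects with
    integer NB counts, ``meta`` is the per-cell annotation frame (condition,
    batch, complexity) and ``truth`` holds the planted effects.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = np.array([f"G{i:04d}" for i in range(cfg.n_genes)])
    targets = list(genes[: cfg.n_targets])

    guide_names, guide_target = [], {}
    for t in targets:
        for g in range(cfg.guides_per_target):
            name = f"{t}_sg{g + 1}"
            guide_names.append(name)
            guide_target[name] = t
    for g in range(cfg.n_ntc_guides):
        name = f"NTC_sg{g + 1}"
        guide_names.append(name)
        guide_target[name] = "NTC"

    # planted per-target effect vectors; the target gene itself is elevated
    truth = TruthTables()
    log2fc = np.zeros((len(targets), cfg.n_genes))
    non_target_pool = np.arange(cfg.n_targets, cfg.n_genes)
    n_sens = int(round(cfg.frac_sensitizing * cfg.n_targets))
    for ti, t in enumerate(targets):
        up, down = set(), set()
        if cfg.effect_size_log2fc != 0.0:
            chosen = rng.choice(non_target_pool, size=min(cfg.effect_genes_per_target,
                                                          non_target_pool.size), replace=False)
            signs = rng.choice([1.0, -1.0], size=chosen.size)
            log2fc[ti, chosen] = signs * cfg.effect_size_log2fc
            up = {genes[j] for j, s in zip(chosen, signs) if s > 0}
            down = {genes[j] for j, s in zip(chosen, signs) if s < 0}
            log2fc[ti, ti] = 2.0 * cfg.effect_size_log2fc  # on-target CRISPRa
            up.add(t)
        truth.effects[t] = {"up": up, "down": down}
        truth.hit_class[t] = "sensitizing" if ti < n_sens else "resistance"
        for g in up:
            truth.regulatory_edges.add((t, g, 1))
        for g in down:
            truth.regulatory_edges.add((t, g, -1))

    # shared coculture condition-response program (expressed by every
    # coculture cell, including controls)
    co_lfc = np.zeros(cfg.n_genes)
    if cfg.coculture_program_size > 0 and len(cfg.conditions) > 1:
        pool = np.setdiff1d(non_target_pool, np.flatnonzero(np.any(log2fc != 0, axis=0)))
        prog = rng.choice(pool, size=min(cfg.coculture_program_size, pool.size), replace=False)
        half = prog.size // 2
        co_lfc[prog[:half]] = 1.0
        co_lfc[prog[half:]] = -1.0
        truth.condition_program = {
            "up": {genes[j] for j in prog[:half]},
            "down": {genes[j] for j in prog[half:]},
        }
    else:
        truth.condition_program = {"up": set(), "down": set()}

    base_log_mu = rng.normal(cfg.baseline_mean_log, 1.0, cfg.n_genes)
    batch_factors = np.exp(rng.normal(0.0, cfg.batch_sd_log, (cfg.n_batches, cfg.n_genes)))

    n_cells = len(guide_names) * cfg.cells_per_guide
    cell_ids = np.array([f"C{i:05d}" for i in range(n_cells)])
    true_guide = np.repeat(guide_names, cfg.cells_per_guide)
    # balanced condition x batch layout within each guide
    strata = [(c, b) for c in cfg.conditions for b in range(cfg.n_batches)]
    cond = np.empty(n_cells, dtype=object)
    batch = np.empty(n_cells, dtype=object)
    for i in range(n_cells):
        c, b = strata[i % len(strata)]
        cond[i] = c
        batch[i] = f"batch{b + 1}"
    batch_idx = np.array([int(b[-1]) - 1 for b in batch])

    is_multiplet = rng.random(n_cells) < cfg.multiplet_rate
    second_guide = np.array(
        [rng.choice([g for g in guide_names if g != tg]) if m else ""
         for tg, m in zip(true_guide, is_multiplet)], dtype=object)

    target_index = {t: i for i, t in enumerate(targets)}
    size_factor = np.exp(rng.normal(0.0, 0.3, n_cells))
    log2_eff = np.zeros((n_cells, cfg.n_genes))
    for i in range(n_cells):
        for g in (true_guide[i], second_guide[i]):
            t = guide_target.get(g)
            if t in target_index:
                log2_eff[i] += log2fc[target_index[t]]
        if cond[i] == "co":
            log2_eff[i] += co_lfc
    mu = (np.exp(base_log_mu)[None, :] * batch_factors[batch_idx]
          * np.exp(log2_eff * LN2) * size_factor[:, None])
    counts = _nb_draw(rng, mu, cfg.dispersion)

    # guide capture: high NB mean for the true guide(s), low background
    gmu = np.full((n_cells, len(guide_names)), 0.05)
    gindex = {g: i for i, g in enumerate(guide_names)}
    for i in range(n_cells):
        gmu[i, gindex[true_guide[i]]] = 30.0
        if second_guide[i]:
            gmu[i, gindex[second_guide[i]]] = 30.0
    guide_counts = _nb_draw(rng, gmu, 5.0)

    meta = pd.DataFrame(
        {
            "condition": cond,
            "batch": batch,
            "complexity": (counts > 0).sum(axis=1),
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    for cid, tg, sg in zip(cell_ids, true_guide, second_guide):
        truth.cell_guides[cid] = (tg, sg) if sg else (tg,)

    adata = ad.AnnData(
        X=counts.astype(np.int64),
        obs=meta.copy(),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    gdata = ad.AnnData(
        X=guide_counts.astype(np.int64),
        obs=pd.DataFrame(index=pd.Index(cell_ids, name="cell_id")),
        var=pd.DataFrame(
            {"target": [guide_target[g] for g in guide_names]},
            index=pd.Index(guide_names, name="guide"),
        ),
    )
    return adata, gdata, meta, truth


# ---------------------------------------------------------------------------
# in situ Perturb-seq


def simulate_insitu(cfg: InSituSimConfig):
    """Simulate an in situ Perturb-seq screen across tumors and FOVs.

    Returns ``(counts, meta, truth, orf_counts, barcode_to_orf)``:
    ``counts`` is a cells x genes AnnData whose ``obs`` carries tumor, fov,
    x/y (microns), cell_type and complexity; ``orf_counts`` holds the
    simulated ORF-barcode capture (1-5 barcodes per ORF) used by ORF calling.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = np.array([f"S{i:04d}" for i in range(cfg.panel_size)])
    orfs = [f"ORF{i + 1}" for i in range(cfg.n_orfs)]
    labels = orfs + ["CTRL"]  # control clones carry a barcode but no ORF effect
    cell_types = list(cfg.cell_type_props)
    noncancer = [t for t in cell_types if t != "cancer"]

    # gene bookkeeping: dedicated blocks so planted programs never collide
    cursor = 0

    def take(n):
        nonlocal cursor
        block = genes[cursor: cursor + n]
        cursor += n
        if len(block) < n:
            raise ValueError("panel_size too small for the planted programs")
        return list(block)

    ligand_genes = take(cfg.n_ligands)
    gxe_gene_set = take(cfg.gxe_genes)
    orf_effects = {o: take(cfg.orf_effect_genes) for o in orfs}
    pmcp_map = {(ct, o): set(take(cfg.pmcp_genes_per_pair)) for o in orfs for ct in noncancer}

    truth = TruthTables()
    truth.pmcp_genes = pmcp_map
    for o in orfs:
        half = len(orf_effects[o]) // 2
        truth.effects[o] = {
            "up": set(orf_effects[o][:half]) if cfg.orf_effect_size > 0 else set(),
            "down": set(orf_effects[o][half:]) if cfg.orf_effect_size > 0 else set(),
        }
    receptor_orf = orfs[0]
    truth.gxe = {
        "orf": receptor_orf,
        "genes": list(gxe_gene_set),
        "ligands": list(ligand_genes),
        "beta": {ligand_genes[0]: cfg.gxe_effect_size,
                 **{lg: 0.0 for lg in ligand_genes[1:]}},
    }

    grid = int(np.ceil(np.sqrt(cfg.fovs_per_tumor)))
    rows = []
    for tumor_i in range(cfg.n_tumors):
        tumor = f"tumor{tumor_i + 1}"
        for fov_i in range(cfg.fovs_per_tumor):
            ox = (fov_i % grid) * cfg.fov_size
            oy = (fov_i // grid) * cfg.fov_size
            n = cfg.cells_per_fov
            x = ox + rng.uniform(0, cfg.fov_size, n)
            y = oy + rng.uniform(0, cfg.fov_size, n)
            ct = rng.choice(cell_types, size=n, p=[cfg.cell_type_props[t] for t in cell_types])
            for j in range(n):
                rows.append((tumor, f"{tumor}_fov{fov_i + 1}", x[j], y[j], ct[j]))
    meta = pd.DataFrame(rows, columns=["tumor", "fov", "x", "y", "cell_type"])
    meta.index = pd.Index([f"IS{i:05d}" for i in range(len(meta))], name="cell_id")

    # clone seeds per tumor; ORF of a cancer cell sampled with weights
    # sum_s exp(-d_s^2 / 2 bw^2) per label plus a uniform floor, so
    # bandwidth -> inf degrades to spatially random labels
    side = grid * cfg.fov_size
    meta["orf"] = "none"
    for tumor, sub in meta.groupby("tumor", sort=False):
        cancer = sub.index[sub["cell_type"] == "cancer"]
        if len(cancer) == 0:
            continue
        seed_labels = np.repeat(labels, cfg.clone_seeds_per_orf)
        seeds = rng.uniform(0, side, (len(seed_labels), 2))
        if cfg.correlated_clones and cfg.n_orfs >= 2:
            # place ORF2 seeds right next to ORF1 seeds so clone abundances
            # correlate across space (the pMCP confounding scenario)
            o1 = [i for i, s in enumerate(seed_labels) if s == orfs[0]]
            o2 = [i for i, s in enumerate(seed_labels) if s == orfs[1]]
            for a, b in zip(o1, o2):
                seeds[b] = seeds[a] + rng.normal(0, 20.0, 2)
        pts = meta.loc[cancer, ["x", "y"]].to_numpy()
        d2 = ((pts[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
        w = np.exp(-d2 / (2.0 * cfg.clone_bandwidth**2))
        lw = np.zeros((len(cancer), len(labels)))
        for li, lab in enumerate(labels):
            lw[:, li] = w[:, np.array(seed_labels) == lab].sum(axis=1)
        lw += 1e-4  # uniform misassignment floor
        probs = lw / lw.sum(axis=1, keepdims=True)
        draws = [labels[rng.choice(len(labels), p=p)] for p in probs]
        meta.loc[cancer, "orf"] = draws
    for cid, o in meta["orf"].items():
        truth.cell_orf[cid] = o

    # exposure: non-cancer cells whose k nearest cancer cells contain
    # >= pmcp_min_frac cells of a given ORF
    from sklearn.neighbors import NearestNeighbors

    exposed: dict[str, set] = {o: set() for o in orfs}
    for tumor, sub in meta.groupby("tumor", sort=False):
        cancer = sub[sub["cell_type"] == "cancer"]
        others = sub[sub["cell_type"] != "cancer"]
        if len(cancer) < cfg.pmcp_k or len(others) == 0:
            continue
        nn = NearestNeighbors(n_neighbors=cfg.pmcp_k).fit(cancer[["x", "y"]])
        _, idx = nn.kneighbors(others[["x", "y"]])
        corf = cancer["orf"].to_numpy()
        for row, cid in zip(idx, others.index):
            local = corf[row]
            for o in orfs:
                if (local == o).mean() >= cfg.pmcp_min_frac:
                    exposed[o].add(cid)
    truth.exposed_cells = exposed

    # ligand fields: one smooth per-tumor Gaussian-bump field per ligand
    # (ligands are spatially independent); stromal cells express each ligand
    # proportionally to its own field, and the receptor ORF's planted
    # interaction genes respond to ligand 1 only where that field is high
    field_centers = {
        (tumor, li): rng.uniform(0, side, (2, 2))
        for tumor in meta["tumor"].unique() for li in range(max(cfg.n_ligands, 1))
    }

    def ligand_field(tumor, li, xy):
        c = field_centers[(tumor, li)]
        d2 = ((xy[:, None, :] - c[None, :, :]) ** 2).sum(axis=2)
        return np.exp(-d2 / (2 * 150.0**2)).sum(axis=1)

    fld = np.zeros((len(meta), max(cfg.n_ligands, 1)))
    for tumor, sub in meta.groupby("tumor", sort=False):
        rows_ = meta.index.get_indexer(sub.index)
        for li in range(max(cfg.n_ligands, 1)):
            fld[rows_, li] = ligand_field(tumor, li, sub[["x", "y"]].to_numpy())
    high_field = fld[:, 0] > np.median(fld[:, 0])

    gi = {g: i for i, g in enumerate(genes)}
    base_log_mu = rng.normal(cfg.baseline_mean_log, 0.8, cfg.panel_size)
    type_shift = {t: rng.normal(0.0, 0.6, cfg.panel_size) for t in cell_types}
    lfc = np.zeros((len(meta), cfg.panel_size))
    ct_arr = meta["cell_type"].to_numpy()
    orf_arr = meta["orf"].to_numpy()
    for o in orfs:
        mask = (ct_arr == "cancer") & (orf_arr == o)
        for g in truth.effects[o]["up"]:
            lfc[mask, gi[g]] += cfg.orf_effect_size
        for g in truth.effects[o]["down"]:
            lfc[mask, gi[g]] -= cfg.orf_effect_size
    for (ct, o), gset in pmcp_map.items():
        rows_ = meta.index.get_indexer(
            [c for c in exposed[o] if meta.at[c, "cell_type"] == ct])
        for g in gset:
            lfc[rows_, gi[g]] += cfg.pmcp_effect_size
    # gene-environment interaction for the receptor ORF
    rec_mask = (ct_arr == "cancer") & (orf_arr == receptor_orf) & high_field
    for g in gxe_gene_set:
        lfc[rec_mask, gi[g]] += cfg.gxe_effect_size
    # ligand expression by stromal cells scaled by the ligand's own field
    stromal = ct_arr == noncancer[-1] if noncancer else np.zeros(len(meta), bool)
    for li, lg in enumerate(ligand_genes):
        lfc[stromal, gi[lg]] += 1.5 * fld[stromal, li]

    size_factor = np.exp(rng.normal(0.0, 0.25, len(meta)))
    mu = (np.exp(base_log_mu)[None, :]
          * np.exp(np.array([type_shift[t] for t in ct_arr]))
          * np.exp(lfc * LN2) * size_factor[:, None])
    counts = _nb_draw(rng, mu, cfg.dispersion)
    meta["complexity"] = (counts > 0).sum(axis=1)

    # ORF barcode capture: 1-5 barcodes per label, high counts on the true
    # label's barcodes for cancer cells, low background everywhere
    barcode_to_orf = {}
    barcodes = []
    for li, lab in enumerate(labels):
        n_bc = 1 + (li % 5)
        for b in range(n_bc):
            name = f"{lab}_bc{b + 1}"
            barcodes.append(name)
            barcode_to_orf[name] = lab
    bmu = np.full((len(meta), len(barcodes)), 0.02)
    bidx = {b: i for i, b in enumerate(barcodes)}
    for row, (cid, o) in enumerate(meta["orf"].items()):
        if o == "none":
            continue
        own = [b for b in barcodes if barcode_to_orf[b] == o]
        for b in own:
            bmu[row, bidx[b]] = 8.0 / len(own)
    orf_counts = ad.AnnData(
        X=_nb_draw(rng, bmu, 5.0).astype(np.int64),
        obs=pd.DataFrame(index=meta.index.copy()),
        var=pd.DataFrame(
            {"orf": [barcode_to_orf[b] for b in barcodes]},
            index=pd.Index(barcodes, name="barcode"),
        ),
    )

    adata = ad.AnnData(
        X=counts.astype(np.int64),
        obs=meta.copy(),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    return adata, meta, truth, orf_counts, barcode_to_orf


# ---------------------------------------------------------------------------
# focused generators used by estimator benchmarks


def simulate_gxe_cells(n_fovs=15, cells_per_fov=60, beta_interaction=1.0,
                       beta_orf=0.5, n_ligands=2, fov_sd=0.8, noise_sd=1.0,
                       seed=0) -> pd.DataFrame:
    """Draw cells directly from the gene-environment interaction model.

    ``y ~ (1|FOV) + comp + x + sum_i L_i + sum_i L_i x`` with the interaction
    on ligand 1 set to ``beta_interaction`` and all other interactions zero.
    Used for parameter-recovery benchmarks of the mixed-effects estimator.
    """
    rng = np.random.default_rng(seed)
    rows = []
    u = rng.normal(0, fov_sd, n_fovs)
    lig_high = rng.random((n_fovs, n_ligands)) > 0.5
    for f in range(n_fovs):
        x = rng.random(cells_per_fov) > 0.5
        comp = rng.normal(100, 10, cells_per_fov)
        y = (1.0 + u[f] + 0.01 * comp + beta_orf * x
             + 0.3 * lig_high[f].sum()
             + beta_interaction * lig_high[f, 0] * x
             + rng.normal(0, noise_sd, cells_per_fov))
        for j in range(cells_per_fov):
            rows.append({"fov": f"fov{f}", "y": y[j], "x": int(x[j]),
                         "complexity": comp[j],
                         **{f"L{i + 1}": int(lig_high[f, i]) for i in range(n_ligands)}})
    return pd.DataFrame(rows)


def simulate_fov_confounded(n_tumors=4, fovs_per_tumor=8, cells_per_fov=70,
                            n_genes=40, n_true=8, effect_log2fc=1.0,
                            fov_sd_log2=1.0, frac_orf_fovs=0.35, seed=0):
    """Crossvalidation benchmark with FOV-level confounding.

    The ORF concentrates in a minority of FOVs per tumor (clonal growth);
    every gene also carries a large per-(tumor, FOV) random log2 shift.
    Within any one tumor those FOV shifts can spuriously correlate with ORF
    status, so a model blind to FOV flags null genes that carry no signal in
    a held-out tumor, whereas a FOV-aware model does not.

    Returns ``(counts AnnData, meta, true_genes)`` with meta columns tumor,
    fov, orf (1/0 for ORF vs control cells) and complexity.
    """
    rng = np.random.default_rng(seed)
    genes = np.array([f"Q{i:03d}" for i in range(n_genes)])
    true_genes = set(genes[:n_true])
    base_log_mu = rng.normal(1.0, 0.5, n_genes)
    rows, xs = [], []
    for t in range(n_tumors):
        n_orf_fovs = max(1, int(round(frac_orf_fovs * fovs_per_tumor)))
        orf_fovs = set(rng.choice(fovs_per_tumor, n_orf_fovs, replace=False))
        for f in range(fovs_per_tumor):
            fov_shift = rng.normal(0, fov_sd_log2, n_genes)
            p_orf = 0.75 if f in orf_fovs else 0.05
            for _ in range(cells_per_fov):
                is_orf = rng.random() < p_orf
                lfc = fov_shift.copy()
                if is_orf:
                    lfc[:n_true] += effect_log2fc
                sf = np.exp(rng.normal(0, 0.25))
                mu = np.exp(base_log_mu) * np.exp(lfc * LN2) * sf
                rows.append(_nb_draw(rng, mu, 2.0))
                xs.append((f"tumor{t + 1}", f"tumor{t + 1}_fov{f + 1}", int(is_orf)))
    counts = np.array(rows)
    meta = pd.DataFrame(xs, columns=["tumor", "fov", "orf"])
    meta.index = pd.Index([f"X{i:05d}" for i in range(len(meta))], name="cell_id")
    meta["complexity"] = (counts > 0).sum(axis=1)
    adata = ad.AnnData(X=counts.astype(np.int64), obs=meta.copy(),
                       var=pd.DataFrame(index=pd.Index(genes, name="gene")))
    return adata, meta, true_genes


# ---------------------------------------------------------------------------
# fixture export


def export_fixture(directory, counts: ad.AnnData, meta: pd.DataFrame,
                   truth: TruthTables | None = None,
                   guide_counts: ad.AnnData | None = None,
                   orf_counts: ad.AnnData | None = None) -> None:
    """Write a dataset as the MTX/CSV/JSON fixture the readers consume."""
    os.makedirs(directory, exist_ok=True)
    pdio.write_mtx(counts, os.path.join(directory, "counts"))
    if guide_counts is not None:
        pdio.write_mtx(guide_counts, os.path.join(directory, "guides"))
    if orf_counts is not None:
        pdio.write_mtx(orf_counts, os.path.join(directory, "orf_counts"))
    pdio.write_cells_csv(meta, os.path.join(directory, "cells.csv"))
    if truth is not None:
        from .utils import atomic_write_text

        atomic_write_text(os.path.join(directory, "truth.json"), truth.to_json())


def import_fixture(directory):
    """Read back a fixture directory; returns (counts, meta, guides?, orf_counts?)."""
    counts = pdio.read_mtx(os.path.join(directory, "counts"))
    meta = pdio.read_cells_csv(os.path.join(directory, "cells.csv"))
    counts.obs = meta.loc[counts.obs_names].copy()
    guides = orfc = None
    gdir = os.path.join(directory, "guides")
    if os.path.isdir(gdir):
        guides = pdio.read_mtx(gdir)
    odir = os.path.join(directory, "orf_counts")
    if os.path.isdir(odir):
        orfc = pdio.read_mtx(odir)
    return counts, meta, guides, orfc
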