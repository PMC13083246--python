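"""In situ Perturb-seq preprocessing: transcript-to-cell assignment, ORF
calling, stable-cell selection, reference-map construction and projection.

The reference map follows the standard single-cell recipe — normalization,
PCA, a shared-nearest-neighbor graph (k=10) and Louvain community detection
(igraph's multilevel algorithm, which is the original Louvain) — using all
panel genes rather than a highly-variable subset, as appropriate for
targeted spatial panels. Query cells are projected with a kNN classifier in
the reference PC space whose vote fraction serves as the confidence score;
cells at confidence <= 0.8 are dropped downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import anndata as ad
import igraph
import numpy as np
import pandas as pd
from scipy import sparse, stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

log = logging.getLogger(__name__)

LN2 = np.log(2.0)


def _dense(x):
    return np.asarray(x.todense()) if sparse.issparse(x) else np.asarray(x)


def log_tpm(counts: ad.AnnData, scale: float = 1e3) -> np.ndarray:
    """log2(1 + scaled transcript fraction) per cell.

    The default scale of 1,000 (transcripts per thousand) is the
    panel-appropriate analog of TPM: with a ~100-1,000 gene panel and a few
    hundred transcripts per cell it keeps log-values in a numerically stable
    range (a raw TPM scale would swing single-count genes by ~12 log2 units,
    drowning every downstream linear model in detection noise).
    """
    x = _dense(counts.X).astype(float)
    totals = x.sum(axis=1)
    totals[totals == 0] = 1.0
    return np.log1p(scale * x / totals[:, None]) / LN2


# ---------------------------------------------------------------------------
# transcripts -> cells


def assign_transcripts(transcripts: pd.DataFrame, rasters: dict,
                       genes=None, pixel_size: float = 1.0):
    """Tally molecules into cells via per-FOV segmentation label rasters.

    ``transcripts`` needs columns gene, x, y, fov (coordinates in microns);
    ``rasters[fov]`` is a 2-D integer label image (0 = background, row =
    y // pixel_size). Molecules landing on background or outside the raster
    are counted (and the out-of-bounds ones warned about) but not assigned,
    so assigned + background equals the table length exactly.

    Returns ``(counts AnnData, n_background)``; per-cell centroids (label
    centroid, microns) and complexity are filled into ``obs``.
    """
    required = {"gene", "x", "y", "fov"}
    if not required <= set(transcripts.columns):
        raise ValueError(f"transcript table needs columns {sorted(required)}")
    if genes is None:
        genes = sorted(transcripts["gene"].unique())
    gi = {g: i for i, g in enumerate(genes)}
    cells: list = []
    cell_idx: dict = {}
    counts_rows: list = []
    n_background = 0
    n_oob = 0
    for _, row in transcripts.iterrows():
        raster = rasters.get(row["fov"])
        if raster is None:
            raise ValueError(f"no segmentation raster for FOV {row['fov']!r}")
        r, c = int(row["y"] // pixel_size), int(row["x"] // pixel_size)
        if not (0 <= r < raster.shape[0] and 0 <= c < raster.shape[1]):
            n_background += 1
            n_oob += 1
            continue
        label = int(raster[r, c])
        if label == 0:
            n_background += 1
            continue
        cid = (row["fov"], label)
        if cid not in cell_idx:
            cell_idx[cid] = len(cells)
            cells.append(cid)
            counts_rows.append(np.zeros(len(genes), dtype=np.int64))
        j = gi.get(row["gene"])
        if j is None:
            raise ValueError(f"gene {row['gene']!r} not in panel")
        counts_rows[cell_idx[cid]][j] += 1
    if n_oob:
        log.warning("%d molecules outside raster bounds counted as background", n_oob)

    x = np.vstack(counts_rows) if counts_rows else np.zeros((0, len(genes)), dtype=np.int64)
    obs = pd.DataFrame(index=pd.Index([f"{f}_cell{l}" for f, l in cells], name="cell_id"))
    obs["fov"] = [f for f, _ in cells]
    cx, cy = [], []
    for f, label in cells:
        rr, cc = np.nonzero(rasters[f] == label)
        cx.append((cc.mean() + 0.5) * pixel_size)
        cy.append((rr.mean() + 0.5) * pixel_size)
    obs["x"], obs["y"] = cx, cy
    obs["complexity"] = (x > 0).sum(axis=1)
    adata = ad.AnnData(X=x, obs=obs, var=pd.DataFrame(index=pd.Index(genes, name="gene")))
    return adata, n_background


# ---------------------------------------------------------------------------
# ORF calling


def call_orf(orf_counts: ad.AnnData, barcode_to_orf: dict, min_count: int = 2) -> pd.Series:
    """Call each cell's ORF from barcode counts (1-5 barcodes per ORF).

    Barcode counts are summed per ORF; the top ORF is called when its total
    reaches ``min_count`` and the runner-up stays below it, otherwise the
    cell is ``none`` (ambiguous or undetected).
    """
    unknown = set(orf_counts.var_names) - set(barcode_to_orf)
    if unknown:
        raise ValueError(f"unknown barcodes: {sorted(unknown)[:5]}")
    orfs = sorted(set(barcode_to_orf.values()))
    x = _dense(orf_counts.X)
    sums = np.zeros((orf_counts.n_obs, len(orfs)))
    for j, bc in enumerate(orf_counts.var_names):
        sums[:, orfs.index(barcode_to_orf[bc])] += x[:, j]
    order = np.argsort(sums, axis=1)
    top = sums[np.arange(len(sums)), order[:, -1]]
    runner = sums[np.arange(len(sums)), order[:, -2]] if len(orfs) > 1 else np.zeros(len(sums))
    calls = np.where((top >= min_count) & (runner < min_count),
                     np.array(orfs, dtype=object)[order[:, -1]], "none")
    return pd.Series(calls, index=orf_counts.obs_names, name="orf")


# ---------------------------------------------------------------------------
# clustering machinery


def snn_cluster(values: np.ndarray, n_pcs: int = 20, k: int = 10,
                resolution: float = 0.4, seed: int = 0,
                algorithm: str = "louvain") -> np.ndarray:
    """PCA -> SNN graph (Jaccard weights) -> Louvain communities.

    ``algorithm="leiden"`` is available as a documented deviation.
    """
    n_pcs = min(n_pcs, values.shape[1], max(1, values.shape[0] - 1))
    if values.shape[0] <= n_pcs:
        raise ValueError("fewer cells than requested principal components")
    pcs = PCA(n_components=n_pcs, random_state=seed).fit_transform(values)
    k_eff = min(k, values.shape[0] - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(pcs)
    _, idx = nn.kneighbors(pcs)
    neigh = [set(row[1:]) for row in idx]
    floor = 1.0 / (2 * k_eff)  # keep every kNN edge so no cell is isolated
    seen = {}
    for i in range(len(neigh)):
        for j in neigh[i]:
            j = int(j)
            key = (min(i, j), max(i, j))
            if key in seen:
                continue
            jac = len(neigh[i] & neigh[j]) / len(neigh[i] | neigh[j])
            seen[key] = max(jac, floor)
    edges, weights = list(seen.keys()), list(seen.values())
    g = igraph.Graph(n=len(neigh), edges=edges)
    if algorithm == "louvain":
        rng_state = igraph.set_random_number_generator
        import random as _random

        rng = _random.Random(seed)
        rng_state(rng)
        part = g.community_multilevel(weights=weights, resolution=resolution)
        rng_state(None)
        labels = np.array(part.membership)
    elif algorithm == "leiden":
        import leidenalg

        part = leidenalg.find_partition(
            g, leidenalg.RBConfigurationVertexPartition, weights=weights,
            resolution_parameter=resolution, seed=seed)
        labels = np.array(part.membership)
    else:
        raise ValueError(f"unknown clustering algorithm {algorithm!r}")
    return labels


def stable_cells(counts: ad.AnnData, n_subsamples: int = 10, frac: float = 0.8,
                 agreement: float = 0.7, seed: int = 0, **cluster_kw) -> pd.Series:
    """High-quality cells: repeatedly co-assigned across data subsamples.

    The full data is clustered once (the anchor); ``n_subsamples`` random
    ``frac`` subsets are re-clustered, subset clusters matched to anchor
    clusters by maximal overlap, and a cell is stable when the fraction of
    subsamples agreeing with its anchor cluster is at least ``agreement``.
    """
    if n_subsamples < 3:
        raise ValueError("n_subsamples must be >= 3")
    vals = log_tpm(counts)
    anchor = snn_cluster(vals, seed=seed, **cluster_kw)
    if len(np.unique(anchor)) == 1:
        log.warning("degenerate clustering (single cluster); all cells stable")
        return pd.Series(True, index=counts.obs_names, name="stable")
    rng = np.random.default_rng(seed)
    n = counts.n_obs
    agree = np.zeros(n)
    times = np.zeros(n)
    for s in range(n_subsamples):
        idx = rng.choice(n, size=int(round(frac * n)), replace=False)
        sub_labels = snn_cluster(vals[idx], seed=seed + s + 1, **cluster_kw)
        # match subset clusters to anchor clusters by maximal overlap
        mapping = {}
        for c in np.unique(sub_labels):
            members = idx[sub_labels == c]
            anchors, cnt = np.unique(anchor[members], return_counts=True)
            mapping[c] = anchors[np.argmax(cnt)]
        times[idx] += 1
        agree[idx] += np.array([mapping[c] for c in sub_labels]) == anchor[idx]
    with np.errstate(invalid="ignore"):
        rate = np.where(times > 0, agree / np.maximum(times, 1), 0.0)
    return pd.Series(rate >= agreement, index=counts.obs_names, name="stable")


# ---------------------------------------------------------------------------
# reference map and projection


@dataclass
class ReferenceMap:
    cell_ids: pd.Index
    pca_mean: np.ndarray
    pca_components: np.ndarray  # n_pcs x n_genes
    embedding: np.ndarray  # cells x n_pcs
    clusters: pd.Series
    genes: pd.Index
    markers: dict = field(default_factory=dict)  # cluster -> DataFrame
    annotation: dict = field(default_factory=dict)  # cluster -> cell type label


def cluster_markers(vals: np.ndarray, labels: np.ndarray, genes,
                    p_max: float = 0.05, lfc_min: float = 0.25) -> dict:
    """Per-cluster marker genes: overexpressed versus all other clusters.

    Two-sample t-test per gene with strict thresholds: p < ``p_max`` and
    log2 fold-change > ``lfc_min`` (mean difference of log2 values).
    """
    out = {}
    for c in np.unique(labels):
        inside, outside = vals[labels == c], vals[labels != c]
        if len(inside) < 2 or len(outside) < 2:
            out[c] = pd.DataFrame(columns=["log2fc", "p"])
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            t, p = stats.ttest_ind(inside, outside, axis=0, equal_var=False)
        lfc = inside.mean(axis=0) - outside.mean(axis=0)
        df = pd.DataFrame({"log2fc": lfc, "p": p}, index=genes)
        out[c] = df[(df.p < p_max) & (df.log2fc > lfc_min)].sort_values("p")
    return out


def annotate_clusters(markers: dict, signatures: dict, universe_size: int) -> dict:
    """Assign each cluster the signature with the best marker enrichment.

    Hypergeometric upper-tail test of each cluster's markers against each
    provided gene set over the panel universe.
    """
    out = {}
    for c, mk in markers.items():
        best, best_p = "unknown", 1.0
        mset = set(mk.index)
        for name, genes in signatures.items():
            gset = set(genes)
            k = len(mset & gset)
            p = stats.hypergeom.sf(k - 1, universe_size, len(gset), len(mset)) if k else 1.0
            if p < best_p:
                best, best_p = name, p
        out[c] = best if best_p < 0.05 else "unknown"
    return out


def build_reference(counts: ad.AnnData, signatures: dict | None = None,
                    n_var_genes: int | None = None, n_pcs: int = 20, k: int = 10,
                    resolution: float = 0.4, seed: int = 0,
                    algorithm: str = "louvain") -> ReferenceMap:
    """Cluster and embed a reference subset of the data.

    Panel data uses all genes (``n_var_genes=None``); set ``n_var_genes`` to
    restrict to the top variable genes for transcriptome-wide data.
    """
    if counts.n_obs == 0:
        raise ValueError("empty reference subset")
    vals = log_tpm(counts)
    genes = counts.var_names
    if n_var_genes is not None and n_var_genes < vals.shape[1]:
        top = np.argsort(vals.var(axis=0))[::-1][:n_var_genes]
        vals = vals[:, np.sort(top)]
        genes = genes[np.sort(top)]
    n_pcs = min(n_pcs, vals.shape[1])
    if vals.shape[0] <= n_pcs:
        raise ValueError("fewer cells than requested principal components")
    pca = PCA(n_components=n_pcs, random_state=seed).fit(vals)
    emb = pca.transform(vals)
    labels = snn_cluster(vals, n_pcs=n_pcs, k=k, resolution=resolution,
                         seed=seed, algorithm=algorithm)
    markers = cluster_markers(vals, labels, genes)
    annotation = (annotate_clusters(markers, signatures, len(genes))
                  if signatures else {c: f"cluster{c}" for c in np.unique(labels)})
    return ReferenceMap(
        cell_ids=counts.obs_names.copy(), pca_mean=pca.mean_,
        pca_components=pca.components_, embedding=emb,
        clusters=pd.Series(labels, index=counts.obs_names, name="cluster"),
        genes=pd.Index(genes), markers=markers, annotation=annotation,
    )


def select_reference_cells(counts: ad.AnnData, clusters: pd.Series,
                           per_cluster: int = 2000, score: pd.Series | None = None,
                           score_min: float = 0.3, seed: int = 0) -> pd.Index:
    """Reference subset: up to ``per_cluster`` cells per cluster plus every
    cell whose signature score exceeds ``score_min`` (e.g. a T cell score),
    guaranteeing rare scored populations enter the reference."""
    rng = np.random.default_rng(seed)
    chosen: list = []
    for c in clusters.unique():
        ids = clusters.index[clusters == c]
        if len(ids) > per_cluster:
            ids = pd.Index(rng.choice(ids, per_cluster, replace=False))
        chosen.extend(ids)
    picked = pd.Index(pd.unique(pd.Index(chosen)))
    if score is not None:
        picked = picked.union(score.index[score > score_min])
    return picked


def project(reference: ReferenceMap, query: ad.AnnData, k: int = 10,
            conf_min: float = 0.8) -> pd.DataFrame:
    """Project query cells into the reference PC space and annotate them.

    Label = majority cluster among the k nearest reference cells;
    confidence = that cluster's vote fraction. A query coinciding exactly
    with a reference cell inherits its label at confidence 1 (self-map). The
    ``retained`` column applies the strict ``confidence > conf_min`` rule.
    """
    if reference.clusters.nunique() < 1:
        raise ValueError("reference has no classes")
    vals = log_tpm(query[:, list(reference.genes)])
    emb = (vals - reference.pca_mean) @ reference.pca_components.T
    k_eff = min(k, len(reference.embedding))
    nn = NearestNeighbors(n_neighbors=k_eff).fit(reference.embedding)
    dist, idx = nn.kneighbors(emb)
    ref_labels = reference.clusters.to_numpy()
    labels, conf = [], []
    # sqrt of accumulated float64 rounding puts an exact re-projection at
    # ~1e-7 from its reference point, so the self-match tolerance sits well
    # above that and far below any real inter-cell distance
    scale_tol = 1e-6 * (1.0 + float(np.abs(reference.embedding).max()))
    for row_d, row_i in zip(dist, idx):
        if row_d[0] <= scale_tol:
            labels.append(ref_labels[row_i[0]])
            conf.append(1.0)
            continue
        votes = ref_labels[row_i]
        uniq, cnt = np.unique(votes, return_counts=True)
        order = np.argsort((-cnt, uniq.astype(str)), axis=-1) if False else np.lexsort(
            (uniq.astype(str), -cnt))
        labels.append(uniq[order[0]])
        conf.append(cnt[order[0]] / k_eff)
    out = pd.DataFrame({"cluster": labels, "confidence": conf}, index=query.obs_names)
    out["cell_type"] = [reference.annotation.get(c, str(c)) for c in out["cluster"]]
    out["retained"] = out["confidence"] > conf_min
    return out
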