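"""Perturb-seq hit scoring, signed regulatory networks, ligand-receptor
integration and co-regulation analysis.

A gene g is scored against the phenotype classes of the CRISPRa
perturbations that regulate it: S_sen(g) = Sen_up(g) + Res_down(g) and
S_res(g) = Res_up(g) + Sen_down(g), where e.g. Sen_up(g) counts the
sensitizing CRISPRa hits whose GA signature contains g in the up set. A
Perturb-seq sensitizing hit requires S_sen >= 2 and S_res == 0 (resistance
mirrored), so the two classes are mutually exclusive by construction.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

log = logging.getLogger(__name__)


def classify_hits(signatures, crispra_labels: dict) -> pd.DataFrame:
    """Score and classify Perturb-seq hits from GA signatures.

    ``crispra_labels`` maps each perturbed target to ``"sensitizing"`` or
    ``"resistance"``; targets without a label (and labels whose gene is
    absent from every signature) contribute nothing. Each perturbation
    counts a regulated gene once.
    """
    known = {t for s in signatures for t in ([s.target])}
    for gene in set(crispra_labels) - known:
        log.warning("CRISPRa label for %s matches no signature; counted as zeros", gene)
    genes = sorted({g for s in signatures for g in (set(s.up) | set(s.down))})
    tab = pd.DataFrame(0, index=pd.Index(genes, name="gene"),
                       columns=["sen_up", "sen_down", "res_up", "res_down"])
    for sig in signatures:
        cls = crispra_labels.get(sig.target)
        if cls not in ("sensitizing", "resistance"):
            continue
        pre = "sen" if cls == "sensitizing" else "res"
        tab.loc[list(sig.up), f"{pre}_up"] += 1
        tab.loc[list(sig.down), f"{pre}_down"] += 1
    tab["s_sen"] = tab.sen_up + tab.res_down
    tab["s_res"] = tab.res_up + tab.sen_down
    tab["hit_class"] = "none"
    tab.loc[(tab.s_sen >= 2) & (tab.s_res == 0), "hit_class"] = "sensitizing"
    tab.loc[(tab.s_res >= 2) & (tab.s_sen == 0), "hit_class"] = "resistance"
    return tab


def build_network(signatures) -> nx.DiGraph:
    """Signed directed regulatory graph from GA signatures.

    Edge ``(A, B, sign=+1)`` iff B is in A's up set; ``-1`` for down. A
    self-edge (the on-target effect) is kept but flagged.
    """
    if not signatures:
        raise ValueError("need at least one signature")
    g = nx.DiGraph()
    for sig in signatures:
        g.add_node(sig.target, perturbed=True)
        for gene, sign in [*((x, 1) for x in sig.up), *((x, -1) for x in sig.down)]:
            g.add_edge(sig.target, gene, sign=sign, self_edge=(gene == sig.target))
    return g


def prune_network(net: nx.DiGraph, crispra_hits: set, hit_table: pd.DataFrame) -> nx.DiGraph:
    """Keep CRISPRa-hit and/or Perturb-seq-hit nodes and edges among them.

    Node attributes record both hit classes; ``incoming_rank`` orders nodes
    by incoming degree (ties alphabetical), the most-regulated gene last —
    the left-to-right layout of the pruned network figure.
    """
    ps_hits = set(hit_table.index[hit_table.hit_class != "none"])
    keep = (set(net.nodes) & set(crispra_hits)) | (set(net.nodes) & ps_hits)
    sub = net.subgraph(keep).copy()
    for n in sub.nodes:
        sub.nodes[n]["crispra_hit"] = n in crispra_hits
        sub.nodes[n]["perturbseq_hit"] = (
            hit_table.hit_class.get(n, "none") if n in hit_table.index else "none")
    order = sorted(sub.nodes, key=lambda n: (sub.in_degree(n), n))
    for rank, n in enumerate(order):
        sub.nodes[n]["incoming_rank"] = rank
    return sub


def integrate_lr(net: nx.DiGraph, lr_pairs: pd.DataFrame) -> tuple[nx.DiGraph, pd.DataFrame]:
    """Overlay undirected ligand-receptor edges on the pruned network.

    A pair is added when either member is already a network node (the other
    member joins as an L-R partner node). Hubs are maximal components of the
    L-R overlay that touch nodes of at least two hit classes (CRISPRa hit /
    Perturb-seq hit; a dual hit counts as both); the returned frame lists
    per-hub interaction and member-hit counts.
    """
    if not {"ligand", "receptor"} <= set(lr_pairs.columns):
        raise ValueError("ligand-receptor table needs 'ligand' and 'receptor' columns")
    g = net.copy()
    overlay = nx.Graph()
    for _, row in lr_pairs.iterrows():
        a, b = str(row["ligand"]), str(row["receptor"])
        if a in net.nodes or b in net.nodes:
            overlay.add_edge(a, b)
            for n in (a, b):
                if n not in g:
                    g.add_node(n, crispra_hit=False, perturbseq_hit="none", lr_partner=True)
            g.add_edge(a, b, kind="lr", sign=0)
            g.add_edge(b, a, kind="lr", sign=0)
    hubs = []
    for comp in nx.connected_components(overlay):
        classes = set()
        n_hits = 0
        for n in comp:
            is_crispra = net.nodes.get(n, {}).get("crispra_hit", False)
            ps = net.nodes.get(n, {}).get("perturbseq_hit", "none")
            if is_crispra:
                classes.add("crispra")
            if ps != "none":
                classes.add("perturbseq")
            if is_crispra or ps != "none":
                n_hits += 1
        if len(classes) >= 2:
            hubs.append({
                "n_nodes": len(comp),
                "n_interactions": overlay.subgraph(comp).number_of_edges(),
                "n_hits": n_hits,
                "members": ",".join(sorted(comp)),
            })
    hubs = pd.DataFrame(hubs, columns=["n_nodes", "n_interactions", "n_hits", "members"])
    return g, hubs


def lr_enrichment(hits_a: set, hits_b: set, lr_pairs: pd.DataFrame) -> float:
    """Restricted-universe hypergeometric test of ligand-receptor convergence.

    The universe is the set of genes appearing in any pair. The binding
    partners of ``hits_a`` and of ``hits_b`` (within the universe) are
    intersected and the overlap tested against the hypergeometric upper
    tail: P(X >= k) with population N = |universe|, K = |partners(a)|,
    draws n = |partners(b)|.
    """
    universe: set = set()
    partners: dict[str, set] = {}
    for _, row in lr_pairs.iterrows():
        a, b = str(row["ligand"]), str(row["receptor"])
        universe.update((a, b))
        partners.setdefault(a, set()).add(b)
        partners.setdefault(b, set()).add(a)
    if not universe:
        raise ValueError("empty ligand-receptor universe")

    def _partners(s):
        out = set()
        for gene in set(s) & universe:
            out |= partners[gene]
        return out

    pa, pb = _partners(hits_a), _partners(hits_b)
    k = len(pa & pb)
    return float(stats.hypergeom.sf(k - 1, len(universe), len(pa), len(pb)))


def coregulation(signatures, n_clusters: int | None = None) -> dict:
    """Co-regulation counts and modules across perturbations.

    ``score[g, h]`` counts the perturbations whose signature moves g and h
    in the same direction (both up or both down); the diagonal counts the
    signatures containing the gene at all. Modules come from average-linkage
    hierarchical clustering of ``1 - score / sqrt(diag_g * diag_h)``.
    """
    if len(signatures) < 2:
        raise ValueError("need >= 2 signatures")
    genes = sorted({g for s in signatures for g in (set(s.up) | set(s.down))})
    gi = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    score = np.zeros((n, n), dtype=int)
    for sig in signatures:
        for block in (sig.up, sig.down):
            idx = np.array([gi[g] for g in block], dtype=int)
            score[np.ix_(idx, idx)] += 1
    mat = pd.DataFrame(score, index=genes, columns=genes)
    out = {"matrix": mat}
    diag = np.diag(score).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = score / np.sqrt(np.outer(diag, diag))
    norm[~np.isfinite(norm)] = 0.0
    np.fill_diagonal(norm, 1.0)
    dist = np.clip(1.0 - norm, 0.0, None)
    if n >= 2:
        link = average(squareform(dist, checks=False))
        out["linkage"] = link
        if n_clusters:
            out["clusters"] = pd.Series(
                fcluster(link, t=n_clusters, criterion="maxclust"), index=genes)
    return out


def read_lr_pairs(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    df.columns = [c.lower() for c in df.columns]
    if not {"ligand", "receptor"} <= set(df.columns):
        if df.shape[1] >= 2:
            df.columns = ["ligand", "receptor", *df.columns[2:]]
        else:
            raise ValueError("malformed ligand-receptor table")
    return df[["ligand", "receptor"]].astype(str)


def read_crispra_hits(path) -> dict:
    df = pd.read_csv(path, sep="\t", comment="#")
    df.columns = [c.lower() for c in df.columns]
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
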