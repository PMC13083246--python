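# perturbdecode

Analysis toolkit for decoding gain-of-function perturbation effects on cells
and tissues, for computational biologists working with CRISPRa Perturb-seq
and imaging-based (in situ) Perturb-seq screens. It covers the full analytic
chain from raw count matrices to perturbation-phenotype networks and spatial
statistics, and ships a synthetic-data generator with planted ground truth
so every stage can be exercised and validated without any external download.

## What it computes

**Dissociated Perturb-seq** (`perturbdecode.perturbseq`): sgRNA singlet
assignment from guide UMI counts; tp10k/tp100k log normalization;
pseudobulk aggregation by (guide, condition, batch); per-gene NB GLM
differential expression `y ~ batch + x` with a quasi-likelihood moderated
Wald test; gene-activation (GA) signatures at FDR < 0.01 in either culture
condition; per-sgRNA expression shifts

&nbsp;&nbsp;&nbsp;&nbsp;Z_k = (1/JI) Σ_j Σ_i (P_kji − C_ji)

on mean log1p tp100k profiles (P = perturbed, C = control pseudobulk in
batch j, condition i); pairwise sgRNA concordance stratified into
same-target / different-target / control pairs; leave-one-sgRNA-out
crossvalidation with signature-score AUROC; and coculture-response (co-UP /
co-DOWN) gene sets from control cells (FDR < 0.01, |log2FC| > 0.25).

**Hit scoring and networks** (`perturbdecode.hits`): Perturb-seq hits from
phenotype-classed regulators, S_sen(g) = Sen_up(g) + Res_down(g) and
S_res(g) = Res_up(g) + Sen_down(g), with a sensitizing hit requiring
S_sen ≥ 2 and S_res = 0 (resistance mirrored); signed regulatory networks
(edge ⟨A,B,±1⟩ iff B is in A's GA signature); pruning to hit nodes with an
incoming-degree layout; ligand–receptor overlay with hub detection; a
restricted-universe hypergeometric convergence test; and perturbation
co-regulation matrices with hierarchical modules.

**In situ Perturb-seq** (`perturbdecode.insitu`): transcript-to-cell
assignment over segmentation label rasters; ORF calling from concatenated
barcode counts; stable-cell selection by subsample co-clustering; reference
maps (PCA, SNN k=10, Louvain) with marker-based annotation; and kNN
projection of all cells with a vote-fraction confidence (> 0.8 retained).

**Spatial statistics** (`perturbdecode.spatial`): clonal zonation
permutation tests (same-ORF fraction among k = 10 nearest cancer cells,
labels permuted within slide); spatially aware GA signatures via linear
mixed models `y ~ (1|FOV) + ORF + complexity` (REML) against a nonspatial
hurdle baseline, compared by leave-one-tumor-out AUROC; micro-FOV
pseudobulks with perturbation abundances; perturbation multicellular
programs (pMCPs) by partial Spearman correlation at BH FDR < 0.1; and
gene–environment interaction models
`y ~ (1|FOV) + comp + x + Σ L_i + Σ L_i·x` with ligand-high micro-FOV
indicators.

## Worked example

```python
from perturbdecode.simulate import PerturbseqSimConfig, simulate_perturbseq
from perturbdecode import perturbseq as ps

cfg = PerturbseqSimConfig(seed=1)          # 8 targets x 3 sgRNAs + 6 NTC guides
counts, guides, meta, truth = simulate_perturbseq(cfg)

assign = ps.assign_perturbations(guides, min_umi=3)
meta = meta.join(assign)
singlet = (meta.status == "singlet").to_numpy()
counts, meta = counts[singlet], meta[singlet]
print(assign.status.value_counts().to_dict())
# {'singlet': 1014, 'multiplet': 65, 'unassigned': 1}

target = sorted(truth.effects)[0]          # 'G0000'
sig = ps.run_target_de(counts, meta, target, fdr=0.01)
planted = truth.effects[target]["up"] | truth.effects[target]["down"]
recovered = set(sig.up) | set(sig.down)
print(len(planted), len(recovered), len(planted & recovered))
# 31 22 22
```

The simulation plants a log2FC = 1 effect on 30 genes per target (plus the
on-target elevation). At this depth the GA signature recovers 22 of the 31
planted genes with no false positives (Jaccard 0.71): the NB GLM is
deliberately conservative at FDR < 0.01 with six pseudobulks per side.

Running leave-one-sgRNA-out crossvalidation on a strong perturbation
(`effect_size_log2fc=2`, 50 effect genes) yields

```python
ps.loocv_sgrna(counts, meta, target)[["left_out", "t_p", "auroc"]]
#      left_out        t_p  auroc
# 0  G0000_sg1  3.2e-103    1.0
# ...
```

an AUROC of 1.0 per held-out guide — each guide's cells are fully
recognizable from a signature learned without them — while a null
simulation gives AUROC ≈ 0.5.

A command-line interface mirrors the library:

```bash
perturbdecode simulate --kind insitu --seed 5 --out fx/
perturbdecode spatial --data fx/ --mode zonation --n-perm 999 --out out/
```

`out/zonation.tsv` then holds, per tumor and ORF, the observed same-ORF
neighbor fraction, its permutation-null mean, and the empirical p-value
(p < 0.01 for every planted clone configuration).

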