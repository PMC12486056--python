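# heist

Hierarchical graph-transformer embeddings for spatial transcriptomics
and proteomics, with a synthetic-tissue generator that makes every
stage testable on a desk-scale CPU budget.

Single-cell spatial assays (MERFISH, Xenium, CODEX) measure per-cell
expression together with 2-D tissue coordinates. `heist` models such a
dataset as a **two-level graph**: a spatial cell graph 𝒢c (cells
connected when their Voronoi regions touch) in which every cell of type
t carries that type's **gene co-expression network** 𝒢g^t (genes
connected when their mutual information across the type's cells exceeds
a threshold τ, chosen adaptively per type). An encoder alternates
intra-level graph attention (over spatial neighbours; over co-expressed
genes within each cell) with **directional cross-level message
passing**,

    CrossMessagePassing(H_to, H_from) = (⟨H_to W_q, H_from W_k⟩ / d) · H_to W_v ,

so gene states are modulated by their parent cell's spatial context and
cell states by the aggregate of their gene states. Pretraining is
self-supervised: a spatially-aware contrastive loss (positives =
same-type cells within radius r; negatives = different-type cells
within r; cell↔cell, gene↔gene and cell↔gene terms), a masked
autoencoding loss over hidden coordinates and gene entries decoded by a
3-layer GIN, an orthogonality penalty on the embedding Gram matrices,
and a learnable sigmoid balance σ(γ) between the first two. Frozen
embeddings are evaluated on clustering (NMI), annotation (macro-F1),
tissue classification (AUROC) and gene imputation (Pearson r), and the
decoder can be fine-tuned for imputation while the encoder stays
frozen.

Everything runs on numpy via a small reverse-mode autodiff core
included in the package — no GPU or deep-learning framework required.
See `docs/methods.md` for the model, the generator's design, and every
numerical default.

## Worked example

```python
import numpy as np
from heist import (GeneratorConfig, ExpressionMatrix, generate,
                   build_hierarchical_graph, pretrain, ModelConfig,
                   TrainConfig, embed_graph, cluster_cells)

tissue = generate(GeneratorConfig(seed=0))          # 1500 cells, 60 genes
expr = ExpressionMatrix(values=tissue.observed_expression,
                        gene_ids=tissue.gene_ids, cell_ids=tissue.cell_ids)
hg = build_hierarchical_graph(expr, tissue.positions,
                              labels=tissue.type_labels.astype(str), seed=0)
print(hg.n_cells, hg.n_genes, len(hg.gene_networks))

ckpt = pretrain(hg, ModelConfig(seed=0), None, TrainConfig(seed=0))
train = ckpt.history.query("split == 'train'")
print(round(train.total.iloc[0], 2), "->", round(train.total.iloc[-1], 2))

Zc, Zg = embed_graph(hg, ckpt)
keep = np.isin(tissue.cell_ids, hg.expression.cell_ids)
res = cluster_cells(Zc, tissue.type_labels[keep], method="spectral",
                    n_clusters=3, seed=0)
print(res.metric_name, round(res.value, 3))
```

which prints

```
1426 60 3
6.28 -> 1.46
NMI 0.87
```

1426 of the 1500 simulated cells survive outlier filtering; three gene
co-expression networks are built (one per cell type); ten epochs of
pretraining bring the combined loss from 6.28 to 1.46; and spectral
clustering of the frozen cell embeddings recovers the generator's
planted cell types at NMI 0.87.

The same pipeline is available from the shell:

```bash
heist simulate --seed 7 -o data/
heist build-graphs --data data/ --seed 7 -o graph.h5
heist pretrain --graph graph.h5 --seed 7 -o ckpt/
heist embed --graph graph.h5 --ckpt ckpt/ -o emb/
heist eval --task cluster --graph graph.h5 --ckpt ckpt/ --seed 7 -o results.csv
```

Every command writes a `manifest.json` (config hash, seeds, versions)
next to its outputs.

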