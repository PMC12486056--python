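"""Synthetic spatial tissues with known ground truth.

The generator emulates the data-generating structure the hierarchical
model assumes: discrete cell types with marker programs, block-structured
gene co-expression modules, spatial niches (Voronoi regions of random
anchors) that modulate expression within a type, and zero-inflation
(dropout) noise.  Every stage of the pipeline — graph construction,
pretraining, downstream evaluation — is testable against the retained
generative state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class GeneratorConfig:
    """Tissue-generator parameters.

    Defaults are sized so a full pretrain + evaluate cycle stays desk
    scale: 1500 cells, 60 genes, 3 types, 3 niches, 2 co-expression
    modules per type, 40% dropout, niche effect 0.8 (in units of the
    latent expression scale).
    """

    n_cells: int = 1500
    n_genes: int = 60
    n_types: int = 3
    n_niches: int = 3
    modules_per_type: int = 2
    niche_effect_size: float = 0.8
    dropout_rate: float = 0.4
    noise_sd: float = 0.3
    marker_strength: float = 2.5
    module_loading: float = 0.6
    niche_gene_fraction: float = 0.33
    seed: int = 0

    def __post_init__(self):
        if self.n_types < 1:
            raise ValueError("n_types must be >= 1")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.niche_effect_size < 0 or self.noise_sd < 0:
            raise ValueError("effect sizes must be >= 0")


@dataclass
class SyntheticTissue:
    """Generated tissue plus the full generative state used to make it."""

    positions: np.ndarray          # (n_cells, 2) in the unit square
    type_labels: np.ndarray        # (n_cells,) int
    niche_labels: np.ndarray       # (n_cells,) int
    module_assignment: np.ndarray  # (n_genes,) int, -1 = no module
    clean_expression: np.ndarray   # (n_cells, n_genes) nonnegative
    observed_expression: np.ndarray  # after dropout
    params: GeneratorConfig = field(repr=False)
    seed: int = 0

    @property
    def cell_ids(self):
        return np.array([f"cell_{i:05d}" for i in range(self.positions.shape[0])])

    @property
    def gene_ids(self):
        return np.array([f"gene_{j:04d}" for j in range(self.clean_expression.shape[1])])

    def validate(self):
        n, g = self.clean_expression.shape
        assert self.observed_expression.shape == (n, g)
        assert self.positions.shape == (n, 2)
        assert (self.observed_expression <= self.clean_expression + 1e-9).all()
        assert (self.clean_expression >= 0).all()


def _softplus(x):
    return np.logaddexp(0.0, x)


def generate(cfg: GeneratorConfig) -> SyntheticTissue:
    """Draw one tissue from the generative model.

    Positions are uniform in the unit square; niches are the Voronoi
    regions of ``n_niches`` seeded anchors (best-candidate placement, so
    regions have comparable areas); cell types follow a
    niche-dependent mixture (each niche favours one type, so niche
    composition varies across space without being deterministic); the
    latent expression of cell i is

        type baseline + marker boost + module factors + niche offset + noise,

    passed through a softplus so expression stays nonnegative.  Module m
    contributes ``f_im * loading`` to its member genes with a per-cell
    latent factor ``f_im ~ N(0, 1)``, which induces within-module
    correlation.  The niche offset applies ``niche_effect_size`` times a
    fixed per-niche pattern to a subset of genes, only modulating — never
    redefining — the type program.  Dropout zeroes entries i.i.d.
    """
    rng = np.random.default_rng(cfg.seed)
    n, g, t_n = cfg.n_cells, cfg.n_genes, cfg.n_types

    positions = rng.uniform(0.0, 1.0, size=(n, 2))
    # anchors by seeded best-candidate sampling: niches get comparable
    # areas, as in real tissue where regions are of the same order of size
    candidates = rng.uniform(0.0, 1.0, size=(64, 2))
    anchors = [candidates[0]]
    for _ in range(cfg.n_niches - 1):
        dmin = np.min([((candidates - a) ** 2).sum(-1) for a in anchors], axis=0)
        anchors.append(candidates[int(np.argmax(dmin))])
    anchors = np.asarray(anchors)
    d2 = ((positions[:, None, :] - anchors[None, :, :]) ** 2).sum(-1)
    niche_labels = d2.argmin(axis=1)

    # niche-dependent type mixture: uniform base + a boost for the
    # niche's favoured type, so composition shifts but all types co-occur
    mix = np.ones((cfg.n_niches, t_n))
    for m in range(cfg.n_niches):
        mix[m, m % t_n] += 2.0
    mix /= mix.sum(axis=1, keepdims=True)
    u = rng.uniform(size=n)
    cum = np.cumsum(mix[niche_labels], axis=1)
    type_labels = (u[:, None] > cum).sum(axis=1)

    # modules: contiguous gene blocks, modules_per_type per type
    n_modules = t_n * cfg.modules_per_type
    module_assignment = np.full(g, -1, dtype=np.int64)
    block = g // n_modules if n_modules else 0
    for m in range(n_modules):
        module_assignment[m * block:(m + 1) * block] = m

    baseline = np.full((t_n, g), 1.0)
    for t in range(t_n):
        # marker genes of type t = genes of type t's modules
        owned = (module_assignment // cfg.modules_per_type) == t
        baseline[t, owned & (module_assignment >= 0)] += cfg.marker_strength

    loadings = np.zeros((n_modules, g))
    for m in range(n_modules):
        loadings[m, module_assignment == m] = cfg.module_loading
    factors = rng.normal(0.0, 1.0, size=(n, n_modules))

    # niche offsets: +/- niche_effect_size on a random gene subset
    # (sign patterns keep every niche's shift at full effect size)
    niche_gene_mask = np.zeros(g, dtype=bool)
    n_niche_genes = max(1, int(round(cfg.niche_gene_fraction * g)))
    niche_gene_mask[rng.choice(g, size=n_niche_genes, replace=False)] = True
    niche_patterns = (rng.choice([-1.0, 1.0], size=(cfg.n_niches, g))
                      * niche_gene_mask)

    latent = (
        baseline[type_labels]
        + factors @ loadings
        + cfg.niche_effect_size * niche_patterns[niche_labels]
        + rng.normal(0.0, cfg.noise_sd, size=(n, g))
    )
    clean = _softplus(latent)

    keep = rng.uniform(size=(n, g)) >= cfg.dropout_rate
    observed = clean * keep

    tissue = SyntheticTissue(
        positions=positions,
        type_labels=type_labels,
        niche_labels=niche_labels,
        module_assignment=module_assignment,
        clean_expression=clean,
        observed_expression=observed,
        params=cfg,
        seed=cfg.seed,
    )
    tissue.validate()
    return tissue


def export(tissue: SyntheticTissue, outdir) -> dict:
    """Write the CSV-triplet dialect plus a ground-truth sidecar.

    Files: ``expression.csv`` (cells × genes, observed), ``coords.csv``
    (cell_id, x, y), ``types.csv`` (cell_id, cell_type) and
    ``truth.json`` (niche labels, module map, generator config).
    Re-export with the same tissue is byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {k: outdir / f"{k}.csv" for k in ("expression", "coords", "types")}
    paths["truth"] = outdir / "truth.json"
    for p in paths.values():
        if p.exists():
            raise FileExistsError(f"refusing to overwrite {p}")

    cell_ids, gene_ids = tissue.cell_ids, tissue.gene_ids
    expr = pd.DataFrame(tissue.observed_expression, index=cell_ids, columns=gene_ids)
    expr.index.name = "cell_id"
    expr.to_csv(paths["expression"], float_format="%.6g")
    pd.DataFrame(
        {"cell_id": cell_ids,
         "x": np.round(tissue.positions[:, 0], 9),
         "y": np.round(tissue.positions[:, 1], 9)}
    ).to_csv(paths["coords"], index=False)
    pd.DataFrame(
        {"cell_id": cell_ids,
         "cell_type": [f"type_{t}" for t in tissue.type_labels]}
    ).to_csv(paths["types"], index=False)

    truth = {
        "cell_ids": cell_ids.tolist(),
        "niche_labels": tissue.niche_labels.tolist(),
        "type_labels": tissue.type_labels.tolist(),
        "module_assignment": {g: int(m) for g, m in
                              zip(gene_ids, tissue.module_assignment)},
        "config": asdict(tissue.params),
        "seed": tissue.seed,
    }
    paths["truth"].write_text(json.dumps(truth, indent=1, sort_keys=True))
    return {k: str(v) for k, v in paths.items()}
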