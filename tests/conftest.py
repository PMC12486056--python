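import numpy as np
import pytest

from heist import (ExpressionMatrix, GeneratorConfig, build_hierarchical_graph,
                   generate)


@pytest.fixture(scope="session")
def small_tissue():
    """300-cell tissue shared by unit tests (generator defaults otherwise)."""
    return generate(GeneratorConfig(n_cells=300, seed=11))


@pytest.fixture(scope="session")
def small_graph(small_tissue):
    t = small_tissue
    expr = ExpressionMatrix(values=t.observed_expression,
                            gene_ids=t.gene_ids, cell_ids=t.cell_ids)
    return build_hierarchical_graph(expr, t.positions,
                                    labels=t.type_labels.astype(str), seed=11)


@pytest.fixture(scope="session")
def small_truth(small_tissue, small_graph):
    """Ground-truth labels aligned with the cells surviving preprocessing."""
    t = small_tissue
    keep = np.isin(t.cell_ids, small_graph.expression.cell_ids)
    return {"types": t.type_labels[keep], "niches": t.niche_labels[keep]}


@pytest.fixture()
def float64_tensors(monkeypatch):
    """Run the autodiff core in float64 for tight numerical checks."""
    import heist._tensor as T
    monkeypatch.setattr(T, "DTYPE", np.float64)
    yield
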