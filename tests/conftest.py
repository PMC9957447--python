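import numpy as np
import pandas as pd
import pytest

from trnkit import synthetic
from trnkit.datamodel import ExpressionMatrix, GOCorpus
import networkx as nx


@pytest.fixture
def small_expr() -> ExpressionMatrix:
    """3 genes x 4 samples, one TF; target G1 = 1.0 * TF1 exactly."""
    values = pd.DataFrame(
        {
            "S1": [1.0, 1.0, 0.5],
            "S2": [-2.0, -2.0, 1.5],
            "S3": [0.3, 0.3, -0.7],
            "S4": [1.2, 1.2, 0.1],
        },
        index=["TF1", "G1", "G2"],
    )
    return ExpressionMatrix(values, ["TF1"])


@pytest.fixture(scope="session")
def planted_500():
    """The reference parameter-recovery dataset: 20 TFs, 500 genes, 200 samples."""
    return synthetic.generate_expression(20, 500, 200, 0.1, 0.1, seed=7)


@pytest.fixture(scope="session")
def toy_corpus() -> GOCorpus:
    r"""Hand-built DAG: root with two branches, four leaves, known annotations.

        root
        /  \
      B1    B2          (is_a)
     /  \     \
    L1  L2    L3        (L2 -> B1 is part_of)
               \
                L4 (child of L3, is_a)
    """
    dag = nx.DiGraph()
    dag.add_edge("B1", "root", relation="is_a")
    dag.add_edge("B2", "root", relation="is_a")
    dag.add_edge("L1", "B1", relation="is_a")
    dag.add_edge("L2", "B1", relation="part_of")
    dag.add_edge("L3", "B2", relation="is_a")
    dag.add_edge("L4", "L3", relation="is_a")
    direct = {
        "g1": {"L1"},
        "g2": {"L1", "L2"},
        "g3": {"L2"},
        "g4": {"L3"},
        "g5": {"L4"},
        "g6": {"L1"},
        "g7": {"L1"},
        "g8": {"B2"},
    }
    return GOCorpus(dag, direct)


@pytest.fixture(scope="session")
def motif_fixture():
    """Planted-motif dataset: 10 TFs, 1000 promoters, pi=0.5 insertions."""
    from trnkit import motifs as mm

    _, model = synthetic.generate_expression(10, 1000, 5, 0.1, 0.0, seed=11)
    model.motif_plants = synthetic.random_motif_plants(model.tf_ids, k=7, pi=0.5, seed=12)
    truth = model.true_network()
    promoters = synthetic.generate_promoters(model, truth, length=1577, seed=13)
    index = mm.index_promoters(promoters, ks=(7,))
    return model, truth, promoters, index
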