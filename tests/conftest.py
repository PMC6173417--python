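import numpy as np
import pandas as pd
import pytest

from vasctx.geneset_io import GeneSet, GeneSetCatalog


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_de_table(gene_ids, lfc, p=None):
    """Build a minimal DE table for scoring/ranking tests."""
    n = len(gene_ids)
    lfc = np.asarray(lfc, dtype=float)
    p = np.full(n, 0.5) if p is None else np.asarray(p, dtype=float)
    df = pd.DataFrame(
        {
            "base_mean": np.ones(n),
            "log2_fold_change": lfc,
            "p_value": p,
            "adj_p": p,
            "status": "ok",
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return df


@pytest.fixture
def de_builder():
    return make_de_table


@pytest.fixture
def smooth_muscle_catalog():
    return GeneSetCatalog(
        (
            GeneSet("GO_SMOOTH_MUSCLE_CONTRACTION", "desc", ("ACTA2", "CNN1", "MYH11")),
            GeneSet("GO_NEURON_DEATH", "desc", ("CASP3", "BAX")),
            GeneSet("Smooth_Muscle_Proliferation", "", ("PDGFRB", "TAGLN")),
        )
    )
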