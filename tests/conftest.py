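import numpy as np
import pandas as pd
import pytest

from tisspec.io_formats import ExpressionMatrix


def make_expr(values, tissues=None, gene_ids=None, exon_counts=None, biotype=None,
              species="test"):
    """Build a small ExpressionMatrix from a 2-D array-like."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    ids = [f"t{i}" for i in range(n)]
    tissues = tissues or [f"tissue{j}" for j in range(m)]
    meta = pd.DataFrame(
        {
            "gene_id": gene_ids if gene_ids is not None else ids,
            "exon_count": exon_counts if exon_counts is not None else 1,
            "biotype": biotype if biotype is not None else "coding",
            "species": species,
        },
        index=pd.Index(ids, name="transcript_id"),
    )
    return ExpressionMatrix(pd.DataFrame(values, index=meta.index, columns=tissues), meta)


@pytest.fixture
def toy_expr():
    """4 transcripts x 4 tissues with one clear single-tissue transcript."""
    return make_expr(
        [
            [10, 0, 0, 0],
            [5, 5, 5, 5],
            [1, 2, 3, 4],
            [0, 0, 0, 8],
        ],
        tissues=["brain", "adipose", "testis", "gut"],
        gene_ids=["g0", "g1", "g2", "g2"],
    )


@pytest.fixture
def toy_genome():
    return {"c1": "ACGTACGTAC"}
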