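import numpy as np
import pandas as pd
import pytest

from polybias import ExpressionMatrix, HomoeologMap


def make_matrix(values, genes=None, tissues=None, replicates=1, unit="tpm", species="sp"):
    """Build an ExpressionMatrix from a 2D array.

    Columns are grouped by tissue: ``tissues`` lists tissue names and
    ``replicates`` how many consecutive columns each tissue owns.
    """
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    if genes is None:
        genes = [f"g{i}" for i in range(n_genes)]
    if tissues is None:
        assert n_samples % replicates == 0
        tissues = [f"t{i}" for i in range(n_samples // replicates)]
    sample_ids, rows = [], []
    for t in tissues:
        for r in range(1, replicates + 1):
            sid = f"{t}_r{r}" if replicates > 1 else t
            sample_ids.append(sid)
            rows.append({"sample_id": sid, "species": species, "tissue": t, "replicate": r})
    assert len(sample_ids) == n_samples
    meta = pd.DataFrame(rows).set_index("sample_id")
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=sample_ids), meta, unit=unit)


@pytest.fixture
def mk():
    return make_matrix


@pytest.fixture
def triad_map():
    """Two triads over subgenomes A, B, C using genes g0..g5."""
    return HomoeologMap(
        {
            "grp0": {"A": "g0", "B": "g1", "C": "g2"},
            "grp1": {"A": "g3", "B": "g4", "C": "g5"},
        },
        ratio_class="triad",
    )
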