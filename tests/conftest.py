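import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from effectome import SignedConnectome, SynthConfig, generate_random_connectome


@pytest.fixture
def codex_csv(tmp_path):
    """Write a small Codex-dialect synapse table and return its path."""

    def _write(rows, name="synapses.csv", header=None):
        header = header or "pre_root_id,post_root_id,syn_count,nt_type"
        path = tmp_path / name
        path.write_text("\n".join([header] + rows) + "\n")
        return path

    return _write


@pytest.fixture
def toy_table():
    """In-memory canonical synapse table builder."""

    def _make(rows):
        return pd.DataFrame(rows, columns=["pre_id", "post_id", "count", "nt_type"])

    return _make


@pytest.fixture
def small_connectome():
    """Deterministic sparse signed connectome, 120 neurons."""
    return generate_random_connectome(
        SynthConfig(d=120, sparsity=0.05, inhibitory_fraction=0.4, seed=11)
    )


@pytest.fixture
def dense_conn():
    """Small dense connectome wrapper for eigen checks."""

    def _make(arr):
        arr = np.asarray(arr, dtype=float)
        return SignedConnectome(
            neuron_index=np.arange(arr.shape[0]), matrix=sp.csr_matrix(arr)
        )

    return _make
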