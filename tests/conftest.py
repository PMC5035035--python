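import numpy as np
import pytest

from cytopipe import fcs


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def toy_fcs(tmp_path, rng):
    """A small FCS file: 100 events x 5 channels, stains on 3 channels."""
    data = rng.uniform(0.0, 1000.0, size=(100, 5)).astype(np.float32)
    path = tmp_path / "toy.fcs"
    fcs.write_fcs(
        path,
        data,
        short_names=["Ir191", "Ir193", "Y89", "Tm169", "Nd146"],
        stain_names=["CD3", "CD4", "CD8", None, None],
    )
    return path, data


@pytest.fixture()
def blob_pair(rng):
    """Two far-separated tight 2-D blobs of 100 points each, labeled."""
    a = rng.normal((0.0, 0.0), 0.5, size=(100, 2))
    b = rng.normal((30.0, 0.0), 0.5, size=(100, 2))
    data = np.vstack([a, b])
    labels = np.repeat([1, 2], 100)
    return data, labels
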