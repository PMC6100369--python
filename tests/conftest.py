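import numpy as np
import pytest

from nirquant.spectra_io import (
    Dataset,
    SampleRecord,
    SpectrumSet,
    WavenumberAxis,
)


@pytest.fixture
def axis():
    """Uniform 4000..10000 cm^-1 grid at 4 cm^-1 spacing."""
    return WavenumberAxis.regular(4000.0, 10000.0, 4.0)


@pytest.fixture
def small_axis():
    return WavenumberAxis.regular(5000.0, 5200.0, 4.0)


def make_spectra(axis, rows, ids=None):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    ids = ids or tuple(f"S{i + 1}" for i in range(rows.shape[0]))
    return SpectrumSet(axis, rows, ids)


def make_dataset(axis, rows, contents, role="pool"):
    spectra = make_spectra(axis, rows)
    records = [
        SampleRecord(id=s, content=float(c), role=role)
        for s, c in zip(spectra.sample_ids, contents)
    ]
    return Dataset(spectra, records)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
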