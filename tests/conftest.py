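import numpy as np
import pytest

from frozenrma import ProbeMatrix


@pytest.fixture
def tiny_pm() -> ProbeMatrix:
    """4 probes in 2 probesets x 3 arrays, strictly positive intensities."""
    return ProbeMatrix(
        intensities=np.array([
            [120.0, 130.0, 110.0],
            [240.0, 260.0, 220.0],
            [55.0, 60.0, 50.0],
            [70.0, 75.0, 66.0],
        ]),
        probe_ids=np.array(["pA_1", "pA_2", "pB_1", "pB_2"], dtype=object),
        probeset_of=np.array(["psA", "psA", "psB", "psB"], dtype=object),
        array_ids=np.array(["arr1", "arr2", "arr3"], dtype=object),
        batch_of={"arr1": "b1", "arr2": "b1", "arr3": "b2"},
    )


@pytest.fixture
def tiny_files(tmp_path, tiny_pm):
    """The tiny matrix written out in the package's TSV formats."""
    from frozenrma import write_probe_matrix

    paths = (tmp_path / "matrix.tsv", tmp_path / "annotation.tsv", tmp_path / "batches.tsv")
    write_probe_matrix(tiny_pm, *paths)
    return paths
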