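import numpy as np
import pandas as pd
import pytest

import survscan as sv


@pytest.fixture
def simple_survival():
    """Eight samples, a few censored, no ties."""
    time = np.array([5.0, 8.0, 12.0, 3.0, 20.0, 15.0, 7.0, 30.0])
    event = np.array([1.0, 1.0, 0.0, 1.0, 0.0, 1.0, 1.0, 0.0])
    return sv.SurvivalData(time, event)


@pytest.fixture
def tiny_matrix():
    """Two chromosomes x 3 samples with a clean deletion/gain structure."""
    ann = sv.MarkerAnnotation(
        pd.DataFrame(
            {
                "marker_id": [f"M{i}" for i in range(1, 7)],
                "chromosome": ["1", "1", "1", "2", "2", "2"],
                "position": [100, 200, 300, 100, 200, 300],
            }
        )
    )
    values = np.array(
        [
            [1.0, 2.0, 3.0],
            [1.1, 2.0, 3.1],
            [0.9, 2.1, 2.9],
            [2.0, 2.0, 2.0],
            [2.1, 1.9, 2.0],
            [2.0, 2.0, 2.1],
        ]
    )
    return sv.GenomeMatrix(values, ann, ["S1", "S2", "S3"])


@pytest.fixture(scope="session")
def demo_sim():
    """One draw of the default planted-deletion study (shared, read-only)."""
    return sv.simulate(sv.demo_spec(seed=11))


@pytest.fixture(scope="session")
def demo_model(demo_sim):
    return sv.GenomeSurvivalScan(demo_sim.matrix, demo_sim.sample_table, sv.ScanConfig())


def write_sample_info(path, rows, header="Sample\tSurvival(numeric)\tEvent(numeric)"):
    path.write_text(header + "\n" + "\n".join(rows) + "\n")
    return path
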