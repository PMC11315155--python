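import numpy as np
import pandas as pd
import pytest

import aromakit as ak


@pytest.fixture(scope="session")
def fixture_panel():
    return ak.load_paper_fixture()


@pytest.fixture()
def tiny_meta():
    return ak.make_sample_meta([
        ("W1r1", "W1", "G1", 1),
        ("W1r2", "W1", "G1", 2),
        ("W2r1", "W2", "G2", 1),
    ])


@pytest.fixture()
def tiny_peaks_csv(tmp_path):
    """Well-formed 3-sample peak CSV with one IS peak per replicate."""
    def _write(extra_rows=(), drop_area=None):
        rows = [
            ("W1r1", 9.9, 1000.0, "2-octanol", True),
            ("W1r1", 5.0, 500.0, "cpdA", False),
            ("W1r2", 9.9, 1000.0, "2-octanol", True),
            ("W1r2", 5.0, 480.0, "cpdA", False),
            ("W2r1", 9.9, 2000.0, "2-octanol", True),
            ("W2r1", 5.0, 2000.0, "cpdA", False),
        ] + list(extra_rows)
        frame = pd.DataFrame(rows, columns=[
            "sample_id", "retention_time", "peak_area", "compound_id",
            "is_internal_standard"])
        if drop_area is not None:
            frame.loc[drop_area, "peak_area"] = 0.0
        path = tmp_path / "peaks.csv"
        frame.to_csv(path, index=False)
        return path
    return _write


@pytest.fixture()
def rng():
    return np.random.default_rng(20240710)
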