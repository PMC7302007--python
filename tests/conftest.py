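import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=60,
                          deadline=None)
settings.load_profile("suite")

DEFAULT_HEADER = ["MarkerName", "Effect", "StdErr", "IntEffect", "IntStdErr",
                  "IntCor", "N"]


def write_joint_file(path, rows, header=DEFAULT_HEADER):
    """Write a tab-delimited joint-model summary fixture."""
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")
    return path


@pytest.fixture
def three_row_file(tmp_path):
    rows = [
        ("rs1", 0.12, 0.03, -0.05, 0.04, 0.1, 1000),
        ("rs2", -0.02, 0.01, 0.08, 0.02, -0.3, 980),
        ("rs3", 0.00, 0.05, 0.00, 0.06, 0.0, 1000),
    ]
    return write_joint_file(tmp_path / "joint.tsv", rows), rows


@pytest.fixture
def rng():
    return np.random.default_rng(20200618)
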