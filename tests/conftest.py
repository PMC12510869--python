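import numpy as np
import pytest
from hypothesis import settings

from uvrsig.core import ExpressionMatrix

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=30)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def toy_matrix(rng):
    """10 genes x 6 samples with distinct values (no ties)."""
    values = rng.permutation(60).reshape(10, 6).astype(float)
    return ExpressionMatrix(
        [f"G{i}" for i in range(10)], [f"S{j}" for j in range(6)], values
    )


@pytest.fixture
def write_gmt_file(tmp_path):
    def _write(lines, name="sets.gmt"):
        p = tmp_path / name
        p.write_text("\n".join(lines) + "\n")
        return p

    return _write
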