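import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "stagecorr",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("stagecorr")


@pytest.fixture
def toy_expression_tsv(tmp_path):
    """4 genes x (3 stages x 2 replicates) expression table on disk."""
    lines = ["gene_id\t10 hpf|r1\t10 hpf|r2\t20 hpf|r1\t20 hpf|r2\t30 hpf|r1\t30 hpf|r2"]
    rows = {
        "g1": [2.0, 4.0, 1.0, 1.0, 0.0, 0.0],
        "g2": [0.0, 0.0, 5.0, 7.0, 2.0, 2.0],
        "g3": [1.5, 2.5, 3.5, 4.5, 5.5, 6.5],
        "g4": [0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
    }
    for g, vals in rows.items():
        lines.append(g + "\t" + "\t".join(str(v) for v in vals))
    path = tmp_path / "expr.tsv"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
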