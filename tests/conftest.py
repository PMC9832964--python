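import numpy as np
import pytest
from hypothesis import HealthCheck, settings as hyp_settings

# Derandomized hypothesis so the suite is reproducible run-to-run.
hyp_settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
hyp_settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def small_table():
    """A tiny hand-written table: 2 domains, 4 variables, mixed signs."""
    from helpers import table_from

    return table_from([
        ("Bacteroides", "Bacteria", "Prevotella", "Bacteria", 0.50),
        ("Bacteroides", "Bacteria", "pH", "Chemistry", -0.35),
        ("Prevotella", "Bacteria", "pH", "Chemistry", 0.31),
        ("Faecalibacterium", "Bacteria", "pH", "Chemistry", 0.30),
        ("Faecalibacterium", "Bacteria", "Prevotella", "Bacteria", -0.20),
    ])
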