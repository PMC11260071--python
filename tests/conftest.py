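import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def toy_msa():
    """Small hand-written alignment used across msa/sca unit tests."""
    from pksforge.msa import MSA

    seqs = [
        "ACDEFGHIKL",
        "ACDEFGHIKL",
        "ACDEYGHIKL",
        "ACDEFGH-KL",
        "ACDEFGHMKL",
        "APDEFGHIKL",
    ]
    return MSA(
        ids=[f"s{i}" for i in range(len(seqs))],
        seqs=seqs,
        column_map=np.arange(10),
    )


def random_msa(rng, n=12, length=8, gap_rate=0.1):
    """Uniform random alignment helper (not a fixture: called with params)."""
    from pksforge.msa import MSA

    codes = rng.integers(0, 20, size=(n, length)).astype(np.int8)
    codes[rng.random((n, length)) < gap_rate] = 20
    return MSA.from_codes([f"r{i}" for i in range(n)], codes)
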