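import numpy as np
import pytest

from paleovir import synthgen as sg
from paleovir.damage import DamageProfile


@pytest.fixture(scope="session")
def small_genome():
    return sg.simulate_genome(5_000, gc=0.5, seed=101)


def profile_from_expected(d1: float, lam: float, b: float, n_per_pos: int = 10**6, P: int = 20):
    """Deterministic profile whose counts equal the expected counts of a
    damage curve — a noise-free input for fit-recovery checks."""
    pos = np.arange(1, P + 1, dtype=float)
    rate = b + (d1 - b) * np.exp(-lam * (pos - 1.0))
    n = np.full(P, n_per_pos, dtype=np.int64)
    k = np.rint(n * rate).astype(np.int64)
    return DamageProfile(contig_id="expected", P=P, n_c_sites=n, n_ct=k, n_reads=n_per_pos)
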