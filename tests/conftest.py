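import numpy as np
import pytest

from mrmkit import io
from mrmkit.assay_design import ProteinRecord


@pytest.fixture(scope="session")
def reference_transitions():
    """The packaged transition list (7 urinary proteins + BSA control)."""
    return io.load_reference_transitions()


@pytest.fixture(scope="session")
def opn_transitions(reference_transitions):
    return [t for t in reference_transitions if t.protein == "OPN"]


@pytest.fixture(scope="session")
def opn_bsa_transitions(reference_transitions):
    return [t for t in reference_transitions if t.protein in ("OPN", "BSA")]


@pytest.fixture()
def toy_background():
    """Three-entry background proteome for uniqueness checks."""
    return [
        ProteinRecord("P1", "parent", "MAAKGDSVVYGLRTTK"),
        ProteinRecord("P2", "other", "MMEAGAQLKPPR"),
        ProteinRecord("P3", "unrelated", "MWWWWHHHH"),
    ]


def gaussian_trace(
    height=1000.0,
    sigma=0.05,
    apex_rt=5.0,
    baseline=0.0,
    noise_sd=0.0,
    t0=4.0,
    t1=6.0,
    dt=0.01,
    seed=0,
    sample_id="s1",
    tid="t1",
):
    """Analytically constructed Gaussian peak trace for peak-model tests."""
    from mrmkit.peaks import Trace

    rng = np.random.default_rng(seed)
    t = np.arange(t0, t1 + dt / 2, dt)
    y = baseline + height * np.exp(-0.5 * ((t - apex_rt) / sigma) ** 2)
    if noise_sd > 0:
        y = y + rng.normal(0, noise_sd, size=t.size)
    y = np.maximum(y, 0.0)
    return Trace(sample_id=sample_id, transition_id=tid, time=t, intensity=y)


@pytest.fixture()
def make_gaussian_trace():
    return gaussian_trace
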