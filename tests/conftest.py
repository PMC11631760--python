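import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=100,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from ndiasim.pipeline import build_species_digests
from ndiasim.windows import (
    AcquisitionMethod,
    DIA_SCAN_OVERHEAD_MS,
    MzRange,
    TimingModel,
    make_fixed_windows,
)
from ndiasim.acquisition import simulate_dia


@pytest.fixture(scope="session")
def human_digest():
    """Small seeded human-like digest: ~350 peptide ions on a 150-s gradient."""
    return build_species_digests(
        seed=3, n_proteins={"human": 20}, gradient_length_s=150.0,
        peak_fwhm_s=5.0,
    )["human"]


@pytest.fixture(scope="session")
def dia_method_2th():
    scheme = make_fixed_windows(MzRange(380.0, 980.0), 2.0)
    timing = TimingModel(3.5, DIA_SCAN_OVERHEAD_MS)
    return AcquisitionMethod.dia(scheme, timing)


@pytest.fixture(scope="session")
def dia_run(human_digest, dia_method_2th):
    return simulate_dia(human_digest, dia_method_2th, 150.0, seed=1, run_id="a")
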