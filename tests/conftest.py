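import pytest
from hypothesis import HealthCheck, settings

from egfoglc.simulate import build_manifest

settings.register_profile(
    "default",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_manifest():
    """20 planted sites, default 5% noise / 3 ppm jitter, 2 replicates."""
    return build_manifest(
        n_proteins=4,
        n_egfs_per_protein=5,
        seed=11,
        consensus_mix=(0.5, 0.3, 0.2, 0.0),
        replicates=2,
    )


@pytest.fixture(scope="session")
def noiseless_manifest():
    return build_manifest(
        n_proteins=4,
        n_egfs_per_protein=5,
        seed=11,
        consensus_mix=(0.5, 0.3, 0.2, 0.0),
        replicates=1,
        noise_fraction=0.0,
        mz_jitter_ppm=0.0,
    )
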