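import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20230917)


@pytest.fixture
def small_spec():
    """A fast zero-nuisance study: 8 subjects, 10 parcels, 60 timepoints."""
    from rsgfc.synthetic import SyntheticSpec

    return SyntheticSpec(
        n_subjects=8,
        n_parcels=10,
        n_timepoints=60,
        n_lead_volumes=0,
        community_count=2,
        nuisance_amplitude=0.0,
        effect_mode="focal",
        effect_targets=(5,),
        delta_z=0.2,
        subject_sd_z=0.05,
        rng_seed=42,
    )


@pytest.fixture
def small_conns(small_spec):
    from rsgfc.pipeline import connectivity_from_dataset
    from rsgfc.synthetic import generate_dataset

    return connectivity_from_dataset(generate_dataset(small_spec))


def random_connectivity(rng, n_parcels=10, subject="sub-01", session="rest1"):
    """A random symmetric Fisher-Z matrix for oracle comparisons."""
    from rsgfc.connectivity import ConnectivityMatrix

    z = rng.normal(0, 0.4, (n_parcels, n_parcels))
    z = (z + z.T) / 2
    np.fill_diagonal(z, np.nan)
    ids = [f"p{i:03d}" for i in range(n_parcels)]
    return ConnectivityMatrix(z=z, parcel_ids=ids, subject=subject, session=session)
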