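import numpy as np
import pytest

import fibrocmr as f


@pytest.fixture(scope="session")
def noiseless_spec():
    return f.PhantomSpec(noise_sd=0.0)


@pytest.fixture(scope="session")
def noiseless_cohort():
    """High-contrast cohort without LGE or fibrosis noise, quantified end to end."""
    params = f.SyntheticCohortParams.noiseless()
    return f.build_synthetic_cohort(params, seed=7)


def random_phantom_spec(rng: np.random.Generator, noise_sd: float = 0.0) -> "f.PhantomSpec":
    """A random but valid phantom spec for oracle-equivalence sweeps."""
    endo = rng.uniform(15.0, 22.0)
    return f.PhantomSpec(
        endo_radius_mm=endo,
        epi_radius_mm=endo + rng.uniform(6.0, 12.0),
        scar_center_deg=rng.uniform(0.0, 360.0),
        scar_width_deg=rng.uniform(40.0, 140.0),
        scar_transmurality_frac=rng.uniform(0.2, 1.0),
        scar_fibrosis_frac=rng.uniform(0.3, 0.8),
        noise_sd=noise_sd,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
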