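import numpy as np
import pytest

from dtialps import (
    CohortSpec,
    alps_phantom_spec,
    compute_scalar_maps,
    fit_tensor,
    generate_cohort,
    make_gradient_table,
    simulate_dwi,
)


@pytest.fixture(scope="session")
def gtab20():
    """The study acquisition: 20 directions at b=1000 plus one b=0."""
    return make_gradient_table(20, 1000.0, 1)


@pytest.fixture(scope="session")
def noiseless_phantom(gtab20):
    """Noiseless bilateral ALPS phantom (analytic index 1.35) with its
    fitted tensor field and scalar maps."""
    spec = alps_phantom_spec(target_alps=1.35)
    dwi, truth = simulate_dwi(spec, gtab20)
    field = fit_tensor(dwi, "wls")
    maps = compute_scalar_maps(field)
    return {"spec": spec, "dwi": dwi, "truth": truth, "field": field,
            "maps": maps}


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(CohortSpec(seed=0))


def random_spd_tensors(n, rng, scale=1e-3):
    """Random symmetric positive-definite tensors with realistic
    diffusivities, as (n, 3, 3) matrices."""
    evals = rng.uniform(0.2, 2.5, (n, 3)) * scale
    out = np.empty((n, 3, 3))
    for i in range(n):
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        out[i] = q @ np.diag(evals[i]) @ q.T
    return out
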