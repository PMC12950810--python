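import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("stable", derandomize=True, deadline=None)
settings.load_profile("stable")

from hergsim.cohort import CohortSpec, generate_cohort
from hergsim.protocols import builtin_protocols
from hergsim.variants import variant_params


@pytest.fixture(scope="session")
def protocols():
    return builtin_protocols()


@pytest.fixture(scope="session")
def wt_params():
    return variant_params("WT")


@pytest.fixture(scope="session")
def wt_cell():
    """One noiseless wild-type cell recorded under all five protocols."""
    spec = CohortSpec("WT", 1, seed=0, variability={}, noise_sd=0.0)
    return generate_cohort(spec)[0]


# ---------------------------------------------------------------------------
# myocyte simulations: the steady-state pacing runs are expensive, so the
# control and g_Kr-reduced results are computed once per session and shared
# by the physiology and acceptance tests.
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def ord_control_run():
    from hergsim.ord import OrdConfig
    from hergsim.ord.sim import run_paced
    return run_paced(OrdConfig(g_kr_scale=1.0), record_beats=2)


@pytest.fixture(scope="session")
def ord_variant_run():
    from hergsim.ord import OrdConfig
    from hergsim.ord.sim import run_paced
    return run_paced(OrdConfig(g_kr_scale=0.31), record_beats=2)
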