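import pytest
from hypothesis import HealthCheck, settings

from ampliquant import analyze_amplification, demo_plan, generate_synthetic_run

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

TRUE_EFFICIENCIES = {"T1": 1.7, "T2": 1.8, "T3": 1.9, "T4": 2.0}


@pytest.fixture(scope="session")
def noiseless_plate():
    """Noise-free demo plate (4 assays x 4 dilutions + controls) with truth."""
    plan = demo_plan(n_replicates=4, noise_sd=0.0)
    run, truth = generate_synthetic_run(plan, seed=1)
    return run, truth.set_index("well")


@pytest.fixture(scope="session")
def noiseless_analysis(noiseless_plate):
    run, truth = noiseless_plate
    return run, truth, analyze_amplification(run)


@pytest.fixture(scope="session")
def noisy_plate():
    """Same plate at 1% multiplicative noise with 8 replicates per assay."""
    plan = demo_plan(n_replicates=8, noise_sd=0.01)
    run, truth = generate_synthetic_run(plan, seed=2)
    return run, truth.set_index("well")


@pytest.fixture(scope="session")
def noisy_analysis(noisy_plate):
    run, truth = noisy_plate
    return run, truth, analyze_amplification(run)
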