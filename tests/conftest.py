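import numpy as np
import pytest

from denet import (
    ControlGrid,
    HiddenInputSpec,
    KnownInput,
    MeasurementSet,
    OdeModel,
    RegularizationConfig,
    generate_truth,
    motif_models,
    simulate,
    solve_den,
)

QUICK = {"substeps": 2, "maxiter": 600}


@pytest.fixture(scope="session")
def u_step():
    """Unit step input held over [0, 12]."""
    return KnownInput(np.array([0.0, 12.0]), np.array([[1.0], [1.0]]))


@pytest.fixture(scope="session")
def motifs():
    return motif_models()


@pytest.fixture(scope="session")
def scalar_decay():
    """dx/dt = -x + w, y = x, x0 = 1 — the scalar linear benchmark."""
    return OdeModel.from_expressions(
        ["x"], ["-x + 0*u"], ["x"], {"k": 1.0}, [1.0], name="decay1")


@pytest.fixture(scope="session")
def chain3_pulse_truth(motifs, u_step):
    """Noiseless single-node pulse truth on the chain motif (node 1)."""
    spec = HiddenInputSpec(target_nodes=(1,), waveform="pulse", amplitude=1.0,
                           onset=2.0, offset=9.0)
    return generate_truth(motifs["chain3"], u_step, spec,
                          np.linspace(0, 12, 25), noise_sd=0.0, seed=1)


@pytest.fixture(scope="session")
def chain3_grid(chain3_pulse_truth):
    return ControlGrid.for_data(chain3_pulse_truth.measurements, n_intervals=24)


@pytest.fixture(scope="session")
def chain3_fit(motifs, u_step, chain3_pulse_truth, chain3_grid):
    """One shared dynamic elastic-net fit of the chain benchmark."""
    cfg = RegularizationConfig(lambda1=0.05, lambda2=0.005)
    sol = solve_den(motifs["chain3"], u_step, chain3_pulse_truth.measurements,
                    cfg, chain3_grid, **QUICK)
    return cfg, sol


@pytest.fixture(scope="session")
def noisy_chain3_data(motifs, u_step):
    """Noisy measurements (5% of range, with sds) from the chain truth."""
    spec = HiddenInputSpec(target_nodes=(1,), waveform="pulse", amplitude=1.0,
                           onset=2.0, offset=9.0)
    truth = generate_truth(motifs["chain3"], u_step, spec,
                           np.linspace(0, 12, 25), noise_sd=None, seed=5)
    return truth
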