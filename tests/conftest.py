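import numpy as np
import pytest

from emgdi.bias_correction import run_bias_simulations
from emgdi.preprocess import bandpass
from emgdi.synth import EcgSpec, SimulationSpec, simulate_emgdi

#: 9-level I2BSNR grid spanning RMS ratios 1.2 .. 10 (1.58 .. 20 dB)
GRID9 = np.linspace(20 * np.log10(1.2), 20.0, 9)


@pytest.fixture(scope="session")
def rms_bias_sweep():
    """Reduced timing-bias characterization sweep for the RMS envelopes.

    9 I2BSNR levels x 200 simulated cycles per level, one shared record per
    level across the three envelope stages; fixed seed.
    """
    return run_bias_simulations(GRID9, 200, seed=12345,
                                methods=["rms_e1", "rms_e2", "rms_e3"])


@pytest.fixture(scope="session")
def clean_record_50():
    """Band-passed synthetic record: 50 cycles at RMS ratio 10, no ECG."""
    rec, truth = simulate_emgdi(SimulationSpec(n_cycles=50, rms_ratio=10.0,
                                               seed=3))
    return bandpass(rec), truth


@pytest.fixture(scope="session")
def contaminated_record():
    """Band-passed synthetic record with an injected ECG (ratio 2, 60 bpm)."""
    spec = SimulationSpec(n_cycles=30, rms_ratio=2.0, seed=5,
                          ecg=EcgSpec(heart_rate=60, qrs_amplitude=8))
    rec, truth = simulate_emgdi(spec)
    return bandpass(rec), truth
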