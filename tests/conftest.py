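import numpy as np
import pytest

import ambubrs as ab


@pytest.fixture(scope="session")
def noiseless_cfg():
    """Generator settings with every noise source off: extraction should
    invert the renderer to within discretisation error."""
    return ab.SimConfig(
        duration_s=60.0, seed=3,
        sbp_noise_sd=0.0, rr_noise_sd_ms=0.0, pat_noise_sd_ms=0.0, rdr_noise_sd=0.0,
    )


@pytest.fixture(scope="session")
def noiseless_truth(noiseless_cfg):
    return ab.simulate_beats(noiseless_cfg)


@pytest.fixture(scope="session")
def noiseless_record(noiseless_truth):
    return ab.render_signals(noiseless_truth)


@pytest.fixture(scope="session")
def noiseless_beat_table(noiseless_record):
    return ab.extract_beat_table(noiseless_record, pulse_roles=("PPG", "ABP"))


def make_pulse(fs=240.0, rise_s=0.1, decay_s=0.3, height=1.0, pad_s=0.1, baseline=0.0):
    """Piecewise-linear test pulse: linear rise then linear decay on a flat
    baseline. Breakpoints fall exactly on samples when rise/decay are
    multiples of 1/fs."""
    n_pad = int(pad_s * fs)
    n_r = int(round(rise_s * fs))
    n_d = int(round(decay_s * fs))
    up = np.linspace(0.0, height, n_r + 1)
    down = np.linspace(height, 0.0, n_d + 1)[1:]
    return baseline + np.concatenate([np.zeros(n_pad), up, down, np.zeros(n_pad)])
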