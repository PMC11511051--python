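import numpy as np
import pytest

from bioqc import (NNGenSpec, NoiseSpec, Signal, add_noise,
                   generate_nn_series, synthesize_ecg)
from bioqc import preprocess


@pytest.fixture(scope="session")
def fs():
    return 1000.0


@pytest.fixture(scope="session")
def clean_ecg_60bpm():
    """120 s clean synthetic ECG at 60 bpm with its ground-truth R times."""
    nn = generate_nn_series(NNGenSpec(mean_nn=1000.0, n_beats=125, seed=42))
    sig, r_times = synthesize_ecg(nn)
    return sig, r_times


@pytest.fixture(scope="session")
def filtered_ecg_60bpm(clean_ecg_60bpm):
    sig, r_times = clean_ecg_60bpm
    filt = preprocess.bandpass(preprocess.notch(sig), 0.3, 100.0)
    return filt, r_times


@pytest.fixture(scope="session")
def noisy_ecg_20db(clean_ecg_60bpm):
    """The 60 bpm record with noise injected at a 20 dB SNR target."""
    sig, r_times = clean_ecg_60bpm
    noisy, achieved, trace = add_noise(sig, NoiseSpec(target_snr_db=20.0,
                                                      seed=7))
    return noisy, r_times, achieved, trace


def match_peaks(detected_times, truth_times, tol_s=0.1):
    """One-to-one greedy matching of detected peaks to ground truth."""
    truth = np.asarray(truth_times, dtype=float)
    used = np.zeros(truth.size, dtype=bool)
    errors = []
    false_pos = 0
    for t in np.asarray(detected_times, dtype=float):
        d = np.abs(truth - t)
        i = int(np.argmin(d))
        if d[i] <= tol_s and not used[i]:
            used[i] = True
            errors.append(d[i])
        else:
            false_pos += 1
    sensitivity = used.mean() if truth.size else 0.0
    precision = ((len(errors)) / (len(errors) + false_pos)
                 if (len(errors) + false_pos) else 0.0)
    mean_err = float(np.mean(errors)) if errors else np.inf
    return sensitivity, precision, mean_err
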