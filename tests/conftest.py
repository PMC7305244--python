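import numpy as np
import pytest

import mousehrv as mh


def match_stats(truth_times, detected_times, lo, hi, tol_ms=1.0):
    """Sensitivity / false-positive rate / timing error inside [lo, hi].

    The margin keeps the zero-phase filter and envelope warm-up transients
    at the recording edges out of the closed-loop accuracy figures.
    """
    tt = truth_times[(truth_times > lo) & (truth_times < hi)]
    vt = np.asarray(detected_times, float)
    if vt.size == 0:
        return 0.0, 0.0, np.inf
    d_truth = np.abs(tt[:, None] - vt[None, :]).min(axis=1) * 1000.0
    sens = float((d_truth < tol_ms).mean())
    vin = vt[(vt > lo) & (vt < hi)]
    d_det = np.abs(vin[:, None] - truth_times[None, :]).min(axis=1) * 1000.0
    fp = float((d_det > tol_ms).mean()) if vin.size else 0.0
    max_err = float(d_truth[d_truth < tol_ms].max()) if np.any(d_truth < tol_ms) else np.inf
    return sens, fp, max_err


@pytest.fixture(scope="session")
def clean_sim():
    """30 s of clean constant-rate (720 bpm) three-channel ECG with truth."""
    design = mh.RRIDesign(
        base_rri_ms=1000 * 60 / 720, fast_amp_ms=3.0, slow_amp_ms=0.0,
        noise_sd_ms=0.3, seed=1,
    )
    seq, truth_comp = mh.simulate_rri(design, 30.0)
    rec, truth_beats = mh.simulate_ecg(
        seq, mh.ECGDesign(fs=5000.0, noise_white=0.02, seed=2)
    )
    return {"seq": seq, "components": truth_comp, "rec": rec,
            "beats": truth_beats}


@pytest.fixture(scope="session")
def clean_detection(clean_sim):
    beats, rri = mh.run_detection(clean_sim["rec"].channels,
                                  clean_sim["rec"].fs)
    return beats, rri


@pytest.fixture(scope="session")
def clean_channel(clean_sim):
    """Preprocessed strongest channel of the clean recording + its envelopes."""
    return mh.preprocess_channel(clean_sim["rec"].channels[0],
                                 clean_sim["rec"].fs)
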