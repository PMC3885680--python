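import numpy as np
import pytest

from fingerdecode import kinematics, preprocess, spectral
from fingerdecode.synth import SynthConfig, generate_dataset

FAST_GRID = dict(c_exponents=tuple(range(-5, 16, 6)),
                 gamma_exponents=tuple(range(-15, 4, 6)))


def prepare_spectra(cfg: SynthConfig, f_max: float = 125.0,
                    use_detector: bool = True):
    """Full front end: generate -> detect -> filter -> CAR -> epochs -> PSD.

    Returns per-finger movement and rest SpectrumSets plus the ground truth.
    """
    rec, kin, table, truth = generate_dataset(cfg)
    if use_detector:
        events = kinematics.detect_all_fingers(kin, cfg.fs, table)
    else:
        events = truth.events
    rec = preprocess.highpass(rec)
    rec = preprocess.notch(rec)
    rec = preprocess.common_average_reference(rec)
    movement, rest = preprocess.extract_epochs(rec, events, table)
    mov_spec = {f: spectral.psd_hanning(movement.for_finger(f), f_max)
                for f in cfg.fingers}
    rest_spec = {f: spectral.psd_hanning(rest.for_finger(f), f_max)
                 for f in cfg.fingers}
    return mov_spec, rest_spec, truth, events


@pytest.fixture(scope="session")
def tiny_cfg():
    return SynthConfig(n_channels=8, trials_per_finger=6,
                       signal_channels=(2, 3, 4, 5), seed=7)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_cfg):
    return generate_dataset(tiny_cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
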