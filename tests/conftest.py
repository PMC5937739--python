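import numpy as np
import pytest

from hybridbci import (EffectConfig, ParadigmConfig, RawRecording,
                       epoch, generate_dataset, preprocess)
from hybridbci.dataio import Montage
from hybridbci.preproc import EpochSet


@pytest.fixture(scope="session")
def small_dataset():
    """One 20-trial synthetic session with default effects."""
    rec, truth = generate_dataset(ParadigmConfig(n_sessions=1, seed=7))
    return rec, truth


@pytest.fixture(scope="session")
def small_epochs(small_dataset):
    """Preprocessed and epoched version of the small session."""
    rec, truth = small_dataset
    pp = preprocess(rec)
    eeg = epoch(pp.eeg, pp.eeg_rate_hz, pp.events, (0.0, 10.0),
                modality="EEG", channel_names=pp.frontal_names)
    hbo = epoch(pp.hbo, pp.nirs_rate_hz, pp.events, (10.0, 15.0),
                modality="HbO")
    hbr = epoch(pp.hbr, pp.nirs_rate_hz, pp.events, (10.0, 15.0),
                modality="HbR")
    return eeg, hbo, hbr, truth


def make_tiny_recording(seed: int = 0, duration_s: float = 12.0,
                        n_events: int = 1) -> RawRecording:
    """Small random-but-valid recording for I/O tests (no structure)."""
    rng = np.random.default_rng(seed)
    n_eeg = int(1000 * duration_s)
    n_nirs = int(12.5 * duration_s)
    events = [(0.5 + i, "MA" if i % 2 == 0 else "BL")
              for i in range(n_events)]
    return RawRecording(
        eeg=rng.normal(size=(22, n_eeg)),
        eog=rng.normal(size=(4, n_eeg)),
        nirs_intensity=1.0 + 0.05 * rng.random((9, 2, n_nirs)),
        events=events,
        montage=Montage(),
    )


@pytest.fixture
def tiny_rec():
    return make_tiny_recording()


def make_class_epochs(n_trials: int = 60, seed: int = 0, *,
                      eeg_attenuation: float = 0.5,
                      nirs_shift: float = 1.0,
                      rate_eeg: float = 200.0, n_eeg_ch: int = 6,
                      eeg_samples: int = 2000,
                      trial_sigma: float = 0.2
                      ) -> tuple[EpochSet, EpochSet, EpochSet]:
    """Cheap structured epochs for decoder tests.

    EEG trials carry 10 Hz narrowband activity whose amplitude is reduced
    by ``eeg_attenuation`` for MA; NIRS trials carry a class mean shift of
    ``nirs_shift`` (in noise-σ units).  EEG and NIRS effects are drawn
    independently.
    """
    from scipy import signal as sig

    rng = np.random.default_rng(seed)
    labels = np.array(["MA", "BL"] * (n_trials // 2))
    labels = labels[rng.permutation(n_trials)]
    y = (labels == "MA").astype(float)

    sos = sig.butter(2, (9.0, 11.0), btype="bandpass", fs=rate_eeg,
                     output="sos")
    alpha = sig.sosfilt(sos, rng.standard_normal((n_trials, eeg_samples)),
                        axis=-1)
    gain = (1.0 - eeg_attenuation * y) \
        * np.exp(rng.normal(0, trial_sigma, n_trials))
    pattern = np.linspace(1.0, 0.3, n_eeg_ch)
    eeg = rng.standard_normal((n_trials, n_eeg_ch, eeg_samples)) * 0.5
    eeg += pattern[None, :, None] * (gain[:, None] * alpha)[:, None, :]
    eeg_ep = EpochSet(eeg, labels, (0.0, 10.0), rate_eeg, "EEG")

    def nirs_block(sign):
        amp = sign * nirs_shift * y \
            + rng.normal(0, 1.0, n_trials)          # independent of EEG
        data = rng.standard_normal((n_trials, 9, 63)) * 0.3
        data += amp[:, None, None]
        return EpochSet(data, labels, (10.0, 15.0), 12.5, "NIRS")

    return eeg_ep, nirs_block(+1.0), nirs_block(-1.0)


@pytest.fixture
def epoch_factory():
    return make_class_epochs
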