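"""Synthetic eyes-closed hybrid EEG+NIRS sessions with known ground truth.

A session follows the block paradigm: pre-rest (15 s), then 20 trials —
visual instruction (2 s), task (10 s, mental arithmetic MA or relaxed
baseline BL), rest of random length (15-17 s) — and a post-rest (15 s).
Event markers sit at task onset (the beep).

The EEG model is deliberately minimal: per-channel 1/f background, one
spatially-patterned α source that is strong while the eyes are closed and
attenuated during MA (task-related α desynchronisation), and low-frequency
ocular sources mixed into the scalp channels with frontally-dominant gains.
NIRS intensities come from a forward Beer-Lambert model driven by canonical
double-gamma hemodynamic responses whose amplitude depends on the task
class (MA evokes the larger response), plus drift and cardiac/respiratory/
Mayer-wave oscillations.

All onsets are snapped to the 0.08 s NIRS sample grid, which is also a
multiple of the 1000 Hz and 200 Hz EEG grids, so epoch lengths are uniform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

from .dataio import EEG_CHANNELS, EOG_CHANNELS, FRONTAL_EEG_CHANNELS, \
    Montage, RawRecording
from .preproc import MbllParams


@dataclass
class ParadigmConfig:
    """Trial timing and sampling of the acquisition paradigm."""

    pre_rest_s: float = 15.0
    instruction_s: float = 2.0
    task_s: float = 10.0
    rest_range_s: tuple[float, float] = (15.0, 17.0)
    post_rest_s: float = 15.0
    n_trials_per_session: int = 20
    n_sessions: int = 3
    eeg_rate_hz: float = 1000.0
    nirs_rate_hz: float = 12.5
    seed: int = 0

    def validate(self) -> None:
        for name in ("pre_rest_s", "instruction_s", "task_s", "post_rest_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.rest_range_s[0] > self.rest_range_s[1] or self.rest_range_s[0] <= 0:
            raise ValueError("rest_range_s must be a positive interval")
        if self.n_trials_per_session < 2:
            raise ValueError("need at least 2 trials per session")
        if self.n_sessions < 1:
            raise ValueError("need at least one session")


@dataclass
class EffectConfig:
    """Effect sizes and nuisance amplitudes of the generative model.

    Concentrations are in mM (0.6 µM = 6e-4); EEG amplitudes in µV.
    ``alpha_attenuation_ma`` is the fractional α-amplitude reduction during
    the MA task; hemodynamic amplitudes are peak-response magnitudes per
    chromophore with the canonical signs applied internally (HbO up, HbR
    down on activation).
    """

    alpha_center_hz: float = 10.0
    alpha_attenuation_ma: float = 0.45
    alpha_amp_uv: float = 20.0
    alpha_eyes_open_gain: float = 0.35
    alpha_trial_sigma: float = 0.4    # lognormal σ of per-trial α amplitude
    hrf_trial_sigma: float = 0.4      # lognormal σ of per-trial HRF amplitude
    hrf_amp_ma: tuple[float, float] = (6e-4, 2e-4)   # (HbO, HbR) magnitudes
    hrf_amp_bl: tuple[float, float] = (3e-4, 1e-4)
    hrf_peak_s: float = 6.0
    hrf_undershoot_s: float = 16.0
    hrf_ratio: float = 1.0 / 6.0
    noise_1f_scale: float = 10.0
    eog_amp_uv: float = 120.0
    eog_mix_gain: np.ndarray | None = None           # (n_eeg, 4) or None
    physio_freqs_hz: tuple[float, float, float] = (1.0, 0.3, 0.1)
    physio_amp: float = 8e-5
    drift_scale: float = 2e-4
    conc_noise: float = 4e-5

    def validate(self) -> None:
        if not 0 <= self.alpha_attenuation_ma <= 1:
            raise ValueError("alpha_attenuation_ma must lie in [0, 1]")
        for amps in (self.hrf_amp_ma, self.hrf_amp_bl):
            if min(amps) < 0:
                raise ValueError("hemodynamic amplitudes must be >= 0")
        if min(self.noise_1f_scale, self.physio_amp, self.drift_scale,
               self.conc_noise, self.alpha_amp_uv, self.eog_amp_uv) < 0:
            raise ValueError("amplitudes must be >= 0")


@dataclass
class GroundTruth:
    """What the generator actually injected, for parameter-recovery tests."""

    labels: np.ndarray                    # "MA"/"BL" per trial
    trial_onsets_s: np.ndarray
    session_index: np.ndarray
    true_hbo: np.ndarray                  # 9 x nirs samples, mM (incl. noise)
    true_hbr: np.ndarray
    eog_sources: np.ndarray               # 4 x eeg samples, µV
    mixing_matrix: np.ndarray             # n_eeg x 4 EOG gains
    alpha_envelope: np.ndarray = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def canonical_hrf(t: np.ndarray, peak_s: float = 6.0,
                  undershoot_s: float = 16.0, ratio: float = 1.0 / 6.0
                  ) -> np.ndarray:
    """Double-gamma hemodynamic impulse response, unit peak.

    Gamma densities with unit rate and shapes ``peak_s + 1`` and
    ``undershoot_s + 1`` place the modes at the requested times; the
    undershoot is subtracted with weight ``ratio``.
    """
    t = np.asarray(t, dtype=float)
    if t.ndim != 1 or (t.size > 1 and np.any(np.diff(t) <= 0)):
        raise ValueError("time grid must be 1-D strictly increasing")
    if np.any(t < 0):
        raise ValueError("time grid must be non-negative")
    if not peak_s < undershoot_s:
        raise ValueError("peak must precede undershoot")
    h = stats.gamma.pdf(t, peak_s + 1.0) \
        - ratio * stats.gamma.pdf(t, undershoot_s + 1.0)
    peak = h.max()
    return h / peak if peak > 0 else h


def forward_mbll(delta_hbo: np.ndarray, delta_hbr: np.ndarray,
                 params: MbllParams | None = None,
                 baseline_intensity: float | np.ndarray = 1.0) -> np.ndarray:
    """Forward Beer-Lambert model: concentrations -> raw intensities.

    Exact algebraic inverse of :func:`hybridbci.preproc.mbll` up to the
    baseline-intensity convention: ΔOD = ε·d·DPF·Δc, I = I0·10^(−ΔOD).
    Output shape channels x 2 wavelengths x samples, strictly positive.
    """
    params = params or MbllParams()
    params.validate()
    hbo = np.atleast_2d(np.asarray(delta_hbo, dtype=float))
    hbr = np.atleast_2d(np.asarray(delta_hbr, dtype=float))
    if hbo.shape != hbr.shape:
        raise ValueError("ΔHbO and ΔHbR must have identical shapes")
    A = params.pathlength_matrix
    conc = np.stack([hbo, hbr], axis=1)            # c x 2 x s
    dod = np.einsum("wk,cks->cws", A, conc)
    i0 = np.broadcast_to(np.asarray(baseline_intensity, dtype=float)
                         .reshape(-1, 1, 1) if np.ndim(baseline_intensity)
                         else np.full((1, 1, 1), baseline_intensity),
                         (hbo.shape[0], 2, 1))
    if np.any(np.asarray(baseline_intensity) <= 0):
        raise ValueError("baseline intensities must be positive")
    return i0 * 10.0 ** (-dod)


def _one_over_f_noise(rng: np.random.Generator, n_channels: int, n: int,
                      rms: float, floor_hz: float = 0.5,
                      rate_hz: float = 1000.0) -> np.ndarray:
    """Gaussian noise with ~1/f power spectrum, RMS-normalised per channel."""
    white = rng.standard_normal((n_channels, n))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n, d=1.0 / rate_hz)
    spec *= 1.0 / np.sqrt(np.maximum(f, floor_hz))
    x = np.fft.irfft(spec, n=n, axis=1)
    x *= rms / np.maximum(x.std(axis=1, keepdims=True), 1e-30)
    return x


def _eog_sources(rng: np.random.Generator, n: int, rate_hz: float,
                 amp: float) -> np.ndarray:
    """4 ocular channels: slow (<4 Hz) drifting gaze plus blink pulses."""
    slow = rng.standard_normal((4, n))
    sos = signal.butter(2, 3.0, btype="lowpass", fs=rate_hz, output="sos")
    slow = signal.sosfiltfilt(sos, slow, axis=1)
    slow *= 0.3 * amp / np.maximum(slow.std(axis=1, keepdims=True), 1e-30)

    blink = np.zeros(n)
    width = int(0.3 * rate_hz)
    pulse = np.hanning(width)
    k = 0
    while True:
        k += int(rng.exponential(6.0) * rate_hz) + width
        if k + width >= n:
            break
        blink[k:k + width] += pulse * rng.uniform(0.7, 1.3)
    out = slow
    out[0] += amp * blink          # vertical channels carry the blinks
    out[1] += 0.8 * amp * blink
    return out


def _default_eog_gains(channels: tuple[str, ...]) -> np.ndarray:
    """Frontally-dominant propagation of ocular potentials, decaying back."""
    tiers = {name: 0.18 for name in FRONTAL_EEG_CHANNELS}
    tiers.update({"Cz": 0.06, "C3": 0.06, "C4": 0.06, "T7": 0.05, "T8": 0.05,
                  "Pz": 0.03, "P3": 0.03, "P4": 0.03, "P7": 0.03, "P8": 0.03,
                  "OI1": 0.015, "OI2": 0.015})
    base = np.array([tiers.get(c, 0.05) for c in channels])
    # vertical EOG couples more strongly than horizontal
    return np.outer(base, [1.0, 0.8, 0.4, 0.4])


def _alpha_pattern(channels: tuple[str, ...]) -> np.ndarray:
    """Posterior-dominant α topography (still clearly present frontally)."""
    tiers = {name: 0.55 for name in FRONTAL_EEG_CHANNELS}
    tiers.update({"Cz": 0.7, "C3": 0.7, "C4": 0.7, "T7": 0.65, "T8": 0.65,
                  "Pz": 0.9, "P3": 0.9, "P4": 0.9, "P7": 0.85, "P8": 0.85,
                  "OI1": 1.0, "OI2": 1.0})
    return np.array([tiers.get(c, 0.6) for c in channels])


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

def generate_dataset(paradigm: ParadigmConfig | None = None,
                     effects: EffectConfig | None = None,
                     mbll_params: MbllParams | None = None
                     ) -> tuple[RawRecording, GroundTruth]:
    """Simulate a full multi-session hybrid recording with ground truth."""
    paradigm = paradigm or ParadigmConfig()
    effects = effects or EffectConfig()
    paradigm.validate()
    effects.validate()
    mbll_params = mbll_params or MbllParams()
    rng = np.random.default_rng(paradigm.seed)

    dt = 1.0 / paradigm.nirs_rate_hz                 # 0.08 s master grid
    n_per = paradigm.n_trials_per_session

    def grid(x):            # duration -> integer number of NIRS samples
        return int(np.ceil(x / dt - 1e-9))

    onsets, labels, sessions = [], [], []
    cursor = 0                                       # in NIRS samples
    for s in range(paradigm.n_sessions):
        half = n_per // 2
        lab = np.array(["MA"] * half + ["BL"] * (n_per - half))
        lab = lab[rng.permutation(n_per)]
        cursor += grid(paradigm.pre_rest_s)
        for i in range(n_per):
            cursor += grid(paradigm.instruction_s)
            onsets.append(cursor)
            labels.append(lab[i])
            sessions.append(s)
            rest = rng.uniform(*paradigm.rest_range_s)
            cursor += grid(paradigm.task_s) + grid(rest)
        cursor += grid(paradigm.post_rest_s)

    n_nirs = cursor
    onsets = np.asarray(onsets)
    labels = np.array(labels)
    sessions = np.asarray(sessions)
    onset_s = onsets * dt

    eeg_per_nirs = int(round(paradigm.eeg_rate_hz * dt))
    n_eeg = n_nirs * eeg_per_nirs
    t_eeg = np.arange(n_eeg) / paradigm.eeg_rate_hz

    # --- EEG -------------------------------------------------------------
    n_task = grid(paradigm.task_s)
    n_instr = grid(paradigm.instruction_s)

    # α gating on the master grid: eyes closed (instruction through task
    # end) -> full amplitude, attenuated during MA tasks; eyes open -> weak.
    gate = np.full(n_nirs, effects.alpha_eyes_open_gain)
    # per-trial lognormal amplitude: the state variability that makes
    # single-trial decoding imperfect, shared by instruction and task span
    trial_amp = np.exp(rng.normal(0.0, effects.alpha_trial_sigma,
                                  size=len(onsets)))
    for k, lab, g in zip(onsets, labels, trial_amp):
        gate[k - n_instr:k] = g
        gate[k:k + n_task] = g * (1.0 - effects.alpha_attenuation_ma
                                  if lab == "MA" else 1.0)
    gate_eeg = np.repeat(gate, eeg_per_nirs)
    # smooth the gate edges (~200 ms) so attenuation is not a step artifact
    sos = signal.butter(2, 2.0, btype="lowpass",
                        fs=paradigm.eeg_rate_hz, output="sos")
    gate_eeg = signal.sosfiltfilt(sos, gate_eeg)

    half_bw = 1.0
    sos_a = signal.butter(2, (effects.alpha_center_hz - half_bw,
                              effects.alpha_center_hz + half_bw),
                          btype="bandpass", fs=paradigm.eeg_rate_hz,
                          output="sos")
    alpha_src = signal.sosfilt(sos_a, rng.standard_normal(n_eeg))
    alpha_src *= effects.alpha_amp_uv / max(alpha_src.std(), 1e-30)
    alpha_src = alpha_src * gate_eeg

    n_scalp = len(EEG_CHANNELS)
    eeg = _one_over_f_noise(rng, n_scalp, n_eeg, effects.noise_1f_scale,
                            rate_hz=paradigm.eeg_rate_hz)
    eeg += np.outer(_alpha_pattern(EEG_CHANNELS), alpha_src)

    eog_src = _eog_sources(rng, n_eeg, paradigm.eeg_rate_hz,
                           effects.eog_amp_uv)
    G = (effects.eog_mix_gain if effects.eog_mix_gain is not None
         else _default_eog_gains(EEG_CHANNELS))
    eeg += G @ eog_src
    eog_rec = eog_src + rng.standard_normal(eog_src.shape) * 2.0

    # --- NIRS ------------------------------------------------------------
    t_hrf = np.arange(0, max(32.0, 2 * effects.hrf_undershoot_s), dt)
    hrf = canonical_hrf(t_hrf, peak_s=effects.hrf_peak_s,
                        undershoot_s=effects.hrf_undershoot_s,
                        ratio=effects.hrf_ratio)
    neural_ma = np.zeros(n_nirs)
    neural_bl = np.zeros(n_nirs)
    hrf_trial_amp = np.exp(rng.normal(0.0, effects.hrf_trial_sigma,
                                      size=len(onsets)))
    for k, lab, g in zip(onsets, labels, hrf_trial_amp):
        target = neural_ma if lab == "MA" else neural_bl
        target[k:k + n_task] += g
    resp_ma = signal.fftconvolve(neural_ma, hrf)[:n_nirs]
    resp_bl = signal.fftconvolve(neural_bl, hrf)[:n_nirs]
    # normalise so a unit-gain 10 s task reaches peak 1
    peak1 = signal.fftconvolve(np.ones(n_task), hrf).max()
    resp_ma /= peak1
    resp_bl /= peak1

    n_ch = 9
    ch_gain = rng.uniform(0.8, 1.2, size=n_ch)
    hbo = np.outer(ch_gain, effects.hrf_amp_ma[0] * resp_ma
                   + effects.hrf_amp_bl[0] * resp_bl)
    hbr = np.outer(ch_gain, -(effects.hrf_amp_ma[1] * resp_ma
                              + effects.hrf_amp_bl[1] * resp_bl))

    t_nirs = np.arange(n_nirs) * dt
    for c in range(n_ch):
        physio = np.zeros(n_nirs)
        for f_hz in effects.physio_freqs_hz:
            physio += np.sin(2 * np.pi * f_hz * t_nirs
                             + rng.uniform(0, 2 * np.pi))
        physio *= effects.physio_amp
        drift = np.cumsum(rng.standard_normal(n_nirs))
        drift *= effects.drift_scale / max(drift.std(), 1e-30)
        noise_o = rng.standard_normal(n_nirs) * effects.conc_noise
        noise_r = rng.standard_normal(n_nirs) * effects.conc_noise
        drift2 = np.cumsum(rng.standard_normal(n_nirs))
        drift2 *= 0.5 * effects.drift_scale / max(drift2.std(), 1e-30)
        hbo[c] += physio + drift + noise_o
        hbr[c] += -0.3 * physio + drift2 + noise_r

    baseline = rng.uniform(0.8, 1.2, size=n_ch)
    intensity = forward_mbll(hbo, hbr, mbll_params,
                             baseline_intensity=baseline)

    events = [(float(o), str(l)) for o, l in zip(onset_s, labels)]
    rec = RawRecording(
        eeg=eeg, eog=eog_rec, nirs_intensity=intensity, events=events,
        eeg_rate_hz=paradigm.eeg_rate_hz, nirs_rate_hz=paradigm.nirs_rate_hz,
        montage=Montage(),
        meta={"generator": "hybridbci.synthgen", "seed": paradigm.seed},
    )
    truth = GroundTruth(
        labels=labels, trial_onsets_s=onset_s, session_index=sessions,
        true_hbo=hbo, true_hbr=hbr, eog_sources=eog_src, mixing_matrix=G,
        alpha_envelope=gate,
    )
    return rec, truth
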