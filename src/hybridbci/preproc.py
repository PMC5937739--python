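"""Signal conditioning for both modalities.

EEG: decimate 1000 -> 200 Hz (anti-aliased), 0.5-50 Hz Butterworth band-pass,
then blind-source-separation EOG rejection.  NIRS: raw dual-wavelength
intensities -> ΔHbO/ΔHbR via the modified Beer-Lambert law, then a
0.01-0.2 Hz zero-phase band-pass.  Epoching cuts half-open [start, end)
windows relative to task onset.

Units: EEG µV, concentrations mM (1 µM = 1e-3), distances mm.  Extinction
coefficients default to the Gratzer/Cope compilation at 760/850 nm expressed
in 1/(mM·mm); DPF defaults are 5.98 (760 nm) and 5.07 (850 nm).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, signal

from .dataio import RawRecording

# Gratzer/Cope molar extinction, rows = (760, 850) nm, cols = (HbO, HbR),
# units 1/(mM·mm) (i.e. 1486.59 1/(M·cm) -> 0.148659).
DEFAULT_EXTINCTION = np.array([[0.14866, 0.38437],
                               [0.25264, 0.17986]])
DEFAULT_DPF = (5.98, 5.07)


@dataclass
class FilterSpec:
    """Butterworth band-pass description."""

    passband_hz: tuple[float, float]
    order: int = 3
    zero_phase: bool = True

    def validate(self, rate_hz: float) -> None:
        lo, hi = self.passband_hz
        if not 0 < lo < hi < rate_hz / 2:
            raise ValueError(
                f"passband {self.passband_hz} outside (0, Nyquist="
                f"{rate_hz / 2}) Hz")


EEG_BANDPASS = FilterSpec(passband_hz=(0.5, 50.0), order=3, zero_phase=True)
NIRS_BANDPASS = FilterSpec(passband_hz=(0.01, 0.2), order=6, zero_phase=True)


@dataclass
class MbllParams:
    """Modified Beer-Lambert parameters for the dual-wavelength conversion."""

    extinction: np.ndarray = field(
        default_factory=lambda: DEFAULT_EXTINCTION.copy())
    dpf: tuple[float, float] = DEFAULT_DPF
    distance_mm: float = 30.0
    baseline_window_s: tuple[float, float] | None = None  # None = whole run

    def validate(self) -> None:
        eps = np.asarray(self.extinction, dtype=float)
        if eps.shape != (2, 2) or abs(np.linalg.det(eps)) < 1e-12:
            raise ValueError("extinction matrix must be 2x2 and invertible")
        if min(self.dpf) <= 0 or self.distance_mm <= 0:
            raise ValueError("dpf and distance must be positive")

    @property
    def pathlength_matrix(self) -> np.ndarray:
        """A with ΔOD = A @ [ΔHbO, ΔHbR]: rows scaled by d·DPF(λ)."""
        eps = np.asarray(self.extinction, dtype=float)
        return eps * (np.asarray(self.dpf)[:, None] * self.distance_mm)


@dataclass
class EpochSet:
    """Trials x channels x samples cut around task onsets."""

    data: np.ndarray
    labels: np.ndarray            # array of "MA"/"BL", one per trial
    window_s: tuple[float, float]
    rate_hz: float
    modality: str = ""
    channel_names: tuple[str, ...] = ()

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be trials x channels x samples")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels length must equal number of trials")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def y(self) -> np.ndarray:
        """Binary coding, MA = 1, BL = 0."""
        return (self.labels == "MA").astype(int)


# ---------------------------------------------------------------------------
# filtering / resampling
# ---------------------------------------------------------------------------

def downsample_eeg(x: np.ndarray, factor: int = 5) -> np.ndarray:
    """Anti-aliased decimation along the last axis (1000 -> 200 Hz default).

    An 8th-order Butterworth low-pass at 0.8·(new Nyquist) — 80 Hz for
    factor 5 — is applied forward-backward (no phase shift, unity DC gain)
    before keeping every ``factor``-th sample.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("decimation factor must be a positive integer")
    x = np.asarray(x, dtype=float)
    if factor == 1:
        return x.copy()
    sos = signal.butter(8, 0.8 / factor, btype="lowpass", output="sos")
    return signal.sosfiltfilt(sos, x, axis=-1)[..., ::int(factor)]


def bandpass(x: np.ndarray, spec: FilterSpec, rate_hz: float) -> np.ndarray:
    """Butterworth band-pass along the last axis."""
    spec.validate(rate_hz)
    sos = signal.butter(spec.order, spec.passband_hz, btype="bandpass",
                        fs=rate_hz, output="sos")
    if spec.zero_phase:
        return signal.sosfiltfilt(sos, x, axis=-1)
    return signal.sosfilt(sos, x, axis=-1)


# ---------------------------------------------------------------------------
# EOG rejection
# ---------------------------------------------------------------------------

def _joint_diagonalize(mats: np.ndarray, *, tol: float = 1e-8,
                       max_sweeps: int = 100) -> np.ndarray:
    """Orthogonal approximate joint diagonalisation (Jacobi angles).

    ``mats`` is (k, n, n) symmetric.  Returns the rotation V maximising the
    sum of squared diagonals of Vᵀ M V.  Deterministic.
    """
    k, n, _ = mats.shape
    M = mats.copy()
    V = np.eye(n)
    for _ in range(max_sweeps):
        changed = False
        for p in range(n - 1):
            for q in range(p + 1, n):
                # Cardoso-Souloumiac closed-form Givens angle
                h = np.array([M[:, p, p] - M[:, q, q],
                              M[:, p, q] + M[:, q, p]])
                G = h @ h.T
                ton, toff = G[0, 0] - G[1, 1], G[0, 1] + G[1, 0]
                theta = 0.5 * np.arctan2(toff, ton + np.hypot(ton, toff))
                c, s = np.cos(theta), np.sin(theta)
                if abs(s) > tol:
                    changed = True
                    rot = np.array([[c, -s], [s, c]])
                    idx = [p, q]
                    M[:, idx, :] = np.einsum("ij,kjl->kil", rot.T,
                                             M[:, idx, :])
                    M[:, :, idx] = np.einsum("kij,jl->kil",
                                             M[:, :, idx], rot)
                    V[:, idx] = V[:, idx] @ rot
        if not changed:
            break
    return V


def sobi(x: np.ndarray, lags: tuple[int, ...] = (1, 2, 3, 5, 8, 12, 20, 30,
                                                 50, 80, 120),
         rank_tol: float = 1e-10) -> tuple[np.ndarray, np.ndarray]:
    """Second-order blind identification via joint diagonalisation.

    Returns (sources, mixing) with x ≈ mixing @ sources after centering.
    Rank-deficient inputs are handled by truncating the whitening basis.
    """
    x = x - x.mean(axis=1, keepdims=True)
    n, T = x.shape
    if T < n:
        raise ValueError("need at least as many samples as channels")
    C0 = x @ x.T / T
    evals, evecs = linalg.eigh(C0)
    keep = evals > rank_tol * evals.max()
    W = evecs[:, keep] / np.sqrt(evals[keep])     # whitening (n x r)
    z = W.T @ x

    mats = []
    for lag in lags:
        if lag >= T:
            continue
        c = z[:, lag:] @ z[:, :-lag].T / (T - lag)
        mats.append(0.5 * (c + c.T))
    V = _joint_diagonalize(np.array(mats))
    sources = V.T @ z
    mixing = np.linalg.pinv(V.T @ W.T)            # n x r
    return sources, mixing


def remove_eog(eeg: np.ndarray, eog: np.ndarray, *, threshold: float = 0.7,
               method: str = "sobi") -> np.ndarray:
    """Subtract ocular activity from EEG given time-aligned EOG channels.

    ``method="sobi"``: joint BSS on the stacked EEG+EOG block; sources whose
    absolute correlation with any EOG channel exceeds ``threshold`` are
    zeroed before back-projection.  ``method="regression"``: least-squares
    projection of the EOG channels out of each EEG channel.
    """
    eeg = np.asarray(eeg, dtype=float)
    eog = np.asarray(eog, dtype=float)
    if eeg.shape[1] != eog.shape[1]:
        raise ValueError("EEG and EOG must share the sample axis "
                         "(rate mismatch?)")
    if eeg.shape[1] < eeg.shape[0] + eog.shape[0]:
        raise ValueError("fewer samples than channels")

    if method == "regression":
        sol, *_ = np.linalg.lstsq(eog.T, eeg.T, rcond=None)
        return eeg - (sol.T @ eog)
    if method != "sobi":
        raise ValueError(f"unknown EOG method {method!r}")

    stacked = np.vstack([eeg, eog])
    mean = stacked.mean(axis=1, keepdims=True)
    sources, mixing = sobi(stacked)

    eog_c = eog - eog.mean(axis=1, keepdims=True)
    eog_norm = np.linalg.norm(eog_c, axis=1)
    src_norm = np.linalg.norm(sources, axis=1)
    denom = np.outer(src_norm, eog_norm)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.abs(sources @ eog_c.T) / np.where(denom > 0, denom, np.inf)
    artifact = np.nanmax(corr, axis=1) > threshold

    clean_sources = sources.copy()
    clean_sources[artifact] = 0.0
    cleaned = mixing @ clean_sources + mean
    return cleaned[: eeg.shape[0]]


# ---------------------------------------------------------------------------
# modified Beer-Lambert law
# ---------------------------------------------------------------------------

def mbll(intensity: np.ndarray, params: MbllParams | None = None,
         rate_hz: float = 12.5) -> tuple[np.ndarray, np.ndarray]:
    """Convert raw intensities (channels x 2 wavelengths x samples) to
    concentration changes (ΔHbO, ΔHbR), each channels x samples, in mM.

    ΔOD(λ) = −log10(I/I0) with I0 the mean over the baseline window
    (whole recording if unset); [ΔHbO, ΔHbR]ᵀ = (ε·d·DPF)⁻¹ ΔOD.
    """
    params = params or MbllParams()
    params.validate()
    intensity = np.asarray(intensity, dtype=float)
    if intensity.ndim != 3 or intensity.shape[1] != 2:
        raise ValueError("intensity must be channels x 2 wavelengths x samples")
    if np.any(intensity <= 0):
        raise ValueError("intensities must be strictly positive")

    if params.baseline_window_s is None:
        i0 = intensity.mean(axis=2, keepdims=True)
    else:
        lo, hi = params.baseline_window_s
        a, b = int(round(lo * rate_hz)), int(round(hi * rate_hz))
        if not 0 <= a < b <= intensity.shape[2]:
            raise ValueError("baseline window outside recording")
        i0 = intensity[:, :, a:b].mean(axis=2, keepdims=True)

    dod = -np.log10(intensity / i0)              # channels x 2 x samples
    inv = np.linalg.inv(params.pathlength_matrix)
    # conc[c, w, s] = sum_k inv[w, k] dod[c, k, s]  (inv @ dod per channel)
    conc = np.einsum("wk,cks->cws", inv, dod)
    return conc[:, 0, :], conc[:, 1, :]


# ---------------------------------------------------------------------------
# epoching
# ---------------------------------------------------------------------------

def epoch(data: np.ndarray, rate_hz: float,
          events: list[tuple[float, str]],
          window_s: tuple[float, float], *, modality: str = "",
          channel_names: tuple[str, ...] = ()) -> EpochSet:
    """Cut trials x channels x samples on the half-open window [start, end)
    relative to each task onset; sample k lives at time k/rate.
    """
    start, end = window_s
    if end <= start:
        raise ValueError("window end must exceed start")
    events = sorted(events, key=lambda e: e[0])
    n_total = data.shape[1]
    eps = 1e-9
    trials, labels = [], []
    n_keep = None
    for onset, label in events:
        i0 = int(np.ceil(rate_hz * (onset + start) - eps))
        i1 = int(np.ceil(rate_hz * (onset + end) - eps))
        if i0 < 0 or i1 > n_total:
            raise ValueError(
                f"window [{start}, {end}) s at onset {onset} s exceeds the "
                "recording")
        if n_keep is None:
            n_keep = i1 - i0
        trials.append(data[:, i0:i0 + n_keep])
        labels.append(label)
    if not trials:
        shaped = np.empty((0, data.shape[0],
                           int(np.ceil(rate_hz * (end - start) - eps))))
        return EpochSet(shaped, np.array([], dtype="<U2"), (start, end),
                        rate_hz, modality, channel_names)
    return EpochSet(np.stack(trials), np.array(labels), (start, end),
                    rate_hz, modality, channel_names)


# ---------------------------------------------------------------------------
# recording-level convenience
# ---------------------------------------------------------------------------

@dataclass
class PreprocResult:
    """Cleaned continuous streams ready for feature extraction."""

    eeg: np.ndarray               # frontal channels x samples @ eeg_rate
    eeg_rate_hz: float
    hbo: np.ndarray               # 9 x samples (mM), filtered
    hbr: np.ndarray
    nirs_rate_hz: float
    events: list[tuple[float, str]]
    frontal_names: tuple[str, ...]
    provenance: str = ""


def preprocess(rec: RawRecording, *, downsample_factor: int = 5,
               eeg_filter: FilterSpec = EEG_BANDPASS,
               nirs_filter: FilterSpec = NIRS_BANDPASS,
               mbll_params: MbllParams | None = None,
               eog_method: str = "sobi",
               eog_threshold: float = 0.7) -> PreprocResult:
    """Run the full conditioning chain on a raw recording.

    Order: EEG downsample -> band-pass -> BSS EOG rejection (on the frontal
    channels used for decoding); NIRS MBLL -> band-pass.
    """
    rate = rec.eeg_rate_hz / downsample_factor
    eeg = downsample_eeg(rec.frontal_eeg, downsample_factor)
    eog = downsample_eeg(rec.eog, downsample_factor)
    eeg = bandpass(eeg, eeg_filter, rate)
    eog = bandpass(eog, eeg_filter, rate)
    eeg = remove_eog(eeg, eog, threshold=eog_threshold, method=eog_method)

    hbo, hbr = mbll(rec.nirs_intensity, mbll_params, rec.nirs_rate_hz)
    hbo = bandpass(hbo, nirs_filter, rec.nirs_rate_hz)
    hbr = bandpass(hbr, nirs_filter, rec.nirs_rate_hz)

    frontal = tuple(np.asarray(rec.montage.eeg_channels)
                    [rec.montage.frontal_mask])
    prov = hashlib.sha256(rec.eeg[:, :1000].tobytes()).hexdigest()[:12]
    return PreprocResult(eeg=eeg, eeg_rate_hz=rate, hbo=hbo, hbr=hbr,
                         nirs_rate_hz=rec.nirs_rate_hz, events=rec.events,
                         frontal_names=frontal, provenance=prov)
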