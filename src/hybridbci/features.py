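"""Feature extraction: discriminability maps, band selection, CSP, NIRS stats.

EEG features are log-variances of the spatially filtered signal in a
participant-specific passband chosen by a signed-r² heuristic; the six CSP
components kept are the three most MA-favouring and three most BL-favouring
by the ratio-of-medians score.  NIRS features are per-channel mean and
least-squares slope of ΔHbR/ΔHbO over the late (10-15 s) window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, signal

from .preproc import EpochSet, FilterSpec, bandpass

#: Canonical frequency bands of the discriminability map.
STANDARD_BANDS = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "low_beta": (13.0, 20.0),
    "high_beta": (20.0, 30.0),
    "gamma": (30.0, 50.0),
}

DEFAULT_SEARCH_RANGE = (4.0, 35.0)


@dataclass
class BandSpec:
    f_low: float
    f_high: float

    def __post_init__(self):
        if not 0 < self.f_low < self.f_high:
            raise ValueError(f"invalid band [{self.f_low}, {self.f_high}]")

    def as_tuple(self) -> tuple[float, float]:
        return (self.f_low, self.f_high)


@dataclass
class CSPModel:
    filters: np.ndarray            # channels x components (columns = w)
    eigenvalues: np.ndarray        # descending, in [0, 1]
    selected_idx: np.ndarray       # component indices kept for features
    scores: np.ndarray             # ratio-of-medians per component
    band: BandSpec | None = None
    train_hash: str = ""


@dataclass
class FeatureMatrix:
    values: np.ndarray             # trials x features
    labels: np.ndarray
    modality: str                  # EEG | HbR | HbO | META
    names: tuple[str, ...] = ()

    def __post_init__(self):
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")
        if self.values.shape[0] != len(self.labels):
            raise ValueError("feature rows must align with trials")

    def y(self) -> np.ndarray:
        return (np.asarray(self.labels) == "MA").astype(int)


# ---------------------------------------------------------------------------
# signed r²
# ---------------------------------------------------------------------------

def signed_r_squared(values: np.ndarray, labels: np.ndarray) -> float:
    """sign(r)·r² with r the point-biserial correlation (MA = 1, BL = 0).

    Positive means larger values in MA.
    """
    values = np.asarray(values, dtype=float)
    y = (np.asarray(labels) == "MA").astype(float)
    n1, n0 = y.sum(), (1 - y).sum()
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    if np.ptp(values) == 0:
        raise ValueError("zero-variance input")
    r = np.corrcoef(values, y)[0, 1]
    if not np.isfinite(r):
        return 0.0
    return float(np.sign(r) * r * r)


def _signed_r_squared_rows(values: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorised sgn r² for a trials x features block (no error checks)."""
    v = np.asarray(values, dtype=float)
    yc = y - y.mean()
    vc = v - v.mean(axis=0)
    num = yc @ vc
    denom = np.sqrt((yc @ yc) * np.sum(vc * vc, axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, num / denom, 0.0)
    return np.sign(r) * r * r


# ---------------------------------------------------------------------------
# participant-specific band selection
# ---------------------------------------------------------------------------

def trial_psd(epochs: EpochSet, resolution_hz: float = 0.5,
              seg_s: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Welch periodogram per trial/channel on a fixed frequency grid.

    Returns (freqs, psd) with psd shaped trials x channels x bins; 1 s
    Hann segments, 50 % overlap, zero-padded to the requested resolution.
    """
    rate = epochs.rate_hz
    nperseg = int(round(seg_s * rate))
    nfft = int(round(rate / resolution_hz))
    f, p = signal.welch(epochs.data, fs=rate, nperseg=nperseg,
                        noverlap=nperseg // 2, nfft=nfft, axis=-1)
    return f, p


def select_band(epochs: EpochSet, labels: np.ndarray | None = None, *,
                search_range_hz: tuple[float, float] = DEFAULT_SEARCH_RANGE,
                resolution_hz: float = 0.5,
                growth_fraction: float = 0.05,
                psd: tuple[np.ndarray, np.ndarray] | None = None,
                train_idx: np.ndarray | None = None) -> BandSpec:
    """Heuristic discriminative passband from per-bin band-power sgn r².

    The per-trial Welch power in each 0.5 Hz bin, averaged over channels,
    is scored by sgn r² against the class labels.  The band seeds at the
    extremal-score bin and grows outward while the better neighbouring bin
    still contributes at least ``growth_fraction`` of the running score sum
    with the same sign.  Zero-discriminability input falls back to the full
    search range.  ``psd``/``train_idx`` allow reuse of precomputed spectra
    inside cross-validation.
    """
    if psd is None:
        f, p = trial_psd(epochs, resolution_hz)
    else:
        f, p = psd
    labels = epochs.labels if labels is None else np.asarray(labels)
    if train_idx is not None:
        p = p[train_idx]
        labels = labels[train_idx]
    y = (labels == "MA").astype(float)
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValueError("need at least 2 trials per class")

    lo, hi = search_range_hz
    sel = (f >= lo - 1e-9) & (f <= hi + 1e-9)
    if not sel.any():
        raise ValueError("empty search range")
    freqs = f[sel]
    power = p[:, :, sel].mean(axis=1)              # trials x bins
    scores = _signed_r_squared_rows(np.log(np.maximum(power, 1e-300)), y)

    i_star = int(np.argmax(np.abs(scores)))
    if abs(scores[i_star]) < 1e-12:
        return BandSpec(lo, hi)
    sign = np.sign(scores[i_star])
    s = scores * sign                               # extremal bin positive
    left = right = i_star
    total = s[i_star]
    while True:
        cand = []
        if left > 0:
            cand.append((s[left - 1], "L"))
        if right < len(s) - 1:
            cand.append((s[right + 1], "R"))
        if not cand:
            break
        val, side = max(cand)
        if val < growth_fraction * total:
            break
        total += val
        if side == "L":
            left -= 1
        else:
            right += 1
    return BandSpec(float(freqs[left]), float(freqs[right]))


# ---------------------------------------------------------------------------
# CSP
# ---------------------------------------------------------------------------

def _class_covariances(epochs: np.ndarray, y: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Trace-normalised per-trial covariances averaged within class."""
    n_trials, n_ch, _ = epochs.shape
    covs = np.einsum("tcs,tds->tcd", epochs, epochs)
    tr = np.trace(covs, axis1=1, axis2=2)
    covs /= np.maximum(tr, 1e-300)[:, None, None]
    return covs[y == 1].mean(axis=0), covs[y == 0].mean(axis=0)


def csp_fit(epochs: EpochSet | np.ndarray, labels: np.ndarray | None = None,
            band: BandSpec | None = None, *, n_per_side: int = 3,
            reg: float = 1e-10) -> CSPModel:
    """Common spatial patterns via the generalised eigenproblem
    Σ₁w = λ(Σ₁+Σ₂)w on trace-normalised class covariances (class 1 = MA).

    Input epochs must already be band-pass filtered to ``band``.
    Eigenvalues are sorted descending; Wᵀ(Σ₁+Σ₂)W = I.  Component selection
    (``selected_idx``) ranks components by the ratio-of-medians score
    computed on the training trials and keeps ``n_per_side`` per extreme.
    """
    data = epochs.data if isinstance(epochs, EpochSet) else np.asarray(epochs)
    labels = (epochs.labels if labels is None and isinstance(epochs, EpochSet)
              else np.asarray(labels))
    y = (labels == "MA").astype(int)
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("need at least 2 trials per class")

    s1, s2 = _class_covariances(data, y)
    comp = s1 + s2
    comp = comp + reg * np.trace(comp) / comp.shape[0] * np.eye(comp.shape[0])
    lam, W = linalg.eigh(s1, comp)
    order = np.argsort(lam)[::-1]
    lam, W = np.clip(lam[order], 0.0, 1.0), W[:, order]

    variances = np.einsum("tcs,ck->tks", data, W)
    variances = variances.var(axis=2)
    scores = ratio_of_medians(variances, labels)
    selected = select_components(scores, lam, n_per_side=n_per_side)
    return CSPModel(filters=W, eigenvalues=lam, selected_idx=selected,
                    scores=scores, band=band)


def ratio_of_medians(variances: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """med(var | MA) / (med(var | MA) + med(var | BL)) per component."""
    variances = np.atleast_2d(np.asarray(variances, dtype=float))
    y = (np.asarray(labels) == "MA")
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    m1 = np.median(variances[y], axis=0)
    m2 = np.median(variances[~y], axis=0)
    denom = m1 + m2
    if np.any(denom == 0):
        raise ValueError("zero median variance in both classes")
    return m1 / denom


def select_components(scores: np.ndarray, eigenvalues: np.ndarray,
                      n_per_side: int = 3) -> np.ndarray:
    """Indices of the most discriminative components: ``n_per_side`` with
    the largest and smallest ratio-of-medians scores (ties broken by
    eigenvalue order, i.e. by position in the λ-sorted array)."""
    n = len(scores)
    k = min(n_per_side, n // 2)
    order = np.lexsort((np.arange(n), scores))     # stable in λ order
    return np.concatenate([order[:k], order[-k:][::-1]])


def csp_logvar(epochs: EpochSet | np.ndarray, model: CSPModel, *,
               labels: np.ndarray | None = None,
               normalize: bool = True) -> FeatureMatrix:
    """Log-variance of the selected CSP components per trial.

    With ``normalize`` the selected-component variances are divided by their
    per-trial sum before the log (standard CSP practice).  An all-zero
    projected trial is an error; isolated zero-variance components are
    floored and flagged with a warning.
    """
    data = epochs.data if isinstance(epochs, EpochSet) else np.asarray(epochs)
    if labels is None:
        labels = (epochs.labels if isinstance(epochs, EpochSet)
                  else np.array([""] * data.shape[0]))
    W = model.filters[:, model.selected_idx]
    proj = np.einsum("tcs,ck->tks", data, W)
    var = proj.var(axis=2)                         # trials x components
    if np.any(var.sum(axis=1) == 0):
        raise ValueError("constant-zero epoch: no variance to take log of")
    if normalize:
        var = var / var.sum(axis=1, keepdims=True)
    if np.any(var == 0):
        warnings.warn("zero-variance CSP component floored", stacklevel=2)
        var = np.maximum(var, 1e-300)
    names = tuple(f"csp{int(i)}_logvar" for i in model.selected_idx)
    return FeatureMatrix(np.log(var), np.asarray(labels), "EEG", names)


# ---------------------------------------------------------------------------
# NIRS features
# ---------------------------------------------------------------------------

def nirs_mean_slope(epochs: EpochSet, modality: str = "HbO") -> FeatureMatrix:
    """Per-channel window mean and least-squares slope (units/s):
    9 channels x {mean, slope} = 18 features for the standard montage."""
    data = epochs.data
    if data.shape[2] < 3:
        raise ValueError("window too short: need at least 3 samples")
    t = np.arange(data.shape[2]) / epochs.rate_hz
    mean = data.mean(axis=2)
    tc = t - t.mean()
    slope = (data - mean[:, :, None]) @ tc / (tc @ tc)
    values = np.concatenate([mean, slope], axis=1)
    ch = (epochs.channel_names
          or tuple(f"ch{i + 1}" for i in range(data.shape[1])))
    tag = modality.lower()
    names = tuple(f"{c}_{tag}_mean" for c in ch) \
        + tuple(f"{c}_{tag}_slope" for c in ch)
    return FeatureMatrix(values, epochs.labels, modality, names)


# ---------------------------------------------------------------------------
# discriminability maps
# ---------------------------------------------------------------------------

def sgn_r2_band_map(epochs: EpochSet, labels: np.ndarray | None = None,
                    bands: dict[str, tuple[float, float]] | None = None
                    ) -> pd.DataFrame:
    """Channel x band table of band-power sgn r² (positive = larger in MA)."""
    bands = bands or STANDARD_BANDS
    labels = epochs.labels if labels is None else np.asarray(labels)
    y = (labels == "MA").astype(float)
    nyq = epochs.rate_hz / 2
    for name, (lo, hi) in bands.items():
        if not 0 <= lo < hi <= nyq:
            raise ValueError(f"band {name} [{lo}, {hi}] outside (0, {nyq})")
    f, p = trial_psd(epochs)
    out = {}
    for name, (lo, hi) in bands.items():
        sel = (f >= lo) & (f < hi)
        bp = p[:, :, sel].sum(axis=2)              # trials x channels
        out[name] = _signed_r_squared_rows(np.log(np.maximum(bp, 1e-300)), y)
    ch = (epochs.channel_names
          or tuple(f"ch{i + 1}" for i in range(epochs.data.shape[1])))
    return pd.DataFrame(out, index=list(ch))


def bandpass_epochs(epochs: EpochSet, band: BandSpec, order: int = 3
                    ) -> EpochSet:
    """Zero-phase Butterworth band-pass of every trial (helper for CSP)."""
    spec = FilterSpec(passband_hz=band.as_tuple(), order=order,
                      zero_phase=True)
    data = bandpass(epochs.data, spec, epochs.rate_hz)
    return EpochSet(data, epochs.labels, epochs.window_s, epochs.rate_hz,
                    epochs.modality, epochs.channel_names)
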