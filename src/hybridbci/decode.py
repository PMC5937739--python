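"""Classification: shrinkage LDA, meta-classifier fusion, nested CV.

The base classifier is a binary LDA whose pooled within-class covariance is
shrunk toward a scaled identity ν·I (ν = trace/d) with the analytic
Ledoit-Wolf intensity.  The hybrid decoder stacks the continuous scores of
the EEG, HbR and HbO base classifiers into a 2- or 3-dimensional meta
feature; meta-training scores are produced out-of-fold on an inner split so
the meta level never sees resubstitution outputs.

Leakage policy: the discriminative passband, the CSP filters, every sLDA and
the meta classifier are fitted on training-fold trials only; each fitted
object carries a hash of the trial indices it was fitted on.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .features import (BandSpec, FeatureMatrix, bandpass_epochs, csp_fit,
                       csp_logvar, select_band, trial_psd)
from .preproc import EpochSet

#: The fused combinations reported, plus the conventional aliases:
#: "NIRS" = HbR+HbO, "HYB" = EEG+HbR+HbO.
FUSIONS: dict[str, tuple[str, ...]] = {
    "HbR+HbO": ("HbR", "HbO"),
    "EEG+HbR": ("EEG", "HbR"),
    "EEG+HbO": ("EEG", "HbO"),
    "EEG+HbR+HbO": ("EEG", "HbR", "HbO"),
}
MODALITIES = ("EEG", "HbR", "HbO")
ALIASES = {"NIRS": "HbR+HbO", "HYB": "EEG+HbR+HbO"}


def _index_hash(idx: np.ndarray) -> str:
    return hashlib.sha256(np.sort(np.asarray(idx)).astype(np.int64)
                          .tobytes()).hexdigest()[:16]


@dataclass
class SLDAModel:
    """Affine binary discriminant: score = wᵀx + b, MA iff score > 0."""

    w: np.ndarray
    b: float
    gamma: float
    nu: float
    mean_ma: np.ndarray
    mean_bl: np.ndarray
    train_hash: str = ""


def ledoit_wolf_gamma(xc: np.ndarray) -> float:
    """Analytic Ledoit-Wolf shrinkage intensity toward ν·I.

    ``xc`` holds class-centered samples (rows).  Returns γ ∈ [0, 1]
    minimising the expected Frobenius loss of (1−γ)Σ̂ + γνI.
    """
    n, d = xc.shape
    s = xc.T @ xc / n
    nu = np.trace(s) / d
    delta2 = np.sum((s - nu * np.eye(d)) ** 2)
    if delta2 <= 0:
        return 0.0
    sq_norms = np.einsum("ij,ij->i", xc, xc)
    xsx = np.einsum("ij,jk,ik->i", xc, s, xc)
    beta2 = (np.sum(sq_norms ** 2) - 2 * xsx.sum()
             + n * np.sum(s * s)) / n ** 2
    return float(np.clip(beta2 / delta2, 0.0, 1.0))


def slda_fit(features: FeatureMatrix | np.ndarray,
             labels: np.ndarray | None = None,
             shrinkage: str | float = "ledoit-wolf-analytic") -> SLDAModel:
    """Fit the shrinkage-LDA: Σ̃ = (1−γ)Σ̂ + γνI, w = Σ̃⁻¹(m₁−m₂), with the
    bias placing the boundary at the class-mean midpoint (equal priors)."""
    if isinstance(features, FeatureMatrix):
        X, labels = features.values, features.labels
    else:
        X = np.asarray(features, dtype=float)
        labels = np.asarray(labels)
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    y = (labels == "MA").astype(int)
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("need at least 2 trials per class")

    m1, m0 = X[y == 1].mean(axis=0), X[y == 0].mean(axis=0)
    xc = X - np.where(y[:, None] == 1, m1, m0)
    n, d = xc.shape
    s = xc.T @ xc / n
    nu = float(np.trace(s) / d)

    if shrinkage == "ledoit-wolf-analytic":
        gamma = ledoit_wolf_gamma(xc)
    else:
        gamma = float(shrinkage)
        if not 0 <= gamma <= 1:
            raise ValueError("shrinkage intensity must lie in [0, 1]")
    if gamma == 0.0 and d > n:
        raise ValueError("unshrunk covariance is singular for d > n")

    s_shrunk = (1 - gamma) * s + gamma * nu * np.eye(d)
    w = np.linalg.solve(s_shrunk, m1 - m0)
    b = float(-w @ (m1 + m0) / 2)
    return SLDAModel(w=w, b=b, gamma=gamma, nu=nu, mean_ma=m1, mean_bl=m0)


def slda_score(model: SLDAModel, x: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray]:
    """Continuous scores wᵀx + b and hard labels (MA iff score > 0)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != model.w.shape[0]:
        raise ValueError(f"feature dimension {x.shape[1]} != model "
                         f"dimension {model.w.shape[0]}")
    scores = x @ model.w + model.b
    labels = np.where(scores > 0, "MA", "BL")
    return scores, labels


def fuse_meta(base_scores: np.ndarray, labels: np.ndarray,
              members: tuple[str, ...] = MODALITIES) -> SLDAModel:
    """Meta-level sLDA on concatenated base-classifier scores.

    ``base_scores`` is trials x len(members); the caller must supply scores
    generated out-of-sample (inner folds), never resubstitution scores.
    """
    base_scores = np.asarray(base_scores, dtype=float)
    if len(members) < 2:
        raise ValueError("fusion needs at least 2 members")
    if base_scores.shape[1] != len(members):
        raise ValueError("score columns must align with fusion members")
    if base_scores.shape[0] != len(labels):
        raise ValueError("mismatched trial alignment across modalities")
    return slda_fit(base_scores, np.asarray(labels))


# ---------------------------------------------------------------------------
# nested cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    """Per-(repetition, fold) accuracies for every modality and fusion."""

    accuracies: dict[str, np.ndarray]     # name -> (reps, folds), in %
    bands: list[BandSpec]                 # one per (rep, fold), row-major
    predictions: dict[str, np.ndarray]    # name -> (reps, n_trials) 0/1
    labels: np.ndarray
    seed: int
    repetitions: int
    folds: int

    def mean(self, name: str) -> float:
        return float(self.accuracies[self._resolve(name)].mean())

    def std(self, name: str) -> float:
        return float(self.accuracies[self._resolve(name)].std(ddof=1))

    def _resolve(self, name: str) -> str:
        return ALIASES.get(name, name)

    def summary(self) -> dict:
        out = {}
        for name, acc in self.accuracies.items():
            out[name] = {"mean": float(acc.mean()),
                         "std": float(acc.std(ddof=1)),
                         "per_fold": acc.ravel().tolist()}
        out["bands"] = [b.as_tuple() for b in self.bands]
        out["seed"] = self.seed
        return out


class _EEGFeaturizer:
    """Band-selection + CSP pipeline with spectra/filter caches.

    Welch spectra per trial are label- and fold-independent, so they are
    computed once; filtered epochs are cached per selected band.
    """

    def __init__(self, epochs: EpochSet, *, search_range_hz=(4.0, 35.0),
                 resolution_hz: float = 0.5):
        self.epochs = epochs
        self.psd = trial_psd(epochs, resolution_hz)
        self.search_range_hz = search_range_hz
        self.resolution_hz = resolution_hz
        self._filtered: dict[tuple[float, float], EpochSet] = {}

    def band_for(self, train_idx: np.ndarray) -> BandSpec:
        return select_band(self.epochs, psd=self.psd, train_idx=train_idx,
                           search_range_hz=self.search_range_hz,
                           resolution_hz=self.resolution_hz)

    def filtered(self, band: BandSpec) -> EpochSet:
        key = band.as_tuple()
        if key not in self._filtered:
            self._filtered[key] = bandpass_epochs(self.epochs, band)
        return self._filtered[key]

    def fit(self, band: BandSpec, fit_idx: np.ndarray):
        filt = self.filtered(band)
        sub = EpochSet(filt.data[fit_idx], filt.labels[fit_idx],
                       filt.window_s, filt.rate_hz, filt.modality,
                       filt.channel_names)
        model = csp_fit(sub, band=band)
        model.train_hash = _index_hash(fit_idx)
        return model

    def transform(self, band: BandSpec, model, idx: np.ndarray) -> np.ndarray:
        filt = self.filtered(band)
        return csp_logvar(filt.data[idx], model,
                          labels=filt.labels[idx]).values


def cross_validate(eeg_epochs: EpochSet, hbo_epochs: EpochSet,
                   hbr_epochs: EpochSet, *, repetitions: int = 10,
                   folds: int = 5, inner_folds: int = 4, seed: int = 0,
                   search_range_hz: tuple[float, float] = (4.0, 35.0)
                   ) -> CVResult:
    """Repeated stratified k-fold nested cross-validation of all decoders.

    Outer loop: ``repetitions`` random stratified ``folds``-fold partitions.
    Within each outer training fold the passband and CSP filters are re-fit,
    and an inner stratified split produces out-of-fold base scores on which
    the meta classifiers are trained.  Accuracy is the percentage of correct
    test trials per fold.  Fully reproducible from ``seed``.
    """
    from .features import nirs_mean_slope   # local to avoid cycle at import

    labels = eeg_epochs.labels
    y = eeg_epochs.y()
    n = len(labels)
    if not (np.array_equal(labels, hbo_epochs.labels)
            and np.array_equal(labels, hbr_epochs.labels)):
        raise ValueError("mismatched trial alignment across modalities")
    if min((y == 1).sum(), (y == 0).sum()) < folds:
        raise ValueError("need at least `folds` trials per class "
                         "(stratification would leave a class empty)")

    feat_eeg = _EEGFeaturizer(eeg_epochs, search_range_hz=search_range_hz)
    fixed = {"HbO": nirs_mean_slope(hbo_epochs, "HbO").values,
             "HbR": nirs_mean_slope(hbr_epochs, "HbR").values}

    names = list(MODALITIES) + list(FUSIONS)
    acc = {m: np.zeros((repetitions, folds)) for m in names}
    preds = {m: np.zeros((repetitions, n), dtype=int) for m in names}
    bands: list[BandSpec] = []

    rep_seeds = np.random.SeedSequence(seed).generate_state(repetitions)
    for rep in range(repetitions):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=int(rep_seeds[rep] % (2 ** 31)))
        for fold, (tr, te) in enumerate(skf.split(np.zeros(n), y)):
            band = feat_eeg.band_for(tr)
            bands.append(band)

            # base classifiers on the full outer-training fold
            csp = feat_eeg.fit(band, tr)
            base_models, test_scores, train_oof = {}, {}, {}
            for m in MODALITIES:
                if m == "EEG":
                    Xtr = feat_eeg.transform(band, csp, tr)
                    Xte = feat_eeg.transform(band, csp, te)
                else:
                    Xtr, Xte = fixed[m][tr], fixed[m][te]
                model = slda_fit(Xtr, labels[tr])
                model.train_hash = _index_hash(tr)
                base_models[m] = model
                test_scores[m] = slda_score(model, Xte)[0]

            # inner out-of-fold scores for meta training
            k_inner = min(inner_folds, (y[tr] == 1).sum(),
                          (y[tr] == 0).sum())
            oof = {m: np.zeros(len(tr)) for m in MODALITIES}
            inner = StratifiedKFold(
                n_splits=k_inner, shuffle=True,
                random_state=int((rep_seeds[rep] + fold + 1) % (2 ** 31)))
            for itr, ite in inner.split(np.zeros(len(tr)), y[tr]):
                g_itr, g_ite = tr[itr], tr[ite]
                csp_i = feat_eeg.fit(band, g_itr)
                for m in MODALITIES:
                    if m == "EEG":
                        Xi = feat_eeg.transform(band, csp_i, g_itr)
                        Xo = feat_eeg.transform(band, csp_i, g_ite)
                    else:
                        Xi, Xo = fixed[m][g_itr], fixed[m][g_ite]
                    mi = slda_fit(Xi, labels[g_itr])
                    oof[m][ite] = slda_score(mi, Xo)[0]

            # evaluate
            for m in MODALITIES:
                hit = (test_scores[m] > 0).astype(int)
                acc[m][rep, fold] = 100.0 * np.mean(hit == y[te])
                preds[m][rep, te] = hit
            for fname, members in FUSIONS.items():
                meta_X = np.column_stack([oof[m] for m in members])
                meta = fuse_meta(meta_X, labels[tr], members)
                meta.train_hash = _index_hash(tr)
                te_X = np.column_stack([test_scores[m] for m in members])
                hit = (slda_score(meta, te_X)[0] > 0).astype(int)
                acc[fname][rep, fold] = 100.0 * np.mean(hit == y[te])
                preds[fname][rep, te] = hit

    return CVResult(accuracies=acc, bands=bands, predictions=preds,
                    labels=labels, seed=seed, repetitions=repetitions,
                    folds=folds)


def decode_recording(rec, *, repetitions: int = 10, folds: int = 5,
                     seed: int = 0, eeg_window: tuple[float, float] = (0, 10),
                     nirs_window: tuple[float, float] = (10, 15),
                     preproc_kwargs: dict | None = None) -> CVResult:
    """Preprocess a raw recording, epoch both modalities and cross-validate."""
    from .preproc import epoch, preprocess

    pp = preprocess(rec, **(preproc_kwargs or {}))
    eeg_ep = epoch(pp.eeg, pp.eeg_rate_hz, pp.events, eeg_window,
                   modality="EEG", channel_names=pp.frontal_names)
    hbo_ep = epoch(pp.hbo, pp.nirs_rate_hz, pp.events, nirs_window,
                   modality="HbO")
    hbr_ep = epoch(pp.hbr, pp.nirs_rate_hz, pp.events, nirs_window,
                   modality="HbR")
    return cross_validate(eeg_ep, hbo_ep, hbr_ep, repetitions=repetitions,
                          folds=folds, seed=seed)
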