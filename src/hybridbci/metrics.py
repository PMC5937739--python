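"""Evaluation: information transfer rate, summary statistics, group tests.

ITR follows the Wolpaw definition in bits per minute,

    ITR = m · [ log2 N + P log2 P + (1−P) log2((1−P)/(N−1)) ],

with m trials per minute (default 6: one 10 s task per selection), N task
types (default 2) and P the classification accuracy as a proportion.  Group
comparisons use the Friedman omnibus test with Wilcoxon signed-rank
post-hocs (exact for n ≤ 25) and Benjamini-Hochberg FDR correction.

The published per-participant accuracy table of the reference study ships
as package data so every summary derived from it is reproducible offline.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class ItrParams:
    m: float = 6.0          # trials per minute (10 s task, rest excluded)
    n_classes: int = 2
    p: float = 1.0

    def validate(self) -> None:
        if self.n_classes < 2 or self.m <= 0:
            raise ValueError("need N >= 2 and m > 0")
        if not 0 < self.p <= 1:
            raise ValueError("accuracy P must lie in (0, 1]")


def compute_itr(p: float | np.ndarray, n_classes: int = 2,
                m: float = 6.0) -> float | np.ndarray:
    """Bits per minute at accuracy ``p`` (proportion); 0·log0 := 0.

    Below chance (p < 1/N) the value is negative and returned as-is.
    """
    p_arr = np.asarray(p, dtype=float)
    ItrParams(m=m, n_classes=n_classes, p=float(np.min(p_arr))).validate()
    if np.max(p_arr) > 1:
        raise ValueError("accuracy P must lie in (0, 1]")
    with np.errstate(divide="ignore", invalid="ignore"):
        term_p = np.where(p_arr > 0, p_arr * np.log2(p_arr), 0.0)
        q = 1 - p_arr
        term_q = np.where(q > 0, q * np.log2(q / (n_classes - 1)), 0.0)
    bits = np.log2(n_classes) + term_p + term_q
    out = m * bits
    return float(out) if np.isscalar(p) else out


# ---------------------------------------------------------------------------
# reference accuracy table
# ---------------------------------------------------------------------------

def load_reference_table() -> pd.DataFrame:
    """Published per-participant accuracies (%, columns eeg/nirs/hyb) with
    the most frequently selected passband endpoints."""
    with resources.files("hybridbci.data").joinpath("table1.tsv").open() as f:
        return pd.read_csv(f, sep="\t")


def summarize_table(table: pd.DataFrame,
                    columns: tuple[str, ...] = ("eeg", "nirs", "hyb")
                    ) -> dict:
    """Column means/stds plus how often the hybrid beats each unimodal BCI."""
    if len(table) < 2:
        raise ValueError("need at least 2 participants")
    if table[list(columns)].isna().any().any():
        raise ValueError("missing cells in accuracy table")
    n = len(table)
    out = {"n": n, "mean": {}, "std": {}}
    for c in columns:
        out["mean"][c] = float(table[c].mean())
        out["std"][c] = float(table[c].std(ddof=1))
    if "hyb" in columns:
        for c in columns:
            if c == "hyb":
                continue
            count = int((table["hyb"] > table[c]).sum())
            out[f"hyb_gt_{c}_count"] = count
            out[f"hyb_gt_{c}_fraction_pct"] = 100.0 * count / n
    return out


def itr_summary(table: pd.DataFrame, m: float = 6.0, n_classes: int = 2,
                columns: tuple[str, ...] = ("eeg", "nirs", "hyb")) -> dict:
    """Mean of per-participant ITRs (bits/min) per column.

    Averaging participant ITRs, not the ITR of the mean accuracy: ITR is
    convex in P, so by Jensen the former is the larger, and it is the
    convention the reference figures use.
    """
    return {c: float(np.mean(compute_itr(table[c].to_numpy() / 100.0,
                                         n_classes, m)))
            for c in columns}


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------

def friedman_test(matrix: np.ndarray) -> tuple[float, float]:
    """Friedman rank test over a participants x conditions matrix
    (average-rank tie handling).  Returns (chi-square statistic, p)."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[1] < 2 or matrix.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >= 2 rows and columns")
    if np.all(np.ptp(matrix, axis=1) == 0):
        return 0.0, 1.0
    stat, p = stats.friedmanchisquare(*matrix.T)
    return float(stat), float(p)


def wilcoxon_signed_rank(a: np.ndarray, b: np.ndarray
                         ) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped; the null distribution is enumerated
    exactly for n ≤ 25 non-zero differences (normal approximation with
    continuity correction above).
    """
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all differences are zero")
    if d.size < 5:
        raise ValueError("need at least 5 non-zero differences")
    mode = "exact" if d.size <= 25 else "approx"
    res = stats.wilcoxon(d, alternative="two-sided", method=mode,
                         correction=(mode == "approx"))
    return float(res.statistic), float(res.pvalue)


def fdr_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (original order kept)."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def compare_conditions(matrix: np.ndarray,
                       names: tuple[str, ...]) -> dict:
    """Omnibus Friedman plus FDR-corrected pairwise Wilcoxon post-hocs."""
    matrix = np.asarray(matrix, dtype=float)
    stat, p_omni = friedman_test(matrix)
    pairs, raw = [], []
    k = matrix.shape[1]
    for i in range(k):
        for j in range(i + 1, k):
            w, pw = wilcoxon_signed_rank(matrix[:, i], matrix[:, j])
            pairs.append({"pair": f"{names[i]} vs {names[j]}",
                          "statistic": w, "p_raw": pw})
            raw.append(pw)
    adj = fdr_adjust(np.array(raw))
    for rec, pa in zip(pairs, adj):
        rec["p_fdr"] = float(pa)
    return {"friedman": {"statistic": stat, "p": p_omni}, "pairwise": pairs}


# ---------------------------------------------------------------------------
# analysis-window sweep
# ---------------------------------------------------------------------------

def window_sweep(rec, eeg_windows: list[tuple[float, float]],
                 nirs_windows: list[tuple[float, float]], *,
                 repetitions: int = 3, folds: int = 5, seed: int = 0,
                 preproc_kwargs: dict | None = None) -> pd.DataFrame:
    """Accuracy grid over analysis windows, one axis varied at a time.

    Every (EEG window, NIRS window) pair in the cross product is decoded
    with the full nested CV; the returned table has one row per pair and
    one accuracy column per modality/fusion.
    """
    from .decode import cross_validate
    from .preproc import epoch, preprocess

    pp = preprocess(rec, **(preproc_kwargs or {}))
    rows = []
    for ew in eeg_windows:
        eeg_ep = epoch(pp.eeg, pp.eeg_rate_hz, pp.events, tuple(ew),
                       modality="EEG", channel_names=pp.frontal_names)
        for nw in nirs_windows:
            hbo_ep = epoch(pp.hbo, pp.nirs_rate_hz, pp.events, tuple(nw),
                           modality="HbO")
            hbr_ep = epoch(pp.hbr, pp.nirs_rate_hz, pp.events, tuple(nw),
                           modality="HbR")
            res = cross_validate(eeg_ep, hbo_ep, hbr_ep,
                                 repetitions=repetitions, folds=folds,
                                 seed=seed)
            row = {"eeg_window": f"{ew[0]}-{ew[1]}",
                   "nirs_window": f"{nw[0]}-{nw[1]}"}
            row.update({name: float(a.mean())
                        for name, a in res.accuracies.items()})
            rows.append(row)
    return pd.DataFrame(rows)
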