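"""Linear synchronization: Pearson, band coherence, cross-correlation lag.

All estimators share the spectral stage's windowing: the metric is computed
per one-second window and averaged, or (for coherence) the auto- and
cross-spectra are averaged across windows before forming the magnitude-
squared coherence ``coh(ω) = |S_ij|² / (S_ii S_jj)``, which is then averaged
over the bins of each EEG band.

Cross-correlation adds a time axis to Pearson's r: the normalized
correlation is evaluated on an integer-sample lag grid, averaged across
windows, and the peak value and its lag (in ms) are reported. A positive lag
means the second series is delayed relative to the first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EstimatorError, ParameterError
from .spectral import BANDS

#: Homologous interhemispheric channel pairs used for cross-correlation:
#: frontal, parietal, temporal, occipital.
CC_PAIRS: dict[str, tuple[str, str]] = {
    "F": ("F3-C3", "F4-C4"),
    "P": ("C3-P3", "C4-P4"),
    "T": ("T3-T5", "T4-T6"),
    "O": ("P3-O1", "P4-O2"),
}


@dataclass
class SyncResult:
    """Synchronization summary for one subject.

    ``pearson`` is the window-mean correlation matrix; ``coh`` maps band name
    to the band-mean coherence matrix; ``cc_pairs`` maps paired-lobe name to
    ``(CC_max, lag_ms)``; ``skipped`` counts windows dropped for zero
    variance.
    """

    labels: list[str]
    pearson: np.ndarray
    coh: dict[str, np.ndarray]
    cc_pairs: dict[str, tuple[float, float]] = field(default_factory=dict)
    skipped: int = 0


def pearson_matrix(data: np.ndarray, windows: list[tuple[int, int]]
                   ) -> tuple[np.ndarray, int]:
    """Mean of per-window Pearson correlation matrices.

    Windows in which any channel has zero variance are skipped entirely and
    counted; returns ``(matrix, n_skipped)``.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape[0] < 2:
        raise EstimatorError("need at least 2 channels")
    if not windows:
        raise EstimatorError("need at least 1 window")
    acc = np.zeros((data.shape[0], data.shape[0]))
    used = 0
    for a, b in windows:
        seg = data[:, a:b]
        if np.any(seg.std(axis=1) == 0):
            continue
        acc += np.corrcoef(seg)
        used += 1
    if used == 0:
        raise EstimatorError("all windows skipped (zero-variance channels)")
    return acc / used, len(windows) - used


def cross_spectra(data: np.ndarray, windows: list[tuple[int, int]],
                  fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Window-averaged cross-spectral matrix on the 0.5-Hz grid.

    Returns ``(freqs, S)`` with ``S`` of shape (n_channels, n_channels,
    n_freqs), Hermitian in the channel indices. Uses the same zero-padded
    one-second windows as the spectral stage.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    nwin = windows[0][1] - windows[0][0]
    nfft = 2 * nwin
    nch = data.shape[0]
    S = np.zeros((nch, nch, nfft // 2 + 1), dtype=complex)
    for a, b in windows:
        X = np.fft.rfft(data[:, a:b], n=nfft, axis=1)
        S += np.einsum("if,jf->ijf", X, np.conj(X))
    S /= len(windows)
    return np.fft.rfftfreq(nfft, d=1.0 / fs), S


def coherence_matrices(data: np.ndarray, windows: list[tuple[int, int]],
                       fs: float,
                       bands: dict[str, tuple[float, float]] | None = None,
                       weighted: bool = False) -> dict[str, np.ndarray]:
    """Band-mean magnitude-squared coherence for every channel pair.

    Requires at least two windows — coherence estimated from a single
    window is identically 1. Bins where an auto-spectrum vanishes are
    excluded from the band mean. ``weighted=True`` weights bins by the
    geometric mean auto-power instead of the default unweighted mean.
    """
    if len(windows) < 2:
        raise EstimatorError(
            "coherence needs at least 2 windows (one window gives coh = 1)")
    bands = bands or BANDS
    freqs, S = cross_spectra(data, windows, fs)
    auto = np.real(np.einsum("iif->if", S))  # (nch, nfreq)
    denom = auto[:, None, :] * auto[None, :, :]
    num = np.abs(S) ** 2
    valid = denom > 0
    coh = np.where(valid, num / np.where(valid, denom, 1.0), np.nan)
    out = {}
    for band, (lo, hi) in bands.items():
        mask = (freqs >= lo) & (freqs < hi)
        C = coh[:, :, mask]
        if weighted:
            w = np.sqrt(denom[:, :, mask])
            w = np.where(np.isfinite(C), w, 0.0)
            out[band] = np.nansum(C * w, axis=2) / np.maximum(
                w.sum(axis=2), np.finfo(float).tiny)
        else:
            out[band] = np.nanmean(C, axis=2)
    return out


def coherence_matrix(data: np.ndarray, windows: list[tuple[int, int]],
                     fs: float, band: str) -> np.ndarray:
    """Coherence matrix for a single named band."""
    if band not in BANDS:
        raise ParameterError(f"unknown band {band!r}")
    return coherence_matrices(data, windows, fs, {band: BANDS[band]})[band]


def region_sync(matrix: np.ndarray, labels: list[str],
                region_channels: list[str]) -> float:
    """Mean of a synchronization metric over all unordered pairs in a region.

    Three channels per lobe give 3 pairs; the eight distinct lateral channels
    of a hemisphere give 28.
    """
    missing = [c for c in region_channels if c not in labels]
    if missing:
        raise EstimatorError("channels not in matrix: " + ", ".join(missing))
    if len(region_channels) < 2:
        raise EstimatorError("region needs at least 2 channels")
    idx = [labels.index(c) for c in region_channels]
    vals = [matrix[i, j] for k, i in enumerate(idx) for j in idx[k + 1:]]
    return float(np.mean(vals))


def cross_correlation_lag(x: np.ndarray, y: np.ndarray, fs: float,
                          max_lag_ms: float = 50.0,
                          windows: list[tuple[int, int]] | None = None
                          ) -> tuple[float, float]:
    """Peak of the window-averaged normalized cross-correlation.

    For every integer-sample lag within ±``max_lag_ms`` the Pearson
    correlation between ``x[t]`` and ``y[t + lag]`` is computed per window
    (over the overlapping part) and averaged across windows; the maximum of
    the averaged curve and its lag in ms are returned. Positive lag means
    ``y`` is delayed relative to ``x``. Ties are broken toward smaller
    absolute lag, then toward positive lag.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("series must be 1-D and of equal length")
    if max_lag_ms < 1000.0 / fs:
        raise ParameterError("max_lag_ms below one sample period")
    if windows is None:
        windows = [(0, len(x))]
    maxlag = int(max_lag_ms * fs / 1000.0)
    lags = np.arange(-maxlag, maxlag + 1)
    X = np.stack([x[a:b] for a, b in windows])  # (W, nwin)
    Y = np.stack([y[a:b] for a, b in windows])
    if np.any(X.std(axis=1) == 0) or np.any(Y.std(axis=1) == 0):
        raise EstimatorError("zero-variance input in a window")
    acc = np.zeros(len(lags))
    for i, lag in enumerate(lags):
        if lag >= 0:
            xv = X[:, : X.shape[1] - lag or None]
            yv = Y[:, lag:]
        else:
            xv, yv = X[:, -lag:], Y[:, :lag]
        xd = xv - xv.mean(axis=1, keepdims=True)
        yd = yv - yv.mean(axis=1, keepdims=True)
        denom = np.sqrt((xd * xd).sum(axis=1) * (yd * yd).sum(axis=1))
        ok = denom > 0
        acc[i] = np.where(ok, (xd * yd).sum(axis=1)
                          / np.where(ok, denom, 1.0), 0.0).mean()
    # tie-break: smaller |lag| first, positive before negative at equal |lag|
    order = np.lexsort((lags < 0, np.abs(lags)))
    best = order[np.argmax(acc[order])]
    return float(acc[best]), float(lags[best] * 1000.0 / fs)


def paired_lobe_cc(record, windows: list[tuple[int, int]] | None = None,
                   max_lag_ms: float = 50.0
                   ) -> dict[str, tuple[float, float]]:
    """Interhemispheric cross-correlation for the four paired lobes.

    Left-hemisphere channel first, so a positive lag means the right
    hemisphere lags the left.
    """
    out = {}
    for lobe, (left, right) in CC_PAIRS.items():
        out[lobe] = cross_correlation_lag(
            record.channel(left), record.channel(right), record.fs,
            max_lag_ms=max_lag_ms, windows=windows)
    return out


def sync_summary(record, windows: list[tuple[int, int]],
                 max_lag_ms: float = 50.0) -> SyncResult:
    """Full synchronization stage for one bipolar record."""
    pearson, skipped = pearson_matrix(record.data, windows)
    coh = coherence_matrices(record.data, windows, record.fs)
    cc = paired_lobe_cc(record, windows, max_lag_ms)
    return SyncResult(labels=list(record.labels), pearson=pearson, coh=coh,
                      cc_pairs=cc, skipped=skipped)
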