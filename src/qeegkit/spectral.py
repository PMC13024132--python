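"""Windowed power spectra, band areas and Shannon spectral entropy.

The estimator follows routine clinical qEEG practice: the record is cut into
one-second moving windows with 10% overlap, each window is zero-padded to
twice its length before the FFT so the spectrum lands on a 0.5-Hz grid, and
per-window one-sided power densities (µV²/Hz, Parseval-consistent: the
integral of the density equals the window variance) are averaged.

Band areas integrate the mean density over the classical EEG bands
(δ 0.5–4, θ 4–8, α 8–13, β 13–30 Hz, half-open intervals so shared edges are
counted once) and are reported both raw (µV²) and as ``logPS = log10(area)``.
Shannon spectral entropy (SSE) is computed per window on the probability
density of the 0.5–30 Hz spectrum and normalized by ``log2`` of the number of
bins, so SSE ∈ [0, 1] with 1 for a flat spectrum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DataError, DurationError, EstimatorError, ParameterError

#: Classical EEG band edges in Hz; intervals are half-open [low, high).
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}

#: Frequency range over which entropy probabilities are defined (inclusive).
ENTROPY_RANGE: tuple[float, float] = (0.5, 30.0)


def make_windows(n_samples: int, fs: float, win_s: float = 1.0,
                 overlap: float = 0.10) -> list[tuple[int, int]]:
    """Moving-window index ranges, last window fully inside the data.

    With the defaults (1-s windows, 10% overlap) a 120-s record yields 133
    windows: starts at 0, 0.9, 1.8, … ≤ 119 s.
    """
    if win_s * fs < 2:
        raise ParameterError("window must contain at least 2 samples")
    if not 0 <= overlap < 1:
        raise ParameterError("overlap must be in [0, 1)")
    nwin = int(round(win_s * fs))
    if n_samples < nwin:
        raise DurationError(
            f"record of {n_samples} samples shorter than one "
            f"{nwin}-sample window")
    step = max(1, int(round(nwin * (1 - overlap))))
    starts = range(0, n_samples - nwin + 1, step)
    return [(s, s + nwin) for s in starts]


def segment_windows(segments: list[tuple[int, int]], fs: float,
                    win_s: float = 1.0,
                    overlap: float = 0.10) -> list[tuple[int, int]]:
    """Windows that never straddle an artifact-splice boundary.

    Windowing restarts at each retained segment; segments shorter than one
    window contribute none.
    """
    out: list[tuple[int, int]] = []
    for start, end in segments:
        try:
            wins = make_windows(end - start, fs, win_s, overlap)
        except DurationError:
            continue
        out.extend((start + a, start + b) for a, b in wins)
    if not out:
        raise DurationError("no segment long enough for a single window")
    return out


@dataclass
class SpectrumSet:
    """Per-channel windowed and window-averaged power spectra.

    Attributes
    ----------
    freqs : ndarray
        One-sided frequency grid, 0.5-Hz spacing.
    S : ndarray, shape (n_windows, n_channels, n_freqs)
        Per-window one-sided power density in µV²/Hz.
    S_mean : ndarray, shape (n_channels, n_freqs)
        Arithmetic mean over windows.
    labels : list of str
        Channel labels, one per channel row.
    """

    freqs: np.ndarray
    S: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        if self.S.ndim != 3:
            raise ValueError("S must be (windows, channels, freqs)")
        if np.any(self.S < 0):
            raise ValueError("power density must be non-negative")

    @property
    def S_mean(self) -> np.ndarray:
        return self.S.mean(axis=0)

    @property
    def n_windows(self) -> int:
        return self.S.shape[0]

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])

    def channel(self, label: str) -> np.ndarray:
        """Window-averaged spectrum of one channel."""
        return self.S_mean[self.labels.index(label)]


def power_spectrum(data: np.ndarray, fs: float,
                   windows: list[tuple[int, int]],
                   labels: list[str] | None = None,
                   taper: str = "boxcar") -> SpectrumSet:
    """Windowed one-sided power density on a 0.5-Hz grid.

    Each window of ``n = fs`` samples is zero-padded to ``2 n`` points before
    the FFT, which halves the bin spacing to 0.5 Hz while keeping the
    one-second windows. Scaling is Parseval-consistent: summing the density
    times the bin width over the one-sided grid recovers the window's mean
    square amplitude.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples) or (n_samples,)
    fs : float
    windows : list of (start, end)
        From :func:`make_windows` / :func:`segment_windows`.
    taper : str
        Window taper applied before the FFT (any scipy window name);
        the default boxcar applies none.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if not np.all(np.isfinite(data)):
        raise DataError("non-finite samples in input")
    if labels is None:
        labels = [f"ch{i}" for i in range(data.shape[0])]
    nwin = windows[0][1] - windows[0][0]
    nfft = 2 * nwin
    if taper == "boxcar":
        w = np.ones(nwin)
    else:
        from scipy.signal import get_window
        w = get_window(taper, nwin)
    # Parseval: sum |x|^2 = (1/M) sum |X|^2 for DFT length M; density scaled
    # so that  sum_k S_k * df = window mean power (df = fs / nfft).
    norm = fs * np.sum(w ** 2)
    spectra = np.empty((len(windows), data.shape[0], nfft // 2 + 1))
    for i, (a, b) in enumerate(windows):
        X = np.fft.rfft(data[:, a:b] * w, n=nfft, axis=1)
        P = (np.abs(X) ** 2) / norm
        P[:, 1:-1] *= 2.0  # fold negative frequencies, DC/Nyquist excepted
        spectra[i] = P
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    return SpectrumSet(freqs=freqs, S=spectra, labels=list(labels))


def spectrum_from_record(rec, win_s: float = 1.0, overlap: float = 0.10,
                         taper: str = "boxcar") -> SpectrumSet:
    """Convenience: windows honoring segments, then :func:`power_spectrum`."""
    wins = segment_windows(rec.segments, rec.fs, win_s, overlap)
    labels = rec.labels if hasattr(rec, "labels") else list(rec.electrodes)
    return power_spectrum(rec.data, rec.fs, wins, labels=labels)


def band_area(spec: SpectrumSet, low: float, high: float,
              channel: int | str | None = None) -> np.ndarray | float:
    """Integrated mean power (µV²) over ``[low, high)`` for each channel."""
    mask = (spec.freqs >= low) & (spec.freqs < high)
    areas = spec.S_mean[:, mask].sum(axis=1) * spec.df
    if channel is None:
        return areas
    idx = spec.labels.index(channel) if isinstance(channel, str) else channel
    return float(areas[idx])


def band_powers(spec: SpectrumSet,
                bands: dict[str, tuple[float, float]] | None = None):
    """Per-channel band areas and logPS as a tidy DataFrame.

    Columns: channel, band, area (µV²), logps (log10 µV²). A zero band area
    yields a missing logPS with a warning rather than −inf.
    """
    import pandas as pd

    bands = bands or BANDS
    if spec.freqs[-1] < max(h for _, h in bands.values()) - spec.df:
        raise ParameterError("spectrum grid does not cover the band map")
    rows = []
    for band, (lo, hi) in bands.items():
        areas = band_area(spec, lo, hi)
        for ch, area in zip(spec.labels, areas):
            if area > 0:
                logps = float(np.log10(area))
            else:
                warnings.warn(
                    f"zero {band} area in channel {ch}; logPS set missing",
                    stacklevel=2)
                logps = np.nan
            rows.append({"channel": ch, "band": band,
                         "area": float(area), "logps": logps})
    return pd.DataFrame(rows)


def spectral_entropy(spec: SpectrumSet,
                     frange: tuple[float, float] = ENTROPY_RANGE
                     ) -> np.ndarray:
    """Normalized Shannon spectral entropy per channel.

    For every window the power density over the 0.5–30 Hz grid (inclusive,
    60 bins at 0.5-Hz spacing) is normalized to a probability distribution
    p_k; the raw entropy ``-Σ p_k log2 p_k`` is averaged across windows and
    divided by ``log2(n_bins)`` so the result lies in [0, 1]. Normalizing
    the spectrum first makes the entropy insensitive to overall amplitude.
    """
    mask = (spec.freqs >= frange[0]) & (spec.freqs <= frange[1])
    nbins = int(mask.sum())
    if nbins < 2:
        raise EstimatorError("entropy needs at least 2 frequency bins")
    P = spec.S[:, :, mask] * spec.df  # (windows, channels, bins)
    totals = P.sum(axis=2)
    if np.any(totals <= 0):
        raise EstimatorError(
            "all-zero spectrum in a window: entropy undefined")
    p = P / totals[:, :, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.where(p > 0, p * np.log2(p), 0.0).sum(axis=2)
    return h.mean(axis=0) / np.log2(nbins)


def normalized_average_spectra(cohort: list[SpectrumSet],
                               reference: str = "Cz-Pz") -> np.ndarray:
    """Group-mean spectra after per-subject normalization.

    Every subject's spectra are divided by that subject's maximum mean
    density at the reference channel (the midline Cz–Pz derivation, chosen
    because it is least contaminated by ocular and muscular artifacts), then
    averaged across subjects per channel and bin.

    Returns the (n_channels, n_freqs) group mean on the first subject's
    grid; all subjects must share grid and channel ordering.
    """
    if not cohort:
        raise EstimatorError("empty cohort")
    base = cohort[0]
    out = np.zeros_like(base.S_mean)
    for spec in cohort:
        if spec.labels != base.labels or len(spec.freqs) != len(base.freqs):
            raise ParameterError("subjects must share channels and grid")
        peak = spec.channel(reference).max()
        if peak <= 0:
            raise EstimatorError(
                f"zero spectrum at {reference}: cannot normalize subject")
        out += spec.S_mean / peak
    return out / len(cohort)
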