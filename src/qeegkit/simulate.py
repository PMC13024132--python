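"""Synthetic resting-state EEG cohorts with known ground truth.

Every pipeline stage in this package is testable without clinical
recordings: this module generates referential 19-electrode 10–20 records
whose band structure, posterior alpha peaks, interchannel couplings and
interhemispheric delays are set by an explicit specification, and returns a
ground-truth sidecar alongside each record.

Signal model (per electrode ``e``, band ``b``, all sources unit-variance
Gaussian noise band-pass shaped to the band)::

    x_eb = sqrt(P_b) * [ sqrt(c) * s_(lobe,b)            # regional common
                         + g_e * sqrt(w_lobe) * h_b      # bipolar carrier
                         + sqrt(1 - c - g_e^2 w) * u_eb ]  # independent

- The *regional common* ``s`` has uniform gain within a region, so it sets
  the referential intra-region Pearson r to ``c`` — and cancels exactly in
  every bipolar derivation.
- The *carrier* ``h`` enters electrodes through a monotone front-to-back
  gain ramp ``g_e`` (step 1 per chain position), so every double-banana
  derivation retains it with gain +1; it is shared between hemispheres with
  the injected integer-sample delay, and its per-lobe variance share ``w``
  is the knob that moves bipolar-montage synchronization.
- Alpha-band sources are narrow-band (band-pass centred on the region's
  alpha peak) and are never shared across hemispheres, so asynchronous
  subjects keep clean, distinct peaks; the alpha carrier is therefore
  per (lobe, side) and carries no interhemispheric lag.

Predicted referential correlation between electrodes i, j of one region is
``c + g_i g_j w (1 - f_alpha)`` with ``f_alpha`` the alpha power fraction
(the carrier spans the non-alpha bands only).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import signal

from .errors import ConfigurationError, ValidationError
from .montage import Recording, TEN_TWENTY
from .spectral import BANDS

#: Electrode -> (lobe, side). Central electrodes are grouped with the
#: parieto-occipital region whose bipolar chains they open.
ELECTRODE_REGION: dict[str, tuple[str, str]] = {
    "Fp1": ("F", "left"), "F3": ("F", "left"), "F7": ("F", "left"),
    "Fz": ("F", "mid"),
    "Fp2": ("F", "right"), "F4": ("F", "right"), "F8": ("F", "right"),
    "C3": ("PO", "left"), "P3": ("PO", "left"), "O1": ("PO", "left"),
    "Cz": ("PO", "mid"), "Pz": ("PO", "mid"),
    "C4": ("PO", "right"), "P4": ("PO", "right"), "O2": ("PO", "right"),
    "T3": ("T", "left"), "T5": ("T", "left"),
    "T4": ("T", "right"), "T6": ("T", "right"),
}

#: Carrier gain ramp: chain position front (+2) to back (−2); every
#: double-banana derivation then carries the shared source with gain +1.
CARRIER_GAIN: dict[str, float] = {
    "Fp1": 2, "F3": 1, "C3": 0, "P3": -1, "O1": -2,
    "F7": 1, "T3": 0, "T5": -1,
    "Fz": 1, "Cz": 0, "Pz": -1,
    "Fp2": 2, "F4": 1, "C4": 0, "P4": -1, "O2": -2,
    "F8": 1, "T4": 0, "T6": -1,
}

BAND_NAMES = ("delta", "theta", "alpha", "beta")


@dataclass
class RegionBandSpec:
    """Target band structure for one scalp region.

    ``band_power`` maps band name to target power in µV² (the variance the
    band contributes to each electrode of the region); ``alpha_peak`` is the
    centre of the narrow-band alpha oscillator in Hz and ``alpha_bandwidth``
    its width.
    """

    lobe: str
    side: str
    band_power: dict[str, float]
    alpha_peak: float = 10.5
    alpha_bandwidth: float = 1.0

    def __post_init__(self) -> None:
        if self.lobe not in ("F", "PO", "T"):
            raise ConfigurationError(f"unknown lobe {self.lobe!r}")
        if self.side not in ("left", "right", "mid"):
            raise ConfigurationError(f"unknown side {self.side!r}")
        for band, p in self.band_power.items():
            if band not in BAND_NAMES:
                raise ConfigurationError(f"unknown band {band!r}")
            if p < 0:
                raise ValidationError(f"negative {band} power: {p}")
        if self.band_power.get("alpha", 0) > 0 and not (
                7.5 <= self.alpha_peak <= 13):
            raise ValidationError(
                f"alpha peak {self.alpha_peak} Hz outside [7.5, 13]")

    @property
    def key(self) -> str:
        return f"{self.lobe}_{self.side}"


def _region_key(electrode: str) -> str:
    lobe, side = ELECTRODE_REGION[electrode]
    return f"{lobe}_{side}"


def _shaped_noise(rng: np.random.Generator, n: int, fs: float,
                  low: float, high: float, order: int = 6,
                  norm_band: tuple[float, float] | None = None
                  ) -> np.ndarray:
    """Gaussian noise band-pass filtered to [low, high], scaled to unit
    in-band power.

    Normalizing to the power actually inside ``[low, high)`` (measured on
    the full-length periodogram) rather than to total variance compensates
    for the filter skirts, so generated band areas land on their targets.
    """
    x = rng.standard_normal(n)
    sos = signal.butter(order, [low, min(high, 0.499 * fs)],
                        btype="bandpass", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos, x)
    # confine the source spectrally to its band: the Butterworth response
    # shapes the in-band spectrum, the out-of-band skirts are removed so
    # band powers do not bleed into neighbouring bands
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    nlow, nhigh = norm_band if norm_band is not None else (low, high)
    Y = np.fft.rfft(y)
    Y[(freqs < nlow) | (freqs >= nhigh)] = 0.0
    y = np.fft.irfft(Y, n=n)
    return y / y.std()


def generate_subject(regions: dict[str, RegionBandSpec] | list[RegionBandSpec],
                     duration_s: float = 120.0, fs: float = 512.0,
                     seed: int = 0,
                     coupling: dict[str, float] | None = None,
                     carrier: dict[str, float] | None = None,
                     lag_ms: float = 0.0,
                     noise_uv: float = 0.0,
                     subject_id: str = "synthetic") -> Recording:
    """Generate one referential 19-electrode record.

    Parameters
    ----------
    regions : mapping region key ("F_left", "PO_mid", ...) to RegionBandSpec
        Must cover the region of every 10–20 electrode (temporal midline
        has no electrode and needs no entry).
    coupling : lobe -> c
        Referential intra-region correlation target per lobe (default 0.45).
    carrier : lobe -> w
        Carrier variance share per lobe (default 0.08); together with the
        gain ramp this must satisfy ``c + 4 w <= 1``.
    lag_ms : float
        Interhemispheric delay of shared sources, right hemisphere delayed.
    noise_uv : float
        Standard deviation of an optional white contaminant, µV.
    """
    if isinstance(regions, list):
        regions = {r.key: r for r in regions}
    if duration_s < 2:
        raise ConfigurationError("duration must be at least 2 s")
    if fs < 128:
        raise ConfigurationError("sampling rate must be at least 128 Hz")
    for e in TEN_TWENTY:
        if _region_key(e) not in regions:
            raise ConfigurationError(
                f"region map does not cover electrode {e} "
                f"({_region_key(e)})")
    coupling = {"F": 0.45, "PO": 0.45, "T": 0.45, **(coupling or {})}
    carrier = {"F": 0.08, "PO": 0.08, "T": 0.08, **(carrier or {})}
    for lobe in ("F", "PO", "T"):
        if not 0 <= coupling[lobe] <= 1:
            raise ConfigurationError(f"coupling[{lobe}] outside [0, 1]")
        if coupling[lobe] + 4 * carrier[lobe] > 1:
            raise ConfigurationError(
                f"coupling[{lobe}] + 4*carrier[{lobe}] exceeds 1: "
                "no variance left for independent sources")

    n = int(round(duration_s * fs))
    L = int(round(lag_ms * fs / 1000.0))
    rng = np.random.default_rng(seed)
    nonalpha = [(b, lo, hi) for b, (lo, hi) in BANDS.items() if b != "alpha"]

    # shared sources, length n + L so the right hemisphere can lag
    s = {(lobe, b): _shaped_noise(rng, n + L, fs, lo, hi)
         for lobe in ("F", "PO", "T") for b, lo, hi in nonalpha}
    h = {}
    for b, lo, hi in nonalpha:
        hb = _shaped_noise(rng, n + L, fs, lo, hi)
        for lobe in ("F", "PO", "T"):
            s_ = s[(lobe, b)]
            hb = hb - (hb @ s_) / (s_ @ s_) * s_
        h[b] = hb / hb.std()
    # alpha commons and carriers: per region, never shared across sides
    s_alpha, h_alpha = {}, {}
    for key, spec in regions.items():
        if spec.band_power.get("alpha", 0) > 0:
            half = spec.alpha_bandwidth / 2.0
            s_alpha[key] = _shaped_noise(
                rng, n, fs, spec.alpha_peak - half, spec.alpha_peak + half,
                order=2, norm_band=BANDS["alpha"])
            ha = _shaped_noise(
                rng, n, fs, spec.alpha_peak - half, spec.alpha_peak + half,
                order=2, norm_band=BANDS["alpha"])
            s_ = s_alpha[key]
            ha = ha - (ha @ s_) / (s_ @ s_) * s_
            h_alpha[key] = ha / ha.std()

    def _slice(src: np.ndarray, side: str) -> np.ndarray:
        # right(t) = shared(t - L): the right hemisphere lags
        return src[:n] if side == "right" else src[L: L + n]

    def _orthogonalize(u: np.ndarray, *shared: np.ndarray) -> np.ndarray:
        # remove the finite-sample covariance of an independent source with
        # the shared sources so mixture band powers hit their targets
        # exactly instead of within the cross-term sampling error
        for s_ in shared:
            u = u - (u @ s_) / (s_ @ s_) * s_
        return u / u.std()

    data = np.zeros((len(TEN_TWENTY), n))
    for i, e in enumerate(TEN_TWENTY):
        lobe, side = ELECTRODE_REGION[e]
        spec = regions[_region_key(e)]
        c, w, g = coupling[lobe], carrier[lobe], CARRIER_GAIN[e]
        x = np.zeros(n)
        for b, lo, hi in nonalpha:
            P = spec.band_power.get(b, 0.0)
            if P <= 0:
                continue
            s_b = _slice(s[(lobe, b)], side)
            h_b = _slice(h[b], side)
            indep = _orthogonalize(_shaped_noise(rng, n, fs, lo, hi),
                                   s_b, h_b)
            mix = (np.sqrt(c) * s_b + g * np.sqrt(w) * h_b
                   + np.sqrt(1 - c - g * g * w) * indep)
            x += np.sqrt(P) * mix
        P = spec.band_power.get("alpha", 0.0)
        if P > 0:
            half = spec.alpha_bandwidth / 2.0
            indep = _orthogonalize(
                _shaped_noise(rng, n, fs, spec.alpha_peak - half,
                              spec.alpha_peak + half, order=2,
                              norm_band=BANDS["alpha"]),
                s_alpha[spec.key], h_alpha[spec.key])
            mix = (np.sqrt(c) * s_alpha[spec.key]
                   + g * np.sqrt(w) * h_alpha[spec.key]
                   + np.sqrt(1 - c - g * g * w) * indep)
            x += np.sqrt(P) * mix
        if noise_uv > 0:
            x += noise_uv * rng.standard_normal(n)
        data[i] = x
    return Recording(subject_id, fs, list(TEN_TWENTY), data)


# ---------------------------------------------------------------------------
# Cohort profiles


def default_profile(kind: str) -> dict[str, RegionBandSpec]:
    """Built-in group profiles.

    ``control`` has a dominant posterior alpha at 10.5 Hz; the
    ``ds_synchronous`` profile raises delta and theta globally, doubles
    frontal beta, halves posterior alpha power and slows the peak by 1 Hz;
    ``ds_asynchronous`` additionally splits the hemispheric posterior peaks
    (left 9.0 Hz, right 10.5 Hz, interhemispheric difference 1.5 Hz).
    """
    base = {
        "F": {"delta": 25.0, "theta": 18.0, "alpha": 28.0, "beta": 12.0},
        "PO": {"delta": 25.0, "theta": 18.0, "alpha": 90.0, "beta": 8.0},
        "T": {"delta": 25.0, "theta": 18.0, "alpha": 45.0, "beta": 8.0},
    }
    peaks = {"left": 10.5, "right": 10.5, "mid": 10.5}
    if kind == "control":
        pass
    elif kind in ("ds_synchronous", "ds_asynchronous"):
        for lobe in base:
            base[lobe] = dict(base[lobe])
            base[lobe]["delta"] *= 2.5
            base[lobe]["theta"] *= 2.2
        base["F"]["beta"] *= 2.0
        base["PO"]["alpha"] *= 0.5
        base["T"]["alpha"] *= 0.7
        if kind == "ds_synchronous":
            peaks = {"left": 9.5, "right": 9.5, "mid": 9.5}
        else:
            peaks = {"left": 9.0, "right": 10.5, "mid": 9.5}
    else:
        raise ConfigurationError(f"unknown profile kind {kind!r}")
    out = {}
    for lobe in ("F", "PO", "T"):
        for side in ("left", "right", "mid"):
            if lobe == "T" and side == "mid":
                continue
            out[f"{lobe}_{side}"] = RegionBandSpec(
                lobe=lobe, side=side, band_power=dict(base[lobe]),
                alpha_peak=peaks[side])
    return out


#: Default synchronization knobs per group: the clinical pattern has the
#: parieto-occipital coupling reduced in the DS profiles.
DEFAULT_COUPLING = {
    "control": {"F": 0.45, "PO": 0.45, "T": 0.45},
    "ds": {"F": 0.45, "PO": 0.35, "T": 0.45},
}
DEFAULT_CARRIER = {
    "control": {"F": 0.08, "PO": 0.10, "T": 0.08},
    "ds": {"F": 0.10, "PO": 0.05, "T": 0.06},
}


@dataclass
class CohortSpec:
    """Specification of a synthetic cohort.

    ``asynchrony_fraction`` is realized deterministically: the first
    ``round(fraction * n_subjects)`` subjects get the asynchronous profile,
    so the asynchronous count in the ground truth is exact. ``iq_model``
    maps the latent IQ (drawn from ``iq_mean``/``iq_sd``) to mild relative
    perturbations of slow-band power and parieto-occipital coupling.
    """

    n_subjects: int = 22
    group: str = "ds"
    asynchrony_fraction: float = 8.0 / 22.0
    duration_s: float = 120.0
    fs: float = 512.0
    coupling: dict[str, float] | None = None
    carrier: dict[str, float] | None = None
    lag_ms: float = 0.0
    iq_mean: float | None = None
    iq_sd: float = 8.0
    iq_model: dict[str, float] = field(default_factory=lambda: {
        "slow_power_slope": -0.004, "po_carrier_slope": 0.004})
    noise_uv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if not 0 <= self.asynchrony_fraction <= 1:
            raise ConfigurationError("asynchrony_fraction outside [0, 1]")
        if self.group not in ("ds", "control"):
            raise ConfigurationError(f"unknown group {self.group!r}")
        if self.iq_mean is None:
            self.iq_mean = 45.0 if self.group == "ds" else 100.0


@dataclass
class SubjectTruth:
    """Ground-truth sidecar for one generated subject."""

    subject_id: str
    group: str
    sync_class: str
    iq: float
    seed: int
    lag_ms: float
    alpha_peaks: dict[str, float]
    band_power: dict[str, dict[str, float]]
    coupling: dict[str, float]
    carrier: dict[str, float]


def generate_cohort(spec: CohortSpec
                    ) -> list[tuple[Recording, SubjectTruth]]:
    """Generate a cohort with deterministic class assignment.

    With the DS group the first ``round(asynchrony_fraction * n)`` subjects
    are asynchronous (controls are always synchronous). Given a seed the
    output is bit-reproducible.
    """
    n_async = (int(round(spec.asynchrony_fraction * spec.n_subjects))
               if spec.group == "ds" else 0)
    rng = np.random.default_rng(spec.seed)
    iqs = spec.iq_mean + spec.iq_sd * rng.standard_normal(spec.n_subjects)
    base_coupling = dict(spec.coupling or DEFAULT_COUPLING[spec.group])
    base_carrier = dict(spec.carrier or DEFAULT_CARRIER[spec.group])
    out = []
    for i in range(spec.n_subjects):
        asynchronous = i < n_async
        kind = ("control" if spec.group == "control" else
                "ds_asynchronous" if asynchronous else "ds_synchronous")
        regions = default_profile(kind)
        iq_dev = float(iqs[i] - spec.iq_mean)
        slow = max(0.1, 1.0 + spec.iq_model.get("slow_power_slope", 0.0)
                   * iq_dev)
        for r in regions.values():
            r.band_power["delta"] *= slow
            r.band_power["theta"] *= slow
        carrier = dict(base_carrier)
        carrier["PO"] = float(np.clip(
            carrier["PO"] * (1.0 + spec.iq_model.get("po_carrier_slope", 0.0)
                             * iq_dev),
            0.0, (1.0 - base_coupling["PO"]) / 4.0))
        sid = f"{spec.group}{i + 1:03d}"
        rec = generate_subject(
            regions, duration_s=spec.duration_s, fs=spec.fs,
            seed=spec.seed + 1000 + i, coupling=base_coupling,
            carrier=carrier, lag_ms=spec.lag_ms, noise_uv=spec.noise_uv,
            subject_id=sid)
        truth = SubjectTruth(
            subject_id=sid, group=spec.group,
            sync_class="asynchronous" if asynchronous else "synchronous",
            iq=float(iqs[i]), seed=spec.seed + 1000 + i, lag_ms=spec.lag_ms,
            alpha_peaks={k: r.alpha_peak for k, r in regions.items()},
            band_power={k: dict(r.band_power) for k, r in regions.items()},
            coupling=dict(base_coupling), carrier=carrier)
        out.append((rec, truth))
    return out


# ---------------------------------------------------------------------------
# Sidecar and EDF output


def write_sidecars(truths: list[SubjectTruth], path: str | Path) -> None:
    """Tab-separated ground-truth table, one row per subject.

    Nested mappings are flattened into dotted column names; floats are
    written with shortest-round-trip precision so the table reads back
    bit-identical.
    """
    rows = []
    for t in truths:
        d = asdict(t)
        flat = {}
        for k, v in d.items():
            if isinstance(v, dict):
                for k2, v2 in v.items():
                    if isinstance(v2, dict):
                        for k3, v3 in v2.items():
                            flat[f"{k}.{k2}.{k3}"] = v3
                    else:
                        flat[f"{k}.{k2}"] = v2
            else:
                flat[k] = v
        rows.append(flat)
    cols = list(rows[0])
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(repr(row[c]) if isinstance(row[c], float)
                               else str(row[c]) for c in cols) + "\n")


def read_sidecars(path: str | Path) -> list[SubjectTruth]:
    with open(path) as fh:
        cols = fh.readline().rstrip("\n").split("\t")
        truths = []
        for line in fh:
            vals = line.rstrip("\n").split("\t")
            flat = dict(zip(cols, vals))
            nested: dict = {}
            for k, v in flat.items():
                parts = k.split(".")
                d = nested
                for p in parts[:-1]:
                    d = d.setdefault(p, {})
                d[parts[-1]] = v
            truths.append(SubjectTruth(
                subject_id=nested["subject_id"],
                group=nested["group"],
                sync_class=nested["sync_class"],
                iq=float(nested["iq"]),
                seed=int(nested["seed"]),
                lag_ms=float(nested["lag_ms"]),
                alpha_peaks={k: float(v)
                             for k, v in nested["alpha_peaks"].items()},
                band_power={k: {b: float(p) for b, p in v.items()}
                            for k, v in nested["band_power"].items()},
                coupling={k: float(v)
                          for k, v in nested["coupling"].items()},
                carrier={k: float(v)
                         for k, v in nested["carrier"].items()}))
    return truths


def write_edf(rec: Recording, path: str | Path) -> None:
    """Write a minimal EDF file (16-bit, one 1-s data record per second).

    Physical range is set per channel from the data extrema, so the
    quantization step is range/65535.
    """
    fs = int(round(rec.fs))
    n_rec = rec.n_samples // fs
    if n_rec * fs != rec.n_samples:
        raise ValidationError("EDF export needs a whole number of seconds")
    ns = len(rec.electrodes)

    def pad(text: str, width: int) -> bytes:
        return text[:width].ljust(width).encode("ascii")

    header = b"".join([
        pad("0", 8),
        pad(f"X X X {rec.subject_id}", 80),
        pad("Startdate X X X X", 80),
        pad("01.01.00", 8), pad("00.00.00", 8),
        pad(str(256 * (ns + 1)), 8),
        pad("", 44),
        pad(str(n_rec), 8),
        pad("1", 8),
        pad(str(ns), 4),
    ])
    pmins = rec.data.min(axis=1)
    pmaxs = rec.data.max(axis=1)
    # avoid a zero physical span for constant channels
    span0 = pmaxs - pmins == 0
    pmaxs = np.where(span0, pmins + 1.0, pmaxs)
    fields = [
        [pad(f"EEG {e}", 16) for e in rec.electrodes],
        [pad("AgAgCl electrode", 80)] * ns,
        [pad("uV", 8)] * ns,
        [pad(f"{v:.6g}", 8) for v in pmins],
        [pad(f"{v:.6g}", 8) for v in pmaxs],
        [pad("-32768", 8)] * ns,
        [pad("32767", 8)] * ns,
        [pad("", 80)] * ns,
        [pad(str(fs), 8)] * ns,
        [pad("", 32)] * ns,
    ]
    scale = (pmaxs - pmins) / 65535.0
    digital = np.round((rec.data - pmins[:, None]) / scale[:, None]
                       - 32768.0).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        for fld in fields:
            fh.write(b"".join(fld))
        for r in range(n_rec):
            block = digital[:, r * fs:(r + 1) * fs]
            fh.write(block.tobytes())


def write_manifest(spec: CohortSpec, path: str | Path) -> None:
    """Cohort configuration as YAML."""
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(asdict(spec), fh, sort_keys=False)


def read_manifest(path: str | Path) -> CohortSpec:
    import yaml

    with open(path) as fh:
        return CohortSpec(**yaml.safe_load(fh))
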