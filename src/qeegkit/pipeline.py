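"""Per-subject analysis orchestration and cohort-level comparison.

``analyze_subject`` runs the fixed stage order

    read -> duration gate -> band-pass filter -> montage -> windows ->
    spectra -> band areas / SSE -> synchronization -> PDR profile

and returns every intermediate the cohort statistics need. All parameters
live in :class:`AnalysisConfig`; given the same input and configuration the
result is deterministic.

``compare_cohorts`` reproduces the group-level analyses: per-lobe band
structure (logPS) and spectral entropy comparisons, regional
synchronization (Pearson and per-band coherence), interhemispheric
cross-correlation, the posterior-rhythm summary with the
synchronous/asynchronous split, and optional IQ polynomial regressions and
a normative-age fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import montage as mg
from . import spectral as sp
from . import sync as sy
from . import pdr as pdrmod
from . import stats as st
from .errors import DurationError, QeegError
from .topography import LOBES, RegionMap
from .spectral import BANDS


@dataclass
class AnalysisConfig:
    """All tunable parameters of the per-subject pipeline."""

    montage: str = "bipolar"            # {bipolar, avg}
    filter_low: float = 0.5             # Hz
    filter_high: float = 30.0           # Hz
    filter_order: int = 6
    zero_phase: bool = True
    win_s: float = 1.0
    overlap: float = 0.10
    min_duration_s: float = 120.0
    allow_short: bool = False
    peak_band: tuple[float, float] = (8.0, 13.0)
    max_lag_ms: float = 50.0
    strict_nine_term: bool = False
    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(BANDS))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "bands" in raw:
            raw["bands"] = {k: tuple(v) for k, v in raw["bands"].items()}
        if "peak_band" in raw:
            raw["peak_band"] = tuple(raw["peak_band"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        raw = asdict(self)
        raw["peak_band"] = list(self.peak_band)
        raw["bands"] = {k: list(v) for k, v in self.bands.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass
class SubjectResult:
    """Everything the cohort statistics consume for one subject."""

    subject_id: str
    montage: str
    bands: pd.DataFrame                      # channel, band, area, logps
    sse: dict[str, float]                    # channel -> SSE
    region_logps: dict[tuple[str, str], float]   # (region, band) -> logPS
    region_sse: dict[str, float]             # region -> SSE
    sync: sy.SyncResult | None
    region_sync: dict[tuple[str, str], float]    # (region, metric) -> value
    pdr: pdrmod.PDRProfile | None
    qc: dict[str, float]

    def tidy_bands(self) -> pd.DataFrame:
        df = self.bands.copy()
        df.insert(0, "subject", self.subject_id)
        return df

    def tidy_regions(self) -> pd.DataFrame:
        rows = [{"subject": self.subject_id, "region": r, "band": b,
                 "logps": v} for (r, b), v in self.region_logps.items()]
        return pd.DataFrame(rows)


def analyze_subject(source, config: AnalysisConfig | None = None,
                    subject_id: str | None = None) -> SubjectResult:
    """Run the full per-subject pipeline on a path or Recording."""
    cfg = config or AnalysisConfig()
    if isinstance(source, (str, Path)):
        rec = mg.read_recording(source, subject_id=subject_id)
    else:
        rec = source
    if rec.duration_s < cfg.min_duration_s and not cfg.allow_short:
        raise DurationError(
            f"stage duration-gate: {rec.duration_s:.1f} s retained, "
            f"minimum is {cfg.min_duration_s:.0f} s (allow_short overrides)")

    try:
        rec = mg.bandpass(rec, cfg.filter_low, cfg.filter_high,
                          cfg.filter_order, cfg.zero_phase)
        if cfg.montage == "bipolar":
            derived: mg.Recording | mg.BipolarRecord = mg.to_bipolar(rec)
            labels = derived.labels
        elif cfg.montage == "avg":
            derived = mg.to_avg(rec)
            labels = list(derived.electrodes)
        else:
            raise QeegError(f"unknown montage {cfg.montage!r}")

        windows = sp.segment_windows(derived.segments, derived.fs,
                                     cfg.win_s, cfg.overlap)
        spec = sp.power_spectrum(derived.data, derived.fs, windows,
                                 labels=labels)
        bands_df = sp.band_powers(spec, cfg.bands)
        sse = dict(zip(labels, sp.spectral_entropy(spec)))

        region_map = RegionMap(montage=cfg.montage,
                               strict_nine_term=cfg.strict_nine_term)
        region_logps: dict[tuple[str, str], float] = {}
        for band in cfg.bands:
            sub = bands_df[bands_df["band"] == band]
            values = dict(zip(sub["channel"], sub["logps"]))
            for region, chans in region_map.regions.items():
                region_logps[(region, band)] = float(
                    np.mean([values[c] for c in chans]))
        region_sse = {region: float(np.mean([sse[c] for c in chans]))
                      for region, chans in region_map.regions.items()}

        sync_res: sy.SyncResult | None = None
        region_sync: dict[tuple[str, str], float] = {}
        pdr_prof: pdrmod.PDRProfile | None = None
        if cfg.montage == "bipolar":
            sync_res = sy.sync_summary(derived, windows, cfg.max_lag_ms)
            for region, chans in region_map.regions.items():
                region_sync[(region, "pearson")] = sy.region_sync(
                    sync_res.pearson, labels, chans)
                for band, mat in sync_res.coh.items():
                    region_sync[(region, f"coh_{band}")] = sy.region_sync(
                        mat, labels, chans)
            pdr_prof = pdrmod.pdr_profile(spec, cfg.peak_band)

        qc = {"n_windows": float(len(windows)),
              "skipped_windows": float(sync_res.skipped if sync_res else 0),
              "duration_s": float(rec.duration_s)}
        return SubjectResult(rec.subject_id, cfg.montage, bands_df, sse,
                             region_logps, region_sse, sync_res,
                             region_sync, pdr_prof, qc)
    except QeegError:
        raise
    except Exception as exc:  # annotate unexpected stage failures
        raise QeegError(f"pipeline failed for {rec.subject_id}: "
                        f"{exc}") from exc


# ---------------------------------------------------------------------------
# Cohort comparison


@dataclass
class CohortReport:
    """Group-level summary tables.

    ``band_tests``/``sse_tests``/``sync_tests`` hold per-region comparisons
    with Bonferroni-corrected p values (family = one variable across the six
    lobes); ``pdr_summary`` and ``async_counts`` summarize the posterior
    rhythm; ``cc_summary`` the interhemispheric cross-correlation;
    ``iq_regressions`` and ``normative_fit`` are filled when the inputs are
    provided.
    """

    band_tests: pd.DataFrame
    sse_tests: pd.DataFrame
    sync_tests: pd.DataFrame
    pdr_summary: pd.DataFrame
    async_counts: dict[str, int]
    cc_summary: pd.DataFrame
    iq_regressions: pd.DataFrame | None = None
    normative_fit: pdrmod.NormativeFit | None = None


def _collect(results: Sequence[SubjectResult], key,
             table: str) -> np.ndarray:
    if table == "logps":
        return np.array([r.region_logps[key] for r in results])
    if table == "sse":
        return np.array([r.region_sse[key] for r in results])
    return np.array([r.region_sync[key] for r in results])


def _compare_family(results_a, results_b, keys, table, design):
    rows = []
    for key in keys:
        a = _collect(results_a, key, table)
        b = _collect(results_b, key, table)
        rep = st.group_compare(a, b, design=design)
        region = key[0] if isinstance(key, tuple) else key
        rows.append({
            "region": region,
            "variable": key[1] if isinstance(key, tuple) else table,
            "mean_a": float(a.mean()), "mean_b": float(b.mean()),
            "direction": int(np.sign(a.mean() - b.mean())),
            "test": rep.test, "statistic": rep.statistic, "p": rep.p,
            "n_a": len(a), "n_b": len(b)})
    df = pd.DataFrame(rows)
    df["p_adj"] = st.bonferroni(df["p"])
    df["significant"] = df["p_adj"] < 0.05
    return df


def compare_cohorts(results_a: Sequence[SubjectResult],
                    results_b: Sequence[SubjectResult],
                    metadata: pd.DataFrame | None = None,
                    design: str = "independent",
                    normative: Callable | None = None,
                    iq_group: str = "a") -> CohortReport:
    """Compare two analyzed cohorts (a vs b; direction is a minus b).

    ``metadata`` may carry columns ``subject``, ``iq`` and ``age``; IQ
    regressions are fitted within ``iq_group`` (cohort "a" by default) for
    every lobe metric, and the normative-age fit uses (age, alphao) points
    of the same group when a normative PDR(age) callable is given.

    A ``paired`` design requires both cohorts ordered by matched subject.
    """
    if design == "paired" and len(results_a) != len(results_b):
        raise QeegError("paired design with unmatched cohort sizes")
    bands = list(BANDS)
    band_keys = [(lobe, band) for band in bands for lobe in LOBES]
    band_tests = _compare_family(results_a, results_b, band_keys, "logps",
                                 design)
    # Bonferroni family: one band across the six lobes
    for band in bands:
        m = band_tests["variable"] == band
        band_tests.loc[m, "p_adj"] = st.bonferroni(band_tests.loc[m, "p"])
    band_tests["significant"] = band_tests["p_adj"] < 0.05

    sse_tests = _compare_family(results_a, results_b, list(LOBES), "sse",
                                design)
    metrics = ["pearson"] + [f"coh_{b}" for b in bands]
    sync_keys = [(lobe, m) for m in metrics for lobe in LOBES]
    sync_tests = _compare_family(results_a, results_b, sync_keys, "sync",
                                 design)
    for metric in metrics:
        m = sync_tests["variable"] == metric
        sync_tests.loc[m, "p_adj"] = st.bonferroni(sync_tests.loc[m, "p"])
    sync_tests["significant"] = sync_tests["p_adj"] < 0.05

    pdr_rows, async_counts = [], {}
    for name, results in (("a", results_a), ("b", results_b)):
        profs = [r.pdr for r in results if r.pdr is not None]
        async_counts[name] = sum(
            1 for p in profs if p.sync_class == "asynchronous")
        for stat_name, vals in (
                ("alphap", [p.alphap for p in profs]),
                ("alphao", [p.alphao for p in profs]),
                ("ihDif", [p.ihDif for p in profs]),
                ("sd5", [p.sd5 for p in profs])):
            pdr_rows.append({
                "cohort": name, "metric": stat_name,
                "mean": float(np.mean(vals)), "sd": float(np.std(vals,
                                                                 ddof=1))
                if len(vals) > 1 else 0.0, "n": len(vals)})
    pdr_summary = pd.DataFrame(pdr_rows)

    cc_rows = []
    for name, results in (("a", results_a), ("b", results_b)):
        for lobe in sy.CC_PAIRS:
            ccs = [r.sync.cc_pairs[lobe] for r in results
                   if r.sync is not None]
            if not ccs:
                continue
            cc_rows.append({
                "cohort": name, "pair": lobe,
                "cc_max": float(np.mean([c for c, _ in ccs])),
                "lag_ms": float(np.mean([l for _, l in ccs]))})
    cc_summary = pd.DataFrame(cc_rows)

    iq_df = None
    norm_fit = None
    if metadata is not None:
        results = results_a if iq_group == "a" else results_b
        meta = metadata.set_index("subject")
        if "iq" in meta.columns:
            iq_rows = []
            iq = np.array([meta.loc[r.subject_id, "iq"] for r in results],
                          dtype=float)
            for key in band_keys:
                y = _collect(results, key, "logps")
                iq_rows.append(_iq_fit_row(iq, y, key[0], key[1]))
            for key in sync_keys:
                y = _collect(results, key, "sync")
                iq_rows.append(_iq_fit_row(iq, y, key[0], key[1]))
            iq_df = pd.DataFrame(iq_rows)
        if normative is not None and "age" in meta.columns:
            pts = [(float(meta.loc[r.subject_id, "age"]), r.pdr.alphao)
                   for r in results if r.pdr is not None]
            norm_fit = pdrmod.fit_normative_age(pts, normative)

    return CohortReport(band_tests, sse_tests, sync_tests, pdr_summary,
                        async_counts, cc_summary, iq_df, norm_fit)


def _iq_fit_row(iq, y, region, metric) -> dict:
    degree = st.select_degree(iq, y)
    fit = st.fit_polynomial(iq, y, degree)
    return {"region": region, "metric": metric, "degree": degree,
            "r": fit.r, "significant": fit.significant,
            "coefficients": list(np.round(fit.coefficients, 10)),
            "critical_r": st.critical_r(fit.n)}
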