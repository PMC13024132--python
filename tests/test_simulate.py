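import numpy as np
import pytest

import qeegkit as qk
from qeegkit.errors import ConfigurationError, ValidationError
from qeegkit.simulate import (
    CARRIER_GAIN,
    ELECTRODE_REGION,
    default_profile,
)
from qeegkit.spectral import BANDS, band_area


def _beta_regions(power=40.0):
    """Broadband-free profile concentrated in beta for lag tests."""
    out = {}
    for lobe in ("F", "PO", "T"):
        for side in ("left", "right", "mid"):
            if lobe == "T" and side == "mid":
                continue
            out[f"{lobe}_{side}"] = qk.RegionBandSpec(
                lobe=lobe, side=side,
                band_power={"delta": 5.0, "theta": 5.0, "alpha": 0.0,
                            "beta": power})
    return out


class TestGenerateSubject:
    def test_zero_power_spec_gives_zero_record(self):
        regions = {k: qk.RegionBandSpec(lobe=v.lobe, side=v.side,
                                        band_power={})
                   for k, v in default_profile("control").items()}
        rec = qk.generate_subject(regions, duration_s=2.0, seed=0)
        assert np.abs(rec.data).max() == 0.0

    def test_validation_errors(self):
        with pytest.raises(ValidationError):
            qk.RegionBandSpec(lobe="F", side="left",
                              band_power={"delta": -1.0})
        with pytest.raises(ValidationError):
            qk.RegionBandSpec(lobe="F", side="left",
                              band_power={"alpha": 5.0}, alpha_peak=6.0)
        regions = default_profile("control")
        del regions["PO_left"]
        with pytest.raises(ConfigurationError, match="PO_left"):
            qk.generate_subject(regions, duration_s=2.0)
        with pytest.raises(ConfigurationError):
            qk.generate_subject(default_profile("control"), duration_s=2.0,
                                coupling={"PO": 0.9}, carrier={"PO": 0.2})

    def test_band_powers_match_targets(self):
        # full-length periodogram band areas vs generator targets;
        # measured through the spectral module on a 120-s record
        rec = qk.generate_subject(default_profile("control"),
                                  duration_s=120.0, seed=1)
        spec = qk.power_spectrum(rec.data, rec.fs, [(0, rec.n_samples)],
                                 labels=rec.electrodes)
        targets = default_profile("control")
        for ch in ("P3", "F3", "T5", "Cz"):
            lobe, side = ELECTRODE_REGION[ch]
            want = targets[f"{lobe}_{side}"].band_power
            for band, (lo, hi) in BANDS.items():
                got = band_area(spec, lo, hi, ch)
                assert abs(got - want[band]) / want[band] < 0.10, (ch, band)

    def test_referential_coupling_matches_model(self):
        # pairs with a zero carrier-gain product see exactly the common
        # share c; others see c + g_i g_j w (1 - f_alpha)
        rec = qk.generate_subject(default_profile("control"),
                                  duration_s=120.0, seed=2,
                                  coupling={"F": 0.5, "PO": 0.5, "T": 0.5},
                                  carrier={"F": 0.08, "PO": 0.08,
                                           "T": 0.08})
        r = np.corrcoef(rec.channel("C3"), rec.channel("P3"))[0, 1]
        assert r == pytest.approx(0.5, abs=0.06)
        powers = default_profile("control")["F_left"].band_power
        f_alpha = powers["alpha"] / sum(powers.values())
        g = CARRIER_GAIN["Fp1"] * CARRIER_GAIN["F3"]
        pred = 0.5 + g * 0.08 * (1 - f_alpha)
        robs = np.corrcoef(rec.channel("Fp1"), rec.channel("F3"))[0, 1]
        assert robs == pytest.approx(pred, abs=0.06)

    def test_injected_lag_recovered_to_one_sample(self):
        lag_samples = 2
        rec = qk.generate_subject(
            _beta_regions(), duration_s=120.0, seed=3,
            coupling={"F": 0.7, "PO": 0.7, "T": 0.7},
            carrier={"F": 0.05, "PO": 0.05, "T": 0.05},
            lag_ms=lag_samples * 1000.0 / 512.0)
        cc, lag = qk.cross_correlation_lag(rec.channel("P3"),
                                           rec.channel("P4"), rec.fs)
        assert abs(lag - lag_samples * 1000.0 / 512.0) <= 1000.0 / 512.0
        assert cc > 0.5

    def test_alpha_peak_split_reaches_pdr(self):
        rec = qk.generate_subject(default_profile("ds_asynchronous"),
                                  duration_s=120.0, seed=4)
        prof = qk.analyze_subject(rec).pdr
        assert prof.pPS["P3-O1"] == pytest.approx(9.0, abs=0.5)
        assert prof.pPS["P4-O2"] == pytest.approx(10.5, abs=0.5)
        assert prof.sync_class == "asynchronous"


class TestGenerateCohort:
    def test_deterministic_byte_identical(self):
        spec = qk.CohortSpec(n_subjects=1, group="ds", duration_s=2.0,
                             seed=5)
        a = qk.generate_cohort(spec)[0][0]
        b = qk.generate_cohort(spec)[0][0]
        assert a.data.tobytes() == b.data.tobytes()

    def test_exact_asynchronous_count(self):
        spec = qk.CohortSpec(n_subjects=22, group="ds",
                             asynchrony_fraction=8 / 22, duration_s=2.0,
                             seed=6)
        cohort = qk.generate_cohort(spec)
        flagged = [t for _, t in cohort if t.sync_class == "asynchronous"]
        assert len(flagged) == 8

    def test_controls_never_asynchronous(self):
        spec = qk.CohortSpec(n_subjects=4, group="control", duration_s=2.0,
                             asynchrony_fraction=0.5, seed=7)
        assert all(t.sync_class == "synchronous"
                   for _, t in qk.generate_cohort(spec))

    def test_sidecar_roundtrip(self, tmp_path):
        spec = qk.CohortSpec(n_subjects=3, group="ds", duration_s=2.0,
                             asynchrony_fraction=1 / 3, seed=8)
        truths = [t for _, t in qk.generate_cohort(spec)]
        path = tmp_path / "sidecars.tsv"
        qk.write_sidecars(truths, path)
        assert qk.read_sidecars(path) == truths

    def test_manifest_roundtrip(self, tmp_path):
        from qeegkit.simulate import read_manifest, write_manifest

        spec = qk.CohortSpec(n_subjects=5, group="control", seed=9)
        path = tmp_path / "manifest.yaml"
        write_manifest(spec, path)
        assert read_manifest(path) == spec
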