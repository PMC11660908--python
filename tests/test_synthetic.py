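"""Synthetic signal generator and cohort construction: ground-truth recovery."""

import numpy as np
import pytest

import megpipe as mp
from megpipe.connectivity import analytic_epoch, bandpass

from conftest import FS


def _rel_power(x, band, fs=FS):
    _, rel = mp.band_powers(mp.compute_power_spectrum(x, fs))
    return rel[band].to_numpy()


class TestRegionSignal:
    def test_single_band_construction(self):
        spec = mp.SignalSpec(band_weights={"theta": 1.0}, pink_weight=0.0,
                             n_epochs=2, n_samples=4096)
        x = mp.make_region_signal(spec, 0)
        assert np.all(_rel_power(x, "theta") > 0.9)

    def test_invalid_band_name_rejected_with_name(self):
        with pytest.raises(ValueError, match="sigma"):
            mp.SignalSpec(band_weights={"sigma": 1.0})

    def test_seed_contract(self):
        spec = mp.SignalSpec(n_epochs=2, n_samples=2048)
        a = mp.make_region_signal(spec, 1)
        b = mp.make_region_signal(spec, 2)
        assert not np.allclose(a, b)  # distinct samples
        # same expected band-power profile within Monte-Carlo tolerance
        ra = _rel_power(a.reshape(1, -1), "alpha2")
        rb = _rel_power(b.reshape(1, -1), "alpha2")
        assert ra[0] == pytest.approx(rb[0], abs=0.05)
        assert np.array_equal(a, mp.make_region_signal(spec, 1))  # reproducible

    def test_peak_frequency_recovered(self):
        spec = mp.SignalSpec(peak_freq_hz=10.0, n_epochs=6, n_samples=4096)
        x = mp.make_region_signal(spec, 3)
        ps = mp.compute_power_spectrum(x, FS)
        peaks = mp.peak_frequency(ps)
        # peak component occupies 10 +- 0.25 Hz; the argmax must land there
        assert np.all(np.abs(peaks - 10.0) <= 0.3)

    def test_zero_mean_per_epoch(self):
        x = mp.make_region_signal(mp.SignalSpec(n_epochs=3, n_samples=1024), 0)
        assert np.allclose(x.mean(axis=1), 0.0, atol=1e-12)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            mp.SignalSpec(band_weights={"theta": 0.0})

    @pytest.mark.parametrize("weight_grid", [(0.3, 0.6, 1.2)])
    def test_theta_power_monotone_in_theta_weight(self, weight_grid):
        for seed in range(3):
            means = []
            for w in weight_grid:
                spec = mp.SignalSpec(
                    band_weights={"theta": w, "alpha2": 0.7, "beta": 0.5},
                    n_epochs=2, n_samples=2048,
                )
                x = mp.make_region_signal(spec, seed)
                means.append(_rel_power(x, "theta").mean())
            assert means[0] < means[1] < means[2]


class TestCoupling:
    def test_identity_coupling_is_identity(self, rng):
        signals = rng.standard_normal((3, 2, 1024))
        cpl = mp.CouplingSpec(phase_graph=np.zeros((3, 3)),
                              envelope_graph=np.zeros((3, 3)))
        out = mp.apply_coupling(signals, cpl, 0, fs_hz=FS)
        assert np.array_equal(out, signals)

    def test_phase_edge_pli_approaches_one_as_noise_vanishes(self):
        # strong edge, almost no intrinsic signal -> injected lagged
        # oscillator dominates and PLI -> 1
        spec = mp.SignalSpec(band_weights={"theta": 0.01}, pink_weight=0.0,
                             n_epochs=1, n_samples=4096)
        g = np.zeros((2, 2)); g[0, 1] = g[1, 0] = 1.0
        cpl = mp.CouplingSpec(phase_graph=g, envelope_graph=np.zeros((2, 2)))
        epochs = mp.simulate_subject(spec, cpl, 0)
        m = mp.connectivity_matrix(epochs, "pli", "theta", FS).values
        assert m[0, 1] > 0.98

    def test_phase_coupling_monotone_in_weight(self):
        spec = mp.SignalSpec(n_epochs=2, n_samples=2048)
        vals = []
        for w in (0.0, 0.5, 1.0):
            g = np.zeros((2, 2)); g[0, 1] = g[1, 0] = w
            cpl = mp.CouplingSpec(phase_graph=g, envelope_graph=np.zeros((2, 2)))
            acc = [mp.connectivity_matrix(mp.simulate_subject(spec, cpl, s),
                                          "pli", "theta", FS).values[0, 1]
                   for s in range(3)]
            vals.append(np.mean(acc))
        assert vals[0] < vals[1] < vals[2]

    def test_envelope_edge_raises_aecc_not_pli(self):
        spec = mp.SignalSpec(n_epochs=3, n_samples=4096)
        g = np.zeros((2, 2)); g[0, 1] = g[1, 0] = 0.8
        cpl = mp.CouplingSpec(phase_graph=np.zeros((2, 2)), envelope_graph=g)
        aecc_vals, pli_vals = [], []
        for seed in range(5):
            epochs = mp.simulate_subject(spec, cpl, seed)
            aecc_vals.append(
                mp.connectivity_matrix(epochs, "aecc", "beta", FS).values[0, 1])
            pli_vals.append(
                mp.connectivity_matrix(epochs, "pli", "theta", FS).values[0, 1])
        assert np.mean(aecc_vals) > 0.55
        assert np.mean(pli_vals) < 0.15  # PLI stays at its sampling null

    def test_non_symmetric_graph_rejected(self):
        g = np.zeros((2, 2)); g[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            mp.CouplingSpec(phase_graph=g, envelope_graph=np.zeros((2, 2)))

    def test_singular_leakage_rejected(self):
        with pytest.raises(ValueError, match="invertible"):
            mp.CouplingSpec(phase_graph=np.zeros((2, 2)),
                            envelope_graph=np.zeros((2, 2)),
                            leakage_mix=np.zeros((2, 2)))

    def test_null_calibration(self):
        # zero coupling: PLI off-diagonals small, AECc near 0.5
        spec = mp.SignalSpec(n_epochs=1, n_samples=4096)
        cpl = mp.CouplingSpec(phase_graph=np.zeros((3, 3)),
                              envelope_graph=np.zeros((3, 3)))
        plis, aeccs = [], []
        iu = np.triu_indices(3, 1)
        for seed in range(20):
            epochs = mp.simulate_subject(spec, cpl, seed)
            plis.append(mp.connectivity_matrix(epochs, "pli", "theta", FS).values[iu])
            aeccs.append(mp.connectivity_matrix(epochs, "aecc", "alpha", FS).values[iu])
        assert np.mean(plis) < 0.1
        assert np.mean(aeccs) == pytest.approx(0.5, abs=0.02)


class TestCohort:
    def test_manifest_requires_three_matched_controls(self):
        subjects = [
            mp.Subject("c0", "carrier", 50.0),
            mp.Subject("k0", "control", 50.0, matched_carrier_id="c0"),
            mp.Subject("k1", "control", 51.0, matched_carrier_id="c0"),
        ]
        with pytest.raises(ValueError, match="exactly 3"):
            mp.CohortManifest(subjects=subjects)

    def test_manifest_roundtrip_through_frame(self, small_manifest):
        df = small_manifest.to_frame()
        back = mp.CohortManifest.from_frame(df, seed=small_manifest.seed)
        assert [s.id for s in back.subjects] == [s.id for s in small_manifest.subjects]
        assert back.onset_records.keys() == small_manifest.onset_records.keys()

    def test_cohort_generation_is_byte_identical(self, tmp_path, small_manifest):
        spec = mp.SignalSpec(n_epochs=1, n_samples=512)
        cpl = mp.default_coupling(n_regions=4, seed=1)
        shift = mp.CarrierShift()
        p1 = mp.make_cohort(small_manifest, spec, shift, cpl, tmp_path / "a")
        p2 = mp.make_cohort(small_manifest, spec, shift, cpl, tmp_path / "b")
        for f1 in sorted((tmp_path / "a").iterdir()):
            f2 = tmp_path / "b" / f1.name
            assert f1.read_bytes() == f2.read_bytes()

    def test_carrier_theta_shift_raises_group_median(self, tmp_path, small_manifest):
        spec = mp.SignalSpec(n_epochs=2, n_samples=2048)
        cpl = mp.default_coupling(n_regions=4, seed=0)
        shift = mp.CarrierShift(theta_factor=1.5)
        mp.make_cohort(small_manifest, spec, shift, cpl, tmp_path)
        rel = {}
        for s in small_manifest.subjects:
            es = mp.read_epochs(tmp_path, s.id, FS)
            med = np.median([
                _rel_power(epoch, "theta").mean() for epoch in es.data
            ])
            rel.setdefault(s.group, []).append(med)
        assert np.median(rel["carrier"]) > np.median(rel["control"])

    def test_hub_attenuation_drives_group_hdi_negative(self, tmp_path, small_manifest):
        spec = mp.SignalSpec(n_epochs=2, n_samples=2048)
        cpl = mp.default_coupling(n_regions=10, seed=2)
        shift = mp.CarrierShift(hub_attenuation=0.3)
        mp.make_cohort(small_manifest, spec, shift, cpl, tmp_path)
        degs = {"carrier": [], "control": []}
        for s in small_manifest.subjects:
            es = mp.read_epochs(tmp_path, s.id, FS)
            prof = mp.degrees(mp.connectivity_matrix(es.data, "aecc", "beta", FS))
            degs[s.group].append(prof.degree)
        result = mp.group_hdi(degs["carrier"], degs["control"])
        assert result.slope < 0
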