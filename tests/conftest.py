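import numpy as np
import pytest

import megpipe as mp

FS = 312.5
N = 4096


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def sinusoid(freq_hz, n=N, fs=FS, phase=0.0, amplitude=1.0, snap=True):
    """Test tone; by default snapped to the FFT grid (integer cycles per
    epoch) so its spectrum is a single line without leakage."""
    if snap:
        freq_hz = round(freq_hz * n / fs) * fs / n
    t = np.arange(n) / fs
    return amplitude * np.sin(2 * np.pi * freq_hz * t + phase)


@pytest.fixture
def small_manifest():
    """2 carriers with 3 matched controls each."""
    return mp.default_manifest(n_carriers=2, seed=7)


@pytest.fixture(scope="session")
def tiny_cohort_report(tmp_path_factory):
    """End-to-end run on a small synthetic cohort (shared across tests)."""
    out = tmp_path_factory.mktemp("cohort")
    spec = mp.SignalSpec(n_epochs=3, n_samples=1024)
    manifest = mp.default_manifest(n_carriers=3, seed=11)
    coupling = mp.default_coupling(n_regions=8, seed=11)
    shift = mp.CarrierShift.slowing_contrast()
    manifest_path = mp.make_cohort(manifest, spec, shift, coupling, out / "data")
    config = mp.RunConfig(
        n_epochs_required=3, epoch_samples=1024, n_perm=200, seed=5,
        out_dir=str(out / "report"),
    )
    report = mp.run_all(config, manifest_path, out / "data")
    return {"report": report, "out": out, "config": config,
            "manifest_path": manifest_path}
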