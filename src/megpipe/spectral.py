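"""Spectral power analysis for source-level MEG time series.

Per epoch and region, a raw FFT periodogram is restricted to the broad band
0.5–48 Hz and summarised as absolute and relative power in six canonical
frequency bands (delta, theta, alpha1, alpha2, beta, gamma) plus the peak
frequency in the extended alpha window (4–13 Hz).  Values are averaged across
epochs to one value per region per subject, and across regions for whole-brain
summaries.

Relative power in a band is the power in that band divided by the total power
over 0.5–48 Hz, so the six relative powers partition unity.  Band intervals
are half-open [low, high) with the upper edge of the last band inclusive,
which makes the partition exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BandScheme",
    "PowerSpectrum",
    "SpectralSummary",
    "compute_power_spectrum",
    "band_powers",
    "peak_frequency",
    "aggregate",
    "subject_spectral_summary",
    "BROAD_BAND",
    "ALPHA_WINDOW",
]

#: Broad band analysed, Hz.
BROAD_BAND = (0.5, 48.0)
#: Extended alpha window for the peak frequency, Hz.
ALPHA_WINDOW = (4.0, 13.0)

_DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha1": (8.0, 10.0),
    "alpha2": (10.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 48.0),
}


@dataclass(frozen=True)
class BandScheme:
    """Contiguous, non-overlapping frequency bands partitioning the broad band.

    Intervals are half-open ``[low, high)``; the upper edge of the final band
    is inclusive so that a bin exactly at the top of the broad band is counted.
    """

    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_BANDS)
    )

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("band scheme must contain at least one band")
        edges = list(self.bands.values())
        for (name_a, (_, hi)), (name_b, (lo, _)) in zip(
            list(self.bands.items())[:-1], list(self.bands.items())[1:]
        ):
            if not np.isclose(hi, lo):
                raise ValueError(
                    f"bands must be contiguous: {name_a} ends at {hi} Hz "
                    f"but {name_b} starts at {lo} Hz"
                )
        for name, (lo, hi) in self.bands.items():
            if hi <= lo:
                raise ValueError(f"band {name!r} has empty interval [{lo}, {hi})")

    @property
    def names(self) -> list[str]:
        return list(self.bands)

    @property
    def low(self) -> float:
        return next(iter(self.bands.values()))[0]

    @property
    def high(self) -> float:
        return list(self.bands.values())[-1][1]

    def mask(self, freqs: np.ndarray, name: str) -> np.ndarray:
        """Boolean mask of bins whose centre falls in band ``name``."""
        lo, hi = self.bands[name]
        m = (freqs >= lo) & (freqs < hi)
        if name == list(self.bands)[-1]:  # inclusive top edge of the last band
            m |= np.isclose(freqs, hi)
        return m


@dataclass
class PowerSpectrum:
    """Periodogram of one epoch, restricted to the broad band.

    Attributes
    ----------
    freqs_hz : (n_bins,) strictly increasing bin centres, constant spacing.
    power : (n_regions, n_bins) non-negative spectral power.
    df_hz : bin spacing, ``fs / n_samples``.
    """

    freqs_hz: np.ndarray
    power: np.ndarray
    df_hz: float

    def __post_init__(self) -> None:
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        self.power = np.atleast_2d(np.asarray(self.power, dtype=float))
        if self.power.shape[-1] != self.freqs_hz.size:
            raise ValueError("power and freqs_hz bin counts differ")
        if np.any(self.power < 0):
            raise ValueError("spectral power must be non-negative")
        if self.freqs_hz.size > 1:
            d = np.diff(self.freqs_hz)
            if np.any(d <= 0) or not np.allclose(d, self.df_hz, rtol=1e-6):
                raise ValueError("freqs_hz must increase with constant spacing df_hz")

    @property
    def n_regions(self) -> int:
        return self.power.shape[0]


def compute_power_spectrum(
    epoch: np.ndarray, fs_hz: float, *, band: tuple[float, float] = BROAD_BAND
) -> PowerSpectrum:
    """Raw single-epoch periodogram over the broad band.

    ``epoch`` is a (n_regions, n_samples) matrix (a 1-D array is treated as a
    single region).  No taper and no segment averaging are applied: the
    spectrum is ``|FFT|^2`` of the whole epoch, one-sided, restricted to bins
    whose centres lie in ``band``.  The frequency resolution is
    ``fs_hz / n_samples`` (0.076 Hz for 4096 samples at 312 Hz).
    """
    epoch = np.atleast_2d(np.asarray(epoch, dtype=float))
    n = epoch.shape[-1]
    if n < 256:
        raise ValueError(f"epoch has {n} samples; at least 256 required")
    if fs_hz <= 2 * band[1]:
        raise ValueError(
            f"sampling rate {fs_hz} Hz puts {band[1]} Hz at or above Nyquist"
        )
    df = fs_hz / n
    if df > band[0]:
        raise ValueError(
            f"{n} samples at {fs_hz} Hz give {df:.4f} Hz resolution, "
            f"too coarse to resolve {band[0]} Hz"
        )
    freqs = np.fft.rfftfreq(n, d=1.0 / fs_hz)
    # one-sided power; overall scaling cancels in relative power
    spec = np.abs(np.fft.rfft(epoch, axis=-1)) ** 2 / n
    spec[..., 1:] *= 2.0
    if n % 2 == 0:
        spec[..., -1] /= 2.0
    keep = (freqs >= band[0]) & (freqs <= band[1])
    return PowerSpectrum(freqs_hz=freqs[keep], power=spec[:, keep], df_hz=df)


def band_powers(
    spectrum: PowerSpectrum, scheme: BandScheme | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Absolute and relative power per band per region.

    Absolute power in a band is the sum of bin powers whose centres fall in
    the band's half-open interval; relative power divides by the total over
    the whole scheme, so relative powers sum to 1 for every region.

    Returns ``(abs_power, rel_power)`` as (n_regions × n_bands) DataFrames.
    """
    scheme = scheme or BandScheme()
    absd = {}
    for name in scheme.names:
        m = scheme.mask(spectrum.freqs_hz, name)
        if not m.any():
            raise ValueError(
                f"band {name!r} contains no spectral bins at "
                f"df={spectrum.df_hz:.4f} Hz"
            )
        absd[name] = spectrum.power[:, m].sum(axis=1)
    abs_power = pd.DataFrame(absd)
    total = abs_power.sum(axis=1)
    rel_power = abs_power.div(total, axis=0)
    return abs_power, rel_power


def peak_frequency(
    spectrum: PowerSpectrum, window: tuple[float, float] = ALPHA_WINDOW
) -> np.ndarray:
    """Frequency of maximum power within the extended alpha window (4–13 Hz).

    Ties break toward the lowest frequency.  A region whose spectrum is
    identically zero in the window gets NaN (undefined), never the window
    edge.
    """
    m = (spectrum.freqs_hz >= window[0]) & (spectrum.freqs_hz <= window[1])
    if not m.any():
        raise ValueError(f"spectrum has no bins in [{window[0]}, {window[1]}] Hz")
    sub = spectrum.power[:, m]
    freqs = spectrum.freqs_hz[m]
    idx = np.argmax(sub, axis=1)  # argmax returns the first (lowest-f) maximum
    peaks = freqs[idx]
    peaks = np.where(sub.sum(axis=1) > 0, peaks, np.nan)
    return peaks


@dataclass
class SpectralSummary:
    """Per-subject spectral summary after epoch averaging.

    ``regional`` has one row per region with columns ``rel_<band>``,
    ``abs_<band>`` and ``peak_freq_hz``; ``whole_brain`` is the mean of each
    column over regions.
    """

    regional: pd.DataFrame
    whole_brain: pd.Series


def aggregate(epoch_frames: list[pd.DataFrame]) -> SpectralSummary:
    """Average per-epoch regional tables into one subject summary.

    Arithmetic mean across epochs first (one value per region), then across
    regions for the whole-brain values.  The whole-brain peak frequency is the
    mean of the regional epoch-averaged peaks.
    """
    if not epoch_frames:
        raise ValueError("at least one epoch is required")
    shape = epoch_frames[0].shape
    for i, f in enumerate(epoch_frames[1:], start=1):
        if f.shape != shape:
            raise ValueError(
                f"epoch {i} has shape {f.shape}, expected {shape}: "
                "region count must match across epochs"
            )
    regional = sum(epoch_frames[1:], epoch_frames[0].copy()) / len(epoch_frames)
    return SpectralSummary(regional=regional, whole_brain=regional.mean(axis=0))


def subject_spectral_summary(
    epochs: np.ndarray, fs_hz: float, scheme: BandScheme | None = None
) -> SpectralSummary:
    """Full spectral summary for one subject.

    ``epochs`` is (n_epochs, n_regions, n_samples).  Each epoch is analysed
    separately and the per-epoch tables are epoch-averaged.
    """
    scheme = scheme or BandScheme()
    frames = []
    for epoch in np.asarray(epochs, dtype=float):
        ps = compute_power_spectrum(epoch, fs_hz)
        ab, rel = band_powers(ps, scheme)
        tab = pd.concat(
            [rel.add_prefix("rel_"), ab.add_prefix("abs_")], axis=1
        )
        tab["peak_freq_hz"] = peak_frequency(ps)
        frames.append(tab)
    return aggregate(frames)
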