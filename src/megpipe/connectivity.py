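"""Functional connectivity: phase lag index and corrected amplitude envelope correlation.

Signals are band-filtered by FFT masking, and instantaneous phase and
amplitude envelope are taken from the analytic signal (Hilbert transform).

Two leakage-insensitive coupling measures are provided:

* **PLI** — the absolute mean sign of the sine of the instantaneous phase
  difference between two series.  It measures the asymmetry of the phase
  difference distribution: 0 means no (or exactly zero-lag) coupling, 1 means
  a consistent non-zero lag.  Shared zero-lag signal (volume conduction /
  leakage) contributes phase differences of exactly 0, whose sine is 0, so it
  cannot raise the PLI.
* **AECc** — the Pearson correlation of amplitude envelopes after pairwise
  orthogonalization in both directions.  Each series is regressed (least
  squares, with intercept) out of the other in the time domain; the envelope
  of the residual is correlated with the envelope of the regressor, the two
  directional correlations are averaged and mapped to [0, 1] via
  ``(r + 1) / 2``, so 0.5 means no coupling.

Matrices are computed per epoch over all region pairs and averaged across
epochs; the weighted functional degree of a region is the mean of its row
excluding the diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

__all__ = [
    "CANONICAL_BANDS",
    "MEASURE_BANDS",
    "AnalyticEpoch",
    "ConnectivityMatrix",
    "DegreeProfile",
    "bandpass",
    "analytic_epoch",
    "pli",
    "aecc",
    "pli_matrix",
    "aecc_matrix",
    "connectivity_matrix",
    "degrees",
]

#: Frequency bands used for connectivity, Hz.  Alpha here is the full 8–13 Hz
#: band (alpha1 + alpha2), as is conventional for envelope correlations.
CANONICAL_BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}

#: Measure/band combinations the pipeline computes by default.
MEASURE_BANDS = {("pli", "theta"), ("aecc", "alpha"), ("aecc", "beta")}

# Residual variance below this fraction of the original variance marks a
# direction as degenerate (pure leakage): its envelope correlation is
# undefined and treated as 0 (no coupling) rather than noise-driven.
_DEGENERATE_RTOL = 1e-10


def bandpass(
    epoch: np.ndarray, band: tuple[float, float], fs_hz: float
) -> np.ndarray:
    """Zero-phase FFT brick-wall band-pass filter.

    Transforms the signal, zeroes every bin whose frequency lies outside
    ``[low, high]`` (inclusive), and inverse transforms.  Output is real with
    exact band occupancy; edge effects are accepted (no samples discarded).
    """
    epoch = np.asarray(epoch, dtype=float)
    low, high = band
    if not (0 < low < high < fs_hz / 2):
        raise ValueError(
            f"band [{low}, {high}] Hz must lie strictly inside (0, {fs_hz / 2}) Hz"
        )
    n = epoch.shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / fs_hz)
    spec = np.fft.rfft(epoch, axis=-1)
    spec[..., (freqs < low) | (freqs > high)] = 0.0
    return np.fft.irfft(spec, n=n, axis=-1)


@dataclass
class AnalyticEpoch:
    """Instantaneous phase and amplitude envelope of one band-filtered epoch.

    ``phase`` is in (−π, π]; ``envelope`` is non-negative; both are
    (n_regions, n_samples).
    """

    phase: np.ndarray
    envelope: np.ndarray
    analytic: np.ndarray  # the underlying complex analytic signal


def analytic_epoch(filtered: np.ndarray) -> AnalyticEpoch:
    """Analytic signal of a band-filtered epoch via the Hilbert transform."""
    a = hilbert(np.atleast_2d(np.asarray(filtered, dtype=float)), axis=-1)
    return AnalyticEpoch(phase=np.angle(a), envelope=np.abs(a), analytic=a)


def pli(phases_i: np.ndarray, phases_j: np.ndarray) -> float:
    """Phase lag index of two instantaneous phase series.

    ``PLI = | mean_t sign(sin(phi_i(t) - phi_j(t))) |`` with ``sign(0) = 0``,
    so identical phases (zero lag) score exactly 0 and a constant non-zero
    lag scores 1.  Phase differences below floating-point precision
    (|sin| < 1e-12) count as zero lag, so channels that differ only by a
    positive scaling score exactly 0.
    """
    phases_i = np.asarray(phases_i, dtype=float)
    phases_j = np.asarray(phases_j, dtype=float)
    if phases_i.shape != phases_j.shape:
        raise ValueError(
            f"phase series lengths differ: {phases_i.shape} vs {phases_j.shape}"
        )
    s = np.sin(phases_i - phases_j)
    s[np.abs(s) < 1e-12] = 0.0
    return float(np.abs(np.mean(np.sign(s))))


def _direction_corr(env_regressor: np.ndarray, env_residual: np.ndarray) -> float:
    """Pearson correlation of two envelopes (one orthogonalization direction)."""
    a = env_regressor - env_regressor.mean()
    b = env_residual - env_residual.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return 0.0
    return float((a @ b) / denom)


def aecc(filtered_i: np.ndarray, filtered_j: np.ndarray) -> float:
    """Leakage-corrected amplitude envelope correlation of two filtered series.

    Direction i→j: series j is regressed on series i (least squares with
    intercept) and the Hilbert envelope of the residual is correlated with
    the envelope of series i.  Both directions are averaged and the mean is
    mapped to [0, 1] by ``(r + 1) / 2``.  A direction whose residual is
    (numerically) zero — pure zero-lag leakage — contributes a correlation of
    0, so shared instantaneous signal can never score as coupling.
    """
    xi = np.asarray(filtered_i, dtype=float)
    xj = np.asarray(filtered_j, dtype=float)
    if xi.shape != xj.shape:
        raise ValueError(f"series lengths differ: {xi.shape} vs {xj.shape}")
    vi, vj = xi.var(), xj.var()
    if vi == 0 or vj == 0:
        raise ValueError("zero-variance input: envelope correlation undefined")
    ai = hilbert(xi)
    aj = hilbert(xj)
    rs = []
    for (x, ax, vx), (y, ay, vy) in (
        ((xi, ai, vi), (xj, aj, vj)),
        ((xj, aj, vj), (xi, ai, vi)),
    ):
        b = np.cov(x, y, bias=True)[0, 1] / vx
        a0 = y.mean() - b * x.mean()
        # hilbert() is linear and passes constants through, so the analytic
        # signal of the residual is formed without a second transform
        resid_analytic = ay - b * ax - a0
        resid = y - b * x - a0
        if resid.var() <= _DEGENERATE_RTOL * vy:
            rs.append(0.0)  # degenerate: residual is numerical noise
        else:
            rs.append(_direction_corr(np.abs(ax), np.abs(resid_analytic)))
    return float((np.mean(rs) + 1.0) / 2.0)


def pli_matrix(filtered: np.ndarray) -> np.ndarray:
    """Symmetric PLI matrix over all region pairs of one filtered epoch."""
    ph = analytic_epoch(filtered).phase
    s, c = np.sin(ph), np.cos(ph)
    n = ph.shape[0]
    out = np.zeros((n, n))
    for i in range(n - 1):
        # sin(phi_i - phi_j) = sin phi_i cos phi_j - cos phi_i sin phi_j
        cross = s[i] * c[i + 1 :] - c[i] * s[i + 1 :]
        cross[np.abs(cross) < 1e-12] = 0.0  # sub-precision => zero lag
        vals = np.abs(np.mean(np.sign(cross), axis=-1))
        out[i, i + 1 :] = vals
        out[i + 1 :, i] = vals
    return out


def aecc_matrix(filtered: np.ndarray) -> np.ndarray:
    """Symmetric AECc matrix over all region pairs of one filtered epoch.

    Exploits the linearity of the Hilbert transform: analytic signals are
    computed once per region and residual envelopes are formed algebraically,
    which keeps the 80-region case tractable.
    """
    x = np.atleast_2d(np.asarray(filtered, dtype=float))
    n_regions, n = x.shape
    a = hilbert(x, axis=-1)
    mean = x.mean(axis=-1)
    xc = x - mean[:, None]
    var = (xc * xc).mean(axis=-1)
    if np.any(var == 0):
        raise ValueError("zero-variance region: envelope correlation undefined")
    cov = (xc @ xc.T) / n
    env = np.abs(a)

    r_dir = np.zeros((n_regions, n_regions))  # r_dir[i, j]: direction i -> j
    for i in range(n_regions):
        b = cov[i] / var[i]  # regress each j on i
        a0 = mean - b * mean[i]
        resid_a = a - b[:, None] * a[i][None, :] - a0[:, None]
        resid_var = (x - b[:, None] * x[i][None, :] - a0[:, None]).var(axis=-1)
        env_resid = np.abs(resid_a)
        # Pearson correlation of env(i) with each residual envelope
        e0 = env[i] - env[i].mean()
        er = env_resid - env_resid.mean(axis=-1, keepdims=True)
        denom = np.sqrt((e0 @ e0) * np.sum(er * er, axis=-1))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (er @ e0) / denom
        r[~np.isfinite(r)] = 0.0
        r[resid_var <= _DEGENERATE_RTOL * var] = 0.0
        r_dir[i] = r
    out = ((r_dir + r_dir.T) / 2.0 + 1.0) / 2.0
    np.fill_diagonal(out, 0.0)
    return out


@dataclass
class ConnectivityMatrix:
    """Epoch-averaged symmetric connectivity matrix for one measure and band."""

    measure: str
    band: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("connectivity matrix must be symmetric")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


def connectivity_matrix(
    epochs: np.ndarray,
    measure: str,
    band: str,
    fs_hz: float,
    *,
    allow_any_combination: bool = False,
    edge_trim: int = 0,
) -> ConnectivityMatrix:
    """Epoch-averaged connectivity matrix for a subject.

    ``epochs`` is (n_epochs, n_regions, n_samples).  Supported combinations
    are PLI in theta and AECc in alpha (8–13 Hz) and beta; other combinations
    require ``allow_any_combination=True``.  ``edge_trim`` drops that many
    samples from each end of the filtered epoch before phase/envelope
    extraction, to shave Hilbert edge effects if desired (default keeps all).
    """
    measure = measure.lower()
    band = band.lower()
    if measure not in {"pli", "aecc"}:
        raise ValueError(f"unknown measure {measure!r}")
    if band not in CANONICAL_BANDS:
        raise ValueError(f"unknown band {band!r}")
    if (measure, band) not in MEASURE_BANDS and not allow_any_combination:
        raise ValueError(
            f"{measure.upper()} in the {band} band is not part of the standard "
            "analysis; pass allow_any_combination=True to compute it anyway"
        )
    epochs = np.asarray(epochs, dtype=float)
    if epochs.ndim != 3 or epochs.shape[0] < 1:
        raise ValueError("epochs must be (n_epochs, n_regions, n_samples) with >= 1 epoch")
    interval = CANONICAL_BANDS[band]
    acc = None
    for epoch in epochs:
        filt = bandpass(epoch, interval, fs_hz)
        if edge_trim:
            filt = filt[..., edge_trim:-edge_trim]
        mat = pli_matrix(filt) if measure == "pli" else aecc_matrix(filt)
        acc = mat if acc is None else acc + mat
    return ConnectivityMatrix(measure=measure, band=band, values=acc / len(epochs))


@dataclass
class DegreeProfile:
    """Weighted functional degree per region plus the whole-brain mean.

    The degree of region r is the mean of row r of the connectivity matrix
    excluding the diagonal; the whole-brain mean is the mean over all
    unordered off-diagonal pairs (equivalently, the mean of the degrees).
    """

    degree: np.ndarray
    whole_brain_mean: float


def degrees(matrix: ConnectivityMatrix | np.ndarray) -> DegreeProfile:
    """Weighted degree profile of a symmetric connectivity matrix."""
    values = matrix.values if isinstance(matrix, ConnectivityMatrix) else np.asarray(matrix, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("degree computation requires a square matrix")
    if not np.allclose(values, values.T):
        raise ValueError("degree computation requires a symmetric matrix")
    n = values.shape[0]
    off = values.copy()
    np.fill_diagonal(off, 0.0)
    deg = off.sum(axis=1) / (n - 1)
    iu = np.triu_indices(n, k=1)
    return DegreeProfile(degree=deg, whole_brain_mean=float(values[iu].mean()))
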