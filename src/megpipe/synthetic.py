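"""Synthetic source-level MEG cohorts with known spectral and coupling structure.

The generator produces multichannel epochs that mimic the structure the
analysis assumes — band-limited oscillatory components over a 1/f background,
phase coupling with a fixed non-zero lag (raises the phase lag index),
amplitude-envelope coupling on independent-phase carriers (raises the
corrected amplitude envelope correlation, leaves the PLI at its null), and an
instantaneous linear "leakage" mix (the volume-conduction confound both
measures are built to reject).  A carrier/control cohort contrast —
oscillatory slowing (theta up, alpha2 down, lower peak frequency) and
hub-selective coupling attenuation — can be injected with known direction and
size, so every downstream stage has a ground truth to recover.

All randomness flows through explicitly passed ``numpy.random.Generator``
streams derived from a single seed; identical inputs give byte-identical
output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from .spectral import BandScheme

__all__ = [
    "SignalSpec",
    "CouplingSpec",
    "CarrierShift",
    "OnsetRecord",
    "Subject",
    "CohortManifest",
    "band_limited_noise",
    "pink_noise",
    "make_region_signal",
    "apply_coupling",
    "simulate_subject",
    "make_cohort",
    "default_manifest",
    "default_coupling",
]

_BAND_NAMES = ("delta", "theta", "alpha1", "alpha2", "beta", "gamma")

# Injection bands: phase coupling targets the PLI analysis band (theta);
# envelope coupling is injected with carriers in the two AECc analysis bands.
_PHASE_BAND = (4.0, 8.0)
_ENVELOPE_BANDS = ((8.0, 13.0), (13.0, 30.0))
_MODULATOR_BAND = (0.3, 1.5)  # slow shared envelope, a few cycles per epoch


@dataclass(frozen=True)
class SignalSpec:
    """Recipe for one region's uncoupled signal.

    Each epoch is the sum of band-limited Gaussian noise per canonical band
    (weighted by ``band_weights``), a narrowband oscillation at
    ``peak_freq_hz`` whose amplitude follows the weight of the band containing
    the peak, and a ``1/f**pink_exponent`` background scaled by
    ``pink_weight``.  All components have unit RMS per unit weight; epochs are
    zero-mean.
    """

    band_weights: dict[str, float] = field(
        default_factory=lambda: {
            # resting-state-like profile: alpha-dominant with broadband floor
            "delta": 0.7,
            "theta": 0.45,
            "alpha1": 0.6,
            "alpha2": 0.7,
            "beta": 0.55,
            "gamma": 0.2,
        }
    )
    peak_freq_hz: float = 9.5
    pink_exponent: float = 1.0
    pink_weight: float = 0.3
    n_samples: int = 4096
    fs_hz: float = 312.5
    n_epochs: int = 10

    def __post_init__(self) -> None:
        for name in self.band_weights:
            if name not in _BAND_NAMES:
                raise ValueError(
                    f"unknown band name {name!r}; expected one of {_BAND_NAMES}"
                )
        weights = np.array(list(self.band_weights.values()), dtype=float)
        if weights.size == 0 or np.any(weights < 0) or not np.any(weights > 0):
            raise ValueError(
                "band_weights must be non-negative with at least one positive"
            )
        if not 4.0 <= self.peak_freq_hz <= 13.0:
            raise ValueError("peak_freq_hz must lie in the extended alpha band [4, 13]")
        if self.n_samples < 256:
            raise ValueError("n_samples must be at least 256")
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be at least 1")

    def peak_band(self) -> str:
        """Canonical band containing the peak frequency (upper edge exclusive)."""
        for name, (lo, hi) in BandScheme().bands.items():
            if lo <= self.peak_freq_hz < hi:
                return name
        return "gamma"


def band_limited_noise(
    rng: np.random.Generator,
    n_samples: int,
    fs_hz: float,
    band: tuple[float, float],
) -> np.ndarray:
    """Unit-RMS Gaussian noise strictly confined to ``band`` by FFT masking."""
    low, high = band
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs_hz)
    spec = np.fft.rfft(rng.standard_normal(n_samples))
    spec[(freqs < low) | (freqs > high)] = 0.0
    x = np.fft.irfft(spec, n=n_samples)
    rms = np.sqrt(np.mean(x * x))
    if rms == 0:
        raise ValueError(f"band [{low}, {high}] Hz contains no FFT bins")
    return x / rms


def pink_noise(
    rng: np.random.Generator, n_samples: int, fs_hz: float, exponent: float
) -> np.ndarray:
    """Unit-RMS noise with a ``1/f**exponent`` power spectrum (no DC)."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs_hz)
    spec = np.fft.rfft(rng.standard_normal(n_samples)).astype(complex)
    spec[0] = 0.0
    with np.errstate(divide="ignore"):
        shaping = np.where(freqs > 0, freqs ** (-exponent / 2.0), 0.0)
    x = np.fft.irfft(spec * shaping, n=n_samples)
    return x / np.sqrt(np.mean(x * x))


def make_region_signal(
    spec: SignalSpec, seed: int | np.random.Generator
) -> np.ndarray:
    """Generate one region's epochs, shape (n_epochs, n_samples)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scheme = BandScheme()
    peak_band = spec.peak_band()
    out = np.empty((spec.n_epochs, spec.n_samples))
    for e in range(spec.n_epochs):
        x = np.zeros(spec.n_samples)
        for name, w in spec.band_weights.items():
            if w > 0:
                x += w * band_limited_noise(
                    rng, spec.n_samples, spec.fs_hz, scheme.bands[name]
                )
        peak_w = spec.band_weights.get(peak_band, 0.0)
        if peak_w > 0:
            # narrowband (+-0.25 Hz) noise rather than a pure sinusoid:
            # a deterministic tone at one shared frequency would be
            # collinear across regions and corrupt pairwise orthogonalization
            # interval at least one FFT bin wide so short epochs stay valid
            half = max(0.25, spec.fs_hz / spec.n_samples)
            x += peak_w * band_limited_noise(
                rng,
                spec.n_samples,
                spec.fs_hz,
                (spec.peak_freq_hz - half, spec.peak_freq_hz + half),
            )
        if spec.pink_weight > 0:
            x += spec.pink_weight * pink_noise(
                rng, spec.n_samples, spec.fs_hz, spec.pink_exponent
            )
        out[e] = x - x.mean()
    return out


@dataclass
class CouplingSpec:
    """Ground-truth coupling structure for a cohort.

    ``phase_graph`` holds per-edge phase-coupling strengths in [0, 1] with
    per-edge constant, non-zero lags in ``phase_lags`` (radians);
    ``envelope_graph`` holds envelope-correlation strengths in [0, 1];
    ``leakage_mix`` is an invertible instantaneous mixing matrix applied last;
    hub rows/columns of both graphs are scaled by ``hub_attenuation`` before
    injection.
    """

    phase_graph: np.ndarray
    envelope_graph: np.ndarray
    phase_lags: np.ndarray | None = None
    leakage_mix: np.ndarray | None = None
    hub_attenuation: float = 1.0
    hub_ids: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.phase_graph = np.asarray(self.phase_graph, dtype=float)
        self.envelope_graph = np.asarray(self.envelope_graph, dtype=float)
        n = self.phase_graph.shape[0]
        for name, g in (("phase_graph", self.phase_graph),
                        ("envelope_graph", self.envelope_graph)):
            if g.shape != (n, n):
                raise ValueError(f"{name} must be square and match region count")
            if not np.allclose(g, g.T):
                raise ValueError(f"{name} must be symmetric")
            if np.any(np.diag(g) != 0):
                raise ValueError(f"{name} must have a zero diagonal")
        if self.phase_lags is None:
            self.phase_lags = np.full((n, n), np.pi / 4)
            np.fill_diagonal(self.phase_lags, 0.0)
        self.phase_lags = np.asarray(self.phase_lags, dtype=float)
        if np.any((self.phase_graph > 0) & (self.phase_lags == 0)):
            raise ValueError("phase-coupled edges must have a non-zero lag")
        if self.leakage_mix is None:
            self.leakage_mix = np.eye(n)
        self.leakage_mix = np.asarray(self.leakage_mix, dtype=float)
        if self.leakage_mix.shape != (n, n):
            raise ValueError("leakage_mix must be square and match region count")
        if abs(np.linalg.det(self.leakage_mix)) < 1e-12:
            raise ValueError("leakage_mix must be invertible")
        if not 0.0 <= self.hub_attenuation <= 1.0:
            raise ValueError("hub_attenuation must lie in [0, 1]")
        self.hub_ids = np.asarray(self.hub_ids, dtype=int)

    @property
    def n_regions(self) -> int:
        return self.phase_graph.shape[0]

    def effective_graphs(self) -> tuple[np.ndarray, np.ndarray]:
        """Graphs with hub rows/columns scaled by ``hub_attenuation``."""
        f = np.ones(self.n_regions)
        f[self.hub_ids] = self.hub_attenuation
        scale = np.outer(f, f)
        return self.phase_graph * scale, self.envelope_graph * scale


def _analytic_band_noise(rng, n, fs, band):
    return hilbert(band_limited_noise(rng, n, fs, band))


def apply_coupling(
    signals: np.ndarray,
    coupling: CouplingSpec,
    seed: int | np.random.Generator,
    fs_hz: float = 312.5,
) -> np.ndarray:
    """Inject phase and envelope coupling and apply the leakage mix.

    ``signals`` is (n_regions, n_epochs, n_samples).  Phase coupling on edge
    (i, j): a shared band-limited oscillator is added to both regions, with
    region j's copy rotated by the edge's fixed lag, so the injected
    components hold a constant non-zero phase difference (raises PLI,
    monotone in the edge weight).  Envelope coupling: two independent-phase
    carriers in each AECc band are modulated by one shared slow envelope
    (raises AECc, leaves expected PLI at its null).  The instantaneous
    leakage mix is applied last.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = np.array(signals, dtype=float, copy=True)
    if x.ndim != 3:
        raise ValueError("signals must be (n_regions, n_epochs, n_samples)")
    n_regions, n_epochs, n = x.shape
    if coupling.n_regions != n_regions:
        raise ValueError(
            f"coupling is for {coupling.n_regions} regions, signals have {n_regions}"
        )
    fs = fs_hz
    phase_g, env_g = coupling.effective_graphs()
    iu = list(zip(*np.triu_indices(n_regions, k=1)))
    for e in range(n_epochs):
        for i, j in iu:
            w = phase_g[i, j]
            if w > 0:
                osc = _analytic_band_noise(rng, n, fs, _PHASE_BAND)
                lag = coupling.phase_lags[i, j]
                x[i, e] += w * osc.real
                x[j, e] += w * (osc * np.exp(-1j * lag)).real
            w = env_g[i, j]
            if w > 0:
                mod = np.abs(_analytic_band_noise(rng, n, fs, _MODULATOR_BAND))
                for band in _ENVELOPE_BANDS:
                    for r in (i, j):
                        carrier = band_limited_noise(rng, n, fs, band)
                        comp = mod * carrier
                        x[r, e] += w * comp / np.sqrt(np.mean(comp * comp))
        x[:, e] = coupling.leakage_mix @ x[:, e]
    return x


def simulate_subject(
    spec: SignalSpec,
    coupling: CouplingSpec,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """One subject's coupled epochs, shape (n_epochs, n_regions, n_samples)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    base = np.stack(
        [make_region_signal(spec, rng) for _ in range(coupling.n_regions)]
    )  # (R, E, N)
    coupled = apply_coupling(base, coupling, rng, fs_hz=spec.fs_hz)
    return np.transpose(coupled, (1, 0, 2))


@dataclass(frozen=True)
class CarrierShift:
    """Multiplicative/additive deltas applied to carriers' signal recipe.

    ``theta_factor`` and ``alpha2_factor`` multiply the respective band
    weights, ``peak_shift_hz`` is added to the peak frequency, and
    ``hub_attenuation`` replaces the coupling's hub scaling for carriers.
    The identity shift is (1, 1, 0, 1).
    """

    theta_factor: float = 1.0
    alpha2_factor: float = 1.0
    peak_shift_hz: float = 0.0
    hub_attenuation: float = 1.0

    @classmethod
    def slowing_contrast(cls) -> "CarrierShift":
        """Default carrier contrast: oscillatory slowing + hub disconnection.

        Theta power up (×1.6), alpha2 power down (×0.6), peak frequency
        lowered by 1.2 Hz, hub coupling attenuated to 0.4.  Effect sizes are
        free parameters of the generator, chosen once so each effect's
        direction is reliably recoverable at desk scale.
        """
        return cls(
            theta_factor=1.6,
            alpha2_factor=0.6,
            peak_shift_hz=-1.2,
            hub_attenuation=0.4,
        )

    def apply(self, spec: SignalSpec) -> SignalSpec:
        weights = dict(spec.band_weights)
        if "theta" in weights:
            weights["theta"] *= self.theta_factor
        if "alpha2" in weights:
            weights["alpha2"] *= self.alpha2_factor
        peak = float(np.clip(spec.peak_freq_hz + self.peak_shift_hz, 4.0, 13.0))
        return replace(spec, band_weights=weights, peak_freq_hz=peak)


@dataclass(frozen=True)
class OnsetRecord:
    """Reference onset ages (years) for one mutation carrier."""

    parental_onset_age: float | None = None
    family_mean_onset_age: float | None = None
    mutation_mean_onset_age: float | None = None
    sibling_onset_age: float | None = None


@dataclass(frozen=True)
class Subject:
    id: str
    group: str  # "carrier" or "control"
    age: float
    matched_carrier_id: str | None = None


@dataclass
class CohortManifest:
    """Cohort composition: carriers, 3:1 matched controls, onset records."""

    subjects: list[Subject]
    onset_records: dict[str, OnsetRecord] = field(default_factory=dict)
    fs_hz: float = 312.5
    seed: int = 0

    def __post_init__(self) -> None:
        for s in self.subjects:
            if s.group not in ("carrier", "control"):
                raise ValueError(f"subject {s.id}: unknown group {s.group!r}")
            if s.age <= 0:
                raise ValueError(f"subject {s.id}: age must be positive")
        counts: dict[str, int] = {}
        for s in self.subjects:
            if s.group == "control":
                if s.matched_carrier_id is None:
                    raise ValueError(f"control {s.id} has no matched carrier")
                counts[s.matched_carrier_id] = counts.get(s.matched_carrier_id, 0) + 1
        for s in self.carriers:
            if counts.get(s.id, 0) != 3:
                raise ValueError(
                    f"carrier {s.id} has {counts.get(s.id, 0)} matched controls; "
                    "exactly 3 required"
                )

    @property
    def carriers(self) -> list[Subject]:
        return [s for s in self.subjects if s.group == "carrier"]

    @property
    def controls(self) -> list[Subject]:
        return [s for s in self.subjects if s.group == "control"]

    def matched_controls(self, carrier_id: str) -> list[Subject]:
        return [s for s in self.controls if s.matched_carrier_id == carrier_id]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            rec = self.onset_records.get(s.id, OnsetRecord())
            rows.append(
                {
                    "id": s.id,
                    "group": s.group,
                    "age": s.age,
                    "match_id": s.matched_carrier_id or "",
                    "fs_hz": self.fs_hz,
                    "onset_parental": rec.parental_onset_age,
                    "onset_family": rec.family_mean_onset_age,
                    "onset_mutation": rec.mutation_mean_onset_age,
                    "onset_sibling": rec.sibling_onset_age,
                }
            )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, seed: int = 0) -> "CohortManifest":
        subjects, onsets = [], {}
        for _, row in df.iterrows():
            match = str(row.get("match_id", "") or "")
            subjects.append(
                Subject(
                    id=str(row["id"]),
                    group=str(row["group"]),
                    age=float(row["age"]),
                    matched_carrier_id=match or None,
                )
            )
            if str(row["group"]) == "carrier":
                def _opt(key):
                    v = row.get(key)
                    return None if v is None or pd.isna(v) else float(v)
                onsets[str(row["id"])] = OnsetRecord(
                    parental_onset_age=_opt("onset_parental"),
                    family_mean_onset_age=_opt("onset_family"),
                    mutation_mean_onset_age=_opt("onset_mutation"),
                    sibling_onset_age=_opt("onset_sibling"),
                )
        fs = float(df["fs_hz"].iloc[0]) if "fs_hz" in df else 312.5
        return cls(subjects=subjects, onset_records=onsets, fs_hz=fs, seed=seed)


def default_manifest(
    n_carriers: int = 11,
    seed: int = 0,
    fs_hz: float = 312.5,
) -> CohortManifest:
    """A 1:3 matched cohort with ages and onset records in plausible ranges.

    Ages are drawn uniformly from 20–62 years (the study cohort's range) and
    each carrier's three controls are age-matched within ±2 years.  Onset
    records sit near the carrier's age so the three EYBSO measures span both
    signs.
    """
    rng = np.random.default_rng(seed)
    subjects: list[Subject] = []
    onsets: dict[str, OnsetRecord] = {}
    for k in range(n_carriers):
        cid = f"carrier{k:02d}"
        age = float(np.round(rng.uniform(20, 62), 1))
        subjects.append(Subject(id=cid, group="carrier", age=age))
        onsets[cid] = OnsetRecord(
            parental_onset_age=float(np.round(age + rng.uniform(-16, 22), 1)),
            family_mean_onset_age=float(np.round(age + rng.uniform(-8, 32), 1)),
            mutation_mean_onset_age=float(np.round(age + rng.uniform(-12, 27), 1)),
        )
        for m in range(3):
            subjects.append(
                Subject(
                    id=f"control{k:02d}_{m}",
                    group="control",
                    age=float(np.round(np.clip(age + rng.uniform(-2, 2), 18, 80), 1)),
                    matched_carrier_id=cid,
                )
            )
    return CohortManifest(subjects=subjects, onset_records=onsets, fs_hz=fs_hz, seed=seed)


def default_coupling(
    n_regions: int = 80,
    seed: int = 0,
    hub_fraction: float = 0.25,
    density: float = 0.3,
    leakage_strength: float = 0.25,
) -> CouplingSpec:
    """Degree-heterogeneous coupling with designated hubs and mild leakage.

    Regions get a latent 'hubness' (hubs high, periphery low); edge weights
    are products of hubness, thresholded to the requested density, so hubs
    carry the strongest edges and the degree profile is non-constant — the
    structure hub-disruption analysis needs.
    """
    rng = np.random.default_rng(seed)
    n_hubs = max(1, int(round(hub_fraction * n_regions)))
    hub_ids = rng.choice(n_regions, size=n_hubs, replace=False)
    h = rng.uniform(0.35, 0.6, n_regions)
    h[hub_ids] = rng.uniform(0.8, 1.0, n_hubs)
    w = np.outer(h, h)
    np.fill_diagonal(w, 0.0)
    iu = np.triu_indices(n_regions, k=1)
    thresh = np.quantile(w[iu], 1.0 - density)
    w = np.where(w >= thresh, w, 0.0)
    w = np.triu(w, 1) + np.triu(w, 1).T
    lags = np.full((n_regions, n_regions), np.pi / 4)
    np.fill_diagonal(lags, 0.0)
    # row-normalized leakage: each channel receives `leakage_strength` times
    # the weighted mean of the others, so common-mode leakage does not grow
    # with the region count
    off = rng.uniform(0, 1, (n_regions, n_regions))
    np.fill_diagonal(off, 0.0)
    mix = np.eye(n_regions) + leakage_strength * off / off.sum(axis=1, keepdims=True)
    return CouplingSpec(
        phase_graph=0.6 * w,
        envelope_graph=w,
        phase_lags=lags,
        leakage_mix=mix,
        hub_ids=np.sort(hub_ids),
    )


def make_cohort(
    manifest: CohortManifest,
    base_spec: SignalSpec,
    carrier_shift: CarrierShift,
    coupling: CouplingSpec,
    out_dir: str | Path,
    *,
    float_fmt: str = "%.6e",
) -> Path:
    """Write a full cohort to disk and return the manifest path.

    One whitespace-delimited plain-text matrix per subject per epoch
    (samples as rows, regions as columns, no header), named
    ``<subject>_epoch<k>.txt``, plus ``manifest.csv``.  Subject seeds are
    spawned deterministically from ``manifest.seed``, so regenerating with
    the same inputs is byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    carrier_spec = carrier_shift.apply(
        replace(base_spec, fs_hz=manifest.fs_hz)
    )
    control_spec = replace(base_spec, fs_hz=manifest.fs_hz)
    carrier_coupling = CouplingSpec(
        phase_graph=coupling.phase_graph,
        envelope_graph=coupling.envelope_graph,
        phase_lags=coupling.phase_lags,
        leakage_mix=coupling.leakage_mix,
        hub_attenuation=carrier_shift.hub_attenuation,
        hub_ids=coupling.hub_ids,
    )
    for index, subject in enumerate(manifest.subjects):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=manifest.seed, spawn_key=(index,))
        )
        spec = carrier_spec if subject.group == "carrier" else control_spec
        cpl = carrier_coupling if subject.group == "carrier" else coupling
        epochs = simulate_subject(spec, cpl, rng)
        for e, epoch in enumerate(epochs):
            np.savetxt(
                out_dir / f"{subject.id}_epoch{e:02d}.txt", epoch.T, fmt=float_fmt
            )
    manifest_path = out_dir / "manifest.csv"
    manifest.to_frame().to_csv(manifest_path, index=False)
    return manifest_path
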