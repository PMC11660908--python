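"""Hub disruption index (HDI).

The HDI asks whether connectivity changes in a target network depend on how
central ("hub-like") a region is in a reference network.  For every region,
the reference network's weighted degree is subtracted from the target
network's degree; the differences are regressed on the reference degrees and
the slope of that ordinary-least-squares line is the HDI.  A negative slope
means hubs lose connectivity preferentially (and/or low-degree regions gain,
depending on the intercept); a flat, non-significant line means changes are
degree-independent.

Group-level HDI compares group-mean degree profiles; individual HDI compares
one subject against its surrogate reference (the per-region mean degree of
the three matched controls).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .connectivity import ConnectivityMatrix, degrees

__all__ = [
    "HDIResult",
    "hdi",
    "group_hdi",
    "individual_hdi",
    "hdi_permutation_p",
    "plot_hdi",
]


@dataclass
class HDIResult:
    """OLS fit of regional degree differences against reference degrees."""

    slope: float  # the HDI
    intercept: float
    slope_p: float  # two-sided t-test of slope != 0
    r_squared: float
    reference_degree: np.ndarray
    degree_difference: np.ndarray

    @property
    def n_regions(self) -> int:
        return self.reference_degree.size


def _as_degrees(profile) -> np.ndarray:
    if hasattr(profile, "degree"):
        return np.asarray(profile.degree, dtype=float)
    return np.asarray(profile, dtype=float)


def hdi(target_degrees, reference_degrees) -> HDIResult:
    """HDI of a target degree profile against a reference profile.

    Fits ``(target - reference) ~ reference`` by OLS; the slope is the HDI
    and its p-value comes from the standard two-sided slope t-test.  If the
    target is an affine function ``a * reference + b``, the slope is exactly
    ``a - 1`` and the intercept ``b``.
    """
    target = _as_degrees(target_degrees)
    reference = _as_degrees(reference_degrees)
    if target.shape != reference.shape:
        raise ValueError(
            f"degree profiles differ in size: {target.shape} vs {reference.shape}"
        )
    if np.ptp(reference) == 0:
        raise ValueError("reference degrees are constant; HDI slope is undefined")
    diff = target - reference
    fit = sps.linregress(reference, diff)
    return HDIResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        slope_p=float(fit.pvalue),
        r_squared=float(fit.rvalue**2),
        reference_degree=reference,
        degree_difference=diff,
    )


def _profiles(matrices) -> np.ndarray:
    out = []
    for m in matrices:
        if isinstance(m, ConnectivityMatrix) or (
            isinstance(m, np.ndarray) and m.ndim == 2
        ):
            out.append(degrees(m).degree)
        else:
            out.append(_as_degrees(m))
    return np.asarray(out, dtype=float)


def group_hdi(carrier_matrices, control_matrices) -> HDIResult:
    """Group-level HDI: group-mean carrier degrees against group-mean control degrees.

    Degrees are computed per subject, averaged within each group per region,
    and the carrier group mean is the target network, the control group mean
    the reference.
    """
    carriers = _profiles(carrier_matrices)
    controls = _profiles(control_matrices)
    if carriers.shape[0] < 1 or controls.shape[0] < 1:
        raise ValueError("each group needs at least one subject")
    if carriers.shape[1] != controls.shape[1]:
        raise ValueError("carrier and control region counts differ")
    return hdi(carriers.mean(axis=0), controls.mean(axis=0))


def individual_hdi(
    subject_degrees,
    surrogate_degrees,
    *,
    n_surrogates: int | None = None,
    allow_any_group_size: bool = False,
) -> HDIResult:
    """Individual HDI of one subject against its surrogate reference.

    ``surrogate_degrees`` is the per-region mean degree over the subject's
    three matched controls (pass ``n_surrogates`` to assert the group size;
    a size other than 3 is rejected unless ``allow_any_group_size``).
    For control subjects the reference is the mean of their own 3-control
    surrogate group.
    """
    if n_surrogates is not None and n_surrogates != 3 and not allow_any_group_size:
        raise ValueError(
            f"surrogate group has {n_surrogates} controls; 3 required "
            "(use allow_any_group_size to override)"
        )
    return hdi(subject_degrees, surrogate_degrees)


def plot_hdi(result: HDIResult, path, title: str = "") -> None:
    """Scatter of degree differences vs reference degrees with the HDI fit."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.scatter(result.reference_degree, result.degree_difference,
               s=18, color="tab:blue", alpha=0.8)
    xs = np.linspace(result.reference_degree.min(),
                     result.reference_degree.max(), 50)
    ax.plot(xs, result.slope * xs + result.intercept, color="tab:red",
            label=f"HDI = {result.slope:.2f} (p = {result.slope_p:.3g})")
    ax.axhline(0.0, color="grey", lw=0.8, ls=":")
    ax.set_xlabel("reference degree")
    ax.set_ylabel("degree difference (target − reference)")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def hdi_permutation_p(
    target_degrees,
    reference_degrees,
    n_perm: int = 2000,
    seed: int | None = 0,
) -> float:
    """Permutation p-value for the HDI slope by region-label shuffling.

    An alternative to the parametric slope t-test: the pairing between a
    region's degree difference and its reference degree is shuffled, and the
    two-sided tail probability of the observed slope under that null is
    returned (add-one rule).
    """
    rng = np.random.default_rng(seed)
    target = _as_degrees(target_degrees)
    reference = _as_degrees(reference_degrees)
    observed = abs(hdi(target, reference).slope)
    diff = target - reference
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(diff.size)
        slope = sps.linregress(reference, diff[perm]).slope
        if abs(slope) >= observed:
            count += 1
    return (count + 1) / (n_perm + 1)
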