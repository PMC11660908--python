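"""Paired non-parametric statistics for the carrier / surrogate-control design.

Every carrier is compared against its *surrogate control* — the mean of its
three matched controls' outcome measures — so all group comparisons are
paired:

* Wilcoxon matched-pairs signed-rank test (tie-corrected normal
  approximation, exact sign-flip enumeration available) for whole-brain
  measures,
* a paired sign-flip permutation test with maximal-statistic family-wise
  correction for the 80 regional measures (sign flips are applied
  subject-wise across all regions jointly, preserving the spatial
  correlation the max-statistic construction relies on),
* Spearman rank correlations with the Benjamini–Krieger–Yekutieli two-stage
  step-up FDR for clinical associations,
* Kruskal–Wallis plus Dunn's pairwise post-hoc comparisons for the hub
  disruption index groups,
* Tukey-fence (1.5 × IQR) outlier screening of pairwise differences, and
* the estimated-years-before-symptom-onset (EYBSO) helper.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .synthetic import OnsetRecord

__all__ = [
    "PairedSample",
    "WilcoxonResult",
    "RegionalTestResult",
    "KruskalDunnResult",
    "wilcoxon_paired",
    "regional_permutation_test",
    "spearman",
    "fdr_bky",
    "iqr_outliers",
    "kruskal_dunn",
    "eybso",
]


@dataclass
class PairedSample:
    """Matched carrier / surrogate-control values for one outcome measure."""

    carrier: np.ndarray
    surrogate: np.ndarray
    pair_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.carrier = np.asarray(self.carrier, dtype=float)
        self.surrogate = np.asarray(self.surrogate, dtype=float)
        if self.carrier.shape != self.surrogate.shape:
            raise ValueError("carrier and surrogate value counts differ")
        if np.any(np.isnan(self.carrier)) or np.any(np.isnan(self.surrogate)):
            raise ValueError("paired sample contains missing halves")
        if self.carrier.size < 2:
            raise ValueError("at least 2 pairs are required")
        if not self.pair_ids:
            self.pair_ids = [f"pair{i}" for i in range(self.carrier.size)]

    @property
    def differences(self) -> np.ndarray:
        return self.carrier - self.surrogate


@dataclass
class WilcoxonResult:
    z: float  # standardized statistic of the smaller rank sum (<= 0)
    p: float  # two-sided
    n_effective: int  # pairs remaining after dropping zero differences
    median_difference: float  # carrier - surrogate, for direction
    undefined: bool = False


def wilcoxon_paired(
    sample: PairedSample | np.ndarray,
    surrogate: np.ndarray | None = None,
    *,
    exact: bool = False,
) -> WilcoxonResult:
    """Wilcoxon matched-pairs signed-rank test on carrier − surrogate differences.

    Zero differences are dropped; tied absolute differences get mid-ranks.
    The default z is the tie-corrected normal approximation of the smaller
    rank sum (the convention SPSS reports, so z <= 0 regardless of
    direction; use ``median_difference`` for the sign of the effect).  With
    ``exact=True`` the two-sided p comes from exhaustive sign-flip
    enumeration (2**n), feasible for n up to ~20.
    """
    if surrogate is not None:
        sample = PairedSample(carrier=np.asarray(sample), surrogate=surrogate)
    d = sample.differences
    d = d[d != 0]
    n = d.size
    if n == 0:
        return WilcoxonResult(
            z=np.nan, p=np.nan, n_effective=0,
            median_difference=float(np.median(sample.differences)), undefined=True,
        )
    ranks = sps.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    w_neg = float(ranks[d < 0].sum())
    t_stat = min(w_pos, w_neg)
    mu = n * (n + 1) / 4.0
    # tie correction: subtract sum(t^3 - t)/48 over groups of tied |d|
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / 48.0
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if sigma2 <= 0:
        return WilcoxonResult(
            z=np.nan, p=np.nan, n_effective=n,
            median_difference=float(np.median(sample.differences)), undefined=True,
        )
    z = (t_stat - mu) / np.sqrt(sigma2)
    if exact:
        if n > 20:
            raise ValueError("exact enumeration is limited to 20 effective pairs")
        # sign-flip distribution of W+ is symmetric about mu
        dev = abs(w_pos - mu)
        count = 0
        for signs in itertools.product((0, 1), repeat=n):
            w = float(np.dot(signs, ranks))
            if abs(w - mu) >= dev - 1e-12:
                count += 1
        p = count / 2.0**n
    else:
        p = float(2.0 * sps.norm.sf(abs(z)))
    return WilcoxonResult(
        z=float(z),
        p=min(1.0, float(p)),
        n_effective=n,
        median_difference=float(np.median(sample.differences)),
    )


@dataclass
class RegionalTestResult:
    """Per-region paired permutation test with maximal-statistic correction."""

    t_scores: np.ndarray
    p_uncorrected: np.ndarray
    p_corrected: np.ndarray
    n_permutations: int
    seed: int | None


def regional_permutation_test(
    carriers: np.ndarray,
    surrogates: np.ndarray,
    n_perm: int = 2000,
    seed: int | None = 0,
) -> RegionalTestResult:
    """Paired sign-flip permutation test across regions.

    ``carriers`` and ``surrogates`` are (n_regions, n_pairs) with matched
    columns.  The statistic is the paired t-score of the per-pair
    differences in each region.  The null flips the sign of each pair's
    whole difference vector (subject-wise, all regions jointly).  Regional
    p-values count the permutation tail with the add-one rule, so the
    smallest attainable p is 1/(n_perm+1); family-wise corrected p-values
    compare each observed |t| against the permutation distribution of the
    maximum |t| over regions.
    """
    carriers = np.atleast_2d(np.asarray(carriers, dtype=float))
    surrogates = np.atleast_2d(np.asarray(surrogates, dtype=float))
    if carriers.shape != surrogates.shape:
        raise ValueError("carrier and surrogate matrices must have matched shapes")
    n_regions, n_pairs = carriers.shape
    if n_pairs < 2:
        raise ValueError("at least 2 matched pairs are required")
    if n_perm < 100:
        raise ValueError("use at least 100 permutations")
    d = carriers - surrogates  # (R, S)
    ssq = np.sum(d * d, axis=1)  # invariant under sign flips

    def t_from_means(means: np.ndarray) -> np.ndarray:
        # means: (..., R); variance from the flip-invariant sum of squares
        var = (ssq - n_pairs * means**2) / (n_pairs - 1)
        var = np.maximum(var, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = means / np.sqrt(var / n_pairs)
        return np.where(np.isfinite(t), t, np.sign(means) * np.inf)

    t_obs = t_from_means(d.mean(axis=1))
    rng = np.random.default_rng(seed)
    flips = rng.choice((-1.0, 1.0), size=(n_perm, n_pairs))
    perm_means = flips @ d.T / n_pairs  # (n_perm, R)
    t_perm = t_from_means(perm_means)
    abs_obs = np.abs(t_obs)
    p_unc = (1 + np.sum(np.abs(t_perm) >= abs_obs[None, :], axis=0)) / (n_perm + 1)
    max_perm = np.max(np.abs(t_perm), axis=1)  # (n_perm,)
    p_corr = (1 + np.sum(max_perm[:, None] >= abs_obs[None, :], axis=0)) / (n_perm + 1)
    return RegionalTestResult(
        t_scores=t_obs,
        p_uncorrected=p_unc,
        p_corrected=p_corr,
        n_permutations=n_perm,
        seed=seed,
    )


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation with mid-ranks for ties; two-sided p.

    Constant input yields ``(nan, nan)`` (undefined) rather than an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y lengths differ")
    if x.size < 4:
        raise ValueError("at least 4 observations are required")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return (float("nan"), float("nan"))
    rho, p = sps.spearmanr(x, y)
    return (float(rho), float(p))


def fdr_bky(
    p_values: np.ndarray, q: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Krieger–Yekutieli two-stage linear step-up FDR procedure.

    Stage 1 runs Benjamini–Hochberg at ``q' = q / (1 + q)``; the number of
    non-rejections estimates the number of true nulls m0.  If stage 1
    rejects nothing, nothing is rejected; if it rejects everything,
    everything is; otherwise stage 2 reruns the step-up at level
    ``q * m / m0``.  Returns ``(reject_flags, p_adjusted)``, where adjusted
    p-values are the m0-scaled step-up values (flags are the authoritative
    decision; they are monotone in p).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return (np.zeros(0, dtype=bool), np.zeros(0))
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ps = p[order]
    ranks = np.arange(1, m + 1)

    def step_up_count(level: float) -> int:
        ok = ps <= ranks * level / m
        return int(ranks[ok][-1]) if ok.any() else 0

    r1 = step_up_count(q / (1.0 + q))
    if r1 == 0:
        m0 = m
        n_reject = 0
    elif r1 == m:
        m0 = m
        n_reject = m
    else:
        m0 = m - r1
        # stage-2 step-up threshold: p_(i) <= i * (q * m / m0) / m = i * q / m0
        n_reject = step_up_count(q * m / m0)
    reject = np.zeros(m, dtype=bool)
    reject[order[:n_reject]] = True
    adj_sorted = np.minimum.accumulate((m0 * ps / ranks)[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return (reject, adj)


def iqr_outliers(values: np.ndarray, ids: list | None = None) -> list:
    """Tukey-fence outlier screen on pairwise differences.

    Flags points more than 1.5 × IQR below the first or above the third
    quartile (quartiles by linear interpolation).  Returns flagged ids (or
    indices when no ids are given); an empty list means no suspected
    outliers.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError("at least 4 values are required for the IQR screen")
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    mask = (x < q1 - 1.5 * iqr) | (x > q3 + 1.5 * iqr)
    idx = np.flatnonzero(mask)
    if ids is None:
        return idx.tolist()
    return [ids[i] for i in idx]


@dataclass
class KruskalDunnResult:
    h_statistic: float
    df: int
    p: float
    # one row per unordered group pair: (i, j, z, p_uncorrected, p_adjusted)
    pairwise: list[tuple[int, int, float, float, float]]


def kruskal_dunn(
    groups: list[np.ndarray], adjust: str = "holm"
) -> KruskalDunnResult:
    """Kruskal–Wallis H (tie-corrected) with Dunn's pairwise post-hoc z tests.

    Dunn's z compares mean pooled ranks between each pair of groups with the
    tie-corrected variance; pairwise p-values are adjusted over all pairs
    (Holm by default; any ``statsmodels`` ``multipletests`` method name works).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("at least 2 groups are required")
    if any(g.size == 0 for g in groups):
        raise ValueError("all groups must be non-empty")
    h, p = sps.kruskal(*groups)
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes = [], []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start : start + g.size].mean())
        sizes.append(g.size)
        start += g.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    pairs, p_unc = [], []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = np.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se
            pairs.append((i, j, float(z)))
            p_unc.append(2.0 * sps.norm.sf(abs(z)))
    if p_unc:
        _, p_adj, _, _ = multipletests(p_unc, method=adjust)
    else:
        p_adj = []
    pairwise = [
        (i, j, z, float(pu), float(pa))
        for (i, j, z), pu, pa in zip(pairs, p_unc, p_adj)
    ]
    return KruskalDunnResult(
        h_statistic=float(h), df=len(groups) - 1, p=float(p), pairwise=pairwise
    )


def eybso(carrier_age: float, onset: OnsetRecord) -> dict[str, float | None]:
    """Estimated years before symptom onset for one carrier.

    Each estimate is the reference onset age minus the carrier's current
    age, so a negative value means the carrier has passed the estimated
    onset age.  The parental reference falls back to the affected sibling's
    onset age when the parental age is unknown; a missing reference yields
    ``None``.
    """
    if carrier_age <= 0:
        raise ValueError("carrier age must be positive")
    parental = onset.parental_onset_age
    if parental is None:
        parental = onset.sibling_onset_age

    def _diff(ref: float | None) -> float | None:
        return None if ref is None else float(ref - carrier_age)

    return {
        "parent": _diff(parental),
        "family": _diff(onset.family_mean_onset_age),
        "mutation": _diff(onset.mutation_mean_onset_age),
    }
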