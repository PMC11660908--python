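"""End-to-end orchestration: IO, preprocessing, surrogate controls, full runs.

The pipeline reads plain-text epoch matrices (one file per epoch, samples as
rows, one column per atlas region) plus a cohort manifest CSV, computes the
spectral and connectivity measures per subject, builds each carrier's
surrogate control (the mean of its three matched controls' *outcome
measures* — never of raw signals), and runs the paired statistics and
hub-disruption analyses, emitting CSV/JSON tables and a seeded, reproducible
run log.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.signal import resample_poly

from . import connectivity as conn
from . import hub as hubmod
from . import stats as gstats
from .spectral import BandScheme, subject_spectral_summary
from .synthetic import CohortManifest

__all__ = [
    "RegionAtlas",
    "RunConfig",
    "EpochSet",
    "read_epochs",
    "write_epochs",
    "segment_and_downsample",
    "surrogate_average",
    "run_all",
]

# 40 bilateral AAL labels: 78 cortical regions plus the two hippocampi.
_AAL_BASE: list[tuple[str, str]] = [
    ("Precentral", "central"),
    ("Frontal_Sup", "frontal"),
    ("Frontal_Sup_Orb", "frontal"),
    ("Frontal_Mid", "frontal"),
    ("Frontal_Mid_Orb", "frontal"),
    ("Frontal_Inf_Oper", "frontal"),
    ("Frontal_Inf_Tri", "frontal"),
    ("Frontal_Inf_Orb", "frontal"),
    ("Rolandic_Oper", "central"),
    ("Supp_Motor_Area", "central"),
    ("Olfactory", "frontal"),
    ("Frontal_Sup_Medial", "frontal"),
    ("Frontal_Med_Orb", "frontal"),
    ("Rectus", "frontal"),
    ("Insula", "insula"),
    ("Cingulum_Ant", "cingulate"),
    ("Cingulum_Mid", "cingulate"),
    ("Cingulum_Post", "cingulate"),
    ("Hippocampus", "hippocampus"),
    ("ParaHippocampal", "temporal"),
    ("Calcarine", "occipital"),
    ("Cuneus", "occipital"),
    ("Lingual", "occipital"),
    ("Occipital_Sup", "occipital"),
    ("Occipital_Mid", "occipital"),
    ("Occipital_Inf", "occipital"),
    ("Fusiform", "temporal"),
    ("Postcentral", "central"),
    ("Parietal_Sup", "parietal"),
    ("Parietal_Inf", "parietal"),
    ("SupraMarginal", "parietal"),
    ("Angular", "parietal"),
    ("Precuneus", "parietal"),
    ("Paracentral_Lobule", "central"),
    ("Heschl", "temporal"),
    ("Temporal_Sup", "temporal"),
    ("Temporal_Pole_Sup", "temporal"),
    ("Temporal_Mid", "temporal"),
    ("Temporal_Pole_Mid", "temporal"),
    ("Temporal_Inf", "temporal"),
]


@dataclass(frozen=True)
class RegionAtlas:
    """Ordered region labels with hemisphere and lobe tags."""

    labels: tuple[str, ...]
    hemispheres: tuple[str, ...]
    lobes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("atlas labels must be unique")
        if not len(self.labels) == len(self.hemispheres) == len(self.lobes):
            raise ValueError("atlas fields must have equal length")

    def __len__(self) -> int:
        return len(self.labels)

    @classmethod
    def default_80(cls) -> "RegionAtlas":
        """The 80-region parcellation: 78 cortical AAL regions + 2 hippocampi."""
        labels, hemis, lobes = [], [], []
        for base, lobe in _AAL_BASE:
            for hemi in ("L", "R"):
                labels.append(f"{base}_{hemi}")
                hemis.append(hemi)
                lobes.append(lobe)
        return cls(labels=tuple(labels), hemispheres=tuple(hemis), lobes=tuple(lobes))

    @classmethod
    def generic(cls, n_regions: int) -> "RegionAtlas":
        """Numbered labels for non-standard region counts (reduced test runs)."""
        return cls(
            labels=tuple(f"region{i:02d}" for i in range(n_regions)),
            hemispheres=tuple("L" if i % 2 == 0 else "R" for i in range(n_regions)),
            lobes=("unknown",) * n_regions,
        )


@dataclass
class RunConfig:
    """Analysis settings; the defaults reproduce the study protocol.

    10 epochs of 4096 samples per subject, the six-band scheme over
    0.5–48 Hz, PLI in theta and AECc in alpha/beta, 2000 permutations for
    the regional tests.  The sampling rate always comes from the manifest.
    """

    n_epochs_required: int = 10
    epoch_samples: int = 4096
    target_fs: float | None = None  # resample target for raw input, if any
    n_perm: int = 2000
    seed: int = 0
    out_dir: str = "megpipe_out"
    edge_trim: int = 0
    exact_wilcoxon: bool = False
    exclude_self_reference: bool = False
    allow_any_group_size: bool = False
    fdr_q: float = 0.05
    band_scheme: BandScheme = field(default_factory=BandScheme)
    measures: tuple[tuple[str, str], ...] = (
        ("pli", "theta"),
        ("aecc", "alpha"),
        ("aecc", "beta"),
    )

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__ if f not in ("band_scheme", "measures")}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**{k: raw[k] for k in raw})

    def content_hash(self) -> str:
        payload = {
            k: v
            for k, v in asdict(self).items()
            if k not in ("band_scheme",)
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


@dataclass
class EpochSet:
    """One subject's retained epochs: (n_epochs, n_regions, n_samples)."""

    subject_id: str
    data: np.ndarray
    fs_hz: float
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be (n_epochs, n_regions, n_samples)")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]


def read_epochs(
    data_dir: str | Path,
    subject_id: str,
    fs_hz: float,
    atlas: RegionAtlas | int | None = None,
) -> EpochSet:
    """Read a subject's plain-text epoch files (``<id>_epoch*.txt``).

    Files are whitespace-delimited numeric matrices, samples as rows and one
    column per region, loaded in filename order.  The column count must
    match the atlas (an integer is accepted as a bare region count).
    """
    data_dir = Path(data_dir)
    paths = sorted(data_dir.glob(f"{subject_id}_epoch*.txt"))
    if not paths:
        raise FileNotFoundError(f"no epoch files for subject {subject_id!r} in {data_dir}")
    if isinstance(atlas, RegionAtlas):
        n_expected, labels = len(atlas), atlas.labels
    elif isinstance(atlas, int):
        n_expected, labels = atlas, None
    else:
        n_expected, labels = None, None
    epochs = []
    for path in paths:
        try:
            mat = np.loadtxt(path, ndmin=2)
        except ValueError as err:
            raise ValueError(f"non-numeric data in {path}: {err}") from err
        if n_expected is None:
            n_expected = mat.shape[1]
        if mat.shape[1] != n_expected:
            raise ValueError(
                f"{path} has {mat.shape[1]} columns; expected {n_expected} regions"
            )
        epochs.append(mat.T)  # store as regions x samples
    data = np.stack(epochs)
    return EpochSet(subject_id=subject_id, data=data, fs_hz=fs_hz, labels=labels)


def write_epochs(epoch_set: EpochSet, out_dir: str | Path, fmt: str = "%.6e") -> list[Path]:
    """Write an EpochSet back to per-epoch text files (samples as rows)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for e, epoch in enumerate(epoch_set.data):
        path = out_dir / f"{epoch_set.subject_id}_epoch{e:02d}.txt"
        np.savetxt(path, epoch.T, fmt=fmt)
        paths.append(path)
    return paths


def segment_and_downsample(
    raw: np.ndarray,
    fs_in: float,
    target_fs: float,
    epoch_samples: int = 4096,
    n_epochs: int | None = None,
) -> tuple[np.ndarray, float]:
    """Anti-aliased resampling followed by non-overlapping segmentation.

    ``raw`` is (n_regions, n_samples) continuous data.  Polyphase resampling
    brings it to ``target_fs`` (rationalised to within 1e-6), then
    consecutive windows of ``epoch_samples`` are cut; any remainder at the
    end is discarded.  Returns ``(epochs, fs_out)`` with epochs shaped
    (n_epochs, n_regions, epoch_samples).
    """
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    frac = Fraction(target_fs / fs_in).limit_denominator(10000)
    resampled = resample_poly(raw, frac.numerator, frac.denominator, axis=-1)
    fs_out = fs_in * frac.numerator / frac.denominator
    available = resampled.shape[-1] // epoch_samples
    if available < 1 or (n_epochs is not None and available < n_epochs):
        need = (n_epochs or 1) * epoch_samples / fs_out
        raise ValueError(
            f"recording too short: {resampled.shape[-1] / fs_out:.1f} s after "
            f"resampling, {need:.1f} s required"
        )
    n_keep = n_epochs if n_epochs is not None else available
    trimmed = resampled[:, : n_keep * epoch_samples]
    epochs = trimmed.reshape(raw.shape[0], n_keep, epoch_samples).transpose(1, 0, 2)
    return epochs, fs_out


def surrogate_average(control_values: np.ndarray, n_required: int = 3) -> np.ndarray:
    """Mean outcome measure over a carrier's matched controls.

    Applied strictly at the outcome-measure level (band powers, degrees,
    whole-brain means) — raw signals are never mixed.
    """
    control_values = np.asarray(control_values, dtype=float)
    if control_values.shape[0] != n_required:
        raise ValueError(
            f"surrogate averaging expects {n_required} matched controls, "
            f"got {control_values.shape[0]}"
        )
    return control_values.mean(axis=0)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


def _subject_measures(epoch_set: EpochSet, config: RunConfig) -> dict:
    """All outcome measures for one subject."""
    summary = subject_spectral_summary(
        epoch_set.data, epoch_set.fs_hz, config.band_scheme
    )
    out = {
        "spectral_regional": summary.regional,
        "whole_brain": dict(summary.whole_brain),
        "degrees": {},
    }
    for measure, band in config.measures:
        cm = conn.connectivity_matrix(
            epoch_set.data, measure, band, epoch_set.fs_hz, edge_trim=config.edge_trim
        )
        prof = conn.degrees(cm)
        key = f"{measure}_{band}"
        out["degrees"][key] = prof.degree
        out["whole_brain"][f"wb_{key}"] = prof.whole_brain_mean
    return out


def run_all(
    config: RunConfig,
    manifest: CohortManifest | str | Path,
    data_dir: str | Path,
) -> dict:
    """Run the whole analysis and write the report bundle.

    Stages: per-subject spectral and connectivity measures; carrier vs
    surrogate Wilcoxon tests on every whole-brain measure; regional paired
    sign-flip permutation tests with maximal-statistic correction; group and
    individual hub-disruption indices with a Kruskal–Wallis/Dunn comparison
    of the HDI groups; EYBSO and Spearman correlations (BKY-FDR adjusted);
    and a Tukey-fence outlier screen of pair differences.  Deterministic
    given ``config.seed``.
    """
    if not isinstance(manifest, CohortManifest):
        manifest = CohortManifest.from_frame(pd.read_csv(manifest))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    measures: dict[str, dict] = {}
    for subject in manifest.subjects:
        try:
            es = read_epochs(data_dir, subject.id, manifest.fs_hz)
            if es.n_epochs < config.n_epochs_required:
                raise ValueError(
                    f"{es.n_epochs} epochs found, {config.n_epochs_required} required"
                )
            measures[subject.id] = _subject_measures(es, config)
        except Exception as err:
            raise RuntimeError(
                f"stage 'subject measures' failed for subject {subject.id}: {err}"
            ) from err

    wb_names = list(next(iter(measures.values()))["whole_brain"])
    subject_summary = pd.DataFrame(
        {sid: m["whole_brain"] for sid, m in measures.items()}
    ).T.loc[[s.id for s in manifest.subjects], wb_names]
    subject_summary.insert(0, "group", [s.group for s in manifest.subjects])

    carriers = manifest.carriers
    n_req = 3 if not config.allow_any_group_size else None

    def surrogate_wb(carrier_id: str, name: str) -> float:
        vals = np.array(
            [
                measures[c.id]["whole_brain"][name]
                for c in manifest.matched_controls(carrier_id)
            ]
        )
        return float(surrogate_average(vals, n_required=n_req or vals.shape[0]))

    # --- paired Wilcoxon tests on whole-brain measures -------------------
    wilcoxon_rows = []
    pair_diffs: dict[str, np.ndarray] = {}
    for name in wb_names:
        carrier_vals = np.array([measures[c.id]["whole_brain"][name] for c in carriers])
        surrogate_vals = np.array([surrogate_wb(c.id, name) for c in carriers])
        res = gstats.wilcoxon_paired(
            gstats.PairedSample(
                carrier_vals, surrogate_vals, pair_ids=[c.id for c in carriers]
            ),
            exact=config.exact_wilcoxon,
        )
        pair_diffs[name] = carrier_vals - surrogate_vals
        wilcoxon_rows.append(
            {
                "measure": name,
                "z": res.z,
                "p": res.p,
                "n_pairs": len(carriers),
                "median_difference": res.median_difference,
                "carrier_median": float(np.median(carrier_vals)),
                "surrogate_median": float(np.median(surrogate_vals)),
            }
        )
    wilcoxon_table = pd.DataFrame(wilcoxon_rows)

    # --- regional permutation tests --------------------------------------
    seed_seq = np.random.SeedSequence(config.seed)
    regional_tables = {}
    regional_specs = [(f"rel_{b}", "spectral") for b in config.band_scheme.names]
    regional_specs += [("peak_freq_hz", "spectral")]
    regional_specs += [(f"{m}_{b}", "degree") for m, b in config.measures]
    child_seeds = seed_seq.spawn(len(regional_specs))
    for (name, kind), child in zip(regional_specs, child_seeds):
        def regional(sid: str) -> np.ndarray:
            m = measures[sid]
            if kind == "spectral":
                return m["spectral_regional"][name].to_numpy()
            return m["degrees"][name]

        carrier_mat = np.column_stack([regional(c.id) for c in carriers])
        surrogate_mat = np.column_stack(
            [
                surrogate_average(
                    np.array([regional(c.id) for c in manifest.matched_controls(car.id)])
                )
                for car in carriers
            ]
        )
        res = gstats.regional_permutation_test(
            carrier_mat,
            surrogate_mat,
            n_perm=config.n_perm,
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        regional_tables[name] = pd.DataFrame(
            {
                "t_score": res.t_scores,
                "p_uncorrected": res.p_uncorrected,
                "p_corrected": res.p_corrected,
            }
        )

    # --- hub disruption --------------------------------------------------
    hdi_group = {}
    hdi_individual_rows = []
    for measure, band in config.measures:
        key = f"{measure}_{band}"
        carrier_deg = [measures[c.id]["degrees"][key] for c in carriers]
        control_deg = [measures[c.id]["degrees"][key] for c in manifest.controls]
        g = hubmod.group_hdi(carrier_deg, control_deg)
        hubmod.plot_hdi(g, out_dir / f"hdi_group_{key}.png", title=key)
        hdi_group[key] = {
            "slope": g.slope,
            "intercept": g.intercept,
            "slope_p": g.slope_p,
            "r_squared": g.r_squared,
        }
        for car in carriers:
            ref = surrogate_average(
                np.array(
                    [
                        measures[c.id]["degrees"][key]
                        for c in manifest.matched_controls(car.id)
                    ]
                )
            )
            r = hubmod.individual_hdi(measures[car.id]["degrees"][key], ref)
            hdi_individual_rows.append(
                {
                    "subject": car.id,
                    "group": "carrier",
                    "measure": key,
                    "slope": r.slope,
                    "intercept": r.intercept,
                    "slope_p": r.slope_p,
                }
            )
        for ctrl in manifest.controls:
            peers = manifest.matched_controls(ctrl.matched_carrier_id)
            if config.exclude_self_reference:
                peers = [p for p in peers if p.id != ctrl.id]
            ref = np.mean(
                [measures[p.id]["degrees"][key] for p in peers], axis=0
            )
            r = hubmod.individual_hdi(
                measures[ctrl.id]["degrees"][key], ref, allow_any_group_size=True
            )
            hdi_individual_rows.append(
                {
                    "subject": ctrl.id,
                    "group": "control",
                    "measure": key,
                    "slope": r.slope,
                    "intercept": r.intercept,
                    "slope_p": r.slope_p,
                }
            )
    hdi_individual = pd.DataFrame(hdi_individual_rows)

    # Kruskal-Wallis + Dunn across the six HDI groups (2 groups x 3 measures)
    hdi_groups, hdi_group_labels = [], []
    for measure, band in config.measures:
        key = f"{measure}_{band}"
        for grp in ("carrier", "control"):
            sel = hdi_individual.query("measure == @key and group == @grp")["slope"]
            hdi_groups.append(sel.to_numpy())
            hdi_group_labels.append(f"{key}_{grp}")
    kruskal = gstats.kruskal_dunn(hdi_groups)

    # --- EYBSO + correlations --------------------------------------------
    eybso_rows = []
    for car in carriers:
        rec = manifest.onset_records.get(car.id)
        vals = (
            gstats.eybso(car.age, rec)
            if rec is not None
            else {"parent": None, "family": None, "mutation": None}
        )
        eybso_rows.append({"subject": car.id, "age": car.age, **vals})
    eybso_table = pd.DataFrame(eybso_rows)

    corr_measures = [n for n in wb_names if n.startswith(("rel_theta", "rel_alpha2", "peak", "wb_"))]
    clinical = {"age": np.array([c.age for c in carriers])}
    for k in ("parent", "family", "mutation"):
        col = eybso_table[k].to_numpy(dtype=float)
        if not np.any(np.isnan(col)):
            clinical[f"eybso_{k}"] = col
    corr_rows = []
    if len(carriers) >= 4:  # Spearman needs at least 4 observations
        for mname in corr_measures:
            mvals = np.array([measures[c.id]["whole_brain"][mname] for c in carriers])
            for cname, cvals in clinical.items():
                rho, p = gstats.spearman(mvals, cvals)
                corr_rows.append(
                    {"measure": mname, "clinical": cname, "rho": rho, "p": p}
                )
    corr_table = pd.DataFrame(corr_rows)
    if len(corr_table) and corr_table["p"].notna().all():
        reject, p_adj = gstats.fdr_bky(corr_table["p"].to_numpy(), q=config.fdr_q)
        corr_table["p_fdr_bky"] = p_adj
        corr_table["significant_fdr"] = reject

    # --- outlier screen ---------------------------------------------------
    outliers = {
        name: gstats.iqr_outliers(diffs, ids=[c.id for c in carriers])
        for name, diffs in pair_diffs.items()
        if diffs.size >= 4
    }

    # --- write bundle -----------------------------------------------------
    subject_summary.to_csv(out_dir / "subject_summary.csv")
    wilcoxon_table.to_csv(out_dir / "wilcoxon_whole_brain.csv", index=False)
    for name, table in regional_tables.items():
        table.to_csv(out_dir / f"regional_{name}.csv", index=False)
    hdi_individual.to_csv(out_dir / "hdi_individual.csv", index=False)
    eybso_table.to_csv(out_dir / "eybso.csv", index=False)
    corr_table.to_csv(out_dir / "correlations.csv", index=False)
    with open(out_dir / "hdi_group.json", "w") as fh:
        json.dump(hdi_group, fh, indent=2)
    with open(out_dir / "kruskal_dunn.json", "w") as fh:
        json.dump(
            {
                "H": kruskal.h_statistic,
                "df": kruskal.df,
                "p": kruskal.p,
                "groups": hdi_group_labels,
                "pairwise": kruskal.pairwise,
            },
            fh,
            indent=2,
        )
    with open(out_dir / "outliers.json", "w") as fh:
        json.dump(outliers, fh, indent=2)
    with open(out_dir / "run_log.txt", "w") as fh:
        fh.write(
            f"seed: {config.seed}\nconfig_hash: {config.content_hash()}\n"
            f"n_subjects: {len(manifest.subjects)}\n"
            f"n_carriers: {len(carriers)}\nn_perm: {config.n_perm}\n"
        )

    return {
        "subject_summary": subject_summary,
        "wilcoxon": wilcoxon_table,
        "regional": regional_tables,
        "hdi_group": hdi_group,
        "hdi_individual": hdi_individual,
        "kruskal_dunn": kruskal,
        "eybso": eybso_table,
        "correlations": corr_table,
        "outliers": outliers,
    }
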