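# megpipe

Resting-state MEG analysis of oscillatory slowing and hub vulnerability:
spectral band power, phase- and amplitude-based functional connectivity, the
hub disruption index, and the paired non-parametric statistics used to
compare a small group of mutation carriers against age-matched surrogate
controls — together with a seeded synthetic cohort generator that provides
ground truth for every stage.

## Who this is for

Electrophysiologists and methods researchers who work with source-level MEG
(or EEG) region time-series and want a tested, reproducible implementation
of a standard "slowing + hub disconnection" analysis stack, or who need a
controllable signal generator to validate connectivity estimators.

## What it computes

Given region × sample epochs (80 regions by default: 78 cortical AAL regions
plus both hippocampi), per subject:

* **Spectral**: raw FFT periodogram over 0.5–48 Hz; absolute and relative
  power in six bands (δ 0.5–4, θ 4–8, α1 8–10, α2 10–13, β 13–30,
  γ 30–48 Hz), with rel. power *P_b / P_total* summing to 1, and the peak
  frequency `argmax_{4–13 Hz} P(f)`.
* **Connectivity**:
  - phase lag index in theta,
    `PLI = | ⟨ sign( sin(φ_i(t) − φ_j(t)) ) ⟩_t |` — 0 for no or zero-lag
    coupling, 1 for a consistent non-zero lag;
  - leakage-corrected amplitude envelope correlation in alpha (8–13 Hz) and
    beta: pairwise orthogonalization by linear regression in both
    directions, Pearson correlation of Hilbert envelopes, directions
    averaged and mapped to [0, 1] via `(r + 1)/2` (0.5 = no coupling);
  - weighted functional degree `k_r = (1/(n−1)) Σ_{s≠r} W_rs` and
    whole-brain mean connectivity.
* **Hub disruption index**: OLS slope of regional degree differences
  (target − reference) against reference degrees; HDI < 0 means hubs lose
  connectivity preferentially. Group-level and per carrier–surrogate pair.
* **Statistics**: Wilcoxon matched-pairs signed-rank (SPSS-style
  tie-corrected z) on whole-brain measures; paired sign-flip permutation
  tests (default 2000 permutations) with maximal-statistic family-wise
  correction on regional measures; Spearman correlations with
  Benjamini–Krieger–Yekutieli two-stage FDR; Kruskal–Wallis + Dunn for HDI
  groups; 1.5 × IQR outlier screening; estimated years before symptom
  onset (EYBSO).

Each carrier is compared against its *surrogate control* — the mean outcome
measures of its three age-matched controls.

## Worked example

Simulate a small cohort with the built-in "slowing + hub disconnection"
contrast (carriers: theta ×1.6, alpha2 ×0.6, peak −1.2 Hz, hub coupling
attenuated to 0.4) and run the full analysis:

```python
import megpipe as mp

spec     = mp.SignalSpec(n_epochs=4, n_samples=2048)          # desk scale
manifest = mp.default_manifest(n_carriers=3, seed=0)          # 3 : 9 cohort
coupling = mp.default_coupling(n_regions=12, seed=0)
shift    = mp.CarrierShift.slowing_contrast()
path     = mp.make_cohort(manifest, spec, shift, coupling, "demo_cohort")

config = mp.RunConfig(n_epochs_required=4, epoch_samples=2048,
                      n_perm=500, seed=1, out_dir="demo_report")
report = mp.run_all(config, path, "demo_cohort")

w = report["wilcoxon"].set_index("measure")
for m in ["rel_theta", "rel_alpha2", "peak_freq_hz",
          "wb_aecc_alpha", "wb_aecc_beta"]:
    r = w.loc[m]
    print(f"{m:15s} carrier_median={r.carrier_median:.4f} "
          f"surrogate_median={r.surrogate_median:.4f} z={r.z:.3f} p={r.p:.3f}")
for k, v in report["hdi_group"].items():
    print(f"group HDI {k}: slope={v['slope']:.3f} p={v['slope_p']:.4g}")
```

Output:

```
rel_theta       carrier_median=0.2216 surrogate_median=0.1186 z=-1.604 p=0.109
rel_alpha2      carrier_median=0.0961 surrogate_median=0.2341 z=-1.604 p=0.109
peak_freq_hz    carrier_median=8.2970 surrogate_median=9.8186 z=-1.604 p=0.109
wb_aecc_alpha   carrier_median=0.4888 surrogate_median=0.4931 z=-0.535 p=0.593
wb_aecc_beta    carrier_median=0.4994 surrogate_median=0.4986 z=-0.535 p=0.593
group HDI pli_theta: slope=-1.115 p=0.0009544
group HDI aecc_alpha: slope=-1.191 p=0.005666
group HDI aecc_beta: slope=-0.505 p=0.03868
```

The simulated carriers show the programmed pattern: higher relative theta
power, lower alpha2 power, a lower peak frequency, and significantly
negative group HDI slopes — hubs lose coupling preferentially. (With only 3
pairs the Wilcoxon two-sided p cannot fall below 0.109; the z statistic
follows the SPSS smaller-rank-sum convention and is never positive — read
the direction from the medians.) `demo_report/` holds the full bundle:
per-subject summaries, regional permutation-test tables, individual HDIs,
the Kruskal–Wallis/Dunn comparison of HDI groups, EYBSO values and the
seeded run log.

The same pipeline is available from a shell:

```sh
megpipe simulate --config sim.yaml --out cohort/ --seed 3
megpipe run-all --manifest cohort/manifest.csv --data cohort/ \
        --seed 3 --out report/
```

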