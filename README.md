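# aortastiff

Aortic stiffness quantification from flow waveforms, built for method
validation in a case–control setting: coronary artery disease (CAD)
patients versus matched controls.

Aortic pulse wave velocity (PWV) — the speed of the systolic wavefront
along the aorta — is a standard index of arterial stiffness: a stiffer
wall transmits the wave faster. 4D-flow MRI yields flow-rate curves
Q(t) at many planes along the aortic centerline, but at a coarse
effective temporal resolution (~34 ms), far above the few-millisecond
transit times between neighbouring planes. This package implements and
validates the pipeline that makes multi-plane PWV work anyway:

* **Synthetic substrate with known truth** — a parametric 3D aortic
  centerline with the eight standard anatomical landmarks, gamma-variate
  flow waveforms propagated at a prescribed PWV
  (`Q_i(t) = a_i · Q(t − d_i/PWV)`), MRI-like temporal sampling
  (34 ms acquisition → 50 reconstructed phases) and Gaussian noise at a
  stated SNR.
* **Sub-sample transit-time estimators** — a cross-wavelet phase method
  (analytic Morlet; amplitude·f²-weighted phase delays over the systolic
  upslope), a classical intersecting-tangent foot-to-foot method, and a
  normalized upslope cross-correlation with parabolic refinement.
* **Stiffness measures** — multi-plane 4D PWV via a distance–delay
  regression (delay on distance, PWV = 1/slope), two-plane 2D PWV
  (length/transit time), and aortic distensibility
  `D = ΔA/(Amin·PP)` averaged over ascending and descending sites.
* **Case–control statistics** — Shapiro–Wilk-gated t / Wilcoxon rank-sum
  comparisons, Fisher's exact test, Spearman/Pearson correlation
  matrices, and ROC analysis with the Youden-optimal threshold
  (trapezoidal AUC = Mann–Whitney U/(n₁n₂)).
* **Cohort simulator** — two-group Gaussian-copula draws (35 patients /
  18 controls by default) whose marginals match the published group
  summaries and whose within-group copula is calibrated by monotone
  bisection so pooled cross-method Spearman correlations match the
  published mixed-group values.

See `docs/methods.md` for the model, estimator details and numerical
choices.

## Worked example

Simulate one subject end to end and re-estimate the stiffness panel from
its (noisy, coarsely sampled) flow curves:

```python
from aortastiff import (default_cohort_spec, draw_cohort, make_centerline,
                        simulate_subject_flow, make_area_and_pressure,
                        subject_panel)

spec = default_cohort_spec()                 # the 35/18 case-control study
cohort = draw_cohort(spec, seed=1)
subject = cohort[0]

centerline = make_centerline(total_length=330.0, seed=1)
curves = simulate_subject_flow(subject, centerline=centerline,
                               snr_db=20.0, seed=1)   # 34 ms -> 50 phases
aa, da, pressure = make_area_and_pressure(subject)
panel = subject_panel(flow_curves=curves, areas_aa=aa, areas_da=da,
                      pressure=pressure, cf_pwv=subject.true_cf_pwv,
                      centerline=centerline)

print(f"subject {subject.subject_id} ({subject.group}): "
      f"true 4D PWV {subject.true_pwv:.2f} m/s, "
      f"distensibility {subject.true_distensibility:.2f}e-3/mmHg")
for name, value in panel.as_dict().items():
    print(f"  {name:>15}: {value:.2f}")
```

Output:

```
subject s001 (CAD): true 4D PWV 15.71 m/s, distensibility 2.71e-3/mmHg
           cf_pwv: 10.84
           pwv_2d: 11.57
           pwv_4d: 16.45
   distensibility: 2.71
```

The 4D PWV estimate (16.45 m/s) recovers the subject's true propagation
speed (15.71 m/s) from 50-phase, SNR-20 dB curves to within ~5%;
distensibility is recovered exactly because the area generator inverts
the same definition the analysis applies; cf PWV is a tonometry
passthrough. The 2D estimate uses only the two cine-slice landmark planes
and a single transit time, hence its larger spread — reproducing the
practical accuracy ordering of the three PWV methods.

From the shell, the same machinery is available as subcommands:

```bash
aortastiff run-study --seed 1 --out out/          # simulate + analyze + report
aortastiff recovery-benchmark --levels 8,18 --n-seeds 20
```

the latter printing, e.g.:

```
true   8.0 m/s: mean   7.97  bias  -0.4%  SD  2.3%
true  18.0 m/s: mean  18.19  bias  +1.1%  SD  2.8%
```

`run-study` writes `subjects.csv`, `panel.csv`, `report.json`,
`report.txt` (Table-1-style comparisons, the ROC block with thresholds
and sensitivity/specificity, and the stiffness correlation matrix) plus a
`manifest.json` with config snapshot, seed and file digests — identical
seed and config reproduce the outputs byte for byte.

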