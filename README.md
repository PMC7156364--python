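# phantomqc

Quality control for BOLD fMRI scanning with an **active phantom** — a gel
cylinder with embedded copper wires whose local B0 field is perturbed on
command by a stimulus current, producing BOLD-scale (≈ 1–10 %) EPI signal
changes without a subject.  `phantomqc` is for MR physicists and QA
technologists who want to quantify, on any scanner or on simulated data,
how reliably an fMRI protocol detects small task-locked signal changes.

The package contains both halves of that workflow:

* a **physics-based simulator** — wire field model → intra-voxel dephasing
  → noisy 4D EPI time series written as NIfTI-1 — that reproduces a
  standard phantom QA protocol (64×64 matrix, FOV 240 mm, 11 × 5 mm
  slices, TR 2000 ms, TE 30 ms, 100 volumes, alternating 10 s baseline /
  10 s active blocks at 8/12/24/48 mA);
* a **QC analysis stack** that runs on any 4D series, simulated or
  acquired: static spatial noise, temporal fluctuation noise (TFN) and
  SFNR, ROI SNR, Nyquist-ghost ratio, percent signal change (PSC),
  stimulus-detection efficiency, baseline stability, motion and k-space
  stability summaries, and a block-design GLM with thresholded,
  cluster-filtered t-maps.

## Model

A straight wire of radius *a* parallel to B0 carrying current *I* induces
an azimuthal field

```
B(r) = μ0 I r / (2π a²)        r <  a        (inside the wire)
B(r) = μ_rel μ0 I / (2π r)     r ≥  a        (outside, in gel)
```

maximal at the wire surface and perpendicular to B0.  Fields of several
wires superpose as signed in-plane vectors; unconnected wires contribute
nothing.  The field gradient across a voxel dephases spins within it, so
each voxel's signal is attenuated by

```
S = S0 · exp(−TE/T2*) · |sinc(γ · c · Δ B · TE / 2)|
```

where ΔB is the intra-voxel field span (sampled on a q×q subgrid) and *c*
a dimensionless scanner coupling factor.  The phantom has no physiology:
the stimulus regressor is a pure boxcar, with no hemodynamic response
function.  On top of the clean signal the simulator layers linear drift, a
fractional N/2 ghost (a scaled copy shifted by half the matrix along the
phase-encode axis), Rician or Gaussian thermal noise, and optional
whole-volume RF-jamming spikes — everything seeded and bit-reproducible.

The QC metrics follow the conventional definitions: static spatial noise
is the NEMA odd/even volume-sum difference; TFN is the per-voxel temporal
SD and SFNR the ROI mean over the ROI TFN; SNR is Signal/√(noise per time
point); the ghosting ratio is |(ROI_up + ROI_down) − (ROI_right +
ROI_left)| / (2 ROI_center) × 100; PSC is |Active − Baseline|/Baseline ×
100; detection efficiency is N_detected/N_delivered × 100.  The GLM fits
[boxcar, intercept, drift] by OLS per voxel and thresholds t-maps
two-sided at p = 0.05 with a ≥ 5-voxel cluster rule (in-plane
4-connectivity).

## Worked example

```python
from phantomqc import (preset_paper_protocol, simulate_series,
                       compute_qc_report, wire_roi)

geometry, acq, design, noise = preset_paper_protocol(seed=1)
series = simulate_series(geometry, acq, design, noise)
report = compute_qc_report(series, design, psc_roi=wire_roi(geometry, acq))

r9 = report.rois[0]                     # the 3×3 "9 pixel" center ROI
print(f"signal {r9.signal:.1f}  TFN {r9.tfn:.2f}  SFNR {r9.sfnr:.1f}  SNR {r9.snr:.1f}")
print(f"ghost {report.ghosting_ratio_pct:.3f} %   "
      f"baseline stability {report.baseline_stability_pct:.3f} %")
print("PSC:", {k: round(v, 2) for k, v in report.psc_pct.items()})
print(f"detection {report.sensitivity_pct:.0f} % "
      f"({report.n_actual}/{report.n_theoretical})")
```

prints

```
signal 780.9  TFN 2.59  SFNR 301.7  SNR 1600.4
ghost 0.152 %   baseline stability 0.185 %
PSC: {'8 mA': 0.26, '12 mA': 0.61, '24 mA': 2.65, '48 mA': 9.9}
detection 90 % (9/10)
```

The baseline gel signal sits near 781 (S0 e^{−TE/T2*}), its fluctuation is
well under 1 %, and PSC grows monotonically from ≈ 0.3 % at 8 mA to
≈ 10 % at 48 mA — the dynamic range of cortical BOLD responses.  At the
default noise level the weakest (8 mA) stimulus blocks sit near the k = 2
detection threshold, so one of the ten delivered stimuli is missed here.

The same pipeline is available from the shell:

```
phantomqc preset --out cfg.yaml            # dump the editable protocol config
phantomqc run --config cfg.yaml --outdir out/
phantomqc simulate --config cfg.yaml --seed 7 --out series.nii.gz
phantomqc qc series.nii.gz --config cfg.yaml --out report.json
phantomqc glm series.nii.gz --config cfg.yaml --p 0.05 --min-cluster 5
```

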