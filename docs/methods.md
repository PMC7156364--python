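# Methods

This note records the model, the default parameters, the numerical
choices and the known limits of `phantomqc`, in the spirit of a model
documentation page rather than a user manual.

## Wire field model

Wires are treated as infinite straight conductors parallel to the bore.
The induced field magnitude is piecewise in the distance *r* from the
wire axis: μ0·I·r/(2π a²) inside the conductor (radius *a*) and
μ_rel·μ0·I/(2π r) outside.  The gel "relative permeability" enters as the
dimensionless factor μ_rel multiplying μ0 (defaults to 1; agarose
diamagnetism is orders of magnitude below the precision of anything
downstream, and values outside 1 ± 10⁻⁴ are rejected as configuration
errors).  Because all wires are parallel, the per-wire fields at a point
are azimuthal vectors in the axial plane; they are summed as signed
vector components — the sign set by whether the current runs parallel or
antiparallel to B0 — and the magnitude of the sum is taken.  This reduces
exactly to the scalar formula for one wire, doubles at the symmetric
midline point between two co-directed wires, and cancels appropriately
between counter-directed ones.  End effects, eddy currents and RF-coil
fields are out of scope.

Grid conventions: axial plane, millimetres, origin on the cylinder axis,
0-based voxel indices, voxel centers at `(i − (n−1)/2)·Δ` with Δ =
FOV/matrix (3.75 mm at the default 240 mm / 64).  The field is invariant
along the bore, so a single axial map serves all slices.

## Default phantom

A 14 cm inner-diameter gel cylinder with four 1 mm enamelled copper wires
on a line through the axis at 2.5 cm pitch (x = ±12.5, ±37.5 mm).  Only
the wire at +12.5 mm is in the stimulus circuit; the mirror wire at
−12.5 mm is the unconnected control, which by construction carries no
current and shows no modulation.  Gel relaxation defaults are the
peripheral-region relaxometry of a doped agarose recipe: T1 = 1409.8 ms,
T2 = 292.5 ms, T2* = 121.3 ms.  (The center-region values measured for
such phantoms are contaminated by the wires themselves, and a published
center T2 of 372.4 ± 939.1 ms is internally inconsistent — SD larger than
the mean — so the peripheral row is the sensible gel default.)

## Signal model and the coupling constant

The simulator converts field structure to signal loss by intra-voxel
dephasing: each voxel's attenuation is |sinc(γ·c·ΔB·TE/2)| where ΔB is
the range of the field magnitude over a q×q subgrid of the voxel (q = 5
by default; the 1/r field is smooth at 3.75 mm voxels and the span has
converged to ≪ 1 % by q = 5) and γ = 2.675×10⁸ rad s⁻¹ T⁻¹.  This is the
standard static-dephasing (mesoscopic) approximation; the true coupling
between a perpendicular induced field and the resonance offset depends on
scanner properties that vary widely between systems — measured PSC at
identical currents differs by an order of magnitude between 1.5 T and 3 T
scanners — so the model deliberately exposes a single dimensionless
coupling factor *c* rather than predicting per-scanner values.

The default c = 0.08 was fixed once, analytically: the wire-adjacent
voxel's span is ≈ 7×10⁻⁵ T per ampere, so c = 0.08 puts the 48 mA
dephasing argument near 1.1 rad — inside the first sinc lobe, where
attenuation is monotone in current — and makes the 8→48 mA protocol span
a PSC of roughly 0.3 % to 10 %, the dynamic range of cortical BOLD.
Larger couplings push the strongest condition past the first sinc zero,
where more current gives *less* apparent signal change and the PSC-vs-
current ordering inverts; that regime is physically reachable but not a
sane default for a QA instrument.

Baseline amplitude is S0·exp(−TE/T2*) with S0 = 1000, i.e. ≈ 781 at
TE 30 ms — a typical mid-700s phantom EPI reading.  Voxels outside the
cylinder, and voxels whose footprint overlaps a wire (copper gives no MR
signal), carry zero clean signal.

## Noise model and defaults

Layered after the clean signal, in order: linear drift (default
1×10⁻⁵/volume, 0.1 % over a run), N/2 ghost (a copy scaled by
`ghost_fraction`, default 0.004, circularly shifted by matrix/2 along the
phase-encode axis), thermal noise (default SD 2.5 in signal units;
Rician by default since EPI magnitude data are Rician, Gaussian
selectable for analytic calibration work), and whole-volume
multiplicative spikes emulating occasional RF-jamming over-range events
(default rate 0 — the phenomenon is occasional by nature, and a quiet
baseline below 1 % fluctuation is itself a protocol requirement; jamming
studies switch it on explicitly).  These defaults land the simulated
baseline near the behaviour expected of a healthy scanner: TFN ≈ 2.6,
SFNR ≈ 300, baseline fluctuation ≈ 0.2 % with range ≈ 3 signal units,
ghost ratio ≈ 0.15 %.  Identical configuration + seed reproduces the
series bit for bit.

What the generator does *not* emulate: k-space-level EPI artefacts
(distortion, ramp sampling), B1 inhomogeneity, physiological noise,
scanner drift nonlinearity, slice-timing offsets, genuine subject/phantom
motion, and the scanner-specific gain that makes absolute SNR values
machine-dependent.  Tests passing on simulated data therefore validate
the *metric implementations* and the internal consistency of the physics,
not any particular scanner's absolute numbers.

## QC metric conventions

* Volume numbering for the NEMA odd/even split is 1-based; an odd volume
  count is truncated to the largest even count so the sums balance.
* All SDs are population SDs (divide by n) — immaterial at n = 100 but
  fixed for reproducibility.
* "9 pixel" and "4 pixel" ROIs are 3×3 and 2×2 axial squares; default
  placement is the image center of the middle slice.  For even sides the
  square starts at the center voxel.
* SNR takes its noise argument *per time point* (the static-noise ROI
  summary divided by the number of volumes).  With published baseline ROI
  readings — signal means 735.2/755 against a per-time-point noise of
  0.1 — Signal/√0.1 reproduces the reported SNRs of ≈ 2326/2389 to 0.1 %,
  whereas dividing again by the volume count is off by 10×; the package
  follows the former reading.  Note the companion published SFNR values
  (4227/6378) are *not* Signal/TFN of the same readings (≈ 228/379);
  `phantomqc` follows the definitional ratio.
* Ghost background ROIs sit midway between the phantom edge (from a 20 %
  robust-max foreground mask) and the image edge along each axis, same
  size as the center ROI; the up/down pair lies along the phase-encode
  axis.  A background ROI overlapping the foreground is a configuration
  error, not a silent bias.  The ratio's standard error is estimated from
  the per-volume spread of the numerator.
* PSC "Active" means exclude the first volume of each active block (the
  switching transition); "Baseline" is the mean over all baseline
  volumes.  A design-free fallback ("most obvious change": the contiguous
  window deviating most from the series median) is available for curves
  without timing information.  When one run cycles several current
  levels, per-level PSC groups active blocks by level against the pooled
  baseline.
* A stimulus block counts as detected when its mean (minus transition
  volume) differs from the flanking baseline means by more than k × the
  baseline TFN of the curve; k defaults to 2 and is exposed because no
  standard fixes it.  Block segmentation is structural — an active window
  driven at 0 mA is still a window, so false-positive behaviour is
  measurable.
* Motion: translation is the voxel-size-scaled displacement of the
  per-volume foreground center of mass; rotation is the orientation
  change of the principal second-moment axis of the middle slice.  A gel
  cylinder is nearly circular, so raw intensity moments are
  ill-conditioned for rotation; the moments are instead computed on
  signal-void landmarks (voxels at least 25 % below the slice median
  inside the hole-filled disc — the wire holes), which are strongly
  anisotropic and give ≈ 0.005° jitter at default noise while recovering
  an injected 2° rotation within 4 %.  QC limits default to 0.1 mm /
  0.1°.
* k-space stability: per-volume FFT of the middle slice, amplitude along
  the central horizontal line, normalized by the across-volume *median*
  DC term (per-volume DC normalization would cancel exactly the
  whole-volume amplitude transients the check exists to catch).

## GLM

Per voxel, OLS against [boxcar, intercept, linear drift]; the boxcar is
the binarized current waveform with no HRF convolution (the phantom
switches instantly), and the drift column is included by default because
the simulator injects drift and it is harmless when absent.  t =
β/SE(β), dof = n − rank.  Voxels with numerically zero residual variance
are reported saturated at t = ±10⁶ rather than raising.  Thresholding is
two-sided at the Student-t quantile (p = 0.05 by default, uncorrected),
clustering uses 2D 4-connectivity within each slice (slices are thick —
5 mm — relative to in-plane voxels and activation maps are read
per-slice), and clusters under 5 voxels are discarded.  No slice-timing
or motion correction is applied: phantom motion is orders of magnitude
below a voxel.  Null calibration on a zero-current Gaussian run
(≈ 12 000 gel voxels, 100 volumes) gives an empirical two-sided rejection
rate of ≈ 0.050 at p = 0.05.

When localizing activation, the cluster table is evaluated inside the
phantom foreground mask (as SPM-style pipelines do with a brain mask);
otherwise the injected N/2 ghost — which faithfully copies a fraction of
the modulation into the background — can echo strong activations outside
the phantom.

## Problem sizes

All simulations in the test suite and the acceptance script use the full
protocol matrix (64×64), with either the complete 11-slice volume (QC
report, GLM calibration, detection) or a single slice where the slice
dimension is irrelevant (PSC ladder, ghost sweeps); series length is the
protocol's 100 volumes (200 in one SFNR-scaling check).  A full
simulate + QC + GLM cycle takes ~2 s on one CPU, the whole acceptance
script a few seconds.

## Known limitations

* The coupling factor calibrates the simulator to a plausible scanner; it
  does not predict any specific machine's PSC.
* Magnitude-sum superposition of wire fields discards the component of
  realism where induced-field direction relative to B0 modulates the
  *effective* resonance offset; no quantitative model of that coupling is
  established for this geometry.
* The motion summary is a proxy (moments, not rigid-body registration)
  and its rotation estimate needs visible structure (wire holes); a
  featureless phantom would return 0°.
* Detection efficiency at the default k = 2 is conservative for the
  weakest (8 mA) condition, which hovers at threshold under default
  noise — by design, since that is exactly the regime the QA instrument
  is meant to probe.
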