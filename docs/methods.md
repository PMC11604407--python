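# Methods

## The phantom

The phantom is a single 2D axial slice through a mouse mid-thorax,
composited from ellipses on a `grid_n × grid_n` raster (default 160 px at
0.2 mm): a soft-tissue body outline, two lung fields, a spine disk, and a
myocardial annulus around a contrast-enhanced left-ventricular cavity.
Attenuation coefficients (mm⁻¹) approximate an 80 kVp soft-tissue scale:
soft 0.022, myocardium 0.025, lung 0.005, bone 0.060, and 0.080 for the
iodine-contrast-filled cavity — the blood pool is the brightest
compartment, as it is after i.v. contrast injection in vivo.

A 2D slice rather than a 3D volume is a deliberate choice: the gating
algorithm consumes projections identically in either case, and a slice
keeps a complete simulate–gate–reconstruct–measure experiment at desk
scale. Volumes are therefore areas × 1 mm slice thickness, reported in
µL (1 mm³ = 1 µL).

**Cardiac model.** Per-beat cycle lengths are drawn sequentially as
`L_k = mean · (1 + cv · clip(z_k, −3, 3))`, `z_k ~ N(0,1)` from
`numpy.random.default_rng(seed)`, with `mean = 60/heart_rate_bpm` s and
`cv = cycle_jitter_cv` (default 0.05). This recipe is simple enough to
replay in any language, making the timing oracle independently
reproducible; identical seeds give bitwise-identical beat sequences.
The cardiac-cycle fraction rises piecewise-linearly within each beat.
The endocardial semi-axes scale by `s(φ) = 1 − (1−c)·w(φ)` with `c` the
contraction factor and `w` an asymmetric raised-cosine reaching 1 at
φ = 0.35 (rapid systolic contraction, slower diastolic refill). The
default `c = 0.632` gives a ground-truth area-EF of `(1−c²)·100 ≈ 60%`,
a healthy mouse. Ground-truth cavity area is `π·a·b·s(φ)²`.

**Respiratory model.** The respiratory cycle (default 80 /min, plausible
for an anesthetized mouse) is periodic; inspiration occupies the leading
`inspiratory_fraction` (default 0.30) of each cycle, during which the
diaphragm line is displaced cranially by a raised-cosine pulse (default
amplitude 1.5 mm) that converts lung voxels to soft tissue; expiration is
a flat plateau at zero displacement. Heart position is fixed —
respiratory bulk motion of the heart is deliberately excluded so the two
motions are separable in truth space (see Limitations).

## Acquisition

Parallel-beam geometry stands in for the scanner's cone beam: the gating
algorithm operates on projection time series regardless of beam shape,
and parallel rays remove geometry plumbing irrelevant to gating. One
projection is acquired per frame at 40 fps, rotating 0.5° per frame
(720 views/rotation, 0.2 mm detector pitch); the default 60 s scan gives
2400 projections over 3⅓ rotations. 40 fps exceeds twice the cardiac
band's upper edge (12 Hz); a Nyquist guard warns otherwise.

Line integrals are computed by bilinear sampling along rays at the image
pixel pitch; the back-projector is the exact algebraic adjoint
(same bilinear weights, scatter instead of gather), which makes the
iterative reconstruction's convergence behaviour clean. Mass is
conserved to ≲0.01% at arbitrary angles.

Photon noise, when enabled, is applied in the count domain:
`counts ~ Poisson(I0·exp(−p))`, clamped at 1 count, then log-converted
back to line integrals. In the log domain the delta method predicts
variance `exp(p)/I0`, which the simulation reproduces.

## Gating design choices

- **Registration**: mutual information from a 32-bin equal-width joint
  histogram, exhaustive integer-translation search (±10 px default),
  ties broken by smallest shift norm then lexicographic order.
  Translation-only is sufficient because template and projections share
  scale and orientation; the brute-force search makes the optimum exact,
  not local. In 2D-slice mode projections are 1D, so the search is 1D;
  the code paths are dimension-generic and tested in 2D too.
- **Template**: time-average of the first rotation's projections (both
  motions average out); ROI masks are placed from the phantom's known
  anatomy — the cardiac ROI covers the detector band onto which the
  heart (sitting near the rotation axis) projects at every angle, the
  respiratory ROI the flanking band receiving lung and diaphragm rays.
  A configurable detector offset applied to the template forces the
  registration step to do real work.
- **Bands**: cardiac 5–12 Hz (300–720 bpm), respiratory 0.5–4 Hz
  (30–240 /min). Filters are 4th-order Butterworth run forward-backward
  (zero phase), so filtering does not shift cardiac timing.
- **Rate estimation**: detrended, Hann-windowed, ≥4× zero-padded
  magnitude spectrum; largest in-band peak, refined by parabolic
  interpolation of log-magnitudes; an error is raised when no peak
  exceeds 3× the median in-band magnitude. The 60 s default gives
  ≤0.02 Hz resolution.
- **Inspiration rejection**: within a centred sliding window of 3
  respiratory cycles, samples above the 0.70 amplitude quantile of the
  filtered respiratory signal are rejected. The quantile adapts to
  baseline drift, is exactly scale invariant, and under the phantom's
  0.30 inspiratory duty cycle retains ~70% of projections. A flat-window
  guard (peak-to-peak < 10⁻⁹ of signal scale) rejects nothing, so
  breath-hold segments are kept.
- **Phase assignment**: peak-to-peak linear interpolation, not
  instantaneous (Hilbert) phase — each sample's fraction is
  `(t − t_prev)/(t_next − t_prev)`, exact under cycle-length variation.
  Peaks are found on a **rate-adaptive** re-filtering of the cardiac
  signal, band `[0.75·f₀, min(2.5·f₀, 0.45·f_s)]` with f₀ the estimated
  heart rate: retaining the 2nd harmonic anchors peaks near end-diastole
  (a fundamental-only filter shifts the peak of an asymmetric systolic
  waveform by ~0.07 cycle; with the 2nd harmonic the residual anchor
  offset is ~0.03–0.04 cycle, which dominates the phantom's measured
  circular phase error). Peak positions are refined to sub-sample
  accuracy by parabolic fits — at 40 fps a 400 bpm beat spans only 6
  frames, so integer-sample peaks would quantize phase at ~0.17 cycle.
  Minimum inter-peak distance is 0.6 of the estimated cycle and
  prominence ≥0.3× the signal's median absolute deviation. Samples
  before the first/last detected beat are extrapolated with the nearest
  beat length (clipped to [0,1)) and flagged, keeping projection counts
  auditable rather than silently dropped.
- **Binning**: half-open bins [k/12, (k+1)/12); fraction 1/12 falls in
  bin 1.

## Reconstruction

**FBP**: the ramp filter is built from the spatial-domain Ram-Lak kernel
(h[0] = 1/4d², h[k] = −1/(πkd)² for odd k) rather than a naive |ν| ramp,
avoiding the DC bias/cupping of the latter; optional Shepp-Logan sinc
apodization. Projections are zero-padded 2×, filtered in frequency
domain, back-projected with linear interpolation and weighted π/N — or,
when angular gaps exceed 2× the nominal spacing, by per-view Voronoi gap
widths on the half-circle so clustered views are not over-counted.
Angular gaps >10° trigger a warning (streaking expected).

**Ordered-subset SIRT**: angles are partitioned round-robin into 24
subsets (3 full iterations by default); each update is
`x ← x + λ·C_s·Aᵀ_s R_s (y_s − A_s x)` with R, C the inverse row/column
sums of the subset system, λ = 1, and a nonnegativity clamp. A SIRT
(least-squares) model is the standard choice for log-converted CT line
integrals — OSEM-style transmission models apply to count-domain data.
Data fidelity ‖y − Ax‖ is tracked each full iteration; growth over two
consecutive iterations aborts with advice to reduce λ. The practical
motivation for the iterative route is its *image-level consistency*:
phase bins with 1000 vs 1400 projections reconstruct to mean levels
within 2%, where FBP's level depends on the angular distribution.

**Post-filtering**: Gaussian smoothing of stated FWHM with a periodic
boundary treatment, which preserves the image mean exactly; FWHM 0 is
the identity.

## Cardiac function

Cavity segmentation: Otsu threshold computed inside a centred window of
half the image side, largest connected component — scale invariant, no
tuned absolute threshold. LVID is the chord through the cavity centroid
along the mask's minor-axis direction (an M-mode cursor analog; the
proprietary echo software's exact cursor placement is unknowable, so
this is a declared stand-in). EDV/ESV are the max/min volumes across
bins rather than fixed bins, robust to where systole falls in the bin
grid. Segmental strain parameterizes each endocardial contour by arc
length from the posterior-base anchor (most caudal contour point,
counter-clockwise) into 6 equal-arc segments, mirroring a base-to-apex,
posterior-to-anterior segment layout; GLS is the segment mean. Severity
classes use inclusive boundaries: EF exactly 20 or 40 → moderate heart
failure; fibrosis fraction exactly 20 or 40 → moderate fibrosis.

## Problem sizes and tolerances

Default experiment: 160² grid, 60 s / 2400 projections, 12 bins of
~140 retained projections each, ordered-subset reconstruction — a
complete run takes ~1.5 min on one CPU. The heart-rate sweep for the
detectability bound uses 30 s noiseless scans per rate (100–700 bpm in
50-bpm steps). These sizes are the package's desk-scale defaults; the
gated scans behind the method's original use are an order of magnitude
larger (∼17k–24k projections, 1000–1400 per phase), and nothing in the
implementation depends on the smaller size.

Numerical tolerances worth knowing: rasterized cavity area tracks the
analytic ellipse area to ~2% at the default grid (sub-1% at 256 px);
FBP round-trip NRMSE on a smooth static object is <0.05 with 720 views;
the measured end-to-end EF sits ~2 points below ground truth because
each bin averages the contraction over 1/12 cycle (ESV is sampled
slightly off the exact systolic extreme).

## What the phantom does and does not show

Passing these tests demonstrates the algorithm's correctness under known,
controlled conditions: periodic-with-jitter cardiac motion, a strictly
duty-cycled respiratory pulse, motion-free heart position, monoenergetic
parallel-beam physics, and Poisson-only noise. Real scans add cone-beam
geometry, respiratory cardiac bulk motion (which couples the two
signals), contrast washout drifting the cardiac signal baseline,
scatter/beam hardening, detector blur and arrhythmic beats. The
adaptive-quantile rejection and per-beat phase interpolation are designed
to tolerate drift and rate variation, but their behaviour under real
coupled motion is untested here. The ~70% retention figure emerges from
the phantom's 0.30 inspiratory duty cycle; in vivo it depends on the
animal's breathing pattern.

## Known limitations

- 2D slice mode: volumes are area-based; FS/LVID are in-plane analogs.
- Registration is translation-only and integer-valued.
- The phase anchor retains a small (~0.04 cycle) systematic offset from
  true end-diastole; all phases share it, so EF/strain (which compare
  extremes across bins) are unaffected, but absolute phase labels are
  offset by up to half a bin.
- No MAP priors or regularization in the iterative reconstruction.
- Poisson noise only; no electronic noise floor or detector crosstalk.
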