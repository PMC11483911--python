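# Methods

This note documents the models, the synthetic-data generators, the
numerical choices and the known limitations of `cdicekit`, in the order
of the analysis chain.

## Scaling model of droplet formation and interface crossing

All relations are evaluated in coherent SI units; rotation rates are
accepted in rpm at every interface and converted to rad/s internally.
Dimensionless outputs are invariant under a global change of coherent
unit system (tested against an mm/g/s system to 1e-10 relative).

**Orifice flow.** The chamber sweeps fluid past the capillary orifice at
*U* = Ω·R_i (R_i ≈ 1 cm from the axis; *U* ≈ 2 m/s at 1900 rpm). Droplet
breakup is classified by:

- *Ca* = μU/γ — viscous shear vs. interfacial tension. Below a
  configurable threshold (default 0.1, an order-of-magnitude cut since
  "low Ca" has no sharp published value) breakup is dripping
  (monodisperse pinch-off); above it the emerging drop deforms and
  breakup is shear-unstable.
- the critical jetting flow rate π(D³γ/2ρ_i)^1/2: flow rates above it
  produce an inertial jet. The operating 25 μL/min sits far below the
  ≈130 μL/min critical value, so jetting never competes.
- *Re_D* = ρUD/μ of the cross-flow past the capillary, with the standard
  circular-cylinder wake thresholds: steady below 47, periodic vortex
  shedding in 47–150, three-dimensional instabilities above 150.

**Droplet size.** Balancing the retaining tension force ~πDγ against the
viscous drag ~6πμaU on a droplet of radius *a* gives the radius above
which breakup is expected, *a/D* ~ (6 *Ca*)⁻¹; the predicted diameter
D/(3 Ca) is inversely proportional to rotation rate.

**Transport and secondary breakup.** Droplets ride the azimuthal flow at
*U* while drifting outward at *U_r* = Δρ a²Ω²R_i/μ (Stokes drag vs.
centrifugal buoyancy; cm/s scale — two orders below *U*), so they loiter
in the capillary wake for several revolutions. There the shear rate is
ε̇ ~ ΩR_i/l with *l* bracketed between the capillary outer scale
(0.5 mm) and the capillary-to-wall distance (5 mm). Secondary breakup to
radius *a* stops when *Ca*_ε̇ = μ ε̇ a/γ reaches 1; the corresponding
limiting tension μ ε̇ a for a = 5 μm lands in the 10⁻⁶–10⁻⁵ N/m decade —
unrealistically low for any surfactant-laden aqueous/oil interface, so
wake shear cannot produce GUV-sized droplets.

**Interface crossing.** At the oil/outer-solution interface (R_o from the
axis) the centrifugal acceleration is Ω²R_o; the Bond number
Bo = Δρ(Ω²R_o)r²/γ measures interface deformation by a droplet of radius
r, and the breakthrough condition Δρ Ω²R_o a²/γ ≥ 3/2 gives the largest
tension γ_max = (2/3)Δρ Ω²R_o a² a droplet of radius *a* can still cross.
Production bookkeeping uses the volumetric identities f = Q/(πd³/6) and
N = V/(πd³/6), which conserve flow rate and volume exactly.

Defaults that the sources leave open, chosen once here: R_o = 15 mm (the
interface is placed 2.5 mm inboard of the 17.5 mm chamber radius);
capillary outer diameter 363 μm (standard polyimide-coated fused-silica
tubing for a 100 μm bore) with the 0.5 mm outer scale kept as the wake
length minimum; the tension bracket 10⁻³–10⁻² N/m — reading the published
band as N/m, the only interpretation consistent with the printed Ca range
0.5–10 (both unit readings remain available as presets); oil density
934 kg/m³ (nominal) with the weighed 868.5 kg/m³ as a named constant, and
likewise both density conventions for the sugar-laden inner buffers.
Aggregate reports evaluate tension-dependent groups at the low end of the
bracket and, for droplet-size-dependent groups, default to half the
predicted diameter (transport, Bo) and to the 5 μm GUV radius (wake
shear, breakthrough).

## Synthetic imaging

The generator emulates the statistics that make the real recordings hard
to analyse, not their optics. Diameters are drawn from per-speed
truncated-normal mixtures (floor 2 μm, the measurement floor):
68.6 ± 2.8 μm at 1900 rpm, 28.5 ± 8.7 μm at 2700 rpm, and an equal-weight
273 ± 41 / 15.9 ± 7.3 μm mixture at 1000 rpm (primary plus satellite
droplets). Scene presets render as many droplets as the corresponding
measured samples (152/157/148).

Each droplet is a dark-rimmed, faint-interior disk: rim depth
`contrast_amplitude`×background (default 0.18), interior at 30% of the
rim depth — keeping the interior/background ratio above 0.9, so
segmentation cannot rely on fill contrast, mirroring the weak
water-vs-silicone-oil refractive step (1.333 vs 1.403). The rim's outer
flank is an erf step of scale 0.5 px centred **exactly at the true
radius**; its half-amplitude point therefore marks the true edge and is
invariant under Gaussian blurring. Motion blur is a box convolution along
+x of length speed×exposure/pixel-size (fractional end taps); at the
preset 1 μs exposures this is sub-pixel, as in the real recordings.
Additive Gaussian sensor noise (default 1.2% of background) completes the
frame. Rendering is bit-identical for a fixed seed, and every rendered
droplet carries one ground-truth row (droplets that cannot be placed are
skipped and logged, never silently dropped from the truth table).

Not emulated: diffraction/defocus PSFs, the liquid filament and breakup
dynamics, droplet tracking across frames, out-of-focus droplets,
illumination gradients. Passing recovery tests therefore demonstrates
correctness of the measurement chain against a controlled image model,
not performance on arbitrary real video. Droplet density per frame is a
plausible choice (4–7), not a calibrated one.

## Droplet sizing

Calibration divides the known capillary width by the mean of ≥3 pixel
measurements; its uncertainty is the quadrature sum of the measurement
spread (sample sd) and the capillary-width uncertainty. The default
calibration is 2.431 ± 0.105 μm/px with a 2 μm per-droplet measurement
floor.

Detection works on the signed difference background − frame (droplets
are dark), with the background taken as the per-pixel temporal median of
the (optionally strided) stack. A coarse mask at an absolute contrast
threshold (default 6 grey levels, above the ~5σ noise band) is refined
per candidate by re-thresholding at half the candidate's 90th-percentile
contrast — the rim half-amplitude, i.e. the true droplet edge for
rim-profiled droplets — then hole-filled. Candidates are screened by a
2 px equivalent-diameter resolution floor, circularity 4πA/P² ≥ 0.6, and
a border-exclusion rule; every rejection is logged with its reason.

Each accepted region yields two diameters: area-equivalent 2√(A/π)·px and
caliper (maximum Feret extent − 1 px; the Feret measure spans the pixel
footprint, which overhangs a disk by half a pixel per side). Errors are
the quadrature sum of the relative pixel-size uncertainty and the 2 μm
floor. Motion-blurred regions (eccentricity > 0.2) are sized from their
minor axis, which x-blur leaves untouched. On noise-free synthetic
stacks, per-droplet errors stay below one pixel; on the noisy presets the
recovered mean sits within a third of a pixel of truth.

Population summaries use linear-interpolation quartiles and the
conventional 1.5 IQR boxplot outlier rule. The bimodal split minimises
the weighted within-class variance over all splits of the sorted sample
(exact 1-D Otsu, no histogram binning — deterministic and sufficient for
the ~17× separation between primary and satellite means); the split is
accepted only if the class means differ by more than 3 pooled standard
deviations, otherwise the sample is reported as one population. Note
that the 2 μm truncation floor shifts the satellite population mean
slightly above its nominal 15.9 μm; recovery tests compare against the
truncated-normal expectation.

## Pendant-drop tensiometry

The forward model integrates the Bashforth–Adams arc-length form of the
axisymmetric Young–Laplace equation from the apex (curvature 2/b,
hydrostatic term Δρgz/γ; shape parameter β = Δρgb²/γ) with an RK45
integrator at rtol 1e-10. Exploring the solution family shows that for
β ≳ 0.2 (at b ~ 1 mm and the 0.313 mm instrument needle) the profile's
neck never narrows to the needle radius before reopening — physically,
tensions that low cannot hold the dosed drop, which is exactly the drop
detachment the tensiograms record. Profiles therefore terminate at the
first of: needle attachment (silhouette radius returns to the needle
radius), the neck's narrowest point, or closure (spherical limit);
`require_attachment=True` turns non-attachment into a diagnostic error.
The β = 0 limit reproduces a sphere to 1e-10 relative.

Fitting minimises radial residuals — data radius |x − x₀| minus the
integrated profile's silhouette radius interpolated at the data height —
over (log γ, log b, x₀, z₀) with Levenberg–Marquardt. Radial residuals
are used instead of point-to-curve normal distances because z is
monotone along the arc for a hanging drop, making the silhouette radius
single-valued in z; this is simpler, faster and standard in drop-shape
analysis, and round trips recover γ to better than 0.1% (noise-free)
and 2% under 0.2% point noise. The starting point screens a coarse β
grid, scaling each candidate profile to the observed maximum radius and
keeping the best radial misfit — robust across the whole β range where a
single apex-circle estimate fails for elongated drops. Non-convergence
is always reported in the returned fit object, never silently.

Tensiograms are smoothed with a centred 1 s rolling mean (window =
sampling rate; 25 fps for tubulin/lipid solutions, 5 fps otherwise).
Detachment is declared at three consecutive non-converged fits or a
>50% inter-frame drop volume collapse, and all later samples are
removed; a run detaching before 10% of the nominal duration is flagged
as discarded (the "abnormally fast decrease" rule — the threshold is
this package's quantification, as no published number exists). The
synthetic tensiogram generator uses single-exponential kinetics
γ(t) = γ_end + (γ_start − γ_end)e^(−t/τ); presets preserve only the
qualitative ordering that protein + lipid mixtures equilibrate faster
(smaller τ) than lipid-only dispersions — their absolute curves are not
reconstructable from published summary values. Ward–Tordai adsorption
modelling and image-based contour extraction are out of scope.

## Rheology

The ramp protocol is 24 log-spaced points over 0.5–100 s⁻¹ (2 min at one
sample per 5 s). The reported viscosity is the single highest-shear
sample, as the protocol specifies (plateau averaging is available as an
option); the Newtonian flag requires a coefficient of variation below 5%
over the upper half-decade of shear rates — a quantification of
"constant at higher shear rate". The generator's low-shear artifact term
η(1 + c/γ̇) reproduces the monotone high-bias seen at low rates in real
instruments. At 2% multiplicative noise the reported value recovers the
truth within 3 standard deviations per ramp and within 3% in ensemble
mean; the single-point report inherits the full per-sample noise by
design.

## Interface statistics

Fate fractions come with Wilson 95% score intervals (chosen over Wald
for sane behaviour at extreme proportions; cross-checked against an
independent implementation in tests). The frame-sampling scheme (every
5th frame, 50 frames) is recorded but not modelled: persistent stalled
droplets may be counted repeatedly across sampled frames, a bias the
counts cannot correct — a known limitation. The production ledger
combines the volumetric frequency/count identities with a reported GUV
count to give the conversion ratio (~0.17% at default conditions:
~5.9×10⁵ droplets vs ~10³ GUVs).

## Problem sizes and determinism

Synthetic scenes use 148–157 droplets (matching the measured samples)
on 400²–560² px frames — large enough for the largest 273 μm droplets at
2.431 μm/px. The noisy-fit Monte-Carlo uses 25 seeded replicates and the
rheology ensemble 100 seeds. All stochastic steps take explicit integer
seeds; fixed seeds give bit-identical images and measurement tables.
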