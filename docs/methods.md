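# Methods

This note documents the models behind each pipeline, the parameters that
matter, what the synthetic generators do and do not emulate, and the
numerical choices and known limitations a user should be aware of.

## Alignment score from the FFT radial-intensity histogram

Aligned fibres elongate the central maxima of an image's 2D Fourier
spectrum orthogonally to the fibre direction. Ellipse-eccentricity
measures of that elongation are noise-sensitive (the short axis of a
highly eccentric ellipse is poorly determined), so the score here
integrates the whole spectrum instead:

1. The square tile (side ≥ 32 px) is mean-subtracted, tapered with a Hann
   window (default on; `window="none"` mimics naive pipelines), and
   transformed; the magnitude spectrum `|F|` is centred and a central disc
   of radius 2 px is zeroed. Zeroing only the DC bin leaves windowing
   leakage that dominates every angular sum equally; the 2-px disc kills
   it.
2. For each integer degree θ ∈ 0…179 the spectrum is sampled bilinearly at
   1-px radial steps from `r_min` (default 2 px, skipping the suppressed
   disc) to `radius` (default: half the spectrum side minus one, the
   largest in-bounds radius) and summed. The spectrum of a real image is
   centrosymmetric, so 180–359° is redundant. Nearest-neighbour sampling
   is available for cross-checks. Both radii are exposed because there is
   no canonical choice; the defaults use everything available.
3. A four-parameter Gaussian `A·exp(−(θ−μ)²/2σ²) + B` is least-squares
   fitted to the 180-bin profile and the alignment score is `S = 1/σ`
   (deg⁻¹). The flat offset `B` absorbs the angle-uniform spectral noise
   floor, which would otherwise inflate σ. The score is reported raw, not
   clamped to [0, 1]: it lies in (0, 1] whenever σ ≥ 1°, which covers any
   realistic fibre field, and is exactly invariant under global intensity
   scaling.

Fitting detail: the profile is circularly rolled so its maximum (lowest
angle on ties) sits at bin 90, keeping the peak away from the 0/180 wrap;
μ is un-rolled modulo 180 afterwards. Initialisation is μ₀ = 90,
σ₀ = HWHM/1.177, A₀ = max−min, B₀ = min, with restarts at σ₀ × {0.5, 2} on
non-convergence. The solver is an *unbounded* Levenberg–Marquardt: on
profiles with no real orientation preference it drifts to very large |σ|
(score → 0), which is the desired reading of "no alignment"; σ is capped
at 1000° afterwards so uniform profiles return the defined near-zero score
1/1000 rather than failing. A bounded trust-region solver was rejected —
it parks flat profiles mid-range or latches onto single-bin noise bumps —
and so was a global multi-start: the *global* least-squares minimum on an
isotropic profile is typically a narrow spike fitted to the largest random
angular clump, which is exactly the degenerate behaviour to avoid.

**Known limitation.** On isotropic fields the 180-bin profile is flat
except for finite-sample clumps (a few fibres at nearly the same angle).
The fit occasionally locks onto such a clump and returns a small σ, i.e. a
*high* score for an unaligned field. The median score of isotropic or
pure-noise images is well-behaved (≈ 0.01–0.02 deg⁻¹, far below aligned
fields), but the *mean* has unbounded influence from these rare narrow
fits — with the package's own generator the mean isotropic score exceeds
the mean κ = 2 score. Users comparing weakly aligned conditions should
compare medians or paired distributions, not means; this mirrors the
general noise-sensitivity of spectral alignment measures.

## Local thickness (fibre width and spacing)

The local thickness at a foreground point is the diameter of the largest
disc fully contained in the foreground that covers that point
(Hildebrand–Rüegsegger), computed in 2D because the analysed SHG data are
single optical planes. On the pixel grid the largest safe disc centred on
pixel p has radius `EDT(p) − 0.5`, where EDT is the Euclidean distance to
the nearest background pixel centre and the half-pixel offset places the
disc boundary on the pixel boundary: an isolated pixel reads 1 px and a
7-px bar reads 7 px in its interior. The image frame bounds every disc (a
virtual background ring sits one pixel outside), so a foreground-complete
mask degrades gracefully to the largest disc inscribed in the frame. A
discrete filled disc of radius r reads 2r only to within ~1 px, because
disc centres are pixel centres.

Implementation: distance transform, then discs painted largest-first with
each pixel keeping the largest covering diameter — O(N·r²) against the
O(N²·A) exhaustive oracle reserved for tests. Mean thickness is the
area-weighted mean over foreground pixels (matching "average largest
diameter"; skeleton-point averaging was rejected as a different, unstated
statistic). Spacing is the identical measure on the mask complement. All
outputs scale linearly with pixel size; the area fraction is
scale-free. Default threshold is Otsu (deterministic, no tuning);
`fixed:<value>` is available for reproducibility across conditions.

## Gel contraction

Contraction is the endpoint percentage `100·(A_first − A_last)/A_first` of
the segmented gel area; intermediate timepoints are carried in the CSV for
plotting only. Segmentation is Otsu thresholding, hole filling, then the
largest connected component, with the gel-vs-background polarity chosen
automatically by which polarity yields the more compact largest component
(isoperimetric ratio 4πA/P²) — a gel is a blob, a well rim is not — and a
guard that the component covers ≥ 1% of the frame. Polarity can be forced.
Segmentation accuracy is validated only on synthetic gels (< 2% area
error); real bright-field wells with strong vignetting or meniscus shadows
may need the polarity flag or manual masking.

## AFM indentation and the Hertz fit

A colloidal probe (spring constant k, optical-lever sensitivity s, bead
radius R) gives force `F = k·s·V` from the photodiode voltage V. Past the
contact point z_c the indentation is the piezo travel minus the cantilever
deflection, `δ = (z − z_c) − F/k`, and the Hertz model for a rigid sphere
on an elastic half-space,

    F = (4/3) · E/(1−ν²) · √R · δ^{3/2},

is linear in E at fixed z_c. Defaults: ν = 0.5 (incompressible hydrogel;
exposed because E scales with 1/(1−ν²)), R = 35 µm, fit capped at the
1 nN acquisition setpoint.

Contact-point detection is a residual-minimising search rather than
derivative thresholding, which is unreliable on the gradual force onset of
soft collagen gels: every candidate contact sample is scored by the RSS of
the piecewise flat/Hertz model with the slope and a flat offset profiled
out by linear least squares (the sample set and baseline reference are
fixed by the data, so residuals are comparable across candidates), then
(z_c, log-slope, offset) are refined jointly by Levenberg–Marquardt. A
curve is declared "no contact" when the best piecewise fit fails to beat
the flat-line model by at least 1% RSS. The procedure is deterministic.

**Precision floor.** For curves sampled at n points with iid force noise,
the Cramér–Rao bound for z_c with nuisance slope and offset is ≈ 1.8
sample intervals at 2% force noise under the generator's default geometry
(1000 samples, contact at sample 300, 1 nN setpoint, E = 1 kPa). The
estimator operates near this bound (sd ≈ 2.0 samples, bias ≈ −0.5), so
~90% of noisy fits land within ±3 samples of the true contact point — no
estimator can reach ~95% there. The modulus is far better conditioned: the
median of noisy fits stays within 1% of truth and single noiseless fits
recover E to machine precision. Moduli are aggregated as mean ± s.e.m. per
region (e.g. 30 curves over 6 regions) and per matrix.

Input format is a two-column TSV (`height_m`, `deflection_V`) with
`# key: value` calibration headers. Vendor binaries are out of scope;
export the approach segment with height in metres and deflection in volts
(or metres with sensitivity 1).

## Synthetic generators

All generators are pure functions of (spec, seed).

**Fibre fields** emulate SHG collagen images: straight anti-aliased
segments (distance-to-centre-line coverage rendering, sub-pixel endpoints
and angles) with orientations drawn from a von Mises distribution on the
*doubled* angle — fibre orientations are axial, so a plain von Mises on
[0, 360) would be wrong — with κ = 0 isotropic and κ ≳ 30 strongly
aligned. Defaults mirror the target imaging conditions: 0.3 µm/px, 512-px
fields, 300 fibres of 3 px (~1 µm) width and 64 px (~20 µm) length — a
realistic quasi-straight segment scale for fibrillar collagen; full-field
straight fibres would give each fibre an unphysical ~0.2° delta-like
angular signature — 1-px PSF blur and additive Gaussian noise at 5% of
peak (Poisson photon noise behind a flag, off by default). Fibres combine
by maximum, emulating bundles that do not sum in intensity. Not emulated:
fibre curvature, 3D projection, cell bodies, SHG optics; passing tests
therefore validate the *estimators*, not microscope realism.

**Gel series** are dark anti-aliased discs with linearly interpolated
radii on a bright background with mild noise — enough to validate
segmentation and the contraction arithmetic (an endpoint area ratio of 0.2
is 80% contraction), not well-plate photometry.

**Force curves** solve the self-consistent contact system
`k·d = Hertz((z − z_c) − d)` per sample by bisection, so a refit of a
noiseless curve is an exact inversion; the auto z-range ends where the
force reaches the setpoint, mirroring setpoint-triggered ramps, and force
noise (a fraction of the maximum force) maps to deflection noise through
k.

## Statistics

Condition groups are summarised as mean ± s.e.m. (sd with n−1 denominator;
an n = 1 group reports s.e.m. 0 with a warning). Comparisons use the
two-sided unpaired Student's t-test with pooled variance by default —
Welch's correction is behind a flag — and its type-I error calibrates to
0.05 ± 0.01 under Gaussian nulls. No multiple-testing correction is
applied; with many condition pairs, p-values should be interpreted
accordingly.

## Tiling and orchestration

Large fields are split into non-overlapping square tiles (e.g. a 200 µm
field into four 100 µm tiles) in row-major order; border remainders are
dropped, not padded, because padding contaminates FFT spectra with
artificial edges. The CLI reports per-tile values plus a per-field mean,
leaving the choice of analysis unit to the user. Pixel size is mandatory
at load; TIFF resolution metadata is only a fallback because pixel-size
dialects vary. Every CLI run writes a JSON run-record (inputs, parameters,
library versions) beside its outputs.

## Problem sizes used in the shipped checks

The acceptance script and acceptance-level tests run 50 seeds per κ at
512 px for the alignment sweep, 100 random 32×32 masks against the
exhaustive thickness oracle, 200 noisy force curves, and 10⁴ t-test
replicates — sizes chosen so the full set completes in well under a minute
on one CPU while keeping Monte-Carlo standard errors a small fraction of
the tolerances being checked.
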