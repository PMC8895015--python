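# Methods

This note records the models, conventions and design choices behind
specklekit, in the spirit of a methods appendix: enough detail that every
number the package produces can be traced to a stated rule.

## Conventions

All grids are row-major with 0-based indices. Diffraction-space arrays put
the zero-frequency (DC) pixel at index `(N//2, M//2)`; centred transforms
are `fftshift ∘ fft2 ∘ ifftshift`. Spatial frequency `f` is the
*full-period* frequency, so a feature at frequency `f` has length scale
`d = 1/f`; frequencies are reported in µm⁻¹ and distances in nm
(`d_nm = 1000/f`). The per-pixel frequency increment of a simulated
pattern is `1/(N · pixel)`. On even grids the Friedel partner of pixel
`(i, j)` is `((N−i) mod N, (M−j) mod M)`; the aliased negative-Nyquist
row/column maps to itself.

The default real-space sampling, 13.7 nm/pixel, is what a 5.5 keV beam, a
1.496 m camera length and a 60 µm (3×3-binned) detector pixel give at a
411-pixel grid — the geometry the synthetic experiment mimics.

## The synthetic experiment

`make_phantom` draws a boundary-perturbed, randomly oriented ellipse
(aspect 1.8, area = `object_fraction` × grid area, default 0.08 so linear
oversampling comfortably exceeds 2 per axis) and fills it with smooth
Gaussian blobs affinely mapped onto `density_range = (0.3, 1.0)` electrons
per pixel. This gives a compact object with distinct high- and low-density
interior regions — the two features the damage analysis probes. It does
*not* emulate membrane ultrastructure, texture at the pixel scale, or any
3-D projection effect; conclusions from the tests are about the pipeline's
behaviour, not about organelle biology.

`diffract` returns `|F(ρ)|²` with every pixel valid; Parseval
(`ΣI = N_pix Σρ²`) and Friedel centrosymmetry hold to machine precision.
`add_poisson_noise` rescales the total to a photon budget and draws
independent Poisson counts. The default budget is 10⁶ photons per pattern —
a photon-starved regime in which speckle is clearly visible but shot noise
dominates the high-frequency shells, which is the regime the clustering
stage exists for. For a dose series, `diffract_series` scales each step's
budget by its relative total scattering power: equal exposures of a fading
sample collect fewer photons, and preserving that relative scale is what
makes electron totals comparable across the series after reconstruction.

The beamstop is modelled as a rectangle, optionally off-centre; blocked
pixels whose Friedel partner survives are refilled with the partner's value,
and the residual missing set is centrosymmetric by construction. Binning
sums `b×b` blocks (a block is valid only if all members are), multiplies
the frequency increment by `b`, and conserves counts. The subsequent
deconvolution divides the binned pattern, in its conjugate
(autocorrelation) domain, by the box transfer function wherever its
magnitude exceeds 0.1, leaving the near-zero frequencies untouched to avoid
noise blow-up; small negative excursions of the result are clipped to zero
to keep intensities physical (≈2 % of the total magnitude on realistic
speckle). The exact inverse identity — re-multiplying by the transfer
function recovers the binned spectrum on retained frequencies — holds for
the unclipped core (`deconvolve_box`) and is tested there.

### Damage model

The dose series applies *cumulative* change: each step adds fresh,
independently placed modification on top of the previous step and never
retraces toward step 0. This is the property behind the steadily decreasing
pattern cross-correlations seen in dose series, and it is easy to destroy
by accident: an early version that let the swollen region relax back toward
its starting density produced final patterns that correlated *better* with
step 0 than intermediate ones.

Concretely, with region masks frozen at step 0 (support pixels above the
75th / below the 25th density percentile):

* high region — multiplied each step by a spatially uneven factor of mean
  `1 − high_decay` (default 0.08/step): dense material degrades at
  different rates in different places, so its mean falls monotonically
  while the pattern keeps decorrelating;
* low region, up to `swell_peak_step` (default 2) — gains a fresh additive
  blob field per step, raising the region mean linearly to
  `1 + low_swell` (default 1.35×) of its start: radiation-driven
  aggregation;
* after the peak — the whole non-high interior collapses multiplicatively
  with a profile that is part uniform (guaranteeing a strict low-mean
  decrease), part fresh blobs, and part rim erosion (thinning envelope =
  the strongest low-frequency signature of late-stage damage); the
  mid-density interior is additionally redistributed by a near-zero-mean
  smooth field, which changes structure with little electron change.

The defaults were chosen once as a plausible strong-damage scenario at desk
scale; the support never changes, densities never go negative, and the
high-monotone / low-unimodal mean contracts hold exactly by construction.

## Phase retrieval

`OssReconstructor` iterates, per step: (1) Fourier-magnitude projection on
valid pixels only — missing (beamstop-residue) pixels keep the iterate's
own modelled value, the standard treatment that leaves them as free
parameters; (2) the real-space update — the projected image is kept where
it satisfies the constraints (inside the support, and non-negative in the
default electron-density mode), and HIO feedback `x − β x′` (β = 0.9) is
applied elsewhere; (3) the OSS smoothness step — the region outside the
support is replaced by a Gaussian-low-pass-filtered copy *of itself*, with
the filter width stepping down linearly from N to N/10 frequency pixels
over 10 equal stages (2000 iterations total by default). Each stage
restarts from the best (lowest-R) support-masked image of the previous
stage, and the best image overall is returned.

Filtering the outside region alone, rather than the whole iterate, is a
deliberate choice: filtering the full image leaks the object's DC component
into the exterior as a pedestal that caps noiseless convergence near
R ≈ 10⁻²; filtering the exterior by itself decays it toward its own
(near-zero) mean, preserves the exact plain-HIO limit at infinite width,
and converges to machine precision on clean data. With one stage and an
infinite width the engine reproduces an independently coded HIO recurrence
bit for bit, which the tests check on 32×32 instances.

The starting point is the measured magnitudes under uniform random phases
(seeded); error is the Fourier R-factor of the support-masked projected
image, computed every iteration. Supports come from thresholding the
pattern's autocorrelation at 0.1 of its maximum (after filling missing
pixels with their nearest valid neighbour, without which the zeroed
beamstop residue floods the autocorrelation), followed by morphological
closing and hole filling. The autocorrelation support theorem guarantees
the result contains the centred object for clean data; the threshold trades
support tightness (reconstruction quality) against the risk of clipping the
object, and 0.1 was chosen as the loose-but-safe default. Pipelines that
reconstruct dose series use 0.12 for a slightly tighter mask.

## Clustering and selection

Registration reduces each member to the better of {itself, its point
inversion (Friedel twin)} cyclically shifted by the integer offset
maximizing real-space cross-correlation with the reference; ties go to the
untwinned orientation, making registration idempotent, and constructed
shift/twin cases are undone exactly. Sub-pixel alignment is deliberately
out of scope. In complex mode the global phase is rotated so the
support-mean phase is zero.

The default feature backbone is training-free and fully reproducible: a
fixed bank (seed frozen in the source) of 32 zero-mean, unit-norm random
convolution kernels at scales 3/5/9/15, applied to the L2-normalized image
magnitude, rectified, average-pooled on a 4×4 grid and concatenated
(512 dimensions). Zero-mean kernels ignore constant offsets and a zero
image maps to the zero vector. Any callable image → vector can be
registered as an alternative backbone (e.g. a pretrained CNN layer); the
pipeline shape — convolutional features, then PCA (10 components by
default), then k-means++ (k = 4, seeded, 10 restarts) — stays fixed.

The selected cluster is the one with the lowest mean Fourier R-factor (data
fidelity), ties broken toward the larger cluster, then the lower index; its
`n_best` (default 24) lowest-R members are averaged, each re-registered
against the running mean as it is folded in. A pairwise-correlation
hierarchical baseline (average linkage, dendrogram cut at a configurable
correlation level) is included purely as a comparator.

## Quality metrics

Shells are 1-pixel annuli about the DC pixel up to the Nyquist radius
`min(N, M)//2`; shell `j` is centred at `(j + ½)·w·Δf`. Missing pixels are
excluded from every shell statistic, never imputed; shells left empty are
reported as NaN, not interpolated.

The PRTF is accumulated as the shell *mean of per-pixel ratios*
`|F(ρ̄)|/√I` (the alternative — ratio of shell sums — is a recorded
metadata field, not a silent choice), excluding pixels whose measured
amplitude is below 10⁻⁶ of the maximum to avoid division blow-up. Values
above 1, which shot noise can produce, are flagged in metadata and not
clipped. A self-consistent average over a noiseless pattern scores exactly
1 in every shell; `prtf_random_floor` Monte-Carlos the opposite extreme,
the `1/√N` RMS floor of N fully unconverged members (≈ 0.204 for N = 24).

The noise term is a single constant — the median shell-mean intensity over
the outermost 10 % of shells, where a shot-noise-limited power spectrum
flattens. The Wiener weight is `W = max(PSD − N, 0)/((PSD − N)⁺ + N)`,
which is 0/0-safe, bounded in [0, 1], and multiplies the PRTF pointwise to
give the wPRTF. Resolution is the linear interpolation of the first
crossing below 1/e, converted to nm; a curve that never crosses returns the
Nyquist-limit distance with an explicit `limit_reached` flag.

Amplitude variance is the per-pixel variance of member Fourier magnitudes,
shell-averaged, reported on the natural-log scale by convention (−∞ flags
exactly-zero shells; comparisons in tests use the raw scale, which orders
identically). Cross-correlations are Pearson on raw intensities over
mutually valid pixels — per shell (≥3 shared pixels required, degenerate
shells flagged NaN) or globally as a symmetric unit-diagonal matrix. The
CC flavour is recorded in curve metadata since intensity/amplitude/log
variants are all defensible.

## Damage quantification

Electron totals integrate the (real part of the) image over the support
times an explicit electrons-per-unit calibration (default 1 for synthetic
work; `calibration_from_dc` derives it from the zero-frequency amplitude
when that pixel was measured). Fractional quantities cancel the
calibration exactly. Negative pixel values are kept in sums to avoid
biasing totals. Region trajectories use fixed pixel rectangles on the
common registered frame; series registration reuses the integer-shift/twin
machinery and accepts an external reference (e.g. the ground-truth phantom
in simulation studies). The object boundary for the electron integral is
the support mask.

## Absorbed dose

The dose helper implements the standard uniform-illumination estimate
`D = Φ · E_ph · (μ/ρ)` with fluence Φ = flux × time (photons/µm²), photon
energy in keV and the mass energy-absorption coefficient in cm²/g
(default 30 cm²/g, a soft-tissue-like value at 5.5 keV); it is linear and
additive over exposures. It is a generic helper, not a reproduction of any
specific beamline's dose bookkeeping.

## Problem sizes and test design

The test suite runs everything at desk scale, chosen so the full suite
finishes in about a minute: 64×64 grids, 8–18-member ensembles, 600–1000
OSS iterations, 10⁶-photon patterns, fixed seeds throughout. The
end-to-end damage check reconstructs all four dose steps with 12-run
ensembles and verifies the monotone/unimodal region trends and the CC
orderings; the planted electron-loss check recovers a 5 % uniform decay
within ±30 % relative through the full phasing pipeline. The acceptance
script's Monte-Carlo uses 10,000 bins × 24 phasors.

## Known limitations

Integer-pixel registration only; 2-D only; no partial coherence,
polychromaticity or detector point-spread beyond the box binning; the
feature backbone is untrained (it separates structurally distinct
reconstructions well but is not a learned similarity metric); global CC
margins between consecutive dose steps are small (~10⁻³) in the
photon-starved default regime, so CC orderings on *other* random
realizations than the tested conditions can occasionally invert at the
adjacent-step level; and the rectangle beamstop is a simplification of
real, irregular stops.
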