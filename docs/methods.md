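# Methods

This note records the models behind `subfrac`, the defaults that matter,
and the choices made where the design was genuinely open.  It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Coordinate and intensity conventions

All stacks are `(channel, z, y, x)` with 0-based indices, `y` increasing
downward, half-open crop ranges, and physical calibration carried as
`pixel_size_um` (lateral, isotropic in-plane) and `z_step_um` (axial).  The
default z sampling is 0.5 μm — optical sections of roughly 1 μm oversampled
twofold.  Stored intensities are non-negative integers (12-bit data in
16-bit containers is typical); every threshold operates on raw stored
values, so any stage that produces floats (deconvolution) quantizes back to
the integer domain before counting.  Files are OME-TIFF; experimental
design factors travel in a flat `key=value` sidecar when OME annotations
are unavailable.

## The two measurement macros

**Neuropil macro.**  Each channel of each z-plane is binarized with a
strict `intensity > threshold` test.  Thresholds come from negative-control
images: the pooled control-channel mean plus `k` population standard
deviations, default `k = 3` (the rule is configuration; only the
"derived from control tissue" part is fixed).  Colocalization is
pixel-wise AND of the two masks — a deliberate binary-overlap definition,
not an intensity correlation, because the downstream quantity is a pixel
count.  Per-plane rows and their column sums form the neuropil measures;
8-connected in-plane components above a size floor (default 4 px) provide a
secondary punctum-level count, since "puncta" in common usage can mean
either pixels or spots.

**Membrane macro.**  The plane with the largest colocalized pixel count is
selected (ties break to the lowest z — determinism matters more than the
choice); a supervised override is available and logged.  The somatic
contour is either a manually traced polygon (priority) or an automatic
trace of the marker ring: threshold, keep all connected components above a
size floor, take the convex hull of their union, and simplify the hull
boundary to ≤ 256 vertices.  The union-then-hull step is deliberate — the
ring is interrupted wherever the membrane has no presynaptic terminal, so
the soma outline is generally *not* one connected component, and hole
filling would leak through the gaps.  The soma is convex by construction in
the generator, and very nearly so in the tissue this emulates.  The traced
polygon follows the *outer* edge of the ring.

The "image-based subcellular fraction" is the set of pixels whose exact
Euclidean distance to the closed contour polyline (computed with shapely,
in physical units) is at most half the band thickness — a 2 μm band
centered on the trace, half inside and half outside, since nothing pins the
band to one side.  Band thickness below one pixel is rejected.  Within the
band, receptor∧marker pixels are the synaptic pool and receptor∧¬marker
pixels the extrasynaptic pool; the two always partition the band's receptor
pixels.

## Deconvolution

Richardson–Lucy with a parametric 3-D Gaussian PSF (defaults: σ_lateral
0.2 μm, σ_axial 0.4 μm), run for a small fixed number of multiplicative
updates — default 3 — rather than to convergence.  Early stopping is the
regularizer: a few iterations sharpen puncta; many amplify noise.
Boundaries use reflective padding so that rim structures (the ring of a
tightly framed soma) are not dimmed; total intensity is conserved to a
small fraction of a percent per iteration, non-negativity always.  Both
channels are deconvolved by default; restricting to the receptor channel is
configuration.  Blind PSF estimation is out of scope — the fixed-iteration
contract is what the downstream counts depend on.

## The synthetic scene

One scene is one soma: a hard-edged marker annulus (default centerline
diameter 42 μm, thickness 2 μm) rendered as a cylinder through all planes,
with three planted receptor pools.  Puncta are isotropic in-plane Gaussian
blobs (σ 0.25 μm, amplitude 150) confined to a single plane before blur;
the PSF supplies axial extent.  Synaptic and extrasynaptic puncta sit on
the ring centerline in the equator plane — so the max-colocalization plane
is known by construction — with extrasynaptic sites placed inside planted
full-thickness gaps of the ring (membrane without presynaptic signal).
Intracellular puncta scatter through the soma interior with a 3 μm margin
from the membrane.  On-ring sites are equally spaced slots with random
rotation and jitter, at least 4.5 μm apart, so blurred footprints never
merge; ring gaps are 4 μm wide so marker blur cannot bleed onto an
extrasynaptic punctum.  Channels get a Gaussian-PSF blur, then Poisson
(and/or Gaussian read) noise, then integer quantization; background is a
20-count pedestal.

Two geometric facts make the noiseless limit an exact oracle.  First, with
integer quantization a blob's above-background footprint has radius
σ·√(2·ln(2A)) ≈ 0.85 μm, strictly inside the 2 μm ring when centered on the
centerline — so a synaptic punctum's footprint is receptor∧marker
everywhere and the measured pool masks equal planted-footprint∧band
*exactly*, independent of where the band cuts.  Second, minimum separations
guarantee footprints of different puncta never touch, so pixel sets are
unions of per-punctum footprints and component counts equal punctum counts.
The pre-blur, pre-noise per-class intensity fields are stored in the ground
truth, and tests reproduce the renderer's quantization when computing
expected masks.

What the generator does **not** emulate: tissue texture, vasculature,
multi-neuron occlusion, dendritic membrane, depth-dependent attenuation,
chromatic offsets, or aberrations beyond a Gaussian PSF.  Passing tests
therefore demonstrate the *pipeline's* correctness on scenes whose signal
model matches its assumptions, not robustness to real-tissue artifacts —
on tissue, the manual-contour path and supervised plane override exist
precisely because the automated steps can fail on artifacts.

## The dose model and cohorts

Per-neuron planted counts are negative binomial with overdispersion `a`
(variance μ(1 + aμ), default a = 0.05; a = 0 is the deterministic limit,
counts = round(μ)).  Baselines are 12 synaptic / 8 extrasynaptic / 15
intracellular puncta per neuron.  Dose effects are multiplicative factors
relative to vehicle: total pool 1.3 / 0.8 / 1.8 and synaptic pool 1.1 /
1.0 / 2.0 at the low / mid / high dose (0.01 / 0.1 / 1.0 μM), the
extrasynaptic pool following the total's U shape; the intracellular factor
is derived so the configured total factor is honored.  These magnitudes are
simulation parameters — the study design this emulates reports significance
patterns, not effect sizes — and acceptance is therefore pattern and
parameter recovery, not value matching.  The contralateral hemicord
receives a dose-dependent fraction of the injected-side effect (0.1 / 0.3 /
1.0), reproducing the widespread high-dose spread onto the vehicle side.
Distance from the injection site enters the design (100 μm grid spanning
±600 μm, 13 sites per side at full sampling) but the effect is flat across
it; subjects default to 4 per dose.  Cohorts of rendered scenes clip
extreme on-ring draws to the ring's slot capacity, recording the clipped
value as ground truth.

## Statistics

Neurons are averaged to subject-level cells before inference — the subject
is the experimental unit.  The mixed ANOVA is computed as the classical
balanced split-plot stratum decomposition: dose is tested against
subject-within-dose on subject means; each within factor (side, distance)
and its dose interaction are tested against the factor×subject-within-dose
error on subject×factor cell means.  In balanced designs this is
numerically identical to a subject-random-intercept mixed model, and the
test suite asserts exact F agreement with an independent implementation
(pingouin) on the dose×side design; unbalanced cell structures trigger a
warning and an unweighted-cell-means approximation.  A completely constant
outcome reports p = 1 rather than 0/0.

Tukey HSD runs on subject means over all dose pairs (statsmodels); it
requires ≥ 3 levels and ≥ 2 subjects per level.  The ANCOVA fits
`outcome ~ C(dose, Sum) + C(side, Sum) + covariate` (optionally + dose×side)
by OLS with type-III sums of squares on subject×side cells and reports the
covariate-adjusted dose effect and the covariate slope; it treats cells as
independent, which matches the generator (no subject random intercept) —
with strong subject-level correlation its dose test would be optimistic.
α = 0.05 throughout.  Western-blot helpers implement ratio normalization
to a loading control, averaging of normalized ratios across replicate
runs, the OLS R² of a dilution series (the antibody linear-range check),
and lane background correction: band sum minus band width times the mean
of the median profile densities above and below the band.

## Problem sizes and calibration checks

Monte-Carlo statistics run on the counts-only cohort sampler (no image
rendering): image→count fidelity is established separately by the exact
noiseless closure and by noisy recovery (20 default-noise scenes; mean
per-class punctum counts within 10 % of planted, Spearman ρ ≥ 0.9 against
planted synaptic counts).  Type-I error of the ANOVA/ANCOVA dose tests is
measured on 500 null cohorts (4 subjects per dose, 5 distance sites) and
required to sit in [0.03, 0.07] at α = 0.05; power and the Tukey U-pattern
(high > mid and low > mid for total and extrasynaptic pools) are measured
on 100 cohorts at the default effect sizes and full 13-site sampling.
ANCOVA slope recovery uses synthetic cohorts with synaptic = 0.5·total +
dose effect + noise at 60 subjects.  These sizes were chosen once as the
smallest giving stable Monte-Carlo estimates.

## Known limitations

- The membrane band is a 2-D band in one plane, not a 3-D shell; dendritic
  membrane is not traced.
- Component counts are per-plane (neuropil macro) or 3-D with 26-
  connectivity (scene recovery); sub-pixel spot fitting is out of scope.
- The ANCOVA ignores the side-within-subject correlation (see above).
- The auto-trace assumes a convex soma; concave cells need the manual
  contour path.
- Colocalization is binary overlap; Manders/Pearson coefficients are not
  computed.
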