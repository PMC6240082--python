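# Methods

## Quenching model

The core physics is the resonance energy transfer (RET) between a point
fluorophore and a graphene-like 2-D sheet.  At gap distance *z* (nm) the
transfer efficiency is

    eps(z) = 1 - [1 + A (lambda/z)^4]^(-1)

with emission wavelength `lambda` (570 nm for Cy3B, 665 nm for AF647) and a
single dimensionless coefficient `A` that absorbs the dipole orientation
factor, the coupling strength and the structural difference between
graphene and graphene oxide.  The default `A = 2.6e-8` is the value
obtained from monolayer-GO quenching data.  The closed-form inverse
`z = lambda [A (1-eps)/eps]^(1/4)` is exposed for RET-based height
estimation; it round-trips with the forward law to < 1e-10 relative error.

Quenching is applied as an attenuation of the *emitted photon rate* by
(1 − eps), not as a lifetime model: the estimator this package implements
is built on photon densities, which is also why it is self-referenced
(ratio of densities within a single image, so excitation power, buffer
state and exposure history cancel).  Multi-layer GO films are treated with
the same law; their `A` can be configured separately since the monolayer
value is not established for films.

The thin-film absorption utility compounds a per-nm absorbed fraction
multiplicatively, `1 - (1 - f)^t`.  With the literature-derived
0.45 %/nm monolayer bound this gives 2.2 % for a 5 nm film; published
wording for that number calls it a "transmission of 2 %", which is
numerically the absorbed fraction — we compute absorption and note the
terminology mismatch without resolving it.

## Synthetic scenes and placements

Scenes live in continuous nm coordinates, origin top-left, y downward;
raster masks use half-open pixel bins.  Three templates mirror the
specimen classes of interest: a square GO flake under a uniform dye layer,
smooth-backbone fibres (persistent random walks, default physical width
11 nm from AFM) over a half-field flake, and capsule shells (annuli,
default shell thickness 300 nm within the observed 200–400 nm range) on a
whole-field GO film.

Fluorophore roles:

* **specific** — decorate fibres (uniform along the backbone, transverse
  offset uniform across the width, `z_gap` = spacer + uniform(0, width))
  and capsule shells (uniform on the annulus, `z_gap` = 500 nm, the imaged
  slice height through a bacterium — far outside the ~15 nm quenching
  range, so capsule labels are essentially unquenched);
* **nonspecific_background** — uniform over the field at the spacer
  height, emulating surface-adsorbed excess dye;
* **aggregate_member** — a Poisson number of clusters, each with
  2 + Poisson(size_mean − 2) members placed uniformly in a 30 nm disc at
  the spacer height.  Aggregates are invoked qualitatively in the
  literature; this is the simplest exchangeable cluster model and all
  three knobs are exposed.

Counts are Poisson with mean density × area.  No labelling or background
densities are published for these experiments, so the defaults are
realistic free parameters, not literature claims: a background coating of
tens of dyes per um^2, fibre labelling of a few thousand localizations per
um of backbone, photon budgets of 350–1000 photons per blink.

A single global seed feeds a CRC32-keyed per-operation stream split, so
each stage can be re-run independently and placements are bit-reproducible.

## Photophysics and localization

Blinking is a memoryless per-frame Bernoulli process (`p_on` per frame);
no photobleaching is modelled.  Photons per on-event are
Poisson(budget × (1 − eps_eff)), with eps_eff evaluated from the placement's
`z_gap` when its (x, y) lies over a GO region and 0 otherwise.  Two routes
produce localization tables:

* **direct** — detections below the photon threshold are dropped;
  coordinates are truth + Gaussian noise of sd `psf_sigma/sqrt(N)` per
  axis, which is also the reported uncertainty;
* **end-to-end** — emission events are rendered as pixel-integrated
  Gaussians plus Poisson camera background (16-bit stacks, a guard caps
  the stack at 512 x 512 x 2000 pixels), then localized by 3 x 3
  local-maximum detection (ties resolved in row-major scan order,
  candidates closer than 2 sigma merged toward the brighter) and a
  five-parameter integrated-Gaussian fit (x, y, log N, log sigma, offset).

The spot fit minimizes the Poisson deviance via signed square-root
deviance residuals inside a Levenberg–Marquardt loop — i.e. the
maximum-likelihood estimate for counting noise expressed as a least-squares
problem.  A plain unweighted fit was measured to inflate the empirical
position RMSE 30–50 % above `psf_sigma/sqrt(N)`; the deviance fit sits
within ~10 % of it at N = 100–1600 photons when the camera background is
low (the sqrt(N) scaling check is run at 0.05 background photons/pixel so
the photon-information limit, not the background term, dominates).  Pixels
closer to another detected emitter than to the one being fitted are
excluded from its residuals, which keeps neighbouring spots ~5 sigma apart
from pulling each other.  Diverged fits are dropped and counted.

## Efficiency estimation and the quenching-law fit

`photon_density` sums the photons of localizations whose centres fall in a
mask, divided by the mask area (point-in-mask membership, not PSF-spread
mass — densities are computed from localization tables).  `energy_transfer`
aggregates replicate images to a mean and standard deviation, mirroring
the 5-images-per-condition replication of the measured curves.  Efficiency
estimates above 1 (possible by sampling noise) are retained in reports and
clipped, with a warning, only for fitting.

`fit_quench_curve` performs weighted nonlinear least squares over the
single parameter, on log10 A so positivity is structural, with weights
1/sd^2 when replicate sds are supplied.  A coarse log-grid start plus
Levenberg–Marquardt restarts makes the 1-D problem robust; the standard
error comes from the Jacobian at the optimum.  For the efficiency
experiments the detection threshold is zero, which keeps photon sums — and
hence the density ratio — unbiased; with a realistic positive threshold
the estimator saturates (quenched events vanish entirely), which is the
contrast mechanism itself rather than an estimator defect.

Simulated recovery: with 8 spacer thicknesses (2–15 nm), 5 replicate
images each, ~500 dyes per measurement region and 500-photon budgets, the
fitted A lands within ±0.4e-8 of the 2.6e-8 truth in all of 20 seeds,
with median relative bias below 1 %.

## Rendering

Histogram rendering counts localizations (optionally photon-weighted) per
half-open pixel; gaussian rendering adds a unit-mass pixel-integrated
Gaussian per localization with its uncertainty as kernel sigma, truncated
at 4 sigma (< 0.1 % mass loss, logged when boundary truncation exceeds
it).  The default reconstruction pixel is 10 nm, roughly half the best
resolution of interest; metrics use finer grids (FRC 5 nm, FOI profiles
2–4 nm).  The diffraction-limited renderer convolves quench-attenuated
photon rates with a wide Gaussian PSF (~200 nm FWHM scale) and is the
baseline against which GO "shadows" are shown.

## Metrics

**FRC** — localizations are split once at random (seeded, bit-stable) into
two half-sets, each rendered as a histogram on a common even square grid;
the ring correlation Re(sum F1 F2*) / sqrt(sum|F1|^2 sum|F2|^2) is smoothed
with a 3-ring moving average (edge-normalized) and the resolution is the
inverse of the first, linearly interpolated, crossing below the fixed 1/7
threshold.  No frame-block splitting is used.  A curve that never crosses
within Nyquist yields an explicit "unresolved at this pixel size" result.
On a dense fibre scene (6 fibres, 12 000 localizations per um of backbone)
with 8 nm localization noise the measured resolution is ~23 nm — inside
the 2.355 sigma (1 ± 0.3) band but above the 18.8 nm limit, because the
ring signal-to-noise, not only the blur, sets the crossing at finite
counts.

**FOI** — at every 10 nm along each fibre backbone the image intensity is
sampled along the local normal (bilinear interpolation; profile half-width
5x the expected PSF FWHM), fitted with a 1-D Gaussian plus offset, and the
FWHMs are histogrammed in 4 nm bins (ties toward the smaller bin).  The
modal FWHM minus the fibre width (11 nm) minus the fluorophore size (1 nm)
is the effective PSF; a negative value is reported and flagged rather than
suppressed.  Localization tables are first rendered in gaussian mode.
This subtraction treats the widths of the PSF, the fibre body and the
fluorophore as composing *additively* — the convention the metric inverts.
The prescribed-profile fibre simulator therefore draws transverse scatter
so that the rendered cross-section FWHM equals effective-PSF + 11 + 1 by
construction (removing the render-kernel width in quadrature); under a
strict convolution of a Gaussian PSF with the 11 nm top-hat the additive
rule would not hold exactly, which is a known approximation of the metric
itself, not of this implementation.

**Contrast** — C = (I − I_b)/I_b, mean pixel intensities on images,
photon densities on tables; feature and background masks must be disjoint.
Quenching the background by (1 − eps) multiplies C by ~1/(1 − eps) when
the feature dominates, and contrast improvement factors compose
multiplicatively across serial suppressions.

**Aggregate study** — the same fibre scene is imaged clean and with bright
aggregates (2 clusters/um^2 of ~20 members at 3000-photon budgets:
sparse, compact, very bright artefacts).  Aggregates appear in both FRC
half-sets at essentially the same position, injecting spurious
high-frequency correlation: across seeds the FRC-reported resolution drops
from ~24 nm to ~14 nm (it looks "better"), while the FOI effective PSF —
anchored to the fibre backbones — is unchanged at the bin level.  A
one-sided sign test across >= 10 seeds formalizes the directional claim.
With a GO film under the field and the fibre labels held above the
quenching range, the aggregate condition collapses back onto the clean
one: the coating removes the artefact.

## What the generator does and does not emulate

Captured: quenching-law photon attenuation, stochastic blinking, photon-
count-limited localization error, non-specific background, aggregate
artefacts, replicate-image variability.  Not captured: sample drift,
astigmatic 3-D PSFs, TIRF excitation profiles, photobleaching kinetics,
sCMOS per-pixel noise, fluorophore re-activation correlations, GO surface
wrinkling (which in real samples broadens the efficiency error bars at
intermediate gaps).  Passing tests therefore validate the estimators and
metrics under idealized photophysics; they do not certify performance on
real movies with drift or structured background.

## Numerical choices

* Polygon membership uses a 1e-6 nm outward buffer so boundary points are
  deterministic members; overlapping GO regions behave as their union.
* The quench-law fit clips eps into [0, 1 - 1e-9) before fitting and
  warns; zero replicate sds fall back to uniform weights.
* FRC rings are indexed by rounded integer radius; the DC ring is excluded
  from threshold search.
* FOI profile fits are rejected when flat, diverged, off-centre by more
  than half the profile half-width, or narrower than half the sampling
  step; fewer than 10 accepted fits is an error that lists the reasons.
* CSV numerics are written with 6 significant digits, making
  write -> read -> write byte-identical.
* Problem sizes in the test-suite and acceptance runs (4 um fields, 50–2000
  frame movies, 10^4–10^5 localizations) are chosen so the full suite
  completes in about a minute on one CPU while every statistical tolerance
  retains a >= 2-sigma margin.

## Known limitations

The localizer is single-emitter (no multi-emitter deconvolution); overlap
beyond ~3 sigma separation merges detections.  The FRC band claim is
count-dependent, as discussed above.  The FOI metric requires backbones as
input (ground truth in simulation, external tracing on real data) and its
additive width convention is approximate for wide fibres.  Efficiency
estimates at positive detection thresholds are intentionally
saturation-biased; use threshold 0 for unbiased law fitting.
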