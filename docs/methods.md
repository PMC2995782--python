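# Methods

This note records the models, numerical choices and known limitations of
the package; the README gives the user-facing overview.

## Data model

A hyperspectral stack is a cube indexed `(x, y, w)` with a strictly
increasing wavenumber axis (cm⁻¹) of length W; the axis is the only
mapping from channel index to wavenumber, and all spectral windows are
closed intervals **in wavenumber**, not channel index.  Intensities are
treated as unitless floats (CCD counts without a documented gain).  TIFF
interchange stores float32 pages (one per w-plane) with a JSON sidecar for
the axis; HDF5 stores the float64 cube losslessly and is the dialect used
for reproducibility checks (writes disable HDF5 timestamp tracking so
identical data produce identical bytes).

## Cosmic-ray removal

Cosmic rays hit isolated detector elements, appearing as delta-like spikes
typically an order of magnitude above the Raman signal.  The rule is
strictly per pixel and single-pass: mean μ and **population** standard
deviation σ are computed once over the full, spike-inclusive spectrum, and
every channel with |value − μ| > kσ (default k = 3) is replaced by the
nearest *preceding* unflagged channel value; a flagged run at the start of
the spectrum borrows the first *following* unflagged value.  Choices worth
recording:

* Single-pass statistics (no iterative re-estimation): a spike 10× the
  signal scale still exceeds 3σ of spike-inclusive statistics for
  realistic W, and the single pass keeps the step O(elements).
* The deviation test is two-sided, so dead-pixel dropouts are caught too.
* σ = 0 pixels flag nothing; a fully flagged pixel cannot occur for
  k ≥ 1 (Chebyshev) and is defensively left untouched.
* Only individually exceeding channels are flagged; the flag mask is not
  grown to neighbors.
* The rule's false-positive rate depends on the pixel's spectral
  *structure*: the threshold is kσ of the whole spectrum, so structured
  spectra (any real Raman pixel — substrate background, fluorescence,
  bands) have σ well above the detector-noise floor and flag pure noise
  essentially never, while a hypothetical flat spectrum plus iid Gaussian
  noise would flag at the 2·Φ(−3) ≈ 0.27 % two-sided rate.  The phantom
  therefore gives every region a broad substrate band (see below).

A second pass after repair may flag a few additional channels (the repair
changes μ and σ); idempotence is asserted only statistically on phantom
data, not guaranteed in general.

## Wavenumber calibration

`match_calibration_peaks` greedily pairs measured peak positions with the
nearest unused reference position, accepting pairs within a tolerance
(default 3 cm⁻¹).  It checks an instrument calibration against a database
ethanol spectrum; peak *detection* is out of scope here (the rendering
module finds peaks for color mapping).

## Z-LSR

Per pixel: z̄ = (s̄ − μ)/σ with population σ; slope of the least-squares
line of z̄ against the channel index i = 1…N:

    m = (N·Σ i·zᵢ − Σ i · Σ zᵢ) / (N·Σ i² − (Σ i)²);

re-weighted vector v̄ = m·z̄.  Decisions:

* **Population σ** in both the z-score and the despiking step, pinned for
  exact testability; at W ≈ 10²–10³ the sample/population difference is
  far below every tolerance used.
* **Index regressor** by default.  Because z̄ sums to zero, replacing the
  index with any affine relabelling (e.g. a uniform wavenumber axis) only
  rescales every slope by the same factor, leaving image contrast
  unchanged; a `regressor="wavenumber"` option exists for non-uniform
  axes.
* **Degenerate pixels** (σ = 0: saturated or dead) map to z̄ = 0, m = 0,
  v̄ = 0 — dark in all outputs — rather than raising, so batch processing
  never aborts.
* **The full-axis mean of v̄ is identically zero** (it equals m·mean(z̄)
  and z̄ has zero mean), so the contrast image must use a spectral
  window; the CH-stretch preset 2842.6–3024.5 cm⁻¹ (lipid CH₂ / protein
  CH₃ bands) is the standard choice for cell imaging and the default in
  the pipeline.  The windowless form is kept and tested as the zero
  image.
* The field-averaged v̄ spectrum is max-normalized to 1 for display; the
  normalization is a display convention only.
* Consequence of the construction: v̄ is exactly invariant under any
  per-pixel affine map s̄ → a·s̄ + b (a ≠ 0) — z̄ and m flip sign together
  for a < 0 — which is what removes background bias and illumination
  gradients.

The transform processes pixels in blocks of 2048 so its working set stays
cache-resident regardless of stack size; per-pixel cost is then uniform
and measured wall-clock scales as a power law in pixel count with exponent
≈ 1.05–1.15 over 10³–10⁵ pixels (the scaling check in the test suite
measures each size over enough distinct stacks to be RAM-resident, so the
fit reflects the algorithm rather than the cache hierarchy).

## SVD component analysis

The cube flattens to A (W rows × X·Y columns; raster order row-major over
(y, x) with x fastest, round-trip tested).  A thin SVD (K = min(W, P);
the discarded columns of a full decomposition multiply zero singular
values) gives eigenspectra U and eigenimages V.  The sign of each
component is fixed by making the largest-magnitude entry of its
eigenspectrum positive, so signal eigenspectra are reproducibly
positive-going across linear-algebra backends.

Component ranking uses the RMS magnitude S_RMSD(x̄) = √(Σxᵢ²/N).  Applied
literally to the unit-norm eigenspectra this is constant 1/√W and ranks
nothing (asserted in the suite as a documented degeneracy), so the default
mode scores the **pixel-averaged rank-1 reconstruction** σₖ·uₖ·mean(vₖ):
spatially incoherent noise components average toward zero over the field
while coherent signal survives.  The literal `raw_eigenvector` mode is
retained for reference.  Ties break by ascending component index.

When two signal components have nearly equal singular values the SVD may
return an arbitrary rotation of their eigenspectra within the shared
subspace; validation therefore checks that the span of the top-ranked
eigenspectra captures each known profile, not that individual eigenvectors
match profiles one-to-one.

## Rendering

Contrast normalization is a linear percentile stretch (defaults 1–99) to
[0, 1], clipping outside; a constant image maps to zeros.  Percentiles
rather than min–max resist residual outliers.  Automated false coloring
finds the strongest local maxima (strictly greater than both neighbors,
tallest first, greedily separated by ≥ 20 cm⁻¹ by default) of the global
mean spectrum — per-pixel peak hunting would be noise-dominated — and maps
the top three to R, G, B as the mean intensity within ±8 cm⁻¹ of each
peak (a window rather than a single channel, robust at ~1.6 cm⁻¹
resolution), each channel stretched independently.  A groups-of-windows
per channel variant is exposed (`channel_windows`) but not the default.
Bicubic resampling uses cubic-spline interpolation with edge padding;
factor 1 short-circuits to the identity.  No cross-dataset color
normalization is applied: color maps are comparable within, not across,
acquisitions.

## Phantom generator

Phantoms emulate the imaging conditions the pipeline assumes: named
regions (rasterized in list order, later regions claiming overlapping
pixels so final masks are disjoint — background, cell ellipse, nucleus
ellipse), per-region spectral profiles (Gaussian bands + constant
baseline), a linear illumination-bias field, additive Gaussian detector
noise (Poisson is available as an option; Gaussian keeps closed-form
expectations for tests), and additive single-element cosmic-ray spikes
(a two-adjacent-channel mode exists).  Generation is bit-reproducible
from the spec's seed.

Default macrophage phantom (64×64×300 over 2500–3100 cm⁻¹):

* every region carries a broad quartz-like substrate band (2700 cm⁻¹,
  FWHM 250, amplitude 8) on baseline 1 — this is what gives each pixel a
  realistic, structured σ (see the cosmic-ray section);
* cytoplasm (ellipse, radii 24×20 px) adds CH₂ at 2850 cm⁻¹ (FWHM 30,
  amplitude 10); nucleus (concentric ellipse, 9×8 px) adds CH₃ at
  2930 cm⁻¹ with its amplitude solved numerically so both regions have
  exactly equal mean w-averaged clean intensity — a deliberately
  adversarial design: intensity-based contrast is impossible by
  construction and only spectral shape can separate the regions;
* concentric geometry makes the linear bias field (5 %/3 % across x/y)
  average identically over both cell masks, so the bias cannot leak
  intensity contrast either;
* noise σ = 1 count (peak SNR ≈ 10 per channel); spike rate 200 per cube
  at amplitude 100 (10× the cell band).

What the phantom does *not* model: optical point-spread blur, spatially
correlated noise, fluorescence baselines beyond a constant+band, detector
nonlinearity, and cell-shape irregularity.  Passing tests therefore show
the algorithms behave as specified under their stated statistical
assumptions, not that any biological claim holds on real instrument data.

## Pipeline

Steps always execute in the fixed order cosmic_ray → zlsr → svd → render
(despiking must precede statistics it would corrupt).  A JSON manifest
records package/numpy versions, the full configuration, per-step timings
and the despiking summary; with fixed inputs, config and seed, outputs are
byte-identical across runs.  Unreadable inputs are recorded and skipped
(exit code 1 for partial failure); an invalid configuration aborts before
any processing (exit code 2).

## Problem sizes used in the checks

The suite and the acceptance script use the 64×64×300 default phantom,
32×32×200 ranking phantoms, 64×256 random matrices for the SVD
identities, and 10³–10⁵-pixel stacks at W = 300 for the scaling fit —
sizes chosen so each property is measured with comfortable statistical
margin while the whole suite runs in well under a minute of compute for
everything but the timing fit.
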