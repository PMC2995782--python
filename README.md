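# ramanzlsr

Automated processing of label-free confocal Raman microscope image stacks.

Raman microscopy of live cells (e.g. macrophages) produces hyperspectral
stacks — two spatial axes and one spectral axis of wavenumbers w (cm⁻¹),
one full vibrational spectrum per pixel — at very low signal-to-noise.
Plain averaging over w reduces noise but discards the chemical information,
and multivariate decompositions are too slow for screening large
acquisitions and need a human to pick components.  This package implements
a fast, fully automated alternative, **Z-LSR** (z-score standardization +
least-squares-regression weighting), together with the supporting stages of
a batch pipeline:

1. **Cosmic-ray removal** — per pixel, any channel deviating more than
   3σ from the pixel's own mean is replaced by the nearest preceding
   trusted channel value.
2. **Z-LSR** — per pixel spectrum s̄: standardize
   z̄ = (s̄ − μ)/σ (population σ), fit a least-squares line to z̄ against the
   channel index i = 1…N and keep its slope

   m = (N·Σᵢ i·zᵢ − Σᵢ i · Σᵢ zᵢ) / (N·Σᵢ i² − (Σᵢ i)²),

   then re-weight v̄ = m·z̄.  Averaging v̄ over a spectral window (the
   CH-stretch preset 2842.6–3024.5 cm⁻¹ ships built in) yields an image
   whose contrast comes from spectral *shape*, not intensity — background
   bias and non-flat illumination cancel in the standardization.  Cost is
   O(pixels × channels): linear in stack size.
3. **SVD component analysis** — the stack flattens to a channels × pixels
   matrix A = U·S·Vᵀ; components are ranked automatically by the RMS
   magnitude of the pixel-averaged rank-1 reconstruction σₖ·uₖ·mean(vₖ),
   and the stack is reconstructed from the top-ranked components.
4. **Rendering** — percentile contrast stretch, automated three-peak
   false-color mapping (strongest peaks of the mean spectrum → R, G, B),
   optional bicubic interpolation.

A synthetic phantom generator with full ground truth (region masks, clean
cube, spike coordinates) makes every stage verifiable without instrument
data.

## Worked example

The default phantom is a 64×64×300 cube (2500–3100 cm⁻¹) of a
macrophage-like field: quartz substrate, cytoplasm with a lipid-like CH₂
band (2850 cm⁻¹), and a nucleus with a protein-like CH₃ band (2930 cm⁻¹)
at *equal* mean intensity, plus illumination bias, detector noise, and
~200 cosmic-ray spikes.

```python
from ramanzlsr import (default_macrophage_phantom, remove_cosmic_rays,
                       zlsr_transform, zlsr_image, CH_STRETCH_WINDOW,
                       mean_spectrum, find_top_peaks, colorize)

stack, truth = default_macrophage_phantom(seed=1)
cleaned, report = remove_cosmic_rays(stack, threshold_sigmas=3.0)
v, slopes, z = zlsr_transform(cleaned)
image = zlsr_image(v, *CH_STRETCH_WINDOW)
peaks = find_top_peaks(mean_spectrum(cleaned), min_separation=60.0)
rgb = colorize(v, list(peaks)[:3])
```

Output of this run (seed 1):

```
stack: 64x64 pixels, 300 channels (2500-3100 cm-1)
cosmic rays: 525 channels replaced (4.27e-04 of elements)
nucleus/cytoplasm separation (AUC): Z-LSR 0.996, plain w-average 0.511
strongest peaks of the mean spectrum (cm-1): [2698.7, 2849.2, 2921.4]
false-color R/G/B -> [2698.7, 2849.2, 2921.4] cm-1
```

All 194 injected spikes are caught (the extra flags are the expected
false-positive tail of the 3σ rule).  The separation line is the method's
point: nucleus and cytoplasm have equal mean intensity, so the plain
spectral average cannot distinguish them (AUC ≈ 0.5, chance), while the
Z-LSR image separates them almost perfectly (AUC 0.996) because their
spectra *differ in shape*.  The three strongest bands — substrate, CH₂,
CH₃ — map to the red, green and blue channels, giving each region a
distinct false color.

The same pipeline runs from the shell:

```sh
raman-zlsr simulate --seed 1 -o phantom.h5
raman-zlsr process -i phantom.h5 -o out/        # despike -> Z-LSR -> render
raman-zlsr svd     -i phantom.h5 -o out/ --top-k 3
```

`process` writes the despike report (CSV), slope map and Z-LSR contrast
images (PNG), the v̄ cube (HDF5/TIFF), the false-color PNG with its peak
report, and a JSON manifest recording parameters, timings and versions;
reruns with the same seed are byte-identical.

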