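"""Z-LSR: z-score standardization + least-squares-regression slope weighting.

The transform converts spectral-shape differences into image contrast in
three per-pixel steps, with no pixel-to-pixel coupling:

1. standardize the pixel's spectrum s to a z-score vector
   ``z = (s - mu) / sigma`` (population sigma), which removes absolute
   intensity, background bias and non-flat-field illumination;
2. fit a least-squares line to z against the channel index i = 1..N and keep
   its slope m — a single scalar summarizing the spectral trend of the pixel;
3. re-weight: ``v = m * z``.

Averaging the v cube over a spectral window yields the contrast image.  The
cost is O(pixels x channels), i.e. linear in stack size, which is what makes
the method usable for near real-time screening of large acquisitions where a
full multivariate decomposition is not.

Degenerate (sigma = 0) pixels — saturated or dead — map to z = 0, m = 0,
v = 0 rather than raising, so batch processing never aborts on one pixel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Union

import numpy as np

from .hyperstack import HyperStack, PlaneImage, Spectrum, mean_over_w

#: CH-stretch window (cm^-1) dominated by lipid CH2 / protein CH3 bands;
#: the standard display window for cell imaging.
CH_STRETCH_WINDOW: tuple[float, float] = (2842.6, 3024.5)


@dataclass
class StandardizedStack:
    """Per-pixel z-score cube with the per-pixel statistics that produced it."""

    data: np.ndarray          # (x, y, w) z-scores, dimensionless
    mu_map: np.ndarray        # (x, y) per-pixel mean, original counts
    sigma_map: np.ndarray     # (x, y) per-pixel population sd, original counts
    wavenumbers: np.ndarray


@dataclass
class SlopeMap:
    """Least-squares slope m per pixel (dimensionless, per channel index)."""

    data: np.ndarray          # (x, y)
    n_channels: int


@dataclass
class ZLSRStack:
    """Re-weighted cube: each pixel's v-vector is m times its z-vector."""

    data: np.ndarray          # (x, y, w)
    wavenumbers: np.ndarray


class ZScoreResult(NamedTuple):
    z: np.ndarray
    mu: float
    sigma: float
    degenerate: bool


def zscore_standardize(spectrum: Union[Spectrum, np.ndarray]) -> ZScoreResult:
    """Standardize one spectrum: ``z = (s - mu) / sigma`` with population sigma.

    A constant input (sigma = 0) returns the all-zero vector with the
    ``degenerate`` flag set.  Output length equals input length.
    """
    s = spectrum.values if isinstance(spectrum, Spectrum) else np.asarray(spectrum, float)
    if s.ndim != 1 or s.size < 2:
        raise ValueError("spectrum must be 1-D with length >= 2")
    mu = float(s.mean())
    sigma = float(s.std())
    if sigma == 0.0:
        return ZScoreResult(np.zeros_like(s), mu, 0.0, True)
    return ZScoreResult((s - mu) / sigma, mu, sigma, False)


def regression_slope(z: np.ndarray, regressor: Optional[np.ndarray] = None) -> float:
    """Least-squares slope of z against the channel index i = 1..N.

    ``m = (N * sum(i*z_i) - sum(i) * sum(z_i)) / (N * sum(i^2) - (sum(i))^2)``.
    For a genuinely z-scored input (sum z = 0) the second numerator term
    vanishes.  An explicit ``regressor`` (e.g. the wavenumber axis) may be
    substituted for the index; since z sums to zero this only rescales m
    uniformly across pixels.
    """
    z = np.asarray(z, dtype=float)
    if z.ndim != 1 or z.size < 2:
        raise ValueError("z-vector must be 1-D with length >= 2")
    n = z.size
    i = np.arange(1, n + 1, dtype=float) if regressor is None else np.asarray(regressor, float)
    if i.size != n:
        raise ValueError("regressor length must match z length")
    num = n * (i * z).sum() - i.sum() * z.sum()
    den = n * (i * i).sum() - i.sum() ** 2
    return float(num / den)


def zlsr_transform(
    stack: HyperStack, regressor: str = "index"
) -> tuple[ZLSRStack, SlopeMap, StandardizedStack]:
    """Apply the full Z-LSR transform to every pixel of a stack.

    Parameters
    ----------
    stack
        Input cube with W >= 2 channels.
    regressor
        ``"index"`` (default) fits the slope against i = 1..N as the method
        defines it; ``"wavenumber"`` fits against the cm^-1 axis instead,
        which rescales every slope by the same factor for a uniform axis.

    Returns
    -------
    (ZLSRStack, SlopeMap, StandardizedStack)
        The v cube, the slope image and the intermediate z cube.
    """
    X, Y, W = stack.shape
    if W < 2:
        raise ValueError("Z-LSR needs at least 2 spectral channels")
    if regressor == "index":
        i = np.arange(1, W + 1, dtype=float)
    elif regressor == "wavenumber":
        i = stack.wavenumbers.astype(float)
    else:
        raise ValueError(f"unknown regressor {regressor!r}")
    si, sii = i.sum(), (i * i).sum()
    den = W * sii - si * si

    flat = stack.data.reshape(X * Y, W)
    z = np.empty_like(flat)
    mu = np.empty(X * Y)
    sigma = np.empty(X * Y)
    m = np.empty(X * Y)
    # blocked over pixels so the working set stays cache-resident at any
    # stack size; per-pixel cost is then uniform and total cost O(pixels * W)
    block = 2048
    for lo in range(0, X * Y, block):
        hi = min(lo + block, X * Y)
        d = flat[lo:hi]
        mu[lo:hi] = d.mean(axis=1)
        sigma[lo:hi] = d.std(axis=1)
        s = sigma[lo:hi]
        zb = z[lo:hi]
        np.subtract(d, mu[lo:hi, None], out=zb)
        np.divide(zb, np.where(s > 0, s, 1.0)[:, None], out=zb)
        zb[s == 0] = 0.0
        m[lo:hi] = np.where(s > 0, (W * (zb @ i) - si * zb.sum(axis=1)) / den, 0.0)

    v = (m[:, None] * z).reshape(X, Y, W)
    z = z.reshape(X, Y, W)
    mu = mu.reshape(X, Y)
    sigma = sigma.reshape(X, Y)
    m = m.reshape(X, Y)
    return (
        ZLSRStack(data=v, wavenumbers=stack.wavenumbers),
        SlopeMap(data=m, n_channels=W),
        StandardizedStack(data=z, mu_map=mu, sigma_map=sigma, wavenumbers=stack.wavenumbers),
    )


def zlsr_image(
    zlsr: ZLSRStack, w_lo: Optional[float] = None, w_hi: Optional[float] = None
) -> PlaneImage:
    """Contrast image: per-pixel mean of v over the selected spectral window.

    Note that over the FULL axis the mean of v is identically m * mean(z) = 0
    for every pixel, so a spectral window (e.g. :data:`CH_STRETCH_WINDOW`)
    is what gives the image its contrast.
    """
    as_stack = HyperStack(data=zlsr.data, wavenumbers=zlsr.wavenumbers)
    img = mean_over_w(as_stack, w_lo, w_hi)
    img.label = "Z-LSR " + img.label
    return img


def zlsr_mean_spectrum(zlsr: ZLSRStack, normalize: bool = True) -> Spectrum:
    """Field-averaged v spectrum, max-normalized to 1 by default."""
    values = zlsr.data.mean(axis=(0, 1))
    if normalize:
        peak = np.abs(values).max()
        if peak > 0:
            values = values / peak
    return Spectrum(values=values, wavenumbers=zlsr.wavenumbers)
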