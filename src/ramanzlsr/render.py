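"""Rendering: contrast normalization, automated false-color mapping, resampling.

False coloring is automated by locating the three strongest peaks of the
field-averaged spectrum and assigning red, green and blue to the per-pixel
intensity integrated in a small window around each peak, so the pixel color
reflects the relative strengths of the dominant spectral features.  Each
channel is contrast-stretched independently with a percentile stretch
(robust to residual outliers).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import imageio.v3 as iio
import numpy as np
from skimage.transform import resize

from .hyperstack import HyperStack, PlaneImage, Spectrum
from .zlsr import ZLSRStack


@dataclass
class RGBImage:
    """False-color image; 3 channels in [0, 1], one per mapped peak."""

    data: np.ndarray                       # (x, y, 3)
    peak_wavenumbers: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[2] != 3:
            raise ValueError("RGB image must have shape (x, y, 3)")
        if self.data.min() < 0 or self.data.max() > 1:
            raise ValueError("RGB channel values must lie in [0, 1]")


def _stretch(arr: np.ndarray, p_lo: float, p_hi: float) -> np.ndarray:
    lo, hi = np.percentile(arr, [p_lo, p_hi])
    if hi == lo:  # constant (or degenerate percentile) input -> all zeros
        return np.zeros_like(arr, dtype=float)
    return np.clip((arr - lo) / (hi - lo), 0.0, 1.0)


def normalize_contrast(image: PlaneImage, p_lo: float = 1.0, p_hi: float = 99.0) -> PlaneImage:
    """Linear percentile stretch to [0, 1], clipping outside [p_lo, p_hi]."""
    if not p_lo < p_hi:
        raise ValueError(f"require p_lo < p_hi, got ({p_lo}, {p_hi})")
    return PlaneImage(data=_stretch(image.data, p_lo, p_hi),
                      label=f"{image.label} [stretched {p_lo:g}-{p_hi:g}%]")


@dataclass
class TopPeaks:
    """Peak positions found by :func:`find_top_peaks`, tallest first.

    ``complete`` is False when fewer than the requested number of peaks
    qualified.
    """

    wavenumbers: list[float]
    heights: list[float]
    complete: bool

    def __iter__(self):
        return iter(self.wavenumbers)

    def __len__(self) -> int:
        return len(self.wavenumbers)

    def __getitem__(self, i):
        return self.wavenumbers[i]


def find_top_peaks(
    spectrum: Spectrum, n_peaks: int = 3, min_separation: float = 20.0
) -> TopPeaks:
    """Locate the strongest local maxima of a spectrum.

    A peak is a channel strictly greater than both neighbors.  Candidates are
    taken tallest-first and greedily accepted only if at least
    ``min_separation`` cm^-1 from every already-accepted peak; the list is
    truncated to ``n_peaks`` and flagged incomplete if fewer qualify.
    Endpoints are never peaks (a monotone spectrum yields none).
    """
    v, wn = spectrum.values, spectrum.wavenumbers
    if v.size < 3:
        raise ValueError("spectrum must have at least 3 channels")
    interior = np.arange(1, v.size - 1)
    is_peak = (v[interior] > v[interior - 1]) & (v[interior] > v[interior + 1])
    cand = interior[is_peak]
    cand = cand[np.argsort(-v[cand], kind="stable")]  # tallest first, ties by index
    accepted: list[int] = []
    for c in cand:
        if all(abs(wn[c] - wn[a]) >= min_separation for a in accepted):
            accepted.append(int(c))
        if len(accepted) == n_peaks:
            break
    return TopPeaks(
        wavenumbers=[float(wn[a]) for a in accepted],
        heights=[float(v[a]) for a in accepted],
        complete=len(accepted) == n_peaks,
    )


def colorize(
    stack: Union[HyperStack, ZLSRStack],
    peaks: Sequence[float],
    window_half_width: float = 8.0,
    p_lo: float = 1.0,
    p_hi: float = 99.0,
    channel_windows: Optional[Sequence[Sequence[tuple[float, float]]]] = None,
) -> RGBImage:
    """Map three spectral peaks to R, G, B.

    Channel c of pixel (x, y) is the mean intensity within
    ``+-window_half_width`` cm^-1 of ``peaks[c]``, then each channel is
    independently percentile-stretched to [0, 1].  ``channel_windows`` is the
    optional groups-of-peaks variant: an explicit list of (lo, hi) windows
    per channel that overrides the single-peak windows.
    """
    data, wn = stack.data, stack.wavenumbers
    if channel_windows is None:
        peaks = [float(p) for p in peaks]
        if len(peaks) != 3 or len(set(peaks)) != 3:
            raise ValueError("exactly three distinct peak wavenumbers are required")
        for p in peaks:
            if not wn[0] <= p <= wn[-1]:
                raise ValueError(f"peak {p} cm^-1 lies outside the axis "
                                 f"[{wn[0]}, {wn[-1]}]")
        channel_windows = [[(p - window_half_width, p + window_half_width)]
                           for p in peaks]
        peak_tuple = tuple(peaks)
    else:
        if len(channel_windows) != 3:
            raise ValueError("channel_windows must list windows for exactly 3 channels")
        peak_tuple = tuple(float(np.mean(w)) for w in
                           (np.asarray(cw, float).ravel() for cw in channel_windows))

    rgb = np.zeros(data.shape[:2] + (3,), dtype=float)
    for c, windows in enumerate(channel_windows):
        sel = np.zeros(wn.size, dtype=bool)
        for lo, hi in windows:
            sel |= (wn >= lo) & (wn <= hi)
        if not sel.any():
            raise ValueError(f"channel {c} windows select no spectral channel")
        rgb[:, :, c] = _stretch(data[:, :, sel].mean(axis=2), p_lo, p_hi)
    return RGBImage(data=rgb, peak_wavenumbers=peak_tuple)


def interpolate_bicubic(
    image: Union[PlaneImage, RGBImage], factor: float
) -> Union[PlaneImage, RGBImage]:
    """Bicubic resampling by a scale factor (identity at factor 1)."""
    if factor <= 0:
        raise ValueError("factor must be > 0")
    arr = image.data
    out_xy = tuple(int(round(e * factor)) for e in arr.shape[:2])
    if min(out_xy) < 1:
        raise ValueError(f"factor {factor} collapses extents {arr.shape[:2]} below 1")
    if factor == 1:
        out = arr.copy()
    else:
        shape = out_xy + arr.shape[2:]
        out = resize(arr, shape, order=3, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    if isinstance(image, RGBImage):
        return RGBImage(data=np.clip(out, 0.0, 1.0),
                        peak_wavenumbers=image.peak_wavenumbers)
    return PlaneImage(data=out, label=f"{image.label} [x{factor:g} bicubic]")


# ---------------------------------------------------------------------------
# Output files
# ---------------------------------------------------------------------------

def save_png(image: Union[PlaneImage, RGBImage], path) -> Path:
    """Write an 8-bit PNG; plane images are contrast-stretched first."""
    path = Path(path)
    if isinstance(image, RGBImage):
        arr = image.data
    else:
        arr = _stretch(image.data, 1.0, 99.0)
    # PNG rows are the first array axis; transpose so x runs horizontally
    arr8 = np.round(np.asarray(arr) * 255).astype(np.uint8)
    iio.imwrite(path, np.swapaxes(arr8, 0, 1))
    return path


def write_color_report(image: RGBImage, path) -> Path:
    """JSON sidecar recording which peaks were mapped to which channel."""
    path = Path(path)
    path.write_text(json.dumps({
        "channels": ["red", "green", "blue"],
        "peak_wavenumbers_cm1": list(image.peak_wavenumbers),
    }, indent=2))
    return path
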