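"""Pre-processing: cosmic-ray spike removal and wavenumber-calibration checks.

Cosmic rays reaching the CCD during the long exposures that Raman imaging
requires corrupt isolated detector elements, appearing as delta-function
spikes an order of magnitude above the Raman signal, isolated both spatially
and spectrally.  The removal rule is deliberately simple so that it scales to
batch processing: per pixel, any channel deviating from the pixel's own
spike-inclusive mean by more than ``threshold_sigmas`` standard deviations is
declared an outlier and replaced by the nearest preceding trusted channel
value (a leading run of outliers borrows the first trusted value after it).

Calibration is checked by matching measured peak positions (e.g. from an
ethanol spectrum) against database reference positions within a tolerance in
cm^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .hyperstack import HyperStack


class CosmicRayHit(NamedTuple):
    x: int
    y: int
    w_index: int
    original: float
    replacement: float


@dataclass
class CosmicRayReport:
    """Record of every replaced element.

    Each replacement value is another channel of the same pixel's spectrum
    (the nearest trusted neighbor along w).
    """

    hits: list[CosmicRayHit] = field(default_factory=list)
    threshold_sigmas: float = 3.0

    @property
    def n_flagged(self) -> int:
        return len(self.hits)

    def to_dataframe(self, wavenumbers: Optional[np.ndarray] = None) -> pd.DataFrame:
        df = pd.DataFrame(self.hits, columns=CosmicRayHit._fields)
        if wavenumbers is not None:
            wn = np.asarray(wavenumbers, dtype=float)
            df.insert(3, "wavenumber", wn[df["w_index"].to_numpy(dtype=int)]
                      if len(df) else np.array([], dtype=float))
        return df

    def to_csv(self, path, wavenumbers: Optional[np.ndarray] = None) -> Path:
        path = Path(path)
        self.to_dataframe(wavenumbers).to_csv(path, index=False)
        return path


def remove_cosmic_rays(
    stack: HyperStack, threshold_sigmas: float = 3.0
) -> tuple[HyperStack, CosmicRayReport]:
    """Replace per-pixel spectral outliers beyond ``threshold_sigmas``.

    Statistics are single-pass: the mean and (population) standard deviation
    of each pixel's spectrum are computed once, spikes included, and every
    channel with ``|value - mu| > threshold_sigmas * sigma`` is replaced by
    the nearest preceding unflagged channel value (scanning in increasing w);
    a flagged run at w = 0 takes the first following unflagged value.
    Unflagged channels pass through bit-identical.  A zero-variance pixel
    flags nothing.
    """
    if threshold_sigmas <= 0:
        raise ValueError(f"threshold_sigmas must be > 0, got {threshold_sigmas}")
    X, Y, W = stack.shape
    flat = stack.data.reshape(X * Y, W)
    mu = flat.mean(axis=1, keepdims=True)
    sigma = flat.std(axis=1, keepdims=True)  # population (divide by W)
    flagged = np.abs(flat - mu) > threshold_sigmas * sigma

    repaired = flat.copy()
    report = CosmicRayReport(threshold_sigmas=float(threshold_sigmas))
    if flagged.any():
        rows = np.nonzero(flagged.any(axis=1))[0]
        ok = ~flagged[rows]
        idx = np.arange(W)
        # nearest unflagged channel at-or-before each position ...
        last_ok = np.maximum.accumulate(np.where(ok, idx, -1), axis=1)
        # ... and at-or-after, for leading flagged runs
        first_ok = np.minimum.accumulate(np.where(ok, idx, W)[:, ::-1], axis=1)[:, ::-1]
        fill = np.where(last_ok >= 0, last_ok, first_ok)
        # a fully-flagged row cannot arise for threshold >= 1 (Chebyshev),
        # but guard anyway: leave such a row untouched
        valid = ok.any(axis=1)
        for r, row in enumerate(rows):
            if not valid[r]:
                flagged[row] = False
                continue
            bad = np.nonzero(flagged[row])[0]
            src = fill[r, bad]
            repaired[row, bad] = flat[row, src]
            for w, s in zip(bad, src):
                report.hits.append(
                    CosmicRayHit(
                        x=int(row // Y),
                        y=int(row % Y),
                        w_index=int(w),
                        original=float(flat[row, w]),
                        replacement=float(flat[row, s]),
                    )
                )
    cleaned = HyperStack(
        data=repaired.reshape(X, Y, W),
        wavenumbers=stack.wavenumbers,
        meta={**stack.meta, "cosmic_ray_threshold_sigmas": float(threshold_sigmas),
              "cosmic_ray_n_flagged": report.n_flagged},
    )
    return cleaned, report


# ---------------------------------------------------------------------------
# Wavenumber calibration
# ---------------------------------------------------------------------------

class PeakPair(NamedTuple):
    measured: float
    reference: float
    deviation: float


@dataclass
class PeakMatchResult:
    pairs: list[PeakPair]
    unmatched_measured: list[float]
    unmatched_reference: list[float]

    @property
    def max_deviation(self) -> float:
        return max((p.deviation for p in self.pairs), default=0.0)

    @property
    def n_matched(self) -> int:
        return len(self.pairs)


def match_calibration_peaks(
    measured: Sequence[float],
    reference: Sequence[float],
    tolerance: float = 3.0,
) -> PeakMatchResult:
    """Greedy nearest-neighbor matching of measured vs reference peaks.

    Both lists must be sorted ascending with no duplicates.  Scanning the
    measured peaks in ascending order, each is paired with the nearest
    still-unused reference peak; the pair is accepted iff the absolute
    deviation is within ``tolerance`` (cm^-1).  An empty measured list yields
    a result with zero pairs.
    """
    measured = [float(m) for m in measured]
    reference = [float(r) for r in reference]
    for name, lst in (("measured", measured), ("reference", reference)):
        if any(b <= a for a, b in zip(lst, lst[1:])):
            raise ValueError(f"{name} peak list must be strictly ascending")
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")

    used = [False] * len(reference)
    pairs: list[PeakPair] = []
    unmatched_measured: list[float] = []
    for m in measured:
        best_j = -1
        best_d = np.inf
        for j, r in enumerate(reference):
            if used[j]:
                continue
            d = abs(m - r)
            if d < best_d:
                best_d, best_j = d, j
        if best_j >= 0 and best_d <= tolerance:
            used[best_j] = True
            pairs.append(PeakPair(m, reference[best_j], best_d))
        else:
            unmatched_measured.append(m)
    unmatched_reference = [r for j, r in enumerate(reference) if not used[j]]
    return PeakMatchResult(pairs, unmatched_measured, unmatched_reference)


def read_peak_list(path) -> list[float]:
    """Read a one-wavenumber-per-line text/CSV peak list."""
    out: list[float] = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip().rstrip(",")
        if line:
            out.append(float(line))
    return out
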