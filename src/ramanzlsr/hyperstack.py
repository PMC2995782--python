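"""Data model for hyperspectral Raman stacks.

A confocal Raman microscope produces a stack of x-y intensity planes, one per
spectral position (wavenumber, cm^-1).  The :class:`HyperStack` holds that
3-D cube indexed ``(x, y, w)`` together with the calibrated wavenumber axis,
which is the single source of truth for mapping channel index to cm^-1.

Two interchange formats are supported:

* multi-page TIFF — one grayscale float32 page per w-plane, with a JSON
  sidecar (same basename, ``.json``) carrying the wavenumber axis;
* HDF5 — a single float64 dataset ``/stack`` with a ``wavenumbers``
  attribute (lossless archival dialect).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import pandas as pd
import tifffile


class HyperStackError(Exception):
    """Base class for stack I/O and validation failures."""


class FormatError(HyperStackError, ValueError):
    """The on-disk container is structurally inconsistent."""


class CalibrationMissingError(HyperStackError):
    """No wavenumber axis accompanies the intensity data."""


def _validate_axis(wavenumbers: np.ndarray, w_extent: int) -> np.ndarray:
    wn = np.asarray(wavenumbers, dtype=float).ravel()
    if wn.size != w_extent:
        raise FormatError(
            f"wavenumber axis has length {wn.size}, stack has {w_extent} channels"
        )
    if not np.all(np.isfinite(wn)):
        raise FormatError("wavenumber axis contains non-finite values")
    if wn.size > 1 and not np.all(np.diff(wn) > 0):
        raise FormatError("wavenumber axis must be strictly increasing")
    return wn


@dataclass
class HyperStack:
    """3-D intensity cube ``(x, y, w)`` plus its wavenumber axis.

    Parameters
    ----------
    data
        Intensities in arbitrary counts, shape ``(X, Y, W)``, all finite.
    wavenumbers
        Strictly increasing axis of length ``W`` in cm^-1.
    meta
        Free-form provenance record (instrument, processing history, ...).
    """

    data: np.ndarray
    wavenumbers: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"stack must be 3-D (x, y, w), got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError(f"all extents must be >= 1, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("stack intensities must be finite")
        self.wavenumbers = _validate_axis(self.wavenumbers, self.data.shape[2])

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def window_indices(
        self, w_lo: Optional[float] = None, w_hi: Optional[float] = None
    ) -> np.ndarray:
        """Channel indices whose wavenumber lies in the closed window [w_lo, w_hi]."""
        if w_lo is not None and w_hi is not None and not w_lo < w_hi:
            raise ValueError(f"require w_lo < w_hi, got [{w_lo}, {w_hi}]")
        sel = np.ones(self.wavenumbers.size, dtype=bool)
        if w_lo is not None:
            sel &= self.wavenumbers >= w_lo
        if w_hi is not None:
            sel &= self.wavenumbers <= w_hi
        idx = np.nonzero(sel)[0]
        if idx.size == 0:
            raise ValueError(
                f"window [{w_lo}, {w_hi}] selects no channel of the axis "
                f"[{self.wavenumbers[0]}, {self.wavenumbers[-1]}]"
            )
        return idx


@dataclass
class Spectrum:
    """A single intensity-vs-wavenumber trace (one pixel or a region average)."""

    values: np.ndarray
    wavenumbers: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        self.wavenumbers = _validate_axis(self.wavenumbers, self.values.size)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectrum values must be finite")

    def __len__(self) -> int:
        return self.values.size

    def to_csv(self, path) -> Path:
        path = Path(path)
        pd.DataFrame(
            {"wavenumber": self.wavenumbers, "intensity": self.values}
        ).to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path) -> "Spectrum":
        df = pd.read_csv(path)
        return cls(values=df["intensity"].to_numpy(), wavenumbers=df["wavenumber"].to_numpy())


@dataclass
class PlaneImage:
    """2-D scalar image derived from a stack (e.g. a spectral average)."""

    data: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"plane image must be 2-D, got ndim={self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("plane image values must be finite")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_stack(stack: HyperStack, path, format: str = "hdf5") -> Path:
    """Write a stack to disk.

    ``tiff`` stores one float32 page per w-plane plus a JSON sidecar with the
    axis; ``hdf5`` stores the float64 cube losslessly in dataset ``/stack``
    with the axis as a ``wavenumbers`` attribute.
    """
    path = Path(path)
    if format == "tiff":
        # pages along w: page k is the (x, y) plane at channel k
        pages = np.moveaxis(stack.data, 2, 0).astype(np.float32)
        tifffile.imwrite(path, pages, photometric="minisblack")
        _sidecar_path(path).write_text(
            json.dumps(
                {"wavenumbers": [float(w) for w in stack.wavenumbers], "units": "cm-1"}
            )
        )
    elif format == "hdf5":
        with h5py.File(path, "w", track_order=True) as f:
            ds = f.create_dataset("stack", data=stack.data, track_times=False)
            ds.attrs["wavenumbers"] = stack.wavenumbers
    else:
        raise ValueError(f"unknown format {format!r} (expected 'tiff' or 'hdf5')")
    return path


def read_stack(path, format: Optional[str] = None) -> HyperStack:
    """Read a stack written by :func:`write_stack`.

    The format is inferred from the extension when not given.  TIFF requires
    the JSON sidecar; HDF5 requires dataset ``stack`` with a ``wavenumbers``
    attribute.
    """
    path = Path(path)
    if format is None:
        format = "hdf5" if path.suffix.lower() in {".h5", ".hdf5", ".hdf"} else "tiff"
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tiff":
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise CalibrationMissingError(
                f"no wavenumber sidecar {sidecar.name} next to {path.name}"
            )
        pages = tifffile.imread(path)
        if pages.ndim == 2:  # single-page stack
            pages = pages[None, :, :]
        data = np.moveaxis(pages, 0, 2).astype(float)
        axis = json.loads(sidecar.read_text())
        if "wavenumbers" not in axis:
            raise CalibrationMissingError(f"sidecar {sidecar} lacks 'wavenumbers'")
        return HyperStack(data=data, wavenumbers=np.asarray(axis["wavenumbers"]),
                          meta={"source": str(path), "format": "tiff"})
    if format == "hdf5":
        with h5py.File(path, "r") as f:
            if "stack" not in f:
                raise FormatError(f"{path} has no dataset 'stack'")
            ds = f["stack"]
            if "wavenumbers" not in ds.attrs:
                raise CalibrationMissingError(
                    f"{path} dataset 'stack' lacks 'wavenumbers' attribute"
                )
            return HyperStack(
                data=ds[()],
                wavenumbers=np.asarray(ds.attrs["wavenumbers"]),
                meta={"source": str(path), "format": "hdf5"},
            )
    raise ValueError(f"unknown format {format!r} (expected 'tiff' or 'hdf5')")


# ---------------------------------------------------------------------------
# Projections
# ---------------------------------------------------------------------------

def mean_over_w(
    stack: HyperStack, w_lo: Optional[float] = None, w_hi: Optional[float] = None
) -> PlaneImage:
    """Spectrally averaged image: per-pixel mean over the selected channels.

    The window is closed on wavenumber values; omitting both bounds averages
    the full axis.
    """
    idx = stack.window_indices(w_lo, w_hi)
    img = stack.data[:, :, idx].mean(axis=2)
    if w_lo is None and w_hi is None:
        label = "mean over full axis"
    else:
        lo = stack.wavenumbers[idx[0]]
        hi = stack.wavenumbers[idx[-1]]
        label = f"mean over {lo:g}-{hi:g} cm-1"
    return PlaneImage(data=img, label=label)


def mean_spectrum(stack: HyperStack, mask: Optional[np.ndarray] = None) -> Spectrum:
    """Region-averaged spectrum: per-channel mean over the selected pixels."""
    if mask is None:
        values = stack.data.mean(axis=(0, 1))
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != stack.shape[:2]:
            raise ValueError(
                f"mask shape {mask.shape} does not match spatial extents {stack.shape[:2]}"
            )
        if not mask.any():
            raise ValueError("mask selects no pixel")
        values = stack.data[mask].mean(axis=0)
    return Spectrum(values=values, wavenumbers=stack.wavenumbers)
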