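"""Synthetic phantom stacks with ground truth.

No public Raman stacks of macrophages exist, so validation relies on
phantoms that reproduce the statistical structure the pipeline assumes: a
field partitioned into substrate background, cell body and nucleus, each
with its own spectral profile (Gaussian bands on a constant baseline),
multiplied by a smooth linear illumination-bias field, plus Gaussian
detector noise and sparse additive cosmic-ray spikes.

Every region's profile includes a broad substrate band in addition to any
narrow cell band: real per-pixel Raman spectra are structured (quartz
background, fluorescence), and that structure — not the detector noise —
sets the per-pixel standard deviation against which the cosmic-ray rule
thresholds.

The default macrophage phantom is deliberately adversarial for plain
averaging: the nucleus (protein-like CH3 band near 2930 cm^-1) and the
cytoplasm (lipid-like CH2 band near 2850 cm^-1) are given EQUAL mean
intensity, so only spectral shape — the mechanism Z-LSR exploits — can
separate them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Union

import numpy as np
import yaml

from .hyperstack import HyperStack


@dataclass
class GaussianPeak:
    """One spectral band: center (cm^-1), full width at half maximum, amplitude (counts)."""

    center: float
    fwhm: float
    amplitude: float

    def evaluate(self, wavenumbers: np.ndarray) -> np.ndarray:
        return self.amplitude * np.exp(
            -4.0 * np.log(2.0) * ((wavenumbers - self.center) / self.fwhm) ** 2
        )


@dataclass
class Ellipse:
    cx: float
    cy: float
    rx: float
    ry: float

    def rasterize(self, x_extent: int, y_extent: int) -> np.ndarray:
        if self.rx <= 0 or self.ry <= 0:
            raise ValueError("ellipse radii must be positive")
        x = np.arange(x_extent)[:, None]
        y = np.arange(y_extent)[None, :]
        return ((x - self.cx) / self.rx) ** 2 + ((y - self.cy) / self.ry) ** 2 <= 1.0


@dataclass
class Rectangle:
    """Half-open pixel rectangle: x0 <= x < x1, y0 <= y < y1."""

    x0: int
    y0: int
    x1: int
    y1: int

    def rasterize(self, x_extent: int, y_extent: int) -> np.ndarray:
        if not (0 <= self.x0 < self.x1 <= x_extent and 0 <= self.y0 < self.y1 <= y_extent):
            raise ValueError(f"rectangle {self} not within {x_extent} x {y_extent}")
        m = np.zeros((x_extent, y_extent), dtype=bool)
        m[self.x0:self.x1, self.y0:self.y1] = True
        return m


class FullField:
    """Geometry claiming the whole field; as the first region it is the background."""

    def rasterize(self, x_extent: int, y_extent: int) -> np.ndarray:
        return np.ones((x_extent, y_extent), dtype=bool)


Geometry = Union[Ellipse, Rectangle, FullField]


@dataclass
class Region:
    name: str
    geometry: Geometry
    peaks: list[GaussianPeak]
    baseline: float = 0.0

    def profile(self, wavenumbers: np.ndarray) -> np.ndarray:
        out = np.full(wavenumbers.size, float(self.baseline))
        for p in self.peaks:
            out += p.evaluate(wavenumbers)
        return out


@dataclass
class PhantomSpec:
    """Full recipe for a phantom; a seed makes generation bit-reproducible.

    Regions are rasterized in list order with LATER regions claiming
    overlapping pixels (painter's order), so the resulting named masks are
    disjoint — e.g. background, then cell ellipse, then nucleus ellipse.
    ``bias_gradient`` = (gx, gy) gives the relative illumination change
    across the field: bias(x, y) = 1 + gx*(x/(X-1) - 1/2) + gy*(y/(Y-1) - 1/2).
    """

    x_extent: int
    y_extent: int
    w_extent: int
    wavenumber_range: tuple[float, float]
    regions: list[Region]
    bias_gradient: tuple[float, float] = (0.0, 0.0)
    noise_sigma: float = 0.0
    noise_model: str = "gaussian"          # or "poisson"
    spike_rate: float = 0.0                # probability per element
    spike_amplitude: float = 0.0           # counts added per spike
    spike_width: int = 1                   # 1, or 2 for two adjacent channels
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.x_extent, self.y_extent, self.w_extent) < 1:
            raise ValueError("all extents must be >= 1")
        if not 0.0 <= self.spike_rate <= 1.0:
            raise ValueError("spike_rate must lie in [0, 1]")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.spike_width not in (1, 2):
            raise ValueError("spike_width must be 1 or 2")
        lo, hi = self.wavenumber_range
        if not lo < hi:
            raise ValueError("wavenumber_range must be (lo, hi) with lo < hi")
        if not self.regions:
            raise ValueError("at least one region is required")

    @property
    def wavenumbers(self) -> np.ndarray:
        lo, hi = self.wavenumber_range
        return np.linspace(lo, hi, self.w_extent)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        for r, region in zip(d["regions"], self.regions):
            r["geometry"] = {"kind": type(region.geometry).__name__.lower(),
                             **(asdict(region.geometry)
                                if not isinstance(region.geometry, FullField) else {})}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        regions = []
        for r in d.pop("regions"):
            g = dict(r["geometry"])
            kind = g.pop("kind")
            geometry = {"ellipse": Ellipse, "rectangle": Rectangle,
                        "fullfield": FullField}[kind](**g)
            regions.append(Region(name=r["name"], geometry=geometry,
                                  peaks=[GaussianPeak(**p) for p in r["peaks"]],
                                  baseline=r.get("baseline", 0.0)))
        d["wavenumber_range"] = tuple(d["wavenumber_range"])
        d["bias_gradient"] = tuple(d.get("bias_gradient", (0.0, 0.0)))
        return cls(regions=regions, **d)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path) -> "PhantomSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class PhantomTruth:
    """Everything a test needs: the noise-free cube, masks, spike coordinates."""

    clean: HyperStack
    region_masks: dict[str, np.ndarray]
    spike_coords: list[tuple[int, int, int]]
    spec: PhantomSpec

    def write_masks(self, directory) -> Path:
        """Region masks as PNG (255 = member) plus a JSON listing."""
        import imageio.v3 as iio
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, mask in self.region_masks.items():
            iio.imwrite(directory / f"mask_{name}.png",
                        np.swapaxes(mask.astype(np.uint8) * 255, 0, 1))
        (directory / "truth.json").write_text(json.dumps({
            "regions": sorted(self.region_masks),
            "n_spikes": len(self.spike_coords),
            "spike_coords": [list(c) for c in self.spike_coords],
        }))
        return directory


def bias_field(spec: PhantomSpec) -> np.ndarray:
    gx, gy = spec.bias_gradient
    X, Y = spec.x_extent, spec.y_extent
    bx = (np.arange(X) / (X - 1) - 0.5) if X > 1 else np.zeros(X)
    by = (np.arange(Y) / (Y - 1) - 0.5) if Y > 1 else np.zeros(Y)
    return 1.0 + gx * bx[:, None] + gy * by[None, :]


def generate_phantom(spec: PhantomSpec) -> tuple[HyperStack, PhantomTruth]:
    """Generate (observed, truth).

    observed = clean + noise + spikes, where clean is each region's profile
    evaluated on the axis and multiplied by the bias field.  All randomness
    comes from ``numpy.random.default_rng(spec.seed)`` drawing, in order, the
    noise field then the spike mask, so a fixed spec is bit-reproducible.
    """
    X, Y, W = spec.x_extent, spec.y_extent, spec.w_extent
    wn = spec.wavenumbers

    owner = np.full((X, Y), -1, dtype=int)
    for i, region in enumerate(spec.regions):
        owner[region.geometry.rasterize(X, Y)] = i
    masks = {r.name: owner == i for i, r in enumerate(spec.regions)}

    clean = np.zeros((X, Y, W))
    for i, region in enumerate(spec.regions):
        clean[owner == i] = region.profile(wn)
    clean *= bias_field(spec)[:, :, None]

    rng = np.random.default_rng(spec.seed)
    if spec.noise_model == "gaussian":
        observed = clean + rng.normal(0.0, spec.noise_sigma, clean.shape) \
            if spec.noise_sigma > 0 else clean.copy()
    else:
        observed = rng.poisson(np.clip(clean, 0.0, None)).astype(float)

    spike_coords: list[tuple[int, int, int]] = []
    if spec.spike_rate > 0:
        hit = rng.random(clean.shape) < spec.spike_rate
        coords = np.argwhere(hit)
        for x, y, w in coords:
            observed[x, y, w] += spec.spike_amplitude
            spike_coords.append((int(x), int(y), int(w)))
            if spec.spike_width == 2 and w + 1 < W:
                observed[x, y, w + 1] += spec.spike_amplitude
                spike_coords.append((int(x), int(y), int(w + 1)))

    meta = {"phantom_seed": spec.seed, "phantom_regions": [r.name for r in spec.regions]}
    stack = HyperStack(data=observed, wavenumbers=wn, meta=meta)
    truth = PhantomTruth(
        clean=HyperStack(data=clean, wavenumbers=wn, meta=dict(meta)),
        region_masks=masks, spike_coords=spike_coords, spec=spec,
    )
    return stack, truth


def default_macrophage_phantom(seed: int = 0) -> tuple[HyperStack, PhantomTruth]:
    """The standard test phantom: 64 x 64 x 300 cube over 2500-3100 cm^-1.

    Background is quartz-like substrate (constant baseline plus a broad band
    centered at 2700 cm^-1).  The cell is a concentric ellipse pair: the
    cytoplasm adds a lipid-like CH2 band at 2850 cm^-1 and the nucleus a
    protein-like CH3 band at 2930 cm^-1 whose amplitude is solved so both
    regions have exactly equal mean (w-averaged) clean intensity; with the
    concentric geometry the linear bias field averages identically over both
    masks, so a plain spectral average cannot tell them apart.  Defaults:
    5%/3% linear bias across x/y, unit Gaussian detector noise, and a spike
    rate giving ~200 cosmic rays per cube at 10x the cell-band amplitude.
    """
    X = Y = 64
    W = 300
    wn = np.linspace(2500.0, 3100.0, W)
    substrate = [GaussianPeak(center=2700.0, fwhm=250.0, amplitude=8.0)]
    ch2 = GaussianPeak(center=2850.0, fwhm=30.0, amplitude=10.0)
    # solve the CH3 amplitude so the two cell profiles share the same w-mean
    ch3_unit = GaussianPeak(center=2930.0, fwhm=30.0, amplitude=1.0)
    amp3 = ch2.evaluate(wn).mean() / ch3_unit.evaluate(wn).mean()
    ch3 = GaussianPeak(center=2930.0, fwhm=30.0, amplitude=amp3)

    center = (X - 1) / 2.0
    spec = PhantomSpec(
        x_extent=X, y_extent=Y, w_extent=W,
        wavenumber_range=(2500.0, 3100.0),
        regions=[
            Region("background", FullField(), list(substrate), baseline=1.0),
            Region("cytoplasm", Ellipse(center, center, 24.0, 20.0),
                   list(substrate) + [ch2], baseline=1.0),
            Region("nucleus", Ellipse(center, center, 9.0, 8.0),
                   list(substrate) + [ch3], baseline=1.0),
        ],
        bias_gradient=(0.05, 0.03),
        noise_sigma=1.0,
        spike_rate=200.0 / (X * Y * W),
        spike_amplitude=100.0,
        seed=int(seed),
    )
    return generate_phantom(spec)
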