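"""Batch pipeline: configuration, orchestration, manifest.

Processing order is fixed — cosmic-ray removal always precedes Z-LSR or SVD,
and rendering comes last — because every downstream statistic (per-pixel
mean/sigma, eigenspectra) is corrupted by unremoved spikes.  A run produces
a machine-readable JSON manifest recording versions, parameters, per-step
timings and the cosmic-ray summary, so every output is reproducible from
(inputs, config, seed).

Unreadable inputs are recorded as per-file errors and the batch continues;
an invalid configuration aborts before any processing.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .hyperstack import HyperStack, PlaneImage, mean_spectrum, read_stack, write_stack
from .preprocess import remove_cosmic_rays
from .render import colorize, find_top_peaks, normalize_contrast, save_png, write_color_report
from .svd import build_matrix, decompose, eigenspectra_to_csv, rank_components, reconstruct
from .synthetic import default_macrophage_phantom
from .zlsr import CH_STRETCH_WINDOW, zlsr_image, zlsr_transform

logger = logging.getLogger("ramanzlsr")

_STEP_ORDER = ("cosmic_ray", "zlsr", "svd", "render")


class PipelineError(Exception):
    """Invalid configuration or unrecoverable batch failure."""


@dataclass
class PipelineConfig:
    """Declarative description of one batch run.

    ``inputs`` are stack paths (TIFF or HDF5); the token ``"phantom:default"``
    generates the built-in macrophage phantom from the run seed instead of
    reading a file.  ``steps`` is the subset of
    {cosmic_ray, zlsr, svd, render} to run, always executed in that order.
    """

    inputs: list[str]
    output_dir: str
    steps: list[str] = field(default_factory=lambda: ["cosmic_ray", "zlsr", "render"])
    format: str = "hdf5"
    seed: int = 0
    log_level: str = "INFO"
    # per-step parameters
    threshold_sigmas: float = 3.0
    w_lo: Optional[float] = CH_STRETCH_WINDOW[0]
    w_hi: Optional[float] = CH_STRETCH_WINDOW[1]
    top_k: int = 3
    components: Optional[list[int]] = None
    p_lo: float = 1.0
    p_hi: float = 99.0
    n_peaks: int = 3
    peak_window_half_width: float = 8.0
    interpolation_factor: float = 1.0

    def validate(self) -> None:
        if not self.inputs:
            raise PipelineError("config lists no inputs")
        if not self.steps:
            raise PipelineError("config lists no steps")
        unknown = set(self.steps) - set(_STEP_ORDER)
        if unknown:
            raise PipelineError(f"unknown steps: {sorted(unknown)}")
        if self.threshold_sigmas <= 0:
            raise PipelineError("threshold_sigmas must be > 0")
        if self.w_lo is not None and self.w_hi is not None and not self.w_lo < self.w_hi:
            raise PipelineError("require w_lo < w_hi")
        if not 0 <= self.p_lo < self.p_hi <= 100:
            raise PipelineError("require 0 <= p_lo < p_hi <= 100")
        if self.format not in ("tiff", "hdf5"):
            raise PipelineError(f"unknown format {self.format!r}")
        if self.interpolation_factor <= 0:
            raise PipelineError("interpolation_factor must be > 0")

    @property
    def ordered_steps(self) -> list[str]:
        return [s for s in _STEP_ORDER if s in self.steps]

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        d.update({k: v for k, v in overrides.items() if v is not None})
        try:
            return cls(**d)
        except TypeError as e:
            raise PipelineError(f"invalid config: {e}") from e


def _load_input(token: str, config: PipelineConfig) -> HyperStack:
    if token == "phantom:default":
        stack, _ = default_macrophage_phantom(seed=config.seed)
        return stack
    return read_stack(token)


def _ext(config: PipelineConfig) -> str:
    return ".h5" if config.format == "hdf5" else ".tif"


def _process_one(token: str, config: PipelineConfig, out: Path) -> dict:
    entry: dict = {"input": token, "outputs": [], "steps": {}, "timings_s": {}}
    stack = _load_input(token, config)
    stem = Path(token.replace(":", "_")).stem
    suffix = _ext(config)

    for step in config.ordered_steps:
        t0 = time.perf_counter()
        if step == "cosmic_ray":
            stack, report = remove_cosmic_rays(stack, config.threshold_sigmas)
            p = report.to_csv(out / f"{stem}_cosmic_rays.csv", stack.wavenumbers)
            entry["outputs"].append(str(p))
            entry["steps"]["cosmic_ray"] = {
                "n_flagged": report.n_flagged,
                "threshold_sigmas": report.threshold_sigmas,
                "flagged_fraction": report.n_flagged / stack.data.size,
            }
        elif step == "zlsr":
            vstack, slopes, _zs = zlsr_transform(stack)
            img = zlsr_image(vstack, config.w_lo, config.w_hi)
            p1 = write_stack(
                HyperStack(vstack.data, vstack.wavenumbers), out / f"{stem}_zlsr{suffix}",
                config.format)
            p2 = save_png(normalize_contrast(img, config.p_lo, config.p_hi),
                          out / f"{stem}_zlsr.png")
            slope_img = save_png(normalize_contrast(
                PlaneImage(data=slopes.data, label="regression slopes"),
                config.p_lo, config.p_hi), out / f"{stem}_slopes.png")
            entry["outputs"] += [str(p1), str(p2), str(slope_img)]
            entry["steps"]["zlsr"] = {"window_cm1": [config.w_lo, config.w_hi]}
            entry["_zlsr_stack"] = vstack
        elif step == "svd":
            decomp = decompose(build_matrix(stack))
            ranking = rank_components(decomp)
            chosen = (config.components if config.components
                      else ranking.top(config.top_k))
            recon = reconstruct(decomp, chosen)
            p1 = write_stack(recon, out / f"{stem}_svd_recon{suffix}", config.format)
            p2 = eigenspectra_to_csv(decomp, out / f"{stem}_eigenspectra.csv", chosen)
            entry["outputs"] += [str(p1), str(p2)]
            entry["steps"]["svd"] = {
                "components": [int(c) for c in chosen],
                "top_scores": [float(s) for s in
                               ranking.scores[ranking.order[:config.top_k]]],
            }
        elif step == "render":
            source = entry.pop("_zlsr_stack", stack)
            spec = mean_spectrum(HyperStack(np.asarray(source.data),
                                            source.wavenumbers))
            peaks = find_top_peaks(spec, n_peaks=config.n_peaks)
            render_entry = {"peaks_cm1": list(peaks), "complete": peaks.complete}
            if len(peaks) >= 3:
                rgb = colorize(source, list(peaks)[:3],
                               window_half_width=config.peak_window_half_width,
                               p_lo=config.p_lo, p_hi=config.p_hi)
                if config.interpolation_factor != 1.0:
                    from .render import interpolate_bicubic
                    rgb = interpolate_bicubic(rgb, config.interpolation_factor)
                p1 = save_png(rgb, out / f"{stem}_rgb.png")
                p2 = write_color_report(rgb, out / f"{stem}_rgb_peaks.json")
                entry["outputs"] += [str(p1), str(p2)]
            else:
                logger.warning("%s: only %d peaks found; skipping false color",
                               token, len(peaks))
            entry["steps"]["render"] = render_entry
        entry["timings_s"][step] = round(time.perf_counter() - t0, 6)
    entry.pop("_zlsr_stack", None)
    return entry


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured steps over every input; return (and write) the manifest."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    fh = logging.FileHandler(out / "run.log")
    logger.addHandler(fh)
    try:
        manifest: dict = {
            "package": "ramanzlsr",
            "version": _package_version(),
            "numpy_version": np.__version__,
            "seed": config.seed,
            "config": {k: v for k, v in asdict(config).items()},
            "files": [],
            "errors": [],
        }
        for token in config.inputs:
            logger.info("processing %s", token)
            try:
                manifest["files"].append(_process_one(token, config, out))
            except Exception as e:  # record and continue the batch
                logger.error("failed on %s: %s", token, e)
                manifest["errors"].append({"input": token, "error": str(e)})
        manifest["n_processed"] = len(manifest["files"])
        manifest["n_failed"] = len(manifest["errors"])
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest
    finally:
        logger.removeHandler(fh)
        fh.close()


def _package_version() -> str:
    from . import __version__
    return __version__
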