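"""Synthetic SMLM image stacks with ground truth.

Three benchmark regimes, distinguished by background only:

* ``high_snr`` — mean 500 signal photons/emitter, uniform background of
  10 photons/pixel;
* ``low_snr``  — same signal, uniform background of 50 photons/pixel;
* ``low_snr_gb`` — low-SNR plus an inhomogeneous Gaussian-profile background
  peaking at 50 photons at the frame centre, FWHM half the frame size (the
  kind of vignetting wide-field/TIRF illumination produces).

Per frame: an emitter count is drawn from a Poisson law; positions are uniform
inside an edge margin of 3·σ_PSF; each emitter's photon count is Poisson with
the configured mean, and every photon lands at a position drawn from the 2D
Gaussian PSF around the true centre and is binned to its nearest pixel.  The
expected background is added, shot noise is imposed on the total, and the
photoelectron image is turned back into camera intensities via the effective
gain and bias offset (no stochastic EM amplification, so the realised counts
are exactly Poisson).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .camera import CameraOpticsConfig, psf_sigma_px

__all__ = [
    "SimulationConfig",
    "GroundTruthRecord",
    "simulate_frame",
    "simulate_dataset",
    "expected_background",
    "regime_config",
    "TRUTH_COLUMNS",
]

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # ≈ 2.355
TRUTH_COLUMNS = ["frame", "x_px", "y_px", "x_nm", "y_nm", "photons"]


@dataclass(frozen=True)
class SimulationConfig:
    frame_size: int = 256
    n_frames: int = 100
    emitters_per_frame_mean: float = 40.0  # benchmark scale: 200,000 emitters in ~5,000 frames
    mean_photons: float = 500.0
    uniform_background: float = 10.0  # photons/pixel
    gaussian_bg_peak: float = 0.0     # photons at frame centre; 0 disables
    gaussian_bg_fwhm_frac: float = 0.5
    bias_offset: float = 100.0
    gain: float = 10.0
    pixel_size_nm: float = 64.0
    wavelength_nm: float = 665.0
    numerical_aperture: float = 1.49
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_size < 32:
            raise ValueError("frame_size must be >= 32")
        for name in ("emitters_per_frame_mean", "mean_photons",
                     "uniform_background", "gaussian_bg_peak"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def camera(self) -> CameraOpticsConfig:
        return CameraOpticsConfig(
            bias_offset=self.bias_offset, effective_gain=self.gain,
            pixel_size_nm=self.pixel_size_nm,
            numerical_aperture=self.numerical_aperture,
            emission_wavelength_nm=self.wavelength_nm)

    @property
    def psf_sigma_px(self) -> float:
        return psf_sigma_px(self.camera())


@dataclass(frozen=True)
class GroundTruthRecord:
    frame_index: int
    x_px: float  # column coordinate, pixel centres at integers
    y_px: float  # row coordinate
    photons_emitted: int

    def nm(self, pixel_nm: float) -> tuple[float, float]:
        return self.x_px * pixel_nm, self.y_px * pixel_nm


_REGIMES = {
    "high_snr": dict(uniform_background=10.0, gaussian_bg_peak=0.0),
    "low_snr": dict(uniform_background=50.0, gaussian_bg_peak=0.0),
    "low_snr_gb": dict(uniform_background=50.0, gaussian_bg_peak=50.0),
}


def regime_config(regime: str, **overrides) -> SimulationConfig:
    """A :class:`SimulationConfig` for one of the named benchmark regimes."""
    if regime not in _REGIMES:
        raise ValueError(f"unknown regime {regime!r}; choose from {sorted(_REGIMES)}")
    return SimulationConfig(**{**_REGIMES[regime], **overrides})


def expected_background(cfg: SimulationConfig) -> np.ndarray:
    """Noise-free expected background image, in photons/pixel."""
    n = cfg.frame_size
    bg = np.full((n, n), float(cfg.uniform_background))
    if cfg.gaussian_bg_peak > 0:
        c = (n - 1) / 2.0
        sigma = cfg.gaussian_bg_fwhm_frac * n / FWHM_TO_SIGMA
        yy, xx = np.mgrid[0:n, 0:n]
        bg += cfg.gaussian_bg_peak * np.exp(
            -((xx - c) ** 2 + (yy - c) ** 2) / (2.0 * sigma**2))
    return bg


def simulate_frame(cfg: SimulationConfig, frame_index: int,
                   rng: np.random.Generator
                   ) -> tuple[np.ndarray, list[GroundTruthRecord]]:
    """One raw intensity frame (uint16) and its ground-truth emitters."""
    n = cfg.frame_size
    sigma = cfg.psf_sigma_px
    margin = 3.0 * sigma
    counts = np.zeros((n, n), dtype=np.float64)
    truth: list[GroundTruthRecord] = []

    n_emitters = rng.poisson(cfg.emitters_per_frame_mean)
    for _ in range(n_emitters):
        y0, x0 = rng.uniform(margin, n - 1 - margin, size=2)
        k = int(rng.poisson(cfg.mean_photons))
        if k > 0:
            pos = rng.normal(loc=(y0, x0), scale=sigma, size=(k, 2))
            rows = np.rint(pos[:, 0]).astype(int)
            cols = np.rint(pos[:, 1]).astype(int)
            keep = (rows >= 0) & (rows < n) & (cols >= 0) & (cols < n)
            np.add.at(counts, (rows[keep], cols[keep]), 1.0)
        truth.append(GroundTruthRecord(frame_index, float(x0), float(y0), k))

    expected = counts + expected_background(cfg)
    photoelectrons = rng.poisson(expected).astype(np.float64)
    raw = np.rint(photoelectrons * cfg.gain + cfg.bias_offset)
    return np.clip(raw, 0, 65535).astype(np.uint16), truth


def truth_to_frame(records: list[GroundTruthRecord], pixel_nm: float) -> pd.DataFrame:
    rows = [(r.frame_index, r.x_px, r.y_px, r.x_px * pixel_nm,
             r.y_px * pixel_nm, r.photons_emitted) for r in records]
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def simulate_dataset(cfg: SimulationConfig, out_dir: str | Path,
                     stack_name: str = "stack.tif") -> tuple[Path, Path]:
    """Write a multi-page 16-bit TIFF, a ground-truth CSV and a YAML manifest.

    Returns the TIFF path and the truth CSV path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    all_truth: list[GroundTruthRecord] = []
    tiff_path = out / stack_name
    with tifffile.TiffWriter(tiff_path) as tif:
        for i in range(cfg.n_frames):
            frame, truth = simulate_frame(cfg, i, rng)
            tif.write(frame, contiguous=True)
            all_truth.extend(truth)
    truth_path = out / "truth.csv"
    truth_to_frame(all_truth, cfg.pixel_size_nm).to_csv(truth_path, index=False)
    manifest = {"config": asdict(cfg), "n_emitters": len(all_truth),
                "stack": tiff_path.name, "truth": truth_path.name}
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    return tiff_path, truth_path
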