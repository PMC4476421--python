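"""Camera and optics model: photoelectron conversion and shot-noise constants.

An EMCCD camera reports intensity counts ``I = N_e * G_eff + I_bias``; shot-noise
analysis requires the photoelectron count ``N_e`` back.  Electron multiplication
inflates the Poisson noise by the excess noise factor ``F`` (√2 at high gain), so
the noise in a pixel with ``N_bg`` background photoelectrons is ``F·√N_bg``.

The diffraction-limited optics enter through two derived lengths, both expressed
in camera pixels: the Rayleigh (Airy) radius ``0.61·λ/NA`` and the standard
deviation of the Gaussian approximation to the point spread function,
``0.21·λ/NA``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CameraOpticsConfig",
    "PhotonFrame",
    "to_photoelectrons",
    "noise_sigma",
    "pixel_snr",
    "airy_radius_px",
    "psf_sigma_px",
]

EMCCD_EXCESS_NOISE = math.sqrt(2.0)

# Gaussian approximation of an Airy PSF: sigma ~= 0.21 * lambda / NA.
_PSF_SIGMA_COEF = 0.21
_RAYLEIGH_COEF = 0.61


class ConfigurationError(ValueError):
    """Invalid camera/optics configuration."""


@dataclass(frozen=True)
class CameraOpticsConfig:
    """Instrument constants for one acquisition.

    Parameters
    ----------
    bias_offset
        Camera bias in intensity counts (added to every pixel reading).
    effective_gain
        Intensity counts per photoelectron (EM gain × A/D conversion), > 0.
    excess_noise_factor
        Multiplicative noise inflation of the amplifier; √2 for an EMCCD at
        high gain, 1.0 for a noiseless amplifier. Must be ≥ 1.
    pixel_size_nm
        Physical pixel pitch of the camera sensor, in nm.
    magnification
        Total optical magnification (≥ 1); the sample-plane pixel size is
        ``pixel_size_nm / magnification``.
    numerical_aperture
        NA of the objective, in (0, 1.7].
    emission_wavelength_nm
        Peak emission wavelength, in [300, 1000] nm.
    """

    bias_offset: float = 100.0
    effective_gain: float = 10.0
    excess_noise_factor: float = EMCCD_EXCESS_NOISE
    pixel_size_nm: float = 64.0
    magnification: float = 1.0
    numerical_aperture: float = 1.49
    emission_wavelength_nm: float = 665.0

    def __post_init__(self) -> None:
        if self.effective_gain <= 0:
            raise ConfigurationError("effective_gain must be > 0")
        if self.pixel_size_nm <= 0:
            raise ConfigurationError("pixel_size_nm must be > 0")
        if self.magnification < 1:
            raise ConfigurationError("magnification must be >= 1")
        if not (0 < self.numerical_aperture <= 1.7):
            raise ConfigurationError("numerical_aperture must be in (0, 1.7]")
        if not (300 <= self.emission_wavelength_nm <= 1000):
            raise ConfigurationError("emission_wavelength_nm must be in [300, 1000]")
        if self.excess_noise_factor < 1:
            raise ConfigurationError("excess_noise_factor must be >= 1")

    @property
    def sample_pixel_nm(self) -> float:
        """Pixel size projected to the sample plane, nm."""
        return self.pixel_size_nm / self.magnification


@dataclass
class PhotonFrame:
    """One acquisition frame converted to photoelectron counts."""

    frame_index: int
    pixels: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("PhotonFrame pixels must be 2D")
        if np.any(self.pixels < 0):
            raise ValueError("photoelectron counts must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def to_photoelectrons(raw_frame: np.ndarray, config: CameraOpticsConfig,
                      frame_index: int = 0) -> PhotonFrame:
    """Convert raw camera intensities to photoelectrons.

    Each pixel becomes ``(I - bias_offset) / effective_gain``, clamped below at
    zero: Poisson counts cannot be negative, and readings below the bias are
    read-noise excursions carrying no photon information.
    """
    raw = np.asarray(raw_frame, dtype=np.float64)
    bad = ~np.isfinite(raw)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(f"non-finite intensity at pixel ({r}, {c})")
    electrons = (raw - config.bias_offset) / config.effective_gain
    np.clip(electrons, 0.0, None, out=electrons)
    return PhotonFrame(frame_index=frame_index, pixels=electrons)


def noise_sigma(background_electrons, config: CameraOpticsConfig):
    """Shot-noise standard deviation ``F·√N_bg`` for a background level.

    Accepts scalars or arrays; zero exactly when the background is zero.
    """
    n_bg = np.asarray(background_electrons, dtype=np.float64)
    if np.any(n_bg < 0):
        raise ValueError("background_electrons must be >= 0")
    out = config.excess_noise_factor * np.sqrt(n_bg)
    return float(out) if np.isscalar(background_electrons) else out


def pixel_snr(signal_electrons, background_electrons, config: CameraOpticsConfig):
    """Per-pixel signal-to-noise ratio ``S / (F·√N_bg)``.

    The background must be strictly positive; callers use the floored
    background map (see :mod:`snsmil.background`) to guarantee this.
    """
    n_bg = np.asarray(background_electrons, dtype=np.float64)
    if np.any(n_bg <= 0):
        raise ZeroDivisionError(
            "pixel SNR undefined for zero background; apply a background floor")
    out = np.asarray(signal_electrons, dtype=np.float64) / (
        config.excess_noise_factor * np.sqrt(n_bg))
    return float(out) if np.isscalar(signal_electrons) else out


def airy_radius_px(config: CameraOpticsConfig) -> float:
    """Rayleigh radius ``0.61·λ/NA`` expressed in camera pixels."""
    return (_RAYLEIGH_COEF * config.emission_wavelength_nm
            / config.numerical_aperture / config.sample_pixel_nm)


def psf_sigma_px(config: CameraOpticsConfig) -> float:
    """Theoretical Gaussian-PSF standard deviation ``0.21·λ/NA`` in pixels."""
    return (_PSF_SIGMA_COEF * config.emission_wavelength_nm
            / config.numerical_aperture / config.sample_pixel_nm)
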