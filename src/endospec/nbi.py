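"""Band selection and narrow-band-imaging color reproduction.

Narrow-band endoscopy illuminates at ~415 nm and ~540 nm, the Soret and Q
absorption peaks of hemoglobin, so superficial capillaries (reached by the
415 nm light) appear brown and deeper submucosal vessels (reached by the
540 nm light) appear green.  Given a reconstructed reflectance cube this
module extracts the two bands — either as exact slices or as Gaussian-
weighted averages approximating a physical filter — and maps them to display
channels in the conventional NBI arrangement: the 415 nm image drives the
blue and green display channels, the 540 nm image drives red.

Vessel conspicuity is scored with Weber contrast,
``(background - vessel) / background``, per channel and on Rec.709 luminance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import _GAMMA_MODELS
from .spectral import RGBImage, SpectralImageCube

__all__ = [
    "NBIBandSpec",
    "ContrastReport",
    "extract_band",
    "render_nbi",
    "vessel_contrast",
    "luminance",
]

LUMA_WEIGHTS = np.array([0.2126, 0.7152, 0.0722])  # Rec.709


@dataclass(frozen=True)
class NBIBandSpec:
    """Band centers, band shape and display mapping for the NBI render.

    ``channel_map`` assigns one band center to each display channel (R, G, B
    order).  ``normalization`` is ``"minmax"`` (joint min-max over all three
    channels, preserving hue) or ``"fixed"`` (use ``fixed_range`` as the
    display scale, for comparability across images).
    """

    centers: tuple = (415.0, 540.0)
    band_shape: str = "gaussian"          # 'delta' | 'gaussian'
    fwhm: float = 30.0                    # nm, per band (gaussian shape)
    channel_map: tuple = (540.0, 415.0, 415.0)  # band center per R, G, B
    display_gamma: str = "srgb"
    normalization: str = "minmax"         # 'minmax' | 'fixed'
    fixed_range: tuple = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.band_shape not in ("delta", "gaussian"):
            raise ValueError(f"unknown band shape {self.band_shape!r}")
        if self.band_shape == "gaussian" and self.fwhm <= 0:
            raise ValueError("fwhm must be positive for gaussian bands")
        if len(self.channel_map) != 3:
            raise ValueError("channel_map must give one band per R, G, B channel")
        if any(c not in self.centers for c in self.channel_map):
            raise ValueError("channel_map entries must be among the band centers")
        if self.normalization not in ("minmax", "fixed"):
            raise ValueError(f"unknown normalization {self.normalization!r}")


def extract_band(
    cube: SpectralImageCube, center: float, shape: str = "gaussian", fwhm: float = 30.0
) -> np.ndarray:
    """Single-channel band image at ``center`` nm.

    ``delta`` returns the nearest band slice; ``gaussian`` the normalized
    Gaussian-weighted average over bands (weights sum to exactly 1).
    """
    grid = cube.grid
    if not (grid.start <= center <= grid.stop):
        raise ValueError(f"band center {center} nm outside grid range")
    if shape == "delta":
        return cube.values[:, :, grid.index_of(center)].astype(float)
    if shape != "gaussian":
        raise ValueError(f"unknown band shape {shape!r}")
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    w = np.exp(-0.5 * ((grid.wavelengths - center) / sigma) ** 2)
    w /= w.sum()
    return cube.values.astype(float) @ w


def render_nbi(cube: SpectralImageCube, spec: NBIBandSpec = NBIBandSpec()) -> RGBImage:
    """Color-reproduce the cube as a narrow-band image.

    Band images are extracted per ``spec``, assigned to display channels,
    normalized to [0, 1] (jointly across channels so hue is preserved), and
    display-gamma encoded.
    """
    bands = {
        c: extract_band(cube, c, spec.band_shape, spec.fwhm) for c in set(spec.channel_map)
    }
    img = np.stack([bands[c] for c in spec.channel_map], axis=-1)
    if spec.normalization == "minmax":
        lo, hi = float(img.min()), float(img.max())
        if hi - lo < 1e-12:
            img = np.zeros_like(img)
        else:
            img = (img - lo) / (hi - lo)
    else:
        lo, hi = spec.fixed_range
        img = np.clip((img - lo) / (hi - lo), 0.0, 1.0)
    _, encode = _GAMMA_MODELS[spec.display_gamma]
    return RGBImage(encode(img), encoding="encoded")


def luminance(img: RGBImage) -> np.ndarray:
    """Rec.709 luma of the image values as given (no re-linearization)."""
    return img.values @ LUMA_WEIGHTS


@dataclass
class ContrastReport:
    """Weber contrast (background − vessel)/background of a vessel region."""

    vessel_mean: np.ndarray      # (3,) per channel
    background_mean: np.ndarray  # (3,)
    weber_per_channel: np.ndarray  # (3,)
    vessel_luma: float
    background_luma: float
    weber_luminance: float


def vessel_contrast(
    img: RGBImage, vessel_mask: np.ndarray, background_mask: np.ndarray
) -> ContrastReport:
    vessel_mask = np.asarray(vessel_mask, dtype=bool)
    background_mask = np.asarray(background_mask, dtype=bool)
    if not vessel_mask.any() or not background_mask.any():
        raise ValueError("masks must be non-empty")
    if (vessel_mask & background_mask).any():
        raise ValueError("vessel and background masks overlap")
    v = img.values[vessel_mask].mean(axis=0)
    b = img.values[background_mask].mean(axis=0)
    luma = luminance(img)
    v_l = float(luma[vessel_mask].mean())
    b_l = float(luma[background_mask].mean())
    if b_l <= 0 or np.any(b <= 0):
        raise ValueError("Weber contrast undefined: background mean is not positive")
    return ContrastReport(
        vessel_mean=v,
        background_mean=b,
        weber_per_channel=(b - v) / b,
        vessel_luma=v_l,
        background_luma=b_l,
        weber_luminance=(b_l - v_l) / b_l,
    )
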