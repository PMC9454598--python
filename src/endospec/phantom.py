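"""Synthetic data: color-checker targets, a trichromatic camera, and
two-layer mucosa/vessel phantoms.

Nothing here claims physiological accuracy — the module exists so the
calibration, reconstruction and narrow-band rendering code can be exercised
end-to-end without external data.  Three generators are provided:

* :func:`make_checker` — n smooth random reflectance spectra standing in for
  a 24-patch color-checker chart (one near-flat gray patch included).
* :class:`CameraModel` / :func:`render_rgb` — a trichromatic camera with
  Gaussian spectral sensitivities (centers 460/545/610 nm, FWHM 60 nm), a
  flat illuminant and sRGB display gamma; a perfect reflector maps to
  (1, 1, 1) before gamma by construction.
* :func:`make_phantom` — a flat mucosa background crossed by vessel
  polylines.  Vessel reflectance follows a single-pass Beer–Lambert
  attenuation ``background * exp(-c * eps(lambda) * w_depth(lambda))`` where
  ``eps`` is a hemoglobin-like absorber (Gaussian peaks at 415/540/577 nm,
  Soret:Q amplitude ratio 10:1) and ``w_depth`` is a logistic spectral
  weight: shallow vessels are reached mostly by short wavelengths, deep
  vessels mostly by long ones.  This reproduces the qualitative depth
  behaviour of narrow-band imaging (shallow vessels darkest at 415 nm, deep
  vessels darkest at 540 nm) without radiative transfer.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import CalibrationTarget, _GAMMA_MODELS
from .spectral import RGBImage, SpectralImageCube, Spectrum, WavelengthGrid, make_default_grid

__all__ = [
    "CameraModel",
    "AbsorberModel",
    "Vessel",
    "TissuePhantomSpec",
    "PhantomScene",
    "default_camera",
    "absorption_curve",
    "depth_weight",
    "make_checker",
    "make_checker_rank",
    "render_rgb",
    "make_phantom",
    "make_random_phantom_spec",
    "make_calibration_fixture",
]


def _gaussian(x: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - center) / sigma) ** 2)


_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


# ---------------------------------------------------------------------------
# camera

@dataclass
class CameraModel:
    """Trichromatic camera: channel = exposure * <sensitivity*illuminant, reflectance>,
    normalized so a perfect reflector maps to 1, then gamma-encoded."""

    grid: WavelengthGrid
    sensitivities: np.ndarray  # (3, n_bands), R/G/B rows, non-negative
    illuminant: np.ndarray     # (n_bands,), non-negative
    gamma: str = "srgb"
    exposure: float = 1.0

    def __post_init__(self) -> None:
        self.sensitivities = np.asarray(self.sensitivities, dtype=float)
        self.illuminant = np.asarray(self.illuminant, dtype=float)
        if self.sensitivities.shape != (3, self.grid.count):
            raise ValueError("sensitivities must be (3, n_bands)")
        if self.illuminant.shape != (self.grid.count,):
            raise ValueError("illuminant length mismatch")
        if np.any(self.sensitivities < 0) or np.any(self.illuminant < 0):
            raise ValueError("sensitivities and illuminant must be non-negative")
        if np.any(self.sensitivities.max(axis=1) <= 0):
            raise ValueError("each channel needs a strictly positive sensitivity")
        if self.exposure <= 0:
            raise ValueError("exposure must be positive")

    @property
    def weights(self) -> np.ndarray:
        """(3, n_bands) response weights, each row summing to 1."""
        w = self.sensitivities * self.illuminant
        return w / w.sum(axis=1, keepdims=True)


def default_camera(grid: WavelengthGrid | None = None) -> CameraModel:
    """Gaussian R/G/B sensitivities at 610/545/460 nm (FWHM 60), flat illuminant."""
    grid = grid or make_default_grid()
    wl = grid.wavelengths
    sigma = 60.0 * _FWHM_TO_SIGMA
    sens = np.stack(
        [_gaussian(wl, 610.0, sigma), _gaussian(wl, 545.0, sigma), _gaussian(wl, 460.0, sigma)]
    )
    return CameraModel(grid, sens, np.ones(grid.count))


def render_rgb(camera: CameraModel, scene):
    """Render a Spectrum (-> encoded RGB triplet) or a cube (-> RGBImage)."""
    _, encode = _GAMMA_MODELS[camera.gamma]
    w = camera.weights
    if isinstance(scene, Spectrum):
        if scene.grid != camera.grid:
            raise ValueError("spectrum grid does not match camera grid")
        linear = camera.exposure * (w @ scene.values)
        return encode(np.clip(linear, 0.0, 1.0))
    if isinstance(scene, SpectralImageCube):
        if scene.grid != camera.grid:
            raise ValueError("cube grid does not match camera grid")
        linear = camera.exposure * np.einsum("hwb,cb->hwc", scene.values, w)
        return RGBImage(encode(np.clip(linear, 0.0, 1.0)), encoding="encoded")
    raise TypeError("scene must be a Spectrum or SpectralImageCube")


# ---------------------------------------------------------------------------
# absorber (hemoglobin-like)

@dataclass
class AbsorberModel:
    """Analytic absorber: sum of Gaussian peaks (defaults: Soret band at
    415 nm plus Q-bands at 540/577 nm, amplitude ratio 10:1)."""

    peak_centers: tuple = (415.0, 540.0, 577.0)
    peak_widths: tuple = (13.0, 15.0, 10.0)   # Gaussian sigma, nm
    peak_amplitudes: tuple = (10.0, 1.0, 0.9)

    def __post_init__(self) -> None:
        if not (len(self.peak_centers) == len(self.peak_widths) == len(self.peak_amplitudes)):
            raise ValueError("peak parameter lengths differ")
        if any(w <= 0 for w in self.peak_widths) or any(a < 0 for a in self.peak_amplitudes):
            raise ValueError("widths must be positive and amplitudes non-negative")


def absorption_curve(model: AbsorberModel, grid: WavelengthGrid | None = None) -> np.ndarray:
    """Absorption coefficient curve eps(lambda) on the grid (unitless scale)."""
    grid = grid or make_default_grid()
    wl = grid.wavelengths
    eps = np.zeros(grid.count)
    for c, s, a in zip(model.peak_centers, model.peak_widths, model.peak_amplitudes):
        eps += a * _gaussian(wl, c, s)
    return eps


def depth_weight(depth_class: str, grid: WavelengthGrid | None = None) -> np.ndarray:
    """Spectral weight of the light path reaching a vessel at a given depth.

    Shallow vessels sit in the superficial mucosa reached by short
    wavelengths; deep (submucosal) vessels are reached only by the longer,
    deeper-penetrating wavelengths.  Implemented as logistic ramps in
    wavelength.
    """
    grid = grid or make_default_grid()
    wl = grid.wavelengths
    if depth_class == "shallow":
        return 1.0 - 1.0 / (1.0 + np.exp(-(wl - 520.0) / 30.0))
    if depth_class == "deep":
        return 1.0 / (1.0 + np.exp(-(wl - 480.0) / 20.0))
    raise ValueError(f"unknown depth class {depth_class!r}")


# ---------------------------------------------------------------------------
# checker generation

def _smooth_random(rng: np.random.Generator, t: np.ndarray, n_harmonics: int = 3) -> np.ndarray:
    z = rng.normal(0.0, 0.8) * np.ones_like(t)
    for m in range(1, n_harmonics + 1):
        z = z + rng.normal(0.0, 1.2 / m) * np.cos(np.pi * m * t + rng.uniform(0, 2 * np.pi))
    return z


def make_checker(n: int = 24, seed: int = 0, grid: WavelengthGrid | None = None) -> list[Spectrum]:
    """n smooth random reflectance spectra in [0.02, 0.95].

    Each spectrum is a low-order random Fourier series squashed through a
    logistic into the valid reflectance range; patch 0 is a near-flat gray.
    Fixed seed gives bit-identical output.
    """
    if n < 4:
        raise ValueError("need at least 4 patches")
    grid = grid or make_default_grid()
    rng = np.random.default_rng(seed)
    t = (grid.wavelengths - grid.start) / (grid.stop - grid.start)
    spectra = [Spectrum(grid, np.full(grid.count, 0.45) + 0.01 * t)]  # gray anchor
    for _ in range(n - 1):
        z = _smooth_random(rng, t)
        vals = 0.02 + 0.93 / (1.0 + np.exp(-z))
        spectra.append(Spectrum(grid, vals))
    return spectra


def make_checker_rank(
    n: int = 24, k: int = 3, seed: int = 0, grid: WavelengthGrid | None = None
) -> list[Spectrum]:
    """n spectra lying exactly in a k-dimensional affine span of smooth curves.

    Used for exact-recovery tests: with k <= 3 distinct camera responses the
    calibration regression can recover every training spectrum to numerical
    precision.
    """
    grid = grid or make_default_grid()
    wl = grid.wavelengths
    rng = np.random.default_rng(seed)
    centers = (450.0, 550.0, 650.0, 500.0, 600.0)[:k]
    curves = np.stack([_gaussian(wl, c, 80.0) for c in centers])
    q, _ = np.linalg.qr(curves.T)  # orthonormal columns
    curves = q.T  # (k, n_bands), peak magnitude ~0.1
    mean = 0.5 * np.ones(grid.count)
    coeffs = rng.uniform(-1.0, 1.0, size=(n, k))
    vals = mean + coeffs @ curves
    vals = np.clip(vals, 0.02, 0.98)  # stays clip-free for the default curves
    return [Spectrum(grid, v) for v in vals]


# ---------------------------------------------------------------------------
# tissue phantom

@dataclass
class Vessel:
    points: np.ndarray        # (m, 2) polyline control points, (row, col) px
    width: float              # px
    depth_class: str          # 'shallow' | 'deep'
    concentration: float = 0.5  # concentration * pathlength, unitless

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2 or len(self.points) < 2:
            raise ValueError("polyline needs at least two (row, col) points")
        if self.depth_class not in ("shallow", "deep"):
            raise ValueError(f"unknown depth class {self.depth_class!r}")
        if self.concentration <= 0 or self.width <= 0:
            raise ValueError("width and concentration must be positive")


@dataclass
class TissuePhantomSpec:
    size: tuple = (64, 64)           # (rows, cols)
    vessels: list = field(default_factory=list)
    absorber: AbsorberModel = field(default_factory=AbsorberModel)
    background_seed: int = 0
    grid: WavelengthGrid = field(default_factory=make_default_grid)


@dataclass
class PhantomScene:
    truth_cube: SpectralImageCube
    vessel_masks: list[np.ndarray]   # boolean, pairwise disjoint
    labels: list[str]                # depth class per vessel
    background: Spectrum


def _background_spectrum(grid: WavelengthGrid, seed: int) -> Spectrum:
    """Smooth mucosa-like background: bright, rising toward the red."""
    rng = np.random.default_rng(seed)
    t = (grid.wavelengths - grid.start) / (grid.stop - grid.start)
    base = 0.45 + 0.35 * t  # mucosa reflects more at long wavelengths
    wiggle = 0.05 * np.cos(np.pi * t * rng.uniform(1.0, 2.0) + rng.uniform(0, 2 * np.pi))
    return Spectrum(grid, np.clip(base + wiggle, 0.05, 0.95))


def _polyline_mask(shape: tuple, points: np.ndarray, width: float) -> np.ndarray:
    """Pixels whose center lies within width/2 of the polyline (no AA)."""
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    p = np.stack([rows, cols], axis=-1).astype(float)  # (H, W, 2)
    dmin = np.full(shape, np.inf)
    for a, b in zip(points[:-1], points[1:]):
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0:
            t = np.zeros(shape)
        else:
            t = np.clip(((p - a) @ ab) / denom, 0.0, 1.0)
        closest = a + t[..., None] * ab
        d = np.linalg.norm(p - closest, axis=-1)
        dmin = np.minimum(dmin, d)
    return dmin <= width / 2.0


def make_phantom(spec: TissuePhantomSpec) -> PhantomScene:
    """Rasterize the phantom: background everywhere, Beer–Lambert-attenuated
    reflectance under each vessel.  Overlaps are resolved in favour of the
    shallower vessel; returned masks are pairwise disjoint."""
    h, w = spec.size
    bg = _background_spectrum(spec.grid, spec.background_seed)
    cube = np.broadcast_to(bg.values.astype(np.float32), (h, w, spec.grid.count)).copy()
    eps = absorption_curve(spec.absorber, spec.grid)

    for v in spec.vessels:
        if np.any(v.points < 0) or np.any(v.points[:, 0] > h - 1) or np.any(v.points[:, 1] > w - 1):
            raise ValueError("vessel polyline outside image bounds")

    # shallow vessels claim contested pixels first
    order = sorted(range(len(spec.vessels)),
                   key=lambda i: 0 if spec.vessels[i].depth_class == "shallow" else 1)
    claimed = np.zeros((h, w), dtype=bool)
    masks: list[np.ndarray] = [None] * len(spec.vessels)
    for i in order:
        v = spec.vessels[i]
        m = _polyline_mask((h, w), v.points, v.width) & ~claimed
        claimed |= m
        masks[i] = m
        transmit = np.exp(-v.concentration * eps * depth_weight(v.depth_class, spec.grid))
        cube[m] = cube[m] * transmit.astype(np.float32)

    return PhantomScene(
        SpectralImageCube(spec.grid, cube),
        masks,
        [v.depth_class for v in spec.vessels],
        bg,
    )


def make_random_phantom_spec(
    seed: int,
    size: tuple = (64, 64),
    n_shallow: int = 1,
    n_deep: int = 1,
    concentration: float = 0.5,
    width: float = 4.0,
) -> TissuePhantomSpec:
    """Random vessel layout: each vessel is a 3-point polyline crossing the image."""
    rng = np.random.default_rng(seed)
    h, w = size
    vessels = []
    for depth in ["shallow"] * n_shallow + ["deep"] * n_deep:
        r0, r1 = rng.uniform(0.1 * h, 0.9 * h, size=2)
        rm = (r0 + r1) / 2 + rng.uniform(-0.15 * h, 0.15 * h)
        pts = np.array([[r0, 0.05 * w], [rm, 0.5 * w], [r1, 0.95 * w]])
        pts[:, 0] = np.clip(pts[:, 0], 0, h - 1)
        pts[:, 1] = np.clip(pts[:, 1], 0, w - 1)
        vessels.append(Vessel(pts, width=width, depth_class=depth, concentration=concentration))
    return TissuePhantomSpec(size=size, vessels=vessels, background_seed=seed)


# ---------------------------------------------------------------------------
# calibration fixture

def make_calibration_fixture(
    seed: int = 0,
    n: int = 24,
    camera: CameraModel | None = None,
    rank: int | None = None,
) -> CalibrationTarget:
    """24 synthetic checker spectra plus their camera-rendered encoded RGBs.

    With ``rank=k`` the spectra lie in an exact k-dimensional affine span
    (the exact-recovery configuration); otherwise they are free smooth
    spectra.
    """
    camera = camera or default_camera()
    if rank is None:
        spectra = make_checker(n, seed=seed, grid=camera.grid)
    else:
        spectra = make_checker_rank(n, k=rank, seed=seed, grid=camera.grid)
    rgbs = np.stack([render_rgb(camera, s) for s in spectra])
    labels = [f"patch{i:02d}" for i in range(n)]
    return CalibrationTarget(labels, spectra, rgbs)
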