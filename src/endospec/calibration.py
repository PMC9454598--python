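"""RGB→spectrum calibration from a 24-patch reflectance target.

The calibration follows the standard checker-based spectral-estimation
pipeline: display-encoded patch RGBs are linearized through the camera's
inverse transfer function (sRGB by default), expanded into polynomial
features of (R, G, B), and regressed — with optional ridge regularization —
onto the coefficients of a principal-component basis of the patch reflectance
spectra.  Reconstruction then maps any camera RGB to a full 401-band
reflectance spectrum:

    spectrum(rgb) = mean + B @ (M @ phi(linearize(rgb)))

where ``B`` holds the top-k orthonormal basis spectra (columns), ``phi`` the
monomial expansion, and ``M`` the fitted k×n_terms coefficient map.

Because only 24 patches constrain the fit, the spectral basis is truncated
(default: k = 10 or the smallest k explaining ≥ 99.9 % of variance,
whichever is smaller) and a small feature-scaled ridge penalty (default
1e-6) guards against the near-square design (20 degree-3 monomials vs 24
patches).  The regression features may optionally be formed in CIE XYZ
instead of linear RGB; any invertible linear recoding of the features leaves
the fitted predictions unchanged (up to ridge-scale effects), which the test
suite verifies.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from pathlib import Path

import numpy as np

from .spectral import (
    RGBImage,
    SpectralImageCube,
    Spectrum,
    WavelengthGrid,
    make_default_grid,
)

__all__ = [
    "CalibrationTarget",
    "ExpansionSpec",
    "SpectralBasis",
    "CalibrationModel",
    "srgb_encode",
    "srgb_decode",
    "linearize_rgb",
    "encode_rgb",
    "expand_features",
    "fit_basis",
    "fit_calibration",
    "reconstruct_spectrum",
    "reconstruct_cube",
    "save_model",
    "load_model",
]

MODEL_SCHEMA_VERSION = 1

# sRGB matrix: linear sRGB -> CIE XYZ (D65)
_RGB_TO_XYZ = np.array(
    [
        [0.4123908, 0.3575843, 0.1804808],
        [0.2126390, 0.7151687, 0.0721923],
        [0.0193308, 0.1191948, 0.9505322],
    ]
)


# ---------------------------------------------------------------------------
# transfer functions (gamma models)

def srgb_decode(v: np.ndarray) -> np.ndarray:
    """sRGB electro-optical transfer: encoded -> linear."""
    v = np.asarray(v, dtype=float)
    return np.where(v <= 0.04045, v / 12.92, ((v + 0.055) / 1.055) ** 2.4)


def srgb_encode(v: np.ndarray) -> np.ndarray:
    """Inverse of :func:`srgb_decode`: linear -> encoded."""
    v = np.asarray(v, dtype=float)
    v = np.clip(v, 0.0, None)
    return np.where(v <= 0.0031308, 12.92 * v, 1.055 * v ** (1 / 2.4) - 0.055)


_GAMMA_MODELS = {
    "srgb": (srgb_decode, srgb_encode),
    "gamma2.2": (lambda v: np.clip(v, 0, None) ** 2.2,
                 lambda v: np.clip(v, 0, None) ** (1 / 2.2)),
    "linear": (lambda v: np.asarray(v, dtype=float),
               lambda v: np.asarray(v, dtype=float)),
}


def linearize_rgb(img: RGBImage, gamma: str = "srgb") -> RGBImage:
    """Apply the inverse display transfer function channel-wise."""
    if img.encoding != "encoded":
        raise ValueError("input is already linear (double linearization)")
    decode, _ = _GAMMA_MODELS[gamma]
    return RGBImage(decode(img.values), encoding="linear")


def encode_rgb(img: RGBImage, gamma: str = "srgb") -> RGBImage:
    """Apply the forward display transfer function channel-wise."""
    if img.encoding != "linear":
        raise ValueError("input is already encoded")
    _, encode = _GAMMA_MODELS[gamma]
    return RGBImage(encode(img.values), encoding="encoded")


# ---------------------------------------------------------------------------
# polynomial feature expansion

@dataclass(frozen=True)
class ExpansionSpec:
    """Monomial expansion of linear (R, G, B) up to ``order``.

    The term list is deterministic: monomials R^a G^b B^c with a+b+c ≤ order,
    ordered by total degree, then by the itertools combination order within a
    degree (R before G before B).  Degree 0 (the constant 1) is always first.
    """

    order: int = 3

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("expansion order must be >= 1")

    @property
    def term_list(self) -> list[tuple[int, int, int]]:
        terms = []
        for deg in range(self.order + 1):
            for combo in combinations_with_replacement(range(3), deg):
                e = [0, 0, 0]
                for c in combo:
                    e[c] += 1
                terms.append(tuple(e))
        return terms

    @property
    def n_terms(self) -> int:
        return len(self.term_list)


def expand_features(rgb_linear: np.ndarray, spec: ExpansionSpec) -> np.ndarray:
    """Expand linear RGB triplet(s) into the monomial feature vector.

    Accepts shape (3,) or (..., 3); returns (n_terms,) or (..., n_terms).
    """
    arr = np.asarray(rgb_linear, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("RGB values must be finite")
    r, g, b = arr[..., 0], arr[..., 1], arr[..., 2]
    cols = [r ** a * g ** c * b ** d if (a, c, d) != (0, 0, 0)
            else np.ones_like(r)
            for (a, c, d) in spec.term_list]
    return np.stack(cols, axis=-1)


# ---------------------------------------------------------------------------
# spectral basis (PCA of patch spectra)

@dataclass
class SpectralBasis:
    """Mean spectrum plus k orthonormal principal components."""

    grid: WavelengthGrid
    mean: np.ndarray              # (n_bands,)
    components: np.ndarray        # (k, n_bands), rows orthonormal
    explained_variance: np.ndarray  # (k,) fractions, non-increasing

    @property
    def k(self) -> int:
        return self.components.shape[0]

    def project(self, values: np.ndarray) -> np.ndarray:
        """Spectrum values (..., n_bands) -> coefficients (..., k)."""
        # einsum keeps the summation order independent of array provenance,
        # so a serialized/reloaded model reproduces bit-identical output
        return np.einsum("...b,kb->...k", np.asarray(values) - self.mean,
                         self.components)

    def reconstruct(self, coeffs: np.ndarray) -> np.ndarray:
        """Coefficients (..., k) -> spectrum values (..., n_bands)."""
        return self.mean + np.einsum("...k,kb->...b", np.asarray(coeffs),
                                     self.components)


def fit_basis(spectra: list[Spectrum], k: int) -> SpectralBasis:
    """Top-k PCA of the spectra, ordered by decreasing explained variance."""
    if not spectra:
        raise ValueError("no spectra")
    grid = spectra[0].grid
    X = np.stack([s.values for s in spectra])
    n = X.shape[0]
    if k > n - 1:
        raise ValueError(f"k={k} too large for {n} spectra (max {n - 1})")
    mean = X.mean(axis=0)
    Xc = X - mean
    # SVD of the centered matrix; right singular vectors are the components
    _, sval, vt = np.linalg.svd(Xc, full_matrices=False)
    total = float(np.sum(sval ** 2))
    frac = sval ** 2 / total if total > 0 else np.zeros_like(sval)
    return SpectralBasis(grid, mean, vt[:k].copy(), frac[:k].copy())


# ---------------------------------------------------------------------------
# calibration target + model

@dataclass
class CalibrationTarget:
    """Color-checker measurements: per patch a reflectance spectrum and the
    camera's display-encoded RGB triplet."""

    labels: list[str]
    spectra: list[Spectrum]
    rgbs: np.ndarray  # (n_patches, 3) encoded values in [0, 1]

    def __post_init__(self) -> None:
        self.rgbs = np.asarray(self.rgbs, dtype=float)
        if not (len(self.labels) == len(self.spectra) == self.rgbs.shape[0]):
            raise ValueError("labels, spectra and rgbs must have equal length")
        grid = self.spectra[0].grid
        if any(s.grid != grid for s in self.spectra):
            raise ValueError("all patch spectra must share one grid")

    @property
    def n_patches(self) -> int:
        return len(self.labels)

    def deduplicated(self) -> "CalibrationTarget":
        """Drop duplicate (spectrum, rgb) patches, warning when any are found."""
        seen, keep = set(), []
        for i in range(self.n_patches):
            key = (self.spectra[i].values.tobytes(), self.rgbs[i].tobytes())
            if key in seen:
                continue
            seen.add(key)
            keep.append(i)
        if len(keep) < self.n_patches:
            warnings.warn(
                f"dropped {self.n_patches - len(keep)} duplicate patch(es) "
                "before fitting",
                stacklevel=2,
            )
        return CalibrationTarget(
            [self.labels[i] for i in keep],
            [self.spectra[i] for i in keep],
            self.rgbs[keep],
        )


@dataclass
class CalibrationModel:
    """Fitted RGB→spectrum transform (linearization, expansion, basis, map)."""

    gamma: str
    color_space: str              # 'linear_rgb' or 'xyz'
    expansion: ExpansionSpec
    basis: SpectralBasis
    coefficient_map: np.ndarray   # (k, n_terms)
    training_rmse: float

    def __post_init__(self) -> None:
        # force C order: summation order (hence bit-level output) must not
        # depend on whether the map came from a fit or a reloaded file
        self.coefficient_map = np.ascontiguousarray(self.coefficient_map, dtype=float)
        if self.coefficient_map.shape != (self.basis.k, self.expansion.n_terms):
            raise ValueError("coefficient_map shape mismatch")


def _to_feature_space(rgb_linear: np.ndarray, color_space: str) -> np.ndarray:
    if color_space == "linear_rgb":
        return rgb_linear
    if color_space == "xyz":
        return rgb_linear @ _RGB_TO_XYZ.T
    raise ValueError(f"unknown color space {color_space!r}")


def fit_calibration(
    target: CalibrationTarget,
    expansion: ExpansionSpec | None = None,
    k: int | None = None,
    ridge: float = 1e-6,
    gamma: str = "srgb",
    color_space: str = "linear_rgb",
) -> CalibrationModel:
    """Fit the conversion matrix from a calibration target.

    Parameters
    ----------
    target:
        Patch spectra and their encoded camera RGBs.
    expansion:
        Polynomial feature spec; default degree 3 (20 terms).
    k:
        Basis size.  Default: min(10, smallest k with ≥ 99.9 % explained
        variance), never more than n_patches − 1.
    ridge:
        Non-negative ridge penalty applied on standardized features
        (feature-scaled); 0 gives plain least squares.
    """
    if ridge < 0:
        raise ValueError("ridge must be non-negative")
    expansion = expansion or ExpansionSpec(order=3)
    target = target.deduplicated()
    n = target.n_patches

    # basis size: cap by variance criterion and sample count
    full = fit_basis(target.spectra, k=n - 1)
    if k is None:
        cum = np.cumsum(full.explained_variance)
        k_var = int(np.searchsorted(cum, 0.999) + 1)
        k = min(10, k_var, n - 1)
    else:
        # dedup may have shrunk the sample; cap k at what it can support
        k = min(k, n - 1)
    basis = SpectralBasis(
        full.grid, full.mean, full.components[:k], full.explained_variance[:k]
    )

    if expansion.n_terms > n and ridge == 0:
        warnings.warn(
            f"{expansion.n_terms} features for {n} patches with ridge=0: "
            "the fit is rank-deficient",
            stacklevel=2,
        )

    rgb_lin = _GAMMA_MODELS[gamma][0](target.rgbs)
    feats = expand_features(_to_feature_space(rgb_lin, color_space), expansion)
    coeffs = basis.project(np.stack([s.values for s in target.spectra]))

    # ridge on standardized features: penalty scales with each column's norm
    A = feats  # (n, n_terms)
    scale = np.linalg.norm(A, axis=0)
    scale[scale == 0] = 1.0
    lam = ridge * scale ** 2
    M = np.linalg.solve(A.T @ A + np.diag(lam), A.T @ coeffs).T  # (k, n_terms)

    recon = basis.reconstruct(np.einsum("...t,kt->...k", feats, M))
    truth = np.stack([s.values for s in target.spectra])
    rmse = float(np.sqrt(np.mean((recon - truth) ** 2)))
    return CalibrationModel(gamma, color_space, expansion, basis, M, rmse)


def reconstruct_spectrum(model: CalibrationModel, rgb: np.ndarray) -> Spectrum:
    """Reconstruct the 401-band reflectance spectrum of one encoded RGB."""
    rgb = np.asarray(rgb, dtype=float)
    if rgb.shape != (3,):
        raise ValueError("expected a single RGB triplet of shape (3,)")
    values = _reconstruct_values(model, rgb[None, :])[0]
    return Spectrum(model.basis.grid, values)


def _reconstruct_values(model: CalibrationModel, rgbs: np.ndarray) -> np.ndarray:
    rgb_lin = _GAMMA_MODELS[model.gamma][0](rgbs)
    feats = expand_features(
        _to_feature_space(rgb_lin, model.color_space), model.expansion
    )
    return model.basis.reconstruct(
        np.einsum("...t,kt->...k", feats, model.coefficient_map)
    )


def reconstruct_cube(model: CalibrationModel, img: RGBImage) -> SpectralImageCube:
    """Per-pixel spectral reconstruction of an encoded RGB image."""
    if img.encoding != "encoded":
        raise ValueError("reconstruct_cube expects a display-encoded image")
    h, w = img.height, img.width
    flat = img.values.reshape(-1, 3)
    values = _reconstruct_values(model, flat).reshape(h, w, -1)
    return SpectralImageCube(model.basis.grid, values)


# ---------------------------------------------------------------------------
# model (de)serialization — versioned JSON schema

def save_model(model: CalibrationModel, path) -> None:
    doc = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "gamma": model.gamma,
        "color_space": model.color_space,
        "expansion_order": model.expansion.order,
        "grid": {
            "start": model.basis.grid.start,
            "stop": model.basis.grid.stop,
            "step": model.basis.grid.step,
        },
        "mean_spectrum": model.basis.mean.tolist(),
        "components": model.basis.components.tolist(),
        "explained_variance": model.basis.explained_variance.tolist(),
        "coefficient_map": model.coefficient_map.tolist(),
        "training_rmse": model.training_rmse,
    }
    Path(path).write_text(json.dumps(doc), encoding="utf-8")


def load_model(path) -> CalibrationModel:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    if doc.get("schema_version") != MODEL_SCHEMA_VERSION:
        raise ValueError(f"unsupported model schema {doc.get('schema_version')}")
    grid = WavelengthGrid(**doc["grid"])
    basis = SpectralBasis(
        grid,
        np.array(doc["mean_spectrum"]),
        np.array(doc["components"]),
        np.array(doc["explained_variance"]),
    )
    return CalibrationModel(
        doc["gamma"],
        doc["color_space"],
        ExpansionSpec(order=doc["expansion_order"]),
        basis,
        np.array(doc["coefficient_map"]),
        doc["training_rmse"],
    )
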