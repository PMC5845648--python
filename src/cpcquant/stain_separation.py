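"""Optical-density color deconvolution of AEC / hematoxylin brightfield images.

The red-brown AEC chromogen marks antibody-bound (positive) structures and
hematoxylin counterstains all tissue. Stain concentrations add linearly in
optical density (Beer-Lambert), so a per-pixel 3x3 linear solve against known
stain OD vectors separates the two stains plus an orthogonal residual.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CalibrationError, ParameterError, StainBasisError

# Reference brightfield stain vectors (unit-normalized in StainBasis.default).
HEMATOXYLIN_OD = (0.650, 0.704, 0.286)
AEC_OD = (0.274, 0.679, 0.680)

#: Rec. 601 luma weights used for the brightness screen in estimate_background.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class RGBSlide:
    """A calibrated 8-bit RGB image of one stained section.

    Parameters
    ----------
    pixels : ndarray, shape (H, W, 3)
        Intensities in [0, 255]. uint8 is typical; float arrays in the same
        range are accepted (used by noise-free synthetic round trips).
    mpp : float
        Microns per pixel, > 0.
    slide_id, marker : str
        Free-text metadata; never influence any computation.
    """

    pixels: np.ndarray
    mpp: float
    slide_id: str = ""
    marker: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ParameterError(f"pixels must be H x W x 3, got shape {px.shape}")
        if px.min() < 0 or px.max() > 255:
            raise ParameterError("pixel intensities must lie in [0, 255]")
        if not np.isfinite(self.mpp) or self.mpp <= 0:
            raise ParameterError(f"mpp must be > 0, got {self.mpp}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise StainBasisError("stain vector has zero norm")
    return v / n


@dataclass(frozen=True)
class StainBasis:
    """Unit OD vectors for hematoxylin, the chromogen, and a residual.

    The residual completes an orthogonal complement so the 3x3 system is
    solvable for any pixel; it carries whatever the two stains cannot explain.
    """

    hematoxylin_od: np.ndarray
    chromogen_od: np.ndarray
    residual_od: np.ndarray

    def __post_init__(self) -> None:
        for name in ("hematoxylin_od", "chromogen_od", "residual_od"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (3,):
                raise StainBasisError(f"{name} must be a 3-vector")
            if abs(np.linalg.norm(v) - 1.0) > 1e-6:
                raise StainBasisError(f"{name} must have unit norm")
            object.__setattr__(self, name, v)
        cos_hc = float(np.dot(self.hematoxylin_od, self.chromogen_od))
        if np.degrees(np.arccos(np.clip(abs(cos_hc), 0, 1))) <= 1.0:
            raise StainBasisError("hematoxylin and chromogen vectors are near-collinear")
        for name in ("hematoxylin_od", "chromogen_od"):
            if abs(float(np.dot(getattr(self, name), self.residual_od))) > 1e-6:
                raise StainBasisError(f"residual_od not orthogonal to {name}")

    @classmethod
    def from_stains(cls, hematoxylin, chromogen) -> "StainBasis":
        """Build a basis from two stain vectors, completing the residual.

        The residual is the unit cross product; the chromogen component
        orthogonal to hematoxylin is NOT removed (standard practice keeps the
        measured stain directions as-is).
        """
        h = _unit(hematoxylin)
        c = _unit(chromogen)
        r = np.cross(h, c)
        if np.linalg.norm(r) < 1e-8:
            raise StainBasisError("stain vectors are collinear")
        return cls(h, c, _unit(r))

    @classmethod
    def default(cls) -> "StainBasis":
        """Published brightfield vectors for hematoxylin + AEC."""
        return cls.from_stains(HEMATOXYLIN_OD, AEC_OD)

    @property
    def matrix(self) -> np.ndarray:
        """3x3 matrix with basis vectors as columns."""
        return np.stack(
            [self.hematoxylin_od, self.chromogen_od, self.residual_od], axis=1
        )


@dataclass(frozen=True)
class StainMaps:
    """Per-stain concentration images in OD units (negatives clipped to 0).

    ``raw_concentrations`` keeps the pre-clip linear solution so that the
    reconstruction invariant M @ c_raw == OD can be checked exactly.
    """

    hematoxylin: np.ndarray
    chromogen: np.ndarray
    residual: np.ndarray
    background_intensity: np.ndarray
    raw_concentrations: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        for name in ("hematoxylin", "chromogen", "residual"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if not np.all(np.isfinite(arr)):
                raise ParameterError(f"{name} concentrations must be finite")
            if arr.min() < 0:
                raise ParameterError(f"{name} concentrations must be >= 0")
            object.__setattr__(self, name, arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.hematoxylin.shape

    @property
    def concentrations(self) -> dict[str, np.ndarray]:
        return {
            "hematoxylin": self.hematoxylin,
            "chromogen": self.chromogen,
            "residual": self.residual,
        }


def rgb_to_od(pixels, background_intensity) -> np.ndarray:
    """Convert intensities to optical density against a white reference.

    OD = -log10((I + 1) / (I0 + 1)) per channel; the +1 offsets keep the
    output finite on 8-bit data (I = 0 maps to a large but bounded OD).
    """
    if isinstance(pixels, RGBSlide):
        pixels = pixels.pixels
    i0 = np.asarray(background_intensity, dtype=float)
    if i0.shape != (3,):
        raise CalibrationError("background_intensity must be a 3-vector")
    if np.any(i0 <= 0) or np.any(i0 > 255):
        raise CalibrationError(f"background intensity must lie in (0, 255], got {i0}")
    od = -np.log10((np.asarray(pixels, dtype=float) + 1.0) / (i0 + 1.0))
    return od


def estimate_background(
    slide: RGBSlide, *, luminance_floor: float = 200.0, quantile: float = 0.99
) -> np.ndarray:
    """Robust per-channel white reference from the bright (non-tissue) pixels.

    Takes the per-channel ``quantile`` over pixels whose Rec. 601 luminance
    exceeds ``luminance_floor``; robust even when tissue fills most of the
    frame, as long as some clear background is visible.
    """
    px = slide.pixels.astype(float)
    bright = px @ _LUMA > luminance_floor
    if not bright.any():
        raise CalibrationError(
            f"no pixel exceeds the luminance floor {luminance_floor}; "
            "cannot estimate a white reference"
        )
    ref = np.quantile(px[bright], quantile, axis=0)
    return np.clip(ref, 1.0, 255.0)


def deconvolve(od_image: np.ndarray, basis: StainBasis | None = None,
               background_intensity=None) -> StainMaps:
    """Per-pixel linear solve OD = M @ c for the stain concentrations.

    Negative concentrations are clipped to zero in the public maps; the
    pre-clip solution is retained in ``raw_concentrations``.
    """
    if basis is None:
        basis = StainBasis.default()
    od = np.asarray(od_image, dtype=float)
    if od.ndim != 3 or od.shape[2] != 3:
        raise ParameterError("od_image must be H x W x 3")
    m = basis.matrix
    if abs(np.linalg.det(m)) < 1e-10:
        raise StainBasisError("stain basis matrix is singular")
    inv = np.linalg.inv(m)
    raw = od @ inv.T  # c = M^-1 od, vectorized over pixels
    clipped = np.clip(raw, 0.0, None)
    if background_intensity is None:
        background_intensity = np.array([255.0, 255.0, 255.0])
    return StainMaps(
        hematoxylin=clipped[..., 0],
        chromogen=clipped[..., 1],
        residual=clipped[..., 2],
        background_intensity=np.asarray(background_intensity, dtype=float),
        raw_concentrations=raw,
    )


def separate_stains(slide: RGBSlide, basis: StainBasis | None = None,
                    background_intensity=None) -> StainMaps:
    """Convenience composition: estimate background, OD transform, deconvolve."""
    if background_intensity is None:
        background_intensity = estimate_background(slide)
    od = rgb_to_od(slide, background_intensity)
    return deconvolve(od, basis, background_intensity)
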