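"""Beer-Lambert stain model for brightfield hematoxylin + DAB tiles.

Brightfield immunohistochemistry follows the Beer-Lambert law: a pixel with
stain concentrations ``c_H`` (hematoxylin) and ``c_D`` (DAB) transmits

    I_c = I0_c * 10 ** -(c_H * M_H,c + c_D * M_D,c)

per RGB channel ``c``, where ``M_H`` and ``M_D`` are the unit optical-density
(OD) absorption vectors of the two stains and ``I0`` the blank-slide
(background) intensity.  The same model, inverted, underlies color
deconvolution (see :mod:`tumorbud.detection`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Standard published H-DAB absorption vectors (Ruifrok & Johnston convention),
# unit-normalised in StainModel.hdab().
_HDAB_HEMATOXYLIN = (0.650, 0.704, 0.286)
_HDAB_DAB = (0.268, 0.570, 0.776)

#: |cos angle| above which two stain vectors are treated as collinear.
_COLLINEARITY_LIMIT = 1.0 - 1e-8


class StainModelError(ValueError):
    """Invalid stain-model parameters (non-unit or collinear vectors, bad I0)."""


def _as_unit_vector(v, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.shape != (3,):
        raise StainModelError(f"{name} must be a 3-vector, got shape {v.shape}")
    norm = float(np.linalg.norm(v))
    if not np.isfinite(norm) or abs(norm - 1.0) > 1e-6:
        raise StainModelError(f"{name} must have unit Euclidean norm (norm={norm:.6g})")
    return v


@dataclass(frozen=True)
class StainModel:
    """Optical-density unit vectors for hematoxylin and DAB plus background I0.

    Parameters
    ----------
    od_hematoxylin, od_dab
        Unit-norm 3-vectors of per-channel optical densities.
    background_intensity
        Blank-slide transmitted intensity per RGB channel (``I0``), in the
        same counts as the tiles (255 for 8-bit imagery).
    """

    od_hematoxylin: np.ndarray
    od_dab: np.ndarray
    background_intensity: np.ndarray = field(
        default_factory=lambda: np.array([255.0, 255.0, 255.0])
    )

    def __post_init__(self) -> None:
        h = _as_unit_vector(self.od_hematoxylin, "od_hematoxylin")
        d = _as_unit_vector(self.od_dab, "od_dab")
        if abs(float(h @ d)) > _COLLINEARITY_LIMIT:
            raise StainModelError("stain vectors are (near-)collinear; cannot unmix")
        i0 = np.asarray(self.background_intensity, dtype=float)
        if i0.shape == ():
            i0 = np.full(3, float(i0))
        if i0.shape != (3,) or not np.all(i0 > 0):
            raise StainModelError("background_intensity must be 3 positive reals")
        object.__setattr__(self, "od_hematoxylin", h)
        object.__setattr__(self, "od_dab", d)
        object.__setattr__(self, "background_intensity", i0)

    @classmethod
    def hdab(cls, background_intensity: float | np.ndarray = 255.0) -> "StainModel":
        """Standard H-DAB pair, unit-normalised."""
        h = np.array(_HDAB_HEMATOXYLIN)
        d = np.array(_HDAB_DAB)
        return cls(h / np.linalg.norm(h), d / np.linalg.norm(d),
                   np.broadcast_to(np.asarray(background_intensity, float), (3,)).copy())

    @property
    def matrix(self) -> np.ndarray:
        """3x2 matrix with the stain OD vectors as columns."""
        return np.stack([self.od_hematoxylin, self.od_dab], axis=1)


def rgb_to_od(tile: np.ndarray, background_intensity, eps: float | None = None) -> np.ndarray:
    """Convert a transmitted-intensity RGB tile to optical densities.

    ``OD_c = -log10((I_c + eps) / I0_c)``, clipped below at 0 (pixels brighter
    than background carry no stain).  ``eps`` defaults to 1 for integer-dtype
    tiles — quantized 8-bit counts, where it guards ``log(0)`` — and to 0 for
    floating-point tiles, which keeps the transform an exact inverse of the
    Beer-Lambert forward model.
    """
    tile = np.asarray(tile)
    if tile.ndim != 3 or tile.shape[-1] != 3:
        raise ValueError(f"expected an RGB image of shape (H, W, 3), got {tile.shape}")
    i0 = np.asarray(background_intensity, dtype=float)
    if i0.shape == ():
        i0 = np.full(3, float(i0))
    if i0.shape != (3,) or not np.all(i0 > 0):
        raise ValueError("background_intensity must be positive per channel")
    if eps is None:
        eps = 1.0 if np.issubdtype(tile.dtype, np.integer) else 0.0
    ratio = (tile.astype(float) + eps) / i0
    od = -np.log10(np.maximum(ratio, 1e-12))
    return np.clip(od, 0.0, None)


def transmitted_intensity(c_hematoxylin: np.ndarray, c_dab: np.ndarray,
                          stain: StainModel) -> np.ndarray:
    """Beer-Lambert forward model: concentration maps -> float RGB tile.

    Returns transmitted intensity in the counts of ``stain.background_intensity``
    (no noise, no clipping; both belong to the caller).
    """
    c_h = np.asarray(c_hematoxylin, dtype=float)
    c_d = np.asarray(c_dab, dtype=float)
    od = (c_h[..., None] * stain.od_hematoxylin
          + c_d[..., None] * stain.od_dab)
    return stain.background_intensity * np.power(10.0, -od)


def quantize_tile(tile: np.ndarray) -> np.ndarray:
    """Round a float tile to 8-bit counts for serialization."""
    return np.clip(np.round(tile), 0, 255).astype(np.uint8)
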