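"""Candidate-object detection in pan-cytokeratin IHC tiles.

The selection algorithm: color-deconvolve the RGB tile into hematoxylin and
DAB concentration maps, threshold the DAB channel, group positive pixels into
binary objects (8-connectivity), and retain objects whose surface area lies
between 25 and 5000 µm² — removing sub-bud artifacts below and large tumor-cell
clusters above.

Coordinate conventions: 0-based pixel indices; the physical µm frame has its
origin at the tile's top-left pixel *corner*, x along columns, y along rows, so
the center of pixel (row, col) is at ((col + 0.5) * s, (row + 0.5) * s) µm for
pixel size s.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from skimage import measure, morphology

from .stains import StainModel, rgb_to_od

DEFAULT_PIXEL_SIZE_UM = 0.24
DEFAULT_DAB_THRESHOLD = 0.15
DEFAULT_MIN_AREA_UM2 = 25.0
DEFAULT_MAX_AREA_UM2 = 5000.0


@dataclass(frozen=True)
class ConcentrationMaps:
    """Per-pixel stain concentrations (OD units, clipped at 0)."""

    c_hematoxylin: np.ndarray
    c_dab: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        if self.c_hematoxylin.shape != self.c_dab.shape:
            raise ValueError("concentration maps must share a shape")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")


@dataclass(frozen=True)
class CandidateObject:
    """One detected keratin-positive binary object.

    ``centroid_um`` is the unweighted center of mass of the binary mask in the
    tile's µm frame, (x, y) with x along columns.  ``bbox`` is the skimage
    convention (min_row, min_col, max_row, max_col) in pixels; ``mask`` is the
    binary crop over that box.
    """

    object_id: object
    tile_id: str
    centroid_um: tuple[float, float]
    area_um2: float
    pixel_count: int
    bbox: tuple[int, int, int, int]
    mask: np.ndarray | None = None
    stratum: str | None = None


def deconvolve(od: np.ndarray, stain: StainModel,
               pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> ConcentrationMaps:
    """Unmix an OD image into hematoxylin and DAB concentrations.

    Per pixel, the concentrations are the least-squares projection of the OD
    3-vector onto the two stain vectors (the residual direction is discarded);
    negative solutions are clipped to 0.
    """
    od = np.asarray(od, dtype=float)
    if od.ndim != 3 or od.shape[-1] != 3:
        raise ValueError(f"expected an OD image of shape (H, W, 3), got {od.shape}")
    pinv = np.linalg.pinv(stain.matrix)  # (2, 3); StainModel bars collinearity
    conc = od @ pinv.T
    conc = np.clip(conc, 0.0, None)
    return ConcentrationMaps(conc[..., 0], conc[..., 1], pixel_size_um)


def segment_dab(c_dab: np.ndarray, threshold: float = DEFAULT_DAB_THRESHOLD,
                closing_radius_um: float = 0.0,
                pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> np.ndarray:
    """Threshold the DAB concentration map into a binary mask.

    ``mask = c_dab >= threshold`` followed by morphological closing with a
    disc of physical radius ``closing_radius_um`` (0 disables closing).
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if closing_radius_um < 0:
        raise ValueError("closing_radius_um must be >= 0")
    mask = np.asarray(c_dab) >= threshold
    if closing_radius_um > 0:
        radius_px = int(round(closing_radius_um / pixel_size_um))
        if radius_px > 0:
            mask = morphology.closing(mask, morphology.disk(radius_px))
    return mask


def otsu_dab_threshold(c_dab: np.ndarray) -> float:
    """Data-driven alternative to the fixed concentration threshold."""
    from skimage.filters import threshold_otsu

    return float(threshold_otsu(np.asarray(c_dab, dtype=float)))


def extract_objects(mask: np.ndarray, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
                    tile_id: str = "tile") -> list[CandidateObject]:
    """Group mask pixels into connected components (8-connectivity).

    Object ids are assigned in raster order of each component's first pixel
    (top-most, then left-most), starting at 1.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    labels = measure.label(np.asarray(mask, dtype=bool), connectivity=2)
    props = measure.regionprops(labels)
    # regionprops coords are raster-ordered within each region, so coords[0]
    # is the component's first pixel in scan order.
    props.sort(key=lambda p: (int(p.coords[0][0]), int(p.coords[0][1])))
    px_area = pixel_size_um ** 2
    out: list[CandidateObject] = []
    for i, p in enumerate(props, start=1):
        row_c, col_c = p.centroid
        out.append(CandidateObject(
            object_id=i,
            tile_id=tile_id,
            centroid_um=((col_c + 0.5) * pixel_size_um, (row_c + 0.5) * pixel_size_um),
            area_um2=p.num_pixels * px_area,
            pixel_count=int(p.num_pixels),
            bbox=tuple(int(b) for b in p.bbox),
            mask=p.image.copy(),
        ))
    return out


def filter_by_area(objects: Sequence[CandidateObject],
                   min_um2: float = DEFAULT_MIN_AREA_UM2,
                   max_um2: float = DEFAULT_MAX_AREA_UM2) -> list[CandidateObject]:
    """Retain objects with min_um2 <= area <= max_um2 (inclusive), order kept."""
    if not min_um2 < max_um2:
        raise ValueError("min_um2 must be < max_um2")
    return [o for o in objects if min_um2 <= o.area_um2 <= max_um2]


def detect_candidates(tile: np.ndarray, stain: StainModel,
                      pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
                      dab_threshold: float = DEFAULT_DAB_THRESHOLD,
                      closing_radius_um: float = 0.0,
                      min_area_um2: float = DEFAULT_MIN_AREA_UM2,
                      max_area_um2: float = DEFAULT_MAX_AREA_UM2,
                      roi_um: tuple[float, float, float, float] | None = None,
                      tile_id: str = "tile") -> list[CandidateObject]:
    """Full candidate selection: deconvolve, segment, group, area-filter.

    ``roi_um`` restricts detection to a hotspot rectangle (x, y, width,
    height) in µm; DAB signal outside it is ignored.
    """
    od = rgb_to_od(tile, stain.background_intensity)
    maps = deconvolve(od, stain, pixel_size_um)
    c_dab = maps.c_dab
    if roi_um is not None:
        x, y, w, h = roi_um
        if w <= 0 or h <= 0:
            raise ValueError("ROI width and height must be positive")
        sel = np.zeros_like(c_dab, dtype=bool)
        r0 = max(0, int(np.floor(y / pixel_size_um)))
        c0 = max(0, int(np.floor(x / pixel_size_um)))
        r1 = min(c_dab.shape[0], int(np.ceil((y + h) / pixel_size_um)))
        c1 = min(c_dab.shape[1], int(np.ceil((x + w) / pixel_size_um)))
        sel[r0:r1, c0:c1] = True
        c_dab = np.where(sel, c_dab, 0.0)
    mask = segment_dab(c_dab, dab_threshold, closing_radius_um, pixel_size_um)
    objs = extract_objects(mask, pixel_size_um, tile_id=tile_id)
    return filter_by_area(objs, min_area_um2, max_area_um2)


def candidates_to_frame(objects: Sequence[CandidateObject]) -> pd.DataFrame:
    """Tabulate candidates with the documented CSV columns."""
    return pd.DataFrame({
        "object_id": [o.object_id for o in objects],
        "tile_id": [o.tile_id for o in objects],
        "centroid_x_um": [o.centroid_um[0] for o in objects],
        "centroid_y_um": [o.centroid_um[1] for o in objects],
        "area_um2": [o.area_um2 for o in objects],
        "pixel_count": [o.pixel_count for o in objects],
        "stratum": [o.stratum if o.stratum is not None else "" for o in objects],
    })


def with_stratum(obj: CandidateObject, stratum: str) -> CandidateObject:
    return replace(obj, stratum=stratum)
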