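"""Candidate sampling, group splitting, review-patch extraction, coordinate transfer.

The study design draws a stratified sample from the detected candidate pool —
1900 candidates below 1000 µm² (mostly tumor buds) plus 300 at or above it
(mostly PDCs) — merges any externally supplied candidates, splits the set into
two equal review groups, and shows each candidate to the raters as a square
patch centered on its center of mass with an open marker square.

Candidates are carried as plain DataFrames with the documented columns
(object_id, tile_id, centroid_x_um, centroid_y_um, area_um2, pixel_count,
stratum, group) so every step is file-round-trippable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, field

import numpy as np
import pandas as pd

from .detection import CandidateObject

DEFAULT_STRATUM_BOUNDARY_UM2 = 1000.0
DEFAULT_N_SMALL = 1900
DEFAULT_N_LARGE = 300
DEFAULT_GROUP_SIZES = (1500, 1500)
DEFAULT_PATCH_SIDE_UM = 256.0
DEFAULT_MARKER_AREA_MM2 = 0.03

SMALL, LARGE = "small", "large"


class SamplingError(ValueError):
    """Sampling precondition violated (deficient stratum, bad sizes...)."""


@dataclass(frozen=True)
class CandidateSet:
    """A sampled candidate table plus provenance.

    ``table`` columns include ``stratum`` after sampling and ``group`` after
    splitting.  ``provenance`` records seeds and source identifiers.
    """

    table: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.table["object_id"].duplicated().any():
            raise SamplingError("duplicate object ids in candidate set")

    def __len__(self) -> int:
        return len(self.table)


def assign_strata(table: pd.DataFrame,
                  boundary_um2: float = DEFAULT_STRATUM_BOUNDARY_UM2) -> pd.DataFrame:
    """Label candidates small (< boundary) or large (>= boundary).

    The boundary itself goes to the large stratum (the study phrases the
    strata as "<1000" and ">1000", leaving 1000 exactly unassigned; one
    convention must be fixed).
    """
    out = table.copy()
    out["stratum"] = np.where(out["area_um2"] < boundary_um2, SMALL, LARGE)
    return out


def stratify_sample(pool: pd.DataFrame,
                    n_small: int = DEFAULT_N_SMALL,
                    n_large: int = DEFAULT_N_LARGE,
                    boundary_um2: float = DEFAULT_STRATUM_BOUNDARY_UM2,
                    seed: int = 0) -> CandidateSet:
    """Sample n_small + n_large candidates uniformly within area strata.

    Sampling is without replacement, uniform within each stratum, seeded.
    Raises :class:`SamplingError` naming the deficient stratum when the pool
    cannot cover a request.
    """
    pool = assign_strata(pool, boundary_um2)
    rng = np.random.default_rng(seed)
    parts = []
    for stratum, want in ((SMALL, n_small), (LARGE, n_large)):
        if want < 0:
            raise SamplingError(f"requested negative count for {stratum} stratum")
        sub = pool[pool["stratum"] == stratum]
        if len(sub) < want:
            raise SamplingError(
                f"{stratum} stratum has {len(sub)} candidates, {want} requested")
        if want:
            take = rng.choice(len(sub), size=want, replace=False)
            parts.append(sub.iloc[np.sort(take)])
    table = (pd.concat(parts, ignore_index=True) if parts
             else pool.iloc[0:0].copy())
    return CandidateSet(table, {"seed": seed, "n_small": n_small,
                                "n_large": n_large,
                                "boundary_um2": boundary_um2})


def merge_candidate_sets(a: CandidateSet, b: CandidateSet) -> CandidateSet:
    """Concatenate two candidate sets (e.g. an external candidate list).

    Object ids must stay globally unique; strata are kept as given.
    """
    table = pd.concat([a.table, b.table], ignore_index=True)
    return CandidateSet(table, {"merged": [a.provenance, b.provenance]})


def split_groups(cset: CandidateSet,
                 sizes: tuple[int, ...] = DEFAULT_GROUP_SIZES,
                 seed: int = 0) -> CandidateSet:
    """Uniform random partition of the set into groups 1, 2, ... of exact sizes."""
    if any(s < 0 for s in sizes):
        raise SamplingError("group sizes must be nonnegative")
    if sum(sizes) != len(cset):
        raise SamplingError(
            f"group sizes sum to {sum(sizes)} but the set has {len(cset)} candidates")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(cset))
    group = np.empty(len(cset), dtype=int)
    start = 0
    for g, s in enumerate(sizes, start=1):
        group[perm[start:start + s]] = g
        start += s
    table = cset.table.copy()
    table["group"] = group
    prov = dict(cset.provenance)
    prov.update({"split_seed": seed, "group_sizes": tuple(sizes)})
    return CandidateSet(table, prov)


@dataclass(frozen=True)
class ReviewPatch:
    """A square review patch centered on a candidate's center of mass.

    ``image`` carries the cropped pixels with the open marker square drawn in;
    ``offset_um`` is the (x, y) position of the patch's top-left pixel corner
    in the source tile's µm frame (negative when padding extends past the tile
    edge).
    """

    image: np.ndarray
    object_id: object
    side_um: float
    marker_area_mm2: float
    offset_um: tuple[float, float]


def extract_patch(tile: np.ndarray, obj: CandidateObject,
                  pixel_size_um: float,
                  side_um: float = DEFAULT_PATCH_SIDE_UM,
                  marker_area_mm2: float = DEFAULT_MARKER_AREA_MM2,
                  background=255.0,
                  marker_value=0.0) -> ReviewPatch:
    """Crop a side_um square around the candidate CoM and draw the marker.

    Regions outside the tile are padded with ``background`` (blank-slide
    intensity).  The marker is an open square outline, 2 px wide, of area
    ``marker_area_mm2``, centered on the CoM — never filled, so the candidate
    stays visible.  The source tile is not modified.
    """
    if side_um <= 0:
        raise ValueError("side_um must be positive")
    if marker_area_mm2 < 0:
        raise ValueError("marker_area_mm2 must be >= 0")
    side_px = int(round(side_um / pixel_size_um))
    h, w = tile.shape[:2]
    # CoM in pixel-center coordinates
    com_col = obj.centroid_um[0] / pixel_size_um - 0.5
    com_row = obj.centroid_um[1] / pixel_size_um - 0.5
    ctr_col = int(round(com_col))
    ctr_row = int(round(com_row))
    r0 = ctr_row - side_px // 2
    c0 = ctr_col - side_px // 2
    patch = np.empty((side_px, side_px) + tile.shape[2:], dtype=tile.dtype)
    patch[...] = np.asarray(background, dtype=tile.dtype)
    sr0, sr1 = max(r0, 0), min(r0 + side_px, h)
    sc0, sc1 = max(c0, 0), min(c0 + side_px, w)
    if sr0 < sr1 and sc0 < sc1:
        patch[sr0 - r0:sr1 - r0, sc0 - c0:sc1 - c0] = tile[sr0:sr1, sc0:sc1]
    if marker_area_mm2 > 0:
        m_side_px = int(round(np.sqrt(marker_area_mm2) * 1000.0 / pixel_size_um))
        pr = ctr_row - r0
        pc = ctr_col - c0
        top = pr - m_side_px // 2
        left = pc - m_side_px // 2
        _draw_square_outline(patch, top, left, m_side_px, marker_value)
    return ReviewPatch(patch, obj.object_id, side_um, marker_area_mm2,
                       (c0 * pixel_size_um, r0 * pixel_size_um))


def _draw_square_outline(img: np.ndarray, top: int, left: int, side: int,
                         value, thickness: int = 2) -> None:
    """Draw an open square outline in place, clipped to the image."""
    h, w = img.shape[:2]
    bot, right = top + side, left + side

    def fill(r0, r1, c0, c1):
        r0, r1 = max(r0, 0), min(r1, h)
        c0, c1 = max(c0, 0), min(c1, w)
        if r0 < r1 and c0 < c1:
            img[r0:r1, c0:c1] = value

    fill(top, top + thickness, left, right)              # top edge
    fill(bot - thickness, bot, left, right)              # bottom edge
    fill(top, bot, left, left + thickness)               # left edge
    fill(top, bot, right - thickness, right)             # right edge


def transfer_coordinates(obj: CandidateObject, affine: np.ndarray) -> CandidateObject:
    """Map a candidate's centroid into a co-registered target frame.

    ``affine`` is a 2x3 µm->µm transform: x' = A[:, :2] @ (x, y) + A[:, 2].
    Area and pixel data are carried unchanged — registration fidelity is the
    caller's responsibility (the restaining protocol keeps the section in
    place, so the transform is near-identity in practice).
    """
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (2, 3):
        raise ValueError(f"affine must be 2x3, got {affine.shape}")
    if abs(np.linalg.det(affine[:, :2])) < 1e-12:
        raise ValueError("affine transform is singular")
    x, y = obj.centroid_um
    xn, yn = affine[:, :2] @ (x, y) + affine[:, 2]
    return replace(obj, centroid_um=(float(xn), float(yn)))


def invert_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    ainv = np.linalg.inv(affine[:, :2])
    return np.hstack([ainv, -(ainv @ affine[:, 2])[:, None]])
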