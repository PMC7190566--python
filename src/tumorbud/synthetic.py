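"""Synthetic pan-cytokeratin IHC tiles and multi-rater rating panels.

The tile generator is the forward model of the detection stage: keratin-positive
objects (ellipse-shaped, uniform DAB concentration each) are planted on a
hematoxylin-counterstained background and rendered through the Beer-Lambert
law, with optional additive Gaussian camera noise in transmitted-intensity
space.  Object sizes span the study's spectrum: sub-bud artifacts (<25 µm²),
tumor buds (25–1000 µm²), PDC-scale clusters (1000–5000 µm²) and oversize
epithelial clusters (>5000 µm²).

The panel generator draws a latent true class per object and passes it through
a per-rater confusion matrix, emulating a pathologist panel with controlled
disagreement.  The small-area NEITHER-like class stands in for keratin-positive
debris ("pseudo buds") only at the size/label level; no morphological fidelity
is claimed.

All randomness flows from the integer seed in the spec; no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .consensus import CATEGORIES, RatingPanel
from .stains import StainModel, transmitted_intensity


class PlacementError(RuntimeError):
    """Tile too small/crowded to place a requested object within the retry budget."""


class SpecError(ValueError):
    """Invalid scene or panel specification."""


@dataclass(frozen=True)
class ObjectClass:
    """One planted object class: count, area range (µm²) and DAB range."""

    name: str
    count: int
    area_um2: tuple[float, float]       # uniform (lo, hi); lo == hi for fixed
    dab_concentration: tuple[float, float]

    def __post_init__(self) -> None:
        if self.count < 0:
            raise SpecError(f"class {self.name}: count must be >= 0")
        lo, hi = self.area_um2
        if not 0 < lo <= hi:
            raise SpecError(f"class {self.name}: area range must have positive support")
        dlo, dhi = self.dab_concentration
        if not 0 <= dlo <= dhi:
            raise SpecError(f"class {self.name}: bad DAB concentration range")


def default_object_classes() -> tuple[ObjectClass, ...]:
    """The study's size spectrum: artifact / bud / PDC-scale / oversize."""
    return (
        ObjectClass("artifact", 3, (5.0, 20.0), (0.4, 1.0)),
        ObjectClass("bud", 8, (30.0, 900.0), (0.5, 1.2)),
        ObjectClass("pdc", 2, (1100.0, 4500.0), (0.5, 1.2)),
        ObjectClass("oversize", 1, (5500.0, 6500.0), (0.5, 1.2)),
    )


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic tile."""

    tile_size_px: tuple[int, int] = (1536, 1536)
    pixel_size_um: float = 0.24
    object_classes: tuple[ObjectClass, ...] = field(default_factory=default_object_classes)
    background_hematoxylin: float = 0.3
    noise_sd: float = 2.0               # counts, additive on transmitted intensity
    seed: int = 0
    max_place_tries: int = 1000

    def __post_init__(self) -> None:
        h, w = self.tile_size_px
        if h < 1 or w < 1:
            raise SpecError("tile_size_px must be positive")
        if self.pixel_size_um <= 0:
            raise SpecError("pixel_size_um must be positive")
        if self.background_hematoxylin < 0:
            raise SpecError("background_hematoxylin must be >= 0")
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Planted-object record: label image plus per-object table.

    ``label_mask``: integer image, 0 = background, k = object id (contiguous
    from 1).  ``table`` columns: object_id, class, dab_concentration,
    pixel_count, area_um2, centroid_x_um, centroid_y_um.  Areas are exactly
    pixel_count x pixel_size_um².
    """

    label_mask: np.ndarray
    table: pd.DataFrame
    pixel_size_um: float

    @property
    def n_objects(self) -> int:
        return len(self.table)

    def dab_map(self) -> np.ndarray:
        """Planted per-pixel DAB concentration, reconstructed from the table."""
        lut = np.zeros(self.n_objects + 1)
        lut[self.table["object_id"].to_numpy()] = \
            self.table["dab_concentration"].to_numpy()
        return lut[self.label_mask]


def _ellipse_pixels(target_px: int, aspect: float, theta: float) -> tuple[np.ndarray, np.ndarray]:
    """Exactly ``target_px`` pixel offsets forming a discrete ellipse.

    Pixels are ranked by elliptical radius (ties broken in raster order) and
    the innermost ``target_px`` are kept, so the rasterized area is exact.
    """
    b = np.sqrt(target_px / (np.pi * aspect))
    a = aspect * b
    r = int(np.ceil(a)) + 1
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    ct, st = np.cos(theta), np.sin(theta)
    xr = ct * xx + st * yy
    yr = -st * xx + ct * yy
    rho = (xr / a) ** 2 + (yr / b) ** 2
    order = np.lexsort((xx.ravel(), yy.ravel(), rho.ravel()))[:target_px]
    return yy.ravel()[order], xx.ravel()[order]


def generate_tile(spec: SceneSpec, stain: StainModel) -> tuple[np.ndarray, GroundTruth]:
    """Render one synthetic IHC tile and its ground truth.

    Objects are placed by rejection sampling with a 2-px clearance so planted
    objects stay disjoint connected components under 8-connectivity.  Returns
    a float64 RGB tile (quantize with :func:`tumorbud.stains.quantize_tile`
    before writing 8-bit imagery) and the :class:`GroundTruth`.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.tile_size_px
    px_area = spec.pixel_size_um ** 2
    c_dab = np.zeros((h, w))
    labels = np.zeros((h, w), dtype=np.uint16)
    # occupancy dilated by 2 px: candidate pixels may not touch it
    blocked = np.zeros((h, w), dtype=bool)
    records = []
    obj_id = 0
    # Largest classes first: big objects need the most free room, so placing
    # them into an emptier tile keeps rejection sampling tractable.
    ordered = sorted(spec.object_classes,
                     key=lambda c: -(c.area_um2[0] + c.area_um2[1]))
    for cls in ordered:
        for _ in range(cls.count):
            lo, hi = cls.area_um2
            area = lo if lo == hi else rng.uniform(lo, hi)
            aspect = rng.uniform(1.0, 1.6)
            theta = rng.uniform(0.0, np.pi)
            dab = rng.uniform(*cls.dab_concentration)
            target_px = max(1, int(round(area / px_area)))
            dy, dx = _ellipse_pixels(target_px, aspect, theta)
            r_ext = max(-dy.min(), dy.max(), -dx.min(), dx.max())
            if r_ext + 1 > min(h, w) // 2 - 1:
                raise PlacementError(
                    f"object of class {cls.name!r} ({target_px} px) cannot fit "
                    f"in a {h}x{w} tile")
            placed = False
            for _try in range(spec.max_place_tries):
                cy = int(rng.integers(r_ext + 1, h - r_ext - 1))
                cx = int(rng.integers(r_ext + 1, w - r_ext - 1))
                rr, cc = dy + cy, dx + cx
                if blocked[rr, cc].any():
                    continue
                obj_id += 1
                labels[rr, cc] = obj_id
                c_dab[rr, cc] = dab
                for oy in range(-2, 3):  # 2-px clearance around every pixel
                    for ox in range(-2, 3):
                        blocked[np.clip(rr + oy, 0, h - 1),
                                np.clip(cc + ox, 0, w - 1)] = True
                records.append({
                    "object_id": obj_id,
                    "class": cls.name,
                    "dab_concentration": dab,
                    "pixel_count": int(target_px),
                    "area_um2": target_px * px_area,
                    "centroid_x_um": (cc.mean() + 0.5) * spec.pixel_size_um,
                    "centroid_y_um": (rr.mean() + 0.5) * spec.pixel_size_um,
                })
                placed = True
                break
            if not placed:
                raise PlacementError(
                    f"failed to place object of class {cls.name!r} after "
                    f"{spec.max_place_tries} tries")
    c_hem = np.full((h, w), spec.background_hematoxylin)
    tile = transmitted_intensity(c_hem, c_dab, stain)
    if spec.noise_sd > 0:
        tile = tile + rng.normal(0.0, spec.noise_sd, tile.shape)
    tile = np.clip(tile, 0.0, stain.background_intensity)
    table = pd.DataFrame(records, columns=["object_id", "class",
                                           "dab_concentration", "pixel_count",
                                           "area_um2", "centroid_x_um",
                                           "centroid_y_um"])
    return tile, GroundTruth(labels, table, spec.pixel_size_um)


# ---------------------------------------------------------------------------
# Rating panels


def _validate_stochastic(vec, name: str, tol: float = 1e-12) -> np.ndarray:
    v = np.asarray(vec, dtype=float)
    if np.any(v < 0) or abs(v.sum() - 1.0) > tol:
        raise SpecError(f"{name} must be nonnegative and sum to 1 (got sum={v.sum()!r})")
    return v


@dataclass(frozen=True)
class PanelSpec:
    """Parameters of one synthetic rating panel.

    ``rater_confusions``: per-rater 3x3 row-stochastic matrix; row = latent
    class (TB, PDC, NEITHER order), column = reported class.  A single 3x3
    matrix is broadcast to all raters.
    """

    n_objects: int
    n_raters: int
    class_prevalence: tuple[float, float, float] = (0.5, 0.1, 0.4)
    rater_confusions: np.ndarray | None = None   # None -> identity raters
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_objects < 1 or self.n_raters < 1:
            raise SpecError("n_objects and n_raters must be positive")
        _validate_stochastic(self.class_prevalence, "class_prevalence")
        object.__setattr__(self, "rater_confusions", self._confusions())

    def _confusions(self) -> np.ndarray:
        conf = self.rater_confusions
        if conf is None:
            conf = identity_confusion()
        conf = np.asarray(conf, dtype=float)
        if conf.shape == (3, 3):
            conf = np.broadcast_to(conf, (self.n_raters, 3, 3)).copy()
        if conf.shape != (self.n_raters, 3, 3):
            raise SpecError(
                f"rater_confusions must be (3,3) or (n_raters,3,3), got {conf.shape}")
        for r in range(self.n_raters):
            for row in range(3):
                _validate_stochastic(conf[r, row], f"confusion row {row} of rater {r}")
        return conf


def identity_confusion() -> np.ndarray:
    """Noiseless raters: every report equals the latent class."""
    return np.eye(3)


def uniform_confusion() -> np.ndarray:
    """Raters blind to the latent class: all reports uniform over 3 classes."""
    return np.full((3, 3), 1.0 / 3.0)


def noisy_confusion(error: float) -> np.ndarray:
    """Symmetric confusion: diagonal 1-error, off-diagonal error/2 each."""
    if not 0 <= error <= 1:
        raise SpecError("error must lie in [0, 1]")
    return (1.0 - error) * np.eye(3) + (error / 2.0) * (1.0 - np.eye(3))


def generate_rating_panel(spec: PanelSpec,
                          object_ids=None,
                          rater_ids=None) -> tuple[RatingPanel, pd.Series]:
    """Draw a complete panel: latent class per object, then per-rater reports.

    Returns the panel and the latent true labels (a Series over object ids).
    """
    rng = np.random.default_rng(spec.seed)
    if object_ids is None:
        object_ids = list(range(1, spec.n_objects + 1))
    if rater_ids is None:
        rater_ids = [f"R{i + 1}" for i in range(spec.n_raters)]
    if len(object_ids) != spec.n_objects or len(rater_ids) != spec.n_raters:
        raise SpecError("object_ids/rater_ids lengths must match the spec")
    latent = rng.choice(3, size=spec.n_objects, p=np.asarray(spec.class_prevalence))
    cats = np.array(CATEGORIES, dtype=object)
    data = {}
    for r, rid in enumerate(rater_ids):
        cum = np.cumsum(spec.rater_confusions[r][latent], axis=1)
        u = rng.random(spec.n_objects)
        reports = (u[:, None] >= cum).sum(axis=1)
        data[rid] = cats[np.minimum(reports, 2)]
    ratings = pd.DataFrame(data, index=pd.Index(object_ids, name="object_id"))
    truth = pd.Series(cats[latent], index=ratings.index, name="true_label")
    return RatingPanel(ratings), truth


def panel_from_vote_patterns(patterns, n_raters: int,
                             rater_ids=None) -> RatingPanel:
    """Build a concrete panel realizing given per-object vote-count triples.

    ``patterns`` is an iterable of (n_TB, n_PDC, n_NEITHER) counts, each
    summing to ``n_raters``; ratings are assigned to raters in order (which
    raters hold which vote is immaterial to consensus summaries).  Used to
    reconstruct published summary tables from their vote-pattern marginals.
    """
    if rater_ids is None:
        rater_ids = [f"R{i + 1}" for i in range(n_raters)]
    rows = []
    for i, (tb, pdc, nei) in enumerate(patterns):
        if tb + pdc + nei != n_raters or min(tb, pdc, nei) < 0:
            raise SpecError(f"pattern {i}: counts must be >= 0 and sum to {n_raters}")
        rows.append(["TB"] * tb + ["PDC"] * pdc + ["NEITHER"] * nei)
    ratings = pd.DataFrame(rows, columns=rater_ids,
                           index=pd.Index(range(1, len(rows) + 1), name="object_id"))
    return RatingPanel(ratings)
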