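"""CSV/image file contracts for panels, candidates, tiles and ground truth.

Panels: first column ``object_id``, one column per rater, cells exactly
"TB", "PDC" or "NEITHER" (empty = not rated).  Parsing is strict — unknown
tokens, ragged rows and duplicate ids raise with a line number rather than
being coerced.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .consensus import CATEGORIES, RatingPanel
from .sampling import CandidateSet
from .stains import quantize_tile


class ParseError(ValueError):
    """Malformed input file; message carries the file and line number."""


# --- rating panels ---------------------------------------------------------

def write_panel(path, panel: RatingPanel) -> None:
    df = panel.ratings.copy()
    df.index.name = "object_id"
    df.fillna("").to_csv(path)


def read_panel(path) -> RatingPanel:
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file, expected a header row")
        if not header or header[0] != "object_id":
            raise ParseError(f"{path}:1: first column must be 'object_id'")
        raters = header[1:]
        ids, rows = [], []
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(header):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(row)}")
            ids.append(row[0])
            vals = []
            for tok, rater in zip(row[1:], raters):
                if tok == "":
                    vals.append(np.nan)
                elif tok in CATEGORIES:
                    vals.append(tok)
                else:
                    raise ParseError(
                        f"{path}:{lineno}: unknown category {tok!r} for rater {rater}")
            rows.append(vals)
    # ids round-trip as ints when possible
    try:
        ids = [int(i) for i in ids]
    except ValueError:
        pass
    if len(set(ids)) != len(ids):
        raise ParseError(f"{path}: duplicate object ids")
    ratings = pd.DataFrame(rows, columns=raters,
                           index=pd.Index(ids, name="object_id"), dtype=object)
    return RatingPanel(ratings)


def write_labels(path, labels: pd.Series) -> None:
    """Latent/fused labels as a two-column CSV (object_id, label)."""
    df = labels.rename("label").to_frame()
    df.index.name = "object_id"
    df.to_csv(path)


def read_labels(path) -> pd.Series:
    df = pd.read_csv(path, dtype={"label": str})
    if list(df.columns) != ["object_id", "label"]:
        raise ParseError(f"{path}: expected columns object_id,label")
    return df.set_index("object_id")["label"]


# --- candidate tables ------------------------------------------------------

_CAND_COLS = ["object_id", "tile_id", "centroid_x_um", "centroid_y_um",
              "area_um2", "pixel_count"]
_CAND_OPT = ["stratum", "group"]


def write_candidates(path, table: pd.DataFrame) -> None:
    cols = [c for c in _CAND_COLS + _CAND_OPT if c in table.columns]
    missing = [c for c in _CAND_COLS if c not in table.columns]
    if missing:
        raise ValueError(f"candidate table lacks columns {missing}")
    table[cols].to_csv(path, index=False)


def read_candidates(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in _CAND_COLS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    if df["object_id"].duplicated().any():
        dup = df["object_id"][df["object_id"].duplicated()].iloc[0]
        raise ParseError(f"{path}: duplicate object id {dup!r}")
    return df


def read_candidate_set(path) -> CandidateSet:
    return CandidateSet(read_candidates(path), {"source": str(path)})


# --- images ----------------------------------------------------------------

def write_tile(path, tile: np.ndarray) -> None:
    """8-bit RGB tile as PNG or TIFF, by extension."""
    path = Path(path)
    arr = tile if tile.dtype == np.uint8 else quantize_tile(tile)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        Image.fromarray(arr).save(path)


def read_tile(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(path)
    return np.asarray(Image.open(path).convert("RGB"))


def write_label_mask(path, mask: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(mask, dtype=np.uint16))


def read_label_mask(path) -> np.ndarray:
    return tifffile.imread(path)


# --- ROI rectangles and affine transforms ----------------------------------

def read_rois(path) -> pd.DataFrame:
    """Hotspot rectangles: tile_id, x_um, y_um, width_um, height_um."""
    df = pd.read_csv(path)
    need = ["tile_id", "x_um", "y_um", "width_um", "height_um"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    return df


def read_affines(path) -> dict[str, np.ndarray]:
    """Per-tile-pair 2x3 affine transforms from a 6-number CSV row.

    Columns: tile_id, a11, a12, a21, a22, tx, ty.
    """
    df = pd.read_csv(path)
    need = ["tile_id", "a11", "a12", "a21", "a22", "tx", "ty"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    out = {}
    for _, r in df.iterrows():
        out[str(r["tile_id"])] = np.array([[r["a11"], r["a12"], r["tx"]],
                                           [r["a21"], r["a22"], r["ty"]]])
    return out
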