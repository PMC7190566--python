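import numpy as np
import pandas as pd
import pytest

from tumorbud import CandidateObject, RatingPanel, StainModel


@pytest.fixture(scope="session")
def stain() -> StainModel:
    return StainModel.hdab()


def make_candidates(areas, tile_id="t0"):
    """Candidate objects with prescribed areas (geometry irrelevant)."""
    px_area = 0.24 ** 2
    return [
        CandidateObject(object_id=i + 1, tile_id=tile_id,
                        centroid_um=(10.0 * i, 5.0), area_um2=float(a),
                        pixel_count=max(1, round(a / px_area)),
                        bbox=(0, 0, 1, 1))
        for i, a in enumerate(areas)
    ]


def make_pool(n_small, n_large, seed=0, boundary=1000.0):
    """Candidate table with n_small areas below and n_large above boundary."""
    rng = np.random.default_rng(seed)
    areas = np.concatenate([
        rng.uniform(25.0, boundary - 1e-6, n_small),
        rng.uniform(boundary, 5000.0, n_large),
    ])
    n = n_small + n_large
    return pd.DataFrame({
        "object_id": np.arange(1, n + 1),
        "tile_id": ["t0"] * n,
        "centroid_x_um": rng.uniform(0, 200, n),
        "centroid_y_um": rng.uniform(0, 200, n),
        "area_um2": areas,
        "pixel_count": np.maximum(1, np.round(areas / 0.24 ** 2)).astype(int),
    })


def panel_from_rows(rows, rater_prefix="R"):
    """RatingPanel from explicit per-object rating lists."""
    n = len(rows[0])
    ratings = pd.DataFrame(
        rows, columns=[f"{rater_prefix}{i+1}" for i in range(n)],
        index=pd.Index(range(1, len(rows) + 1), name="object_id"))
    return RatingPanel(ratings)
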