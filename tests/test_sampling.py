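import numpy as np
import pandas as pd
import pytest

from tumorbud import (CandidateObject, CandidateSet, extract_patch,
                      merge_candidate_sets, split_groups, stratify_sample,
                      transfer_coordinates)
from tumorbud.sampling import SamplingError, invert_affine
from conftest import make_pool

PX = 0.24


class TestStratifySample:
    def test_study_counts_from_sufficient_pool(self):
        pool = make_pool(2500, 400)
        cset = stratify_sample(pool, 1900, 300, seed=1)
        assert (cset.table["stratum"] == "small").sum() == 1900
        assert (cset.table["stratum"] == "large").sum() == 300

    def test_zero_request_gives_empty_set(self):
        cset = stratify_sample(make_pool(10, 10), 0, 0)
        assert len(cset) == 0

    def test_deficient_stratum_error_names_stratum(self):
        with pytest.raises(SamplingError, match="small"):
            stratify_sample(make_pool(10, 50), 11, 5)
        with pytest.raises(SamplingError, match="large"):
            stratify_sample(make_pool(50, 3), 10, 4)

    def test_boundary_value_goes_to_large_stratum(self):
        pool = make_pool(5, 0)
        pool.loc[0, "area_um2"] = 1000.0
        cset = stratify_sample(pool, 4, 1, boundary_um2=1000.0)
        large = cset.table[cset.table["stratum"] == "large"]
        assert list(large["area_um2"]) == [1000.0]

    def test_sampling_without_replacement_subset_of_pool(self):
        pool = make_pool(40, 20)
        cset = stratify_sample(pool, 30, 10, seed=3)
        assert cset.table["object_id"].is_unique
        assert set(cset.table["object_id"]) <= set(pool["object_id"])

    def test_selection_frequencies_are_uniform_across_seeds(self):
        # chi-square sanity: each of 12 small candidates picked ~equally often
        from scipy import stats

        pool = make_pool(12, 0)
        hits = np.zeros(12)
        for seed in range(300):
            cset = stratify_sample(pool, 6, 0, seed=seed)
            hits[cset.table["object_id"].to_numpy() - 1] += 1
        p = stats.chisquare(hits).pvalue
        assert p > 1e-4


class TestSplitGroups:
    def test_exact_disjoint_exhaustive_partition(self):
        cset = stratify_sample(make_pool(2500, 400), 1900, 300, seed=0)
        split = split_groups(cset, (1100, 1100), seed=5)
        counts = split.table["group"].value_counts()
        assert counts[1] == 1100 and counts[2] == 1100
        assert set(split.table["object_id"]) == set(cset.table["object_id"])

    def test_same_seed_same_partition(self):
        cset = stratify_sample(make_pool(60, 20), 40, 10, seed=0)
        a = split_groups(cset, (25, 25), seed=7).table["group"]
        b = split_groups(cset, (25, 25), seed=7).table["group"]
        assert a.equals(b)
        c = split_groups(cset, (25, 25), seed=8).table["group"]
        assert not a.equals(c)

    def test_size_mismatch_rejected(self):
        cset = stratify_sample(make_pool(30, 10), 20, 5, seed=0)
        with pytest.raises(SamplingError):
            split_groups(cset, (20, 10))

    def test_duplicate_ids_rejected_on_merge(self):
        a = CandidateSet(make_pool(5, 0))
        with pytest.raises(SamplingError):
            merge_candidate_sets(a, CandidateSet(make_pool(5, 0)))

    def test_merge_external_candidates(self):
        a = CandidateSet(make_pool(5, 0))
        b_tab = make_pool(3, 0, seed=1)
        b_tab["object_id"] += 100
        merged = merge_candidate_sets(a, CandidateSet(b_tab))
        assert len(merged) == 8


def obj_at(x_um, y_um):
    return CandidateObject(1, "t0", (x_um, y_um), 100.0, 1736, (0, 0, 1, 1))


class TestExtractPatch:
    def test_patch_side_in_pixels(self):
        tile = np.full((2000, 2000, 3), 200, dtype=np.uint8)
        p = extract_patch(tile, obj_at(240.0, 240.0), PX)
        assert p.image.shape == (1067, 1067, 3)  # round(256 / 0.24)

    def test_corner_object_padded_and_centered(self):
        tile = np.full((400, 400, 3), 111, dtype=np.uint8)
        p = extract_patch(tile, obj_at(1.2, 1.2), PX, side_um=48.0,
                          marker_area_mm2=0.0, background=255)
        side = p.image.shape[0]
        assert side == 200
        # CoM pixel sits at the patch center within half a pixel
        com_col = 1.2 / PX - 0.5
        patch_col = com_col - p.offset_um[0] / PX
        assert abs(patch_col - side // 2) <= 0.5
        assert (p.image[0, 0] == 255).all()          # padded corner
        assert (p.image[-1, -1] == 111).all()        # inside tile

    def test_interior_pixels_unchanged_except_marker(self):
        rng = np.random.default_rng(0)
        tile = rng.integers(0, 255, (800, 800, 3)).astype(np.uint8)
        obj = obj_at(96.0, 96.0)
        p = extract_patch(tile, obj, PX, side_um=96.0, marker_area_mm2=0.0003)
        side = p.image.shape[0]
        r0 = int(p.offset_um[1] / PX)
        c0 = int(p.offset_um[0] / PX)
        src = tile[r0:r0 + side, c0:c0 + side]
        marker = (p.image != src).any(axis=2)
        m_side = round(np.sqrt(0.0003) * 1000 / PX)  # 72 px outline
        assert marker.sum() == 4 * 2 * m_side - 4 * 2 * 2  # open square only
        assert (p.image[~marker] == src[~marker]).all()
        # the marker is an outline: its interior is untouched
        ctr = side // 2
        assert not marker[ctr - 10:ctr + 10, ctr - 10:ctr + 10].any()

    def test_marker_side_follows_area(self):
        # 0.03 mm^2 -> side sqrt(0.03) mm = 173.2 um
        assert round(np.sqrt(0.03) * 1000) == 173


class TestTransferCoordinates:
    IDENT = np.array([[1.0, 0, 0], [0, 1.0, 0]])

    def test_identity_leaves_object_unchanged(self):
        o = obj_at(12.0, 34.0)
        t = transfer_coordinates(o, self.IDENT)
        assert t.centroid_um == o.centroid_um
        assert t.area_um2 == o.area_um2 and t.pixel_count == o.pixel_count

    def test_translation_shifts_centroid(self):
        t = transfer_coordinates(obj_at(1.0, 2.0),
                                 np.array([[1.0, 0, 5.0], [0, 1.0, -3.0]]))
        assert t.centroid_um == pytest.approx((6.0, -1.0))

    def test_forward_inverse_roundtrip(self):
        aff = np.array([[0.98, 0.05, 12.0], [-0.04, 1.01, -7.5]])
        o = obj_at(123.4, 56.7)
        back = transfer_coordinates(transfer_coordinates(o, aff),
                                    invert_affine(aff))
        assert back.centroid_um == pytest.approx(o.centroid_um, abs=1e-9)

    def test_singular_transform_rejected(self):
        with pytest.raises(ValueError):
            transfer_coordinates(obj_at(0, 0),
                                 np.array([[1.0, 2.0, 0], [2.0, 4.0, 0]]))
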