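"""Annotation parsing, contour/mask conversion and consensus operations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nodulex as nx
from nodulex.annotations import (
    NODULE_LARGE,
    NON_NODULE,
    ReaderAnnotation,
    contours_to_mask,
    mask_to_contours,
    read_annotations,
    write_annotations,
)
from nodulex.consensus import build_consensus


def annotation_from_mask(mask, reader="r0", malignancy=3):
    return ReaderAnnotation.from_mask(reader, mask, malignancy)


def fresh_mask_annotation(mask, reader="r0", malignancy=3):
    """Annotation whose mask is re-rasterised from contours (no cache)."""
    ann = ReaderAnnotation.from_mask(reader, mask, malignancy)
    return ReaderAnnotation(
        reader_id=ann.reader_id,
        region_class=NODULE_LARGE,
        shape=ann.shape,
        slice_contours=ann.slice_contours,
        malignancy=ann.malignancy,
    )


class TestContourMaskConversion:
    @settings(deadline=None, max_examples=200)
    @given(st.integers(0, 2**32 - 1))
    def test_round_trip_is_exact_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((10, 10)) < rng.uniform(0.1, 0.9)
        if not mask.any():
            return
        rings = mask_to_contours(mask)
        np.testing.assert_array_equal(contours_to_mask(rings, mask.shape), mask)

    def test_rasterisation_from_contours_equals_source_mask_3d(self):
        rng = np.random.default_rng(5)
        mask = np.zeros((12, 12, 4), bool)
        mask[3:9, 2:10, 1:3] = rng.random((6, 8, 2)) < 0.7
        if not mask.any():
            pytest.skip("degenerate draw")
        ann = fresh_mask_annotation(mask)
        np.testing.assert_array_equal(ann.mask, mask)

    def test_too_short_contour_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            contours_to_mask([np.array([[0.0, 0.0], [1.0, 1.0]])], (4, 4))


class TestXmlDialect:
    def test_square_contour_mask_area(self, tmp_path):
        square = np.array(
            [[1.5, 1.5], [5.5, 1.5], [5.5, 5.5], [1.5, 5.5]], dtype=float
        )
        ann = ReaderAnnotation(
            reader_id="r0", region_class=NODULE_LARGE, shape=(10, 10, 3),
            slice_contours={1: [square]}, malignancy=2,
        )
        path = write_annotations(
            tmp_path / "a.xml", "P1", (10, 10, 3), (1, 1, 1), {"r0": [ann]}
        )
        parsed = read_annotations(path)
        assert len(parsed) == 1
        assert parsed[0].malignancy == 2
        assert parsed[0].mask.sum() == 16  # 4x4 pixel centres inside

    def test_non_nodule_point_round_trip(self, tmp_path):
        ann = ReaderAnnotation(
            reader_id="r1", region_class=NON_NODULE, shape=(10, 10, 3),
            point=(4.0, 5.0, 1.0),
        )
        path = write_annotations(
            tmp_path / "b.xml", "P1", (10, 10, 3), (1, 1, 1), {"r1": [ann]}
        )
        parsed = read_annotations(path)
        assert parsed[0].region_class == NON_NODULE
        assert parsed[0].point == (4.0, 5.0, 1.0)
        with pytest.raises(ValueError, match="no mask"):
            parsed[0].mask

    def test_malformed_xml_names_problem(self, tmp_path):
        bad = tmp_path / "bad.xml"
        bad.write_text("<LidcReadMessage")
        with pytest.raises(ValueError, match="malformed"):
            read_annotations(bad)

    def test_contract_masks_iff_large_nodule(self):
        with pytest.raises(ValueError, match="point-only"):
            ReaderAnnotation(
                reader_id="r", region_class=NON_NODULE, shape=(4, 4, 2),
                slice_contours={0: [np.zeros((3, 2))]}, point=(1, 1, 1),
            )
        with pytest.raises(ValueError, match="require contours"):
            ReaderAnnotation(
                reader_id="r", region_class=NODULE_LARGE, shape=(4, 4, 2),
                malignancy=3,
            )


class TestClusterOverlapping:
    def _mask(self, shape, box):
        m = np.zeros(shape, bool)
        m[box] = True
        return m

    def test_disjoint_masks_two_clusters(self):
        shape = (10, 10, 2)
        a = annotation_from_mask(self._mask(shape, (slice(0, 3), slice(0, 3), 0)))
        b = annotation_from_mask(self._mask(shape, (slice(6, 9), slice(6, 9), 0)))
        clusters = nx.cluster_overlapping([a, b])
        assert sorted(len(c) for c in clusters) == [1, 1]

    def test_transitive_chain_merges(self):
        shape = (12, 12, 1)
        a = annotation_from_mask(self._mask(shape, (slice(0, 4), slice(0, 4), 0)))
        b = annotation_from_mask(self._mask(shape, (slice(3, 7), slice(3, 7), 0)))
        c = annotation_from_mask(self._mask(shape, (slice(6, 10), slice(6, 10), 0)))
        assert not np.any(a.mask & c.mask)
        clusters = nx.cluster_overlapping([a, b, c])
        assert len(clusters) == 1 and len(clusters[0]) == 3

    def test_single_annotation_singleton(self):
        a = annotation_from_mask(self._mask((6, 6, 1), (slice(1, 3), slice(1, 3), 0)))
        assert nx.cluster_overlapping([a]) == [[a]]

    def test_matches_brute_force_on_random_masks(self):
        """Union-find clustering equals a brute-force transitive closure."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            anns = [
                annotation_from_mask(rng.random((6, 6, 2)) < 0.25, reader=f"r{i}")
                for i in range(5)
            ]
            anns = [a for a in anns if a.mask.any()]
            clusters = nx.cluster_overlapping(anns)
            # brute force: repeated merging until fixpoint
            groups = [{i} for i in range(len(anns))]
            changed = True
            while changed:
                changed = False
                for gi in range(len(groups)):
                    for gj in range(gi + 1, len(groups)):
                        if any(
                            np.any(anns[i].mask & anns[j].mask)
                            for i in groups[gi]
                            for j in groups[gj]
                        ):
                            groups[gi] |= groups[gj]
                            del groups[gj]
                            changed = True
                            break
                    if changed:
                        break
            expected = sorted(
                tuple(sorted(anns[i].reader_id for i in g)) for g in groups
            )
            got = sorted(
                tuple(sorted(a.reader_id for a in c)) for c in clusters
            )
            assert got == expected

    def test_cluster_voxel_sets_pairwise_disjoint(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            anns = [
                annotation_from_mask(rng.random((6, 6, 2)) < 0.2, reader=f"r{i}")
                for i in range(4)
            ]
            anns = [a for a in anns if a.mask.any()]
            clusters = nx.cluster_overlapping(anns)
            unions = [np.any([a.mask for a in c], axis=0) for c in clusters]
            for i in range(len(unions)):
                for j in range(i + 1, len(unions)):
                    assert not np.any(unions[i] & unions[j])


def vote_oracle(masks):
    """Exhaustive per-voxel vote: keep voxels in >= 50% of segmentations."""
    out = np.zeros(masks[0].shape, bool)
    for idx in np.ndindex(masks[0].shape):
        votes = sum(int(m[idx]) for m in masks)
        out[idx] = votes / len(masks) >= 0.5
    return out


class TestConsensusMask:
    def test_single_reader_identity(self):
        rng = np.random.default_rng(2)
        mask = rng.random((5, 5, 3)) < 0.4
        mask[2, 2, 1] = True
        ann = annotation_from_mask(mask)
        np.testing.assert_array_equal(nx.consensus_mask([ann]), mask)

    def test_half_vote_included_third_vote_excluded(self):
        shape = (4, 4, 1)
        base = np.zeros(shape, bool)
        base[1:3, 1:3, 0] = True
        lone = np.zeros(shape, bool)
        lone[0, 0, 0] = True
        # 4 readers, one voxel in exactly 2 of 4 -> included (2/4 >= 50%)
        masks4 = [base.copy() for _ in range(4)]
        masks4[0][3, 3, 0] = True
        masks4[1][3, 3, 0] = True
        cm = nx.consensus_mask([annotation_from_mask(m) for m in masks4])
        assert cm[3, 3, 0]
        # 3 readers, voxel in exactly 1 of 3 -> excluded (1/3 < 50%)
        masks3 = [base.copy() for _ in range(3)]
        masks3[0][0, 0, 0] = True
        cm = nx.consensus_mask([annotation_from_mask(m) for m in masks3])
        assert not cm[0, 0, 0]

    def test_exhaustive_vote_oracle_one_reader_2x2x3(self):
        """All 2^12 single-reader masks of a 2x2x3 grid match the oracle."""
        shape = (2, 2, 3)
        for bits in range(1, 2**12):
            mask = np.array(
                [(bits >> k) & 1 for k in range(12)], dtype=bool
            ).reshape(shape)
            ann = annotation_from_mask(mask)
            np.testing.assert_array_equal(
                nx.consensus_mask([ann]), vote_oracle([mask])
            )

    @settings(deadline=None, max_examples=300)
    @given(st.integers(2, 4), st.integers(0, 2**32 - 1))
    def test_vote_oracle_random_reader_combinations(self, n_readers, seed):
        """Random multi-reader mask combinations on 2x2x3 match the
        per-voxel vote oracle (the full product space is intractable)."""
        rng = np.random.default_rng(seed)
        masks = []
        for _ in range(n_readers):
            m = rng.random((2, 2, 3)) < rng.uniform(0.2, 0.8)
            if not m.any():
                m[0, 0, 0] = True
            masks.append(m)
        anns = [annotation_from_mask(m, reader=f"r{i}") for i, m in enumerate(masks)]
        np.testing.assert_array_equal(nx.consensus_mask(anns), vote_oracle(masks))

    def test_idempotent_on_own_output(self):
        rng = np.random.default_rng(3)
        masks = [rng.random((4, 4, 2)) < 0.5 for _ in range(3)]
        for m in masks:
            m[1, 1, 0] = True
        cm = nx.consensus_mask([annotation_from_mask(m) for m in masks])
        np.testing.assert_array_equal(
            nx.consensus_mask([annotation_from_mask(cm)]), cm
        )

    def test_pure_point_cluster_directs_to_auto_segment(self):
        ann = ReaderAnnotation(
            reader_id="r", region_class=NON_NODULE, shape=(4, 4, 2),
            point=(1, 1, 1),
        )
        with pytest.raises(ValueError, match="auto_segment"):
            nx.consensus_mask([ann])


class TestConsensusRating:
    def _slab(self, zs, shape=(6, 6, 6)):
        m = np.zeros(shape, bool)
        for z in zs:
            m[2:4, 2:4, z] = True
        return m

    def test_uniform_ratings_pass_through(self):
        anns = [
            annotation_from_mask(self._slab([1, 2]), reader=f"r{i}", malignancy=4)
            for i in range(3)
        ]
        cm = nx.consensus_mask(anns)
        assert nx.consensus_rating(anns, cm) == 4

    def test_mean_rounds_to_nearest(self):
        # ratings {4, 5, 5} on one shared slice: mean 4.667 -> 5
        anns = [
            annotation_from_mask(self._slab([1]), reader=f"r{i}", malignancy=m)
            for i, m in enumerate([4, 5, 5])
        ]
        cm = nx.consensus_mask(anns)
        assert nx.consensus_rating(anns, cm) == 5

    def test_rating_outside_consensus_slices_ignored(self):
        # two readers on slice 1 (consensus), a third only on slice 4
        anns = [
            annotation_from_mask(self._slab([1]), reader="r0", malignancy=2),
            annotation_from_mask(self._slab([1]), reader="r1", malignancy=2),
            annotation_from_mask(self._slab([4]), reader="r2", malignancy=5),
        ]
        cm = nx.consensus_mask(anns)  # slice 4 present in 1/3 < 50% -> absent
        assert not cm[:, :, 4].any()
        assert nx.consensus_rating(anns, cm) == 2

    def test_order_invariant(self):
        anns = [
            annotation_from_mask(self._slab([1, 2]), reader=f"r{i}", malignancy=m)
            for i, m in enumerate([1, 3, 5])
        ]
        cm = nx.consensus_mask(anns)
        assert nx.consensus_rating(anns, cm) == nx.consensus_rating(anns[::-1], cm)


class TestConsensusCentroid:
    def test_symmetric_mask_geometric_centre(self):
        m = np.zeros((7, 7, 3), bool)
        m[2:5, 2:5, 1] = True
        ann = annotation_from_mask(m)
        assert nx.consensus_centroid([ann]) == pytest.approx((3.0, 3.0, 1.0))

    def test_two_readers_mean_of_centroids(self):
        m1 = np.zeros((10, 10, 2), bool)
        m1[0:2, 0:2, 0] = True  # centroid (0.5, 0.5, 0)
        m2 = np.zeros((10, 10, 2), bool)
        m2[4:6, 4:6, 0] = True  # centroid (4.5, 4.5, 0)
        c = nx.consensus_centroid([annotation_from_mask(m1),
                                   annotation_from_mask(m2)])
        assert c == pytest.approx((2.5, 2.5, 0.0))

    def test_identical_masks_equal_own_centre_of_mass(self):
        from scipy import ndimage
        rng = np.random.default_rng(4)
        m = rng.random((8, 8, 3)) < 0.4
        m[4, 4, 1] = True
        anns = [annotation_from_mask(m, reader=f"r{i}") for i in range(3)]
        expected = ndimage.center_of_mass(m)
        assert nx.consensus_centroid(anns) == pytest.approx(expected)


class TestRatingCountStats:
    def _ann_on_slices(self, zs, reader):
        m = np.zeros((6, 6, 8), bool)
        for z in zs:
            m[2:4, 2:4, z] = True
        return annotation_from_mask(m, reader=reader)

    def test_max_and_mode(self):
        # per-slice counts [2, 2, 3] -> upper 3, estimate 2
        anns = [
            self._ann_on_slices([0, 1, 2], "r0"),
            self._ann_on_slices([0, 1, 2], "r1"),
            self._ann_on_slices([2], "r2"),
        ]
        assert nx.rating_count_stats(anns) == (3, 2)

    def test_tie_takes_larger_value(self):
        # per-slice counts [1, 1, 2, 2] -> estimate 2
        anns = [
            self._ann_on_slices([0, 1, 2, 3], "r0"),
            self._ann_on_slices([2, 3], "r1"),
        ]
        assert nx.rating_count_stats(anns) == (2, 2)

    def test_upper_bound_capped_at_four(self):
        # 6 ratings on one slice (merged complex nodule) -> upper reported 4
        anns = [self._ann_on_slices([0], f"r{i}") for i in range(6)]
        anns.append(self._ann_on_slices([1], "r6"))
        anns.append(self._ann_on_slices([1], "r7"))
        anns.append(self._ann_on_slices([1], "r8"))
        upper, estimate = nx.rating_count_stats(anns)
        assert upper == 4
        assert estimate == 6  # counts [6, 3]: both once, tie -> larger


class TestBuildConsensus:
    def test_groups_non_nodule_points(self):
        anns = [
            ReaderAnnotation(reader_id=f"r{i}", region_class=NON_NODULE,
                             shape=(20, 20, 5), point=(10.0 + i * 0.2, 10.0, 2.0))
            for i in range(3)
        ]
        nodules = build_consensus("P1", anns)
        assert len(nodules) == 1
        assert nodules[0].is_non_nodule
        assert nodules[0].mask is None
        assert nodules[0].centroid[0] == pytest.approx(10.2)
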