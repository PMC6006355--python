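"""Multi-reader consensus: overlap clustering, voting, ratings, centroids.

Several readers may each delineate the same physical nodule.  Annotations
from one patient are merged into clusters by transitive voxel overlap, and
each cluster is summarised by a >=50% consensus vote mask, a consensus
malignancy rating (mean over per-slice ratings on consensus slices,
rounded), the unweighted mean of the member centroids, and two rater-count
statistics (an upper bound capped at 4 and a modal estimate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .annotations import NODULE_LARGE, NON_NODULE, ReaderAnnotation

__all__ = [
    "ConsensusNodule",
    "cluster_overlapping",
    "consensus_mask",
    "consensus_rating",
    "consensus_centroid",
    "rating_count_stats",
    "build_consensus",
]

MAX_READERS = 4  # no more than four radiologists rate any single nodule


@dataclass
class ConsensusNodule:
    """A merged multi-reader nodule (or a point-only non-nodule region).

    ``rating`` is the consensus malignancy 1-5, or 0 for non-nodule
    regions (which carry no mask until auto-segmentation).  The two
    rater-count fields are independent statistics, not bounds on each
    other.
    """

    patient_id: str
    key: str
    mask: np.ndarray | None
    rating: int
    centroid: tuple[float, float, float]
    n_ratings_upper: int
    n_ratings_estimate: int
    member_annotations: list[ReaderAnnotation]

    @property
    def is_non_nodule(self) -> bool:
        return self.rating == 0


def cluster_overlapping(
    annotations: list[ReaderAnnotation],
) -> list[list[ReaderAnnotation]]:
    """Group contour annotations by transitive voxel overlap.

    Two annotations share a cluster iff they are connected by a chain of
    pairs whose masks share at least one voxel, so the resulting clusters'
    voxel sets are pairwise disjoint.
    """
    annotations = [a for a in annotations if a.region_class == NODULE_LARGE]
    n = len(annotations)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    masks = [a.mask for a in annotations]
    for i in range(n):
        for j in range(i + 1, n):
            if find(i) != find(j) and np.any(masks[i] & masks[j]):
                parent[find(i)] = find(j)

    groups: dict[int, list[ReaderAnnotation]] = {}
    for i, ann in enumerate(annotations):
        groups.setdefault(find(i), []).append(ann)
    return list(groups.values())


def consensus_mask(
    cluster: list[ReaderAnnotation],
    per_slice_denominator: bool = False,
) -> np.ndarray:
    """>=50% vote over the member segmentations of one cluster.

    A voxel is kept iff at least half of the available segmentations
    include it.  By default "available" is counted per nodule (all member
    segmentations); ``per_slice_denominator=True`` counts only the members
    that drew a contour on the voxel's slice.
    """
    members = [a for a in cluster if a.region_class == NODULE_LARGE]
    if not members:
        raise ValueError(
            "cluster has no segmentations; use qif.auto_segment for "
            "point-only (non-nodule) regions"
        )
    votes = np.zeros(members[0].shape, dtype=np.int32)
    for ann in members:
        votes += ann.mask
    if per_slice_denominator:
        denom = np.zeros(members[0].shape[2], dtype=np.int32)
        for ann in members:
            denom[ann.slices] += 1
        denom = np.maximum(denom, 1)[None, None, :]
        return votes * 2 >= denom
    return votes * 2 >= len(members)


def consensus_rating(
    cluster: list[ReaderAnnotation],
    consensus: np.ndarray,
    tie_half_up: bool = True,
) -> int:
    """Mean of per-slice malignancy ratings on consensus slices, rounded.

    One rating is collected per (member annotation, slice) pair for every
    slice where both the member and the consensus mask are present; the
    arithmetic mean is rounded to the nearest integer (exact .5 rounds
    away from zero by default) and clipped to [1, 5].
    """
    consensus_slices = set(np.nonzero(consensus.any(axis=(0, 1)))[0].tolist())
    ratings = [
        ann.malignancy
        for ann in cluster
        if ann.region_class == NODULE_LARGE
        for z in ann.slices
        if z in consensus_slices
    ]
    if not ratings:
        raise ValueError("no rated slices intersect the consensus mask")
    mean = float(np.mean(ratings))
    if tie_half_up:
        rounded = int(np.floor(mean + 0.5))
    else:
        rounded = int(round(mean))  # banker's rounding
    return int(np.clip(rounded, 1, 5))


def consensus_centroid(
    cluster: list[ReaderAnnotation],
) -> tuple[float, float, float]:
    """Unweighted mean of the member segmentations' centres of mass."""
    members = [a for a in cluster if a.region_class == NODULE_LARGE]
    if not members:
        raise ValueError("cluster has no segmentations")
    centroids = [ndimage.center_of_mass(ann.mask) for ann in members]
    return tuple(float(c) for c in np.mean(centroids, axis=0))


def rating_count_stats(cluster: list[ReaderAnnotation]) -> tuple[int, int]:
    """Rater-count statistics for one cluster.

    Returns ``(upper, estimate)``: the per-slice maximum number of ratings
    capped at 4 (merged complex nodules can exceed the true reader count),
    and the modal ratings-per-slice value, taking the larger value on ties.
    """
    members = [a for a in cluster if a.region_class == NODULE_LARGE]
    per_slice: dict[int, int] = {}
    for ann in members:
        for z in ann.slices:
            per_slice[z] = per_slice.get(z, 0) + 1
    if not per_slice:
        raise ValueError("cluster has no rated slices")
    counts = np.asarray(list(per_slice.values()))
    upper = int(min(MAX_READERS, counts.max()))
    values, freq = np.unique(counts, return_counts=True)
    # modal value; ties resolved toward the larger count value
    estimate = int(values[freq == freq.max()].max())
    return upper, estimate


def _group_non_nodule_points(
    annotations: list[ReaderAnnotation], merge_radius_vox: float = 5.0
) -> list[list[ReaderAnnotation]]:
    points = [a for a in annotations if a.region_class == NON_NODULE]
    n = len(points)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            d = np.linalg.norm(np.subtract(points[i].point, points[j].point))
            if d <= merge_radius_vox and find(i) != find(j):
                parent[find(i)] = find(j)
    groups: dict[int, list[ReaderAnnotation]] = {}
    for i, ann in enumerate(points):
        groups.setdefault(find(i), []).append(ann)
    return list(groups.values())


def build_consensus(
    patient_id: str,
    annotations: list[ReaderAnnotation],
    include_non_nodules: bool = True,
    per_slice_denominator: bool = False,
) -> list[ConsensusNodule]:
    """Produce the non-overlapping consensus nodule list for one patient.

    Contour annotations are clustered by voxel overlap and summarised;
    non-nodule point annotations are grouped by proximity into rating-0
    entries whose centroid is the mean marked point and whose mask is left
    to automated segmentation downstream.
    """
    out: list[ConsensusNodule] = []
    for i, cluster in enumerate(cluster_overlapping(annotations)):
        mask = consensus_mask(cluster, per_slice_denominator)
        out.append(
            ConsensusNodule(
                patient_id=patient_id,
                key=f"{patient_id}:N{i}",
                mask=mask,
                rating=consensus_rating(cluster, mask),
                centroid=consensus_centroid(cluster),
                n_ratings_upper=rating_count_stats(cluster)[0],
                n_ratings_estimate=rating_count_stats(cluster)[1],
                member_annotations=cluster,
            )
        )
    if include_non_nodules:
        for j, group in enumerate(_group_non_nodule_points(annotations)):
            centroid = tuple(
                float(c) for c in np.mean([a.point for a in group], axis=0)
            )
            out.append(
                ConsensusNodule(
                    patient_id=patient_id,
                    key=f"{patient_id}:X{j}",
                    mask=None,
                    rating=0,
                    centroid=centroid,
                    n_ratings_upper=min(MAX_READERS, len(group)),
                    n_ratings_estimate=len(group),
                    member_annotations=group,
                )
            )
    return out
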