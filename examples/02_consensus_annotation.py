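"""Merge multi-reader annotations into a consensus nodule.

Four simulated readers contour the same spherical nodule with boundary
jitter; the consensus mask keeps voxels included by at least half of the
segmentations, the consensus rating averages per-slice ratings on
consensus slices (rounded), and two statistics summarise how many readers
rated the nodule.
"""

import nodulex as nx

spec = nx.PhantomSpec(
    "P0001",
    nodules=(nx.NoduleTruth(center=(32.0, 32.0, 12.0), radius_mm=5.0,
                            true_malignancy=4),),
    rng_seed=7,
)
volume, masks = nx.generate_scan(spec)
readers = nx.SimulatedReaderSet(
    n_readers=4, contour_jitter_mm=0.8, rating_noise=0.3, rng_seed=7
)
annotations = nx.simulate_readers(masks[0], 4, readers)

clusters = nx.cluster_overlapping(annotations)
print(f"{len(annotations)} reader annotations merged into {len(clusters)} cluster(s)")

cluster = clusters[0]
consensus = nx.consensus_mask(cluster)
rating = nx.consensus_rating(cluster, consensus)
centroid = nx.consensus_centroid(cluster)
upper, estimate = nx.rating_count_stats(cluster)

print(f"truth mask:      {masks[0].sum()} voxels")
for ann in cluster:
    print(f"  {ann.reader_id}: {ann.mask.sum()} voxels, rating {ann.malignancy}")
print(f"consensus mask:  {consensus.sum()} voxels (>=50% vote)")
print(f"consensus rating {rating}  (true 4), centroid {tuple(round(c,1) for c in centroid)}")
print(f"raters: upper bound {upper}, modal estimate {estimate}")
# The consensus mask sits between the tightest and loosest reader contour,
# and the rating survives individual reader deviations.
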