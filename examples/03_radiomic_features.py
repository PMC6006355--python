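"""Extract the 50 radiomic (QIF) features from a segmented nodule.

All 2-D shape and texture features are computed on the transverse slice
with the largest in-mask area: geometry, first-order HU statistics,
difference-image statistics, gliding-box lacunarity at 10 box sizes, the
five NGTDM textures at distances 1 and 2, distance-to-surface summaries,
fractal dimensions and the boundary gradient.
"""

import nodulex as nx
from nodulex.qif import QIF_FEATURE_NAMES, SegmentedNodule

spec = nx.PhantomSpec(
    "P0001",
    nodules=(nx.NoduleTruth(center=(32.0, 32.0, 12.0), radius_mm=6.0,
                            heterogeneity=0.5, spiculation=0.2),),
    rng_seed=3,
)
volume, masks = nx.generate_scan(spec)
vector = nx.extract_qif(SegmentedNodule(volume.hu, masks[0], volume.spacing))

print(f"{len(vector)} features:")
for name, value in zip(QIF_FEATURE_NAMES, vector):
    print(f"  {name:<22} {value:12.4f}")
# Area/spans scale with the 6 mm radius; heterogeneity drives the HU
# spread, entropy and NGTDM contrast; spiculation lowers circularity.
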