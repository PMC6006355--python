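"""Generate a synthetic CT cohort with simulated multi-reader annotations.

Each patient gets one scan (Gaussian lung-parenchyma background around
-700 HU) containing one nodule; benign-like nodules are smaller and
smoother than malignant-like ones.  Four simulated readers re-draw every
nodule boundary with radial jitter and rate malignancy with occasional
+/-1 deviations, and everything is written to disk as raw volumes plus
LIDC-style XML.
"""

import tempfile
from pathlib import Path

import nodulex as nx

out_dir = Path(tempfile.mkdtemp(prefix="nodulex_cohort_"))
readers = nx.SimulatedReaderSet(
    n_readers=4, contour_jitter_mm=0.5, rating_noise=0.2
)
cohort = nx.generate_cohort(
    n_patients=10,
    class_mix={nx.BENIGN_LIKE: 0.5, nx.MALIGNANT_LIKE: 0.5},
    readers=readers,
    seed=42,
    out_dir=out_dir,
)

print(f"wrote {len(cohort.patients)} patients to {out_dir}")
for pid in cohort.patients[:4]:
    nod = cohort.truths[pid][0]
    ratings = [a.malignancy for a in cohort.annotations[pid]]
    print(
        f"  {pid}: {nod.true_class:<15} radius {nod.radius_mm:4.1f} mm, "
        f"true rating {nod.true_malignancy}, reader ratings {ratings}"
    )
# Reader ratings scatter around the true malignancy; the radius gap between
# the two classes is what downstream classifiers will have to pick up.
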