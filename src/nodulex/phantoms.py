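"""Synthetic CT phantoms: volumes, ground-truth nodules, simulated readers.

The generator emulates the inputs the rest of the pipeline expects from a
chest-CT annotation study: a lung-parenchyma background (Gaussian HU noise
around -700 HU), spherical nodules of elevated HU with controllable size,
contrast, texture heterogeneity and boundary spiculation, vessel-like
bright elongated structures standing in for "non-nodule" findings, and 1-4
simulated readers who re-draw each nodule boundary with radial jitter and
rate its malignancy with occasional +/-1 deviations.

Every output is a pure function of its spec and seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .annotations import (
    NODULE_LARGE,
    NON_NODULE,
    ReaderAnnotation,
    contours_to_mask,
    mask_to_contours,
    write_annotations,
)
from .volume import CTVolume

BENIGN_LIKE = "benign-like"
MALIGNANT_LIKE = "malignant-like"
TRUE_CLASSES = (BENIGN_LIKE, MALIGNANT_LIKE, NON_NODULE)

__all__ = [
    "BENIGN_LIKE",
    "MALIGNANT_LIKE",
    "TRUE_CLASSES",
    "NoduleTruth",
    "PhantomSpec",
    "SimulatedReaderSet",
    "SyntheticCohort",
    "generate_scan",
    "simulate_readers",
    "generate_cohort",
    "load_cohort",
]


@dataclass(frozen=True)
class NoduleTruth:
    """Ground truth for one simulated finding.

    ``heterogeneity`` scales multiplicative texture noise inside the
    nodule; ``spiculation`` scales angular roughness of the boundary
    (0 = exact sphere).  ``true_malignancy`` mirrors the 1 ("highly
    unlikely for cancer") to 5 ("highly suspicious for cancer") rating
    scale; it is carried but unused for ``non-nodule`` findings.
    """

    center: tuple[float, float, float]
    radius_mm: float
    contrast_hu: float = 500.0
    heterogeneity: float = 0.0
    spiculation: float = 0.0
    true_class: str = MALIGNANT_LIKE
    true_malignancy: int = 5

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")
        if not 1 <= int(self.true_malignancy) <= 5:
            raise ValueError("true_malignancy must be in [1, 5]")
        if self.true_class not in TRUE_CLASSES:
            raise ValueError(f"unknown true_class {self.true_class!r}")


@dataclass(frozen=True)
class PhantomSpec:
    """Specification of one synthetic scan."""

    patient_id: str
    volume_shape: tuple[int, int, int] = (64, 64, 24)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    background_hu: tuple[float, float] = (-700.0, 60.0)
    nodules: tuple[NoduleTruth, ...] = ()
    rng_seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodules", tuple(self.nodules))
        if any(n < 16 for n in self.volume_shape):
            raise ValueError("volume_shape must be >= 16 voxels per axis")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        for i, nod in enumerate(self.nodules):
            r_vox = [nod.radius_mm / s for s in self.spacing]
            for ax in range(3):
                lo = nod.center[ax] - r_vox[ax]
                hi = nod.center[ax] + r_vox[ax]
                if lo < 0 or hi > self.volume_shape[ax] - 1:
                    raise ValueError(
                        f"nodule {i} ({nod.true_class}, r={nod.radius_mm} mm) "
                        f"does not fit inside the volume along axis {ax}"
                    )


@dataclass(frozen=True)
class SimulatedReaderSet:
    """Configuration of the simulated radiologists.

    At most 4 readers, matching a four-radiologist annotation study.
    ``rating_noise`` is the probability that a reader's rating deviates
    from truth by +/-1 (clipped to [1, 5]).
    """

    n_readers: int = 4
    contour_jitter_mm: float = 0.5
    rating_noise: float = 0.2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_readers <= 4:
            raise ValueError("n_readers must be between 1 and 4")
        if self.contour_jitter_mm < 0 or not 0 <= self.rating_noise <= 1:
            raise ValueError("invalid reader-noise parameters")


def _smooth_angular_noise(rng: np.random.Generator, amplitude: float):
    """A smooth random function of direction, roughly unit-amplitude."""
    n_lobes = 6
    w = rng.normal(size=(n_lobes, 3))
    w /= np.linalg.norm(w, axis=1, keepdims=True)
    phase = rng.uniform(0, 2 * np.pi, size=n_lobes)
    amp = rng.uniform(0.5, 1.0, size=n_lobes)
    amp /= amp.sum()

    def f(u: np.ndarray) -> np.ndarray:
        # u: (..., 3) unit directions
        acc = np.zeros(u.shape[:-1])
        for k in range(n_lobes):
            acc += amp[k] * np.cos(4.0 * u @ w[k] + phase[k])
        return amplitude * acc

    return f


def _render_nodule(hu, mask_out, nod: NoduleTruth, spacing, rng) -> np.ndarray:
    """Render one nodule in place; return its ground-truth mask."""
    shape = hu.shape
    cx, cy, cz = nod.center
    r_vox = np.asarray([nod.radius_mm / s for s in spacing])
    pad = int(np.ceil(r_vox.max() * (1.0 + nod.spiculation) + 2))
    lo = [max(0, int(np.floor(c)) - pad) for c in nod.center]
    hi = [min(n, int(np.ceil(c)) + pad + 1) for c, n in zip(nod.center, shape)]
    gx, gy, gz = np.meshgrid(
        *[np.arange(lo[a], hi[a]) for a in range(3)], indexing="ij"
    )
    # displacement in mm from the centre
    dx = (gx - cx) * spacing[0]
    dy = (gy - cy) * spacing[1]
    dz = (gz - cz) * spacing[2]
    dist = np.sqrt(dx * dx + dy * dy + dz * dz)

    if nod.spiculation > 0:
        noise = _smooth_angular_noise(rng, nod.spiculation)
        with np.errstate(invalid="ignore", divide="ignore"):
            u = np.stack([dx, dy, dz], axis=-1) / np.maximum(dist, 1e-9)[..., None]
        radius = nod.radius_mm * (1.0 + noise(u))
    else:
        radius = nod.radius_mm

    local = dist <= radius
    if nod.heterogeneity > 0:
        tex = rng.standard_normal(local.shape)
        tex = ndimage.gaussian_filter(tex, sigma=1.0)
        sd = tex.std()
        if sd > 0:
            tex /= sd
        bump = nod.contrast_hu * (1.0 + nod.heterogeneity * tex)
    else:
        bump = np.full(local.shape, float(nod.contrast_hu))

    sub = tuple(slice(lo[a], hi[a]) for a in range(3))
    hu[sub][local] += bump[local]
    mask_out[sub] |= local
    full = np.zeros(shape, dtype=bool)
    full[sub] = local
    return full


def _render_vessel(hu, nod: NoduleTruth, spacing, rng) -> np.ndarray:
    """Render a bright elongated vessel-like structure; return its voxels."""
    shape = hu.shape
    direction = rng.normal(size=3)
    direction[2] *= 0.3  # vessels run mostly in-plane
    direction /= np.linalg.norm(direction)
    half_len = max(3.0 * nod.radius_mm, 6.0)
    grid = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    d = np.stack(
        [(grid[a] - nod.center[a]) * spacing[a] for a in range(3)], axis=-1
    )
    along = d @ direction
    radial = np.sqrt(np.maximum((d * d).sum(axis=-1) - along**2, 0.0))
    local = (np.abs(along) <= half_len) & (radial <= nod.radius_mm)
    if not local.any():  # degenerate geometry: keep at least the seed voxel
        local[tuple(int(round(c)) for c in nod.center)] = True
    hu[local] += nod.contrast_hu
    return local


def generate_scan(spec: PhantomSpec) -> tuple[CTVolume, list[np.ndarray]]:
    """Generate one synthetic scan and per-nodule ground-truth masks.

    Nodules are rendered as (possibly spiculated) spheres of elevated HU
    with multiplicative texture noise; non-nodule findings as bright
    elongated structures.  With ``spiculation=0`` the returned mask is
    exactly the set of lattice points within ``radius_mm`` of the centre.
    """
    rng = np.random.default_rng(spec.rng_seed)
    mean, sd = spec.background_hu
    hu = rng.normal(mean, sd, size=spec.volume_shape)
    rendered = np.zeros(spec.volume_shape, dtype=bool)
    masks: list[np.ndarray] = []
    for nod in spec.nodules:
        if nod.true_class == NON_NODULE:
            masks.append(_render_vessel(hu, nod, spec.spacing, rng))
        else:
            masks.append(_render_nodule(hu, rendered, nod, spec.spacing, rng))
    volume = CTVolume(hu=hu, spacing=spec.spacing, patient_id=spec.patient_id)
    return volume, masks


def _jitter_ring(ring: np.ndarray, sd_px: float, rng) -> np.ndarray:
    """Perturb a closed polygon radially with smoothed Gaussian noise."""
    center = ring.mean(axis=0)
    d = ring - center
    r = np.linalg.norm(d, axis=1)
    u = d / np.maximum(r, 1e-9)[:, None]
    noise = rng.normal(0.0, sd_px, size=len(ring))
    # circular smoothing so neighbouring vertices move coherently
    kernel = np.array([0.25, 0.5, 0.25])
    for _ in range(2):
        noise = (
            kernel[0] * np.roll(noise, 1)
            + kernel[1] * noise
            + kernel[2] * np.roll(noise, -1)
        )
    r_new = np.maximum(r + noise, np.maximum(0.35 * r, 0.51))
    return center + r_new[:, None] * u


def simulate_readers(
    truth_mask: np.ndarray,
    true_malignancy: int,
    readers: SimulatedReaderSet,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> list[ReaderAnnotation]:
    """Simulate per-reader contours and malignancy ratings for one nodule.

    Each reader re-draws every slice boundary with radial Gaussian jitter
    of sd ``contour_jitter_mm`` and reports ``true_malignancy`` perturbed
    by +/-1 with probability ``rating_noise`` (clipped to [1, 5]).
    Deterministic under the reader-set seed.
    """
    truth_mask = np.asarray(truth_mask, dtype=bool)
    if not truth_mask.any():
        raise ValueError("truth mask is empty")
    rng = np.random.default_rng(readers.rng_seed)
    sd_px = readers.contour_jitter_mm / float(np.mean(spacing[:2]))
    out: list[ReaderAnnotation] = []
    z_slices = np.nonzero(truth_mask.any(axis=(0, 1)))[0]
    base = {int(z): mask_to_contours(truth_mask[:, :, z]) for z in z_slices}
    for r in range(readers.n_readers):
        if readers.contour_jitter_mm == 0:
            contours = {z: [ring.copy() for ring in rings] for z, rings in base.items()}
            mask = truth_mask.copy()
        else:
            contours = {}
            mask = np.zeros(truth_mask.shape, dtype=bool)
            for z, rings in base.items():
                jittered = [_jitter_ring(ring, sd_px, rng) for ring in rings]
                filled = contours_to_mask(jittered, truth_mask.shape[:2])
                if not filled.any():  # jitter collapsed the slice; keep truth
                    jittered = [ring.copy() for ring in rings]
                    filled = truth_mask[:, :, z]
                contours[z] = jittered
                mask[:, :, z] = filled
        rating = int(true_malignancy)
        if rng.uniform() < readers.rating_noise:
            rating += int(rng.choice([-1, 1]))
        rating = int(np.clip(rating, 1, 5))
        ann = ReaderAnnotation(
            reader_id=f"reader-{r}",
            region_class=NODULE_LARGE,
            shape=truth_mask.shape,
            slice_contours=contours,
            malignancy=rating,
        )
        ann._mask = mask
        out.append(ann)
    return out


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

# Class-conditional nodule parameter distributions.  Malignant-like nodules
# are larger, more heterogeneous and more spiculated than benign-like ones;
# the radius gap is the main separability dial for downstream classifiers.
_CLASS_PARAMS = {
    BENIGN_LIKE: dict(radius=(3.0, 0.4), heterogeneity=0.15, spiculation=0.05,
                      ratings=(1, 2)),
    MALIGNANT_LIKE: dict(radius=(5.5, 0.6), heterogeneity=0.6, spiculation=0.3,
                         ratings=(4, 5)),
    NON_NODULE: dict(radius=(1.5, 0.2), heterogeneity=0.0, spiculation=0.0,
                     ratings=(3, 3)),
}


@dataclass
class SyntheticCohort:
    """A generated cohort: one scan per patient plus reader annotations."""

    patients: list[str]
    volumes: dict[str, CTVolume]
    truths: dict[str, list[NoduleTruth]]
    truth_masks: dict[str, list[np.ndarray]]
    annotations: dict[str, list[ReaderAnnotation]]
    readers: SimulatedReaderSet
    manifest: list[dict] = field(default_factory=list)


def _allocate_counts(n: int, proportions: dict[str, float]) -> dict[str, int]:
    """Largest-remainder allocation of n patients over classes."""
    items = sorted(proportions.items())
    raw = {c: n * p for c, p in items}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    leftover = n - sum(counts.values())
    by_frac = sorted(items, key=lambda cp: -(raw[cp[0]] - counts[cp[0]]))
    for c, _ in by_frac[:leftover]:
        counts[c] += 1
    return counts


def generate_cohort(
    n_patients: int,
    class_mix: dict[str, float],
    readers: SimulatedReaderSet,
    seed: int,
    volume_shape: tuple[int, int, int] = (64, 64, 24),
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    out_dir=None,
) -> SyntheticCohort:
    """Generate a cohort of synthetic patients, one scan each.

    ``class_mix`` maps true classes to proportions summing to 1; exact
    counts are assigned by largest remainder.  When ``out_dir`` is given,
    each scan is written as a raw-volume ``.npz``, its annotations as XML
    in the dialect :func:`nodulex.annotations.read_annotations` reads, and
    a ``manifest.csv`` maps patients to files.
    """
    if n_patients < 2:
        raise ValueError("need at least 2 patients to allow a patient-level split")
    total = sum(class_mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"class_mix proportions sum to {total}, expected 1")
    for cls in class_mix:
        if cls not in TRUE_CLASSES:
            raise ValueError(f"unknown class {cls!r} in class_mix")

    rng = np.random.default_rng(seed)
    counts = _allocate_counts(n_patients, class_mix)
    classes = [c for c, k in counts.items() for _ in range(k)]
    rng.shuffle(classes)

    cohort = SyntheticCohort(
        patients=[], volumes={}, truths={}, truth_masks={}, annotations={},
        readers=readers,
    )
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    for i, cls in enumerate(classes):
        pid = f"P{i:04d}"
        params = _CLASS_PARAMS[cls]
        radius = float(np.clip(rng.normal(*params["radius"]), 0.8, None))
        margin = radius / min(spacing) + 3
        center = tuple(
            float(rng.uniform(margin, volume_shape[a] - 1 - margin))
            for a in range(3)
        )
        rating = int(rng.choice(params["ratings"]))
        nod = NoduleTruth(
            center=center,
            radius_mm=radius,
            contrast_hu=500.0 if cls != NON_NODULE else 400.0,
            heterogeneity=params["heterogeneity"],
            spiculation=params["spiculation"],
            true_class=cls,
            true_malignancy=rating,
        )
        spec = PhantomSpec(
            patient_id=pid,
            volume_shape=volume_shape,
            spacing=spacing,
            nodules=(nod,),
            rng_seed=int(rng.integers(0, 2**31 - 1)),
        )
        volume, masks = generate_scan(spec)
        reader_seed = int(rng.integers(0, 2**31 - 1))
        patient_readers = replace(readers, rng_seed=reader_seed)
        if cls == NON_NODULE:
            anns = [
                ReaderAnnotation(
                    reader_id=f"reader-{r}",
                    region_class=NON_NODULE,
                    shape=volume_shape,
                    point=center,
                )
                for r in range(readers.n_readers)
            ]
        else:
            anns = simulate_readers(masks[0], rating, patient_readers, spacing)

        cohort.patients.append(pid)
        cohort.volumes[pid] = volume
        cohort.truths[pid] = [nod]
        cohort.truth_masks[pid] = masks
        cohort.annotations[pid] = anns

        if out_dir is not None:
            vol_path = volume.save(out_dir / f"{pid}.volume.npz")
            sessions: dict[str, list[ReaderAnnotation]] = {}
            for ann in anns:
                sessions.setdefault(ann.reader_id, []).append(ann)
            xml_path = write_annotations(
                out_dir / f"{pid}.xml", pid, volume_shape, spacing, sessions
            )
            cohort.manifest.append(
                dict(patient_id=pid, true_class=cls, volume=str(vol_path),
                     xml=str(xml_path))
            )

    if out_dir is not None and cohort.manifest:
        with open(out_dir / "manifest.csv", "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(cohort.manifest[0]))
            writer.writeheader()
            writer.writerows(cohort.manifest)
    return cohort


def load_cohort(cohort_dir) -> SyntheticCohort:
    """Load a previously written cohort directory (manifest + npz + XML)."""
    from .annotations import read_annotations

    cohort_dir = Path(cohort_dir)
    manifest_path = cohort_dir / "manifest.csv"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.csv in {cohort_dir}")
    with open(manifest_path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    cohort = SyntheticCohort(
        patients=[], volumes={}, truths={}, truth_masks={}, annotations={},
        readers=SimulatedReaderSet(), manifest=rows,
    )
    for row in rows:
        pid = row["patient_id"]
        cohort.patients.append(pid)
        cohort.volumes[pid] = CTVolume.load(row["volume"])
        cohort.annotations[pid] = read_annotations(row["xml"])
    return cohort
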