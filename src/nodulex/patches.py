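"""Centroid-centred CT patch extraction and HDF5 train/validation datasets.

A patch is a fixed-size X x Y x Z HU sub-volume centred on the rounded
nodule centroid, stored together with the consensus malignancy rating (0
for non-nodule regions), the whole-scan minimum/maximum HU (used for
intensity normalisation downstream), a binary class id, the patient id and
a stable nodule key shared with the radiomic feature table.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np

from .selection import SelectedNodule
from .volume import CTVolume

SUPPORTED_SIZES = ((47, 47, 5), (21, 21, 5), (21, 21, 3), (31, 31, 3))

__all__ = ["PatchSize", "PatchRecord", "extract_patch", "build_dataset",
           "read_dataset", "SUPPORTED_SIZES"]


@dataclass(frozen=True)
class PatchSize:
    """Patch shape in pixels (x, y) and slices (z).

    The centre voxel index along each axis is ``floor(size/2)``;
    continuous centroids are rounded half-up per axis before cropping.
    """

    x: int
    y: int
    z: int

    def __post_init__(self) -> None:
        if (self.x, self.y, self.z) not in SUPPORTED_SIZES:
            raise ValueError(
                f"unsupported patch size {(self.x, self.y, self.z)}; "
                f"supported: {SUPPORTED_SIZES}"
            )

    @classmethod
    def parse(cls, text: str) -> "PatchSize":
        return cls(*(int(t) for t in text.lower().split("x")))

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.x, self.y, self.z)


@dataclass
class PatchRecord:
    voxels: np.ndarray  # (x, y, z) HU array
    rating: int  # consensus malignancy 1-5, or 0 for non-nodule
    scan_min_hu: float
    scan_max_hu: float
    class_id: int
    patient_id: str
    centroid: tuple[float, float, float]
    key: str = ""

    def __post_init__(self) -> None:
        if self.scan_min_hu > self.scan_max_hu:
            raise ValueError("scan_min_hu must not exceed scan_max_hu")


def extract_patch(
    volume: CTVolume,
    centroid: tuple[float, float, float],
    size: PatchSize,
    pad_value: float | None = None,
    rating: int = 0,
    class_id: int = 0,
    key: str = "",
) -> PatchRecord:
    """Crop an axis-aligned patch whose centre voxel is the rounded centroid.

    Voxels falling outside the scan are filled with ``pad_value`` (default:
    the scan's minimum HU, mimicking air).  The record carries the
    whole-scan HU extremes, not the patch's.
    """
    if not volume.contains(centroid):
        raise ValueError(f"centroid {centroid} lies outside the volume")
    if any(s > n for s, n in zip(size.shape, volume.shape)):
        raise ValueError(
            f"patch size {size.shape} exceeds volume shape {volume.shape}"
        )
    scan_min = float(volume.hu.min())
    scan_max = float(volume.hu.max())
    if pad_value is None:
        pad_value = scan_min

    center = [int(np.floor(c + 0.5)) for c in centroid]
    out = np.full(size.shape, pad_value, dtype=volume.hu.dtype)
    src, dst = [], []
    for ax, (c, s, n) in enumerate(zip(center, size.shape, volume.shape)):
        lo = c - s // 2
        hi = lo + s
        src.append(slice(max(lo, 0), min(hi, n)))
        dst.append(slice(max(lo, 0) - lo, s - (hi - min(hi, n))))
    out[tuple(dst)] = volume.hu[tuple(src)]
    return PatchRecord(
        voxels=out,
        rating=int(rating),
        scan_min_hu=scan_min,
        scan_max_hu=scan_max,
        class_id=int(class_id),
        patient_id=volume.patient_id,
        centroid=tuple(float(c) for c in centroid),
        key=key,
    )


def records_for_selection(
    selection: list[SelectedNodule],
    volumes: dict[str, CTVolume],
    size: PatchSize,
) -> list[PatchRecord]:
    """Extract one patch per selected nodule from its patient's scan."""
    return [
        extract_patch(
            volumes[s.patient_id],
            s.nodule.centroid,
            size,
            rating=s.nodule.rating,
            class_id=s.label,
            key=s.key,
        )
        for s in selection
    ]


def _write_h5(path: Path, records: list[PatchRecord], size: PatchSize) -> None:
    n = len(records)
    with h5py.File(path, "w") as f:
        f.attrs["patch_size"] = size.shape
        # stored slice-major (N, Z, Y, X); in-memory records are (X, Y, Z)
        f.create_dataset(
            "patches",
            data=np.stack([r.voxels.transpose(2, 1, 0) for r in records])
            if n
            else np.zeros((0, size.z, size.y, size.x)),
            chunks=(1, size.z, size.y, size.x) if n else None,
        )
        f.create_dataset("ratings", data=np.asarray([r.rating for r in records]))
        f.create_dataset("class_ids", data=np.asarray([r.class_id for r in records]))
        f.create_dataset("scan_min", data=np.asarray([r.scan_min_hu for r in records]))
        f.create_dataset("scan_max", data=np.asarray([r.scan_max_hu for r in records]))
        f.create_dataset("centroids", data=np.asarray([r.centroid for r in records]))
        str_dt = h5py.string_dtype()
        f.create_dataset(
            "patient_ids", data=[r.patient_id for r in records], dtype=str_dt
        )
        f.create_dataset("keys", data=[r.key for r in records], dtype=str_dt)


def build_dataset(
    train: list[SelectedNodule],
    validation: list[SelectedNodule],
    volumes: dict[str, CTVolume],
    size: PatchSize,
    out_dir,
    seed: int = 0,
) -> tuple[Path, Path]:
    """Write shuffled train/validation patch datasets as two HDF5 files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    paths = []
    for name, selection in (("train", train), ("validation", validation)):
        records = records_for_selection(selection, volumes, size)
        keys = [r.key for r in records]
        if len(set(keys)) != len(keys):
            dup = sorted({k for k in keys if keys.count(k) > 1})
            raise ValueError(f"duplicate nodule keys in {name} set: {dup}")
        order = rng.permutation(len(records))
        path = out_dir / f"{name}.h5"
        _write_h5(path, [records[i] for i in order], size)
        paths.append(path)
    return tuple(paths)  # type: ignore[return-value]


def read_dataset(path) -> list[PatchRecord]:
    """Read an HDF5 patch dataset back into records (lossless round-trip)."""
    out: list[PatchRecord] = []
    with h5py.File(path, "r") as f:
        n = f["patches"].shape[0]
        for i in range(n):
            out.append(
                PatchRecord(
                    voxels=np.asarray(f["patches"][i]).transpose(2, 1, 0),
                    rating=int(f["ratings"][i]),
                    scan_min_hu=float(f["scan_min"][i]),
                    scan_max_hu=float(f["scan_max"][i]),
                    class_id=int(f["class_ids"][i]),
                    patient_id=f["patient_ids"][i].decode(),
                    centroid=tuple(f["centroids"][i]),
                    key=f["keys"][i].decode(),
                )
            )
    return out
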