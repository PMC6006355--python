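"""CT volume container and raw-volume file I/O.

Conventions used throughout the package (documented in the README):

* voxel arrays are indexed ``[x, y, z]`` where ``x`` is the column, ``y``
  the row and ``z`` the transverse slice, all 0-based;
* coordinates are ``(x, y, z)`` tuples in the same order;
* ``spacing`` is millimetres per voxel along ``(x, y, z)``;
* intensities are Hounsfield units (air ~ -1000 HU, water = 0 HU).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["CTVolume"]


@dataclass
class CTVolume:
    """A CT scan: an HU voxel grid plus geometry and rescale metadata.

    ``rescale_slope``/``rescale_intercept`` record how stored integers map
    to HU (``hu = slope * stored + intercept``); the array held here is
    always already in HU, the metadata is carried for provenance only.
    """

    hu: np.ndarray
    spacing: tuple[float, float, float]
    patient_id: str
    rescale_slope: float = 1.0
    rescale_intercept: float = 0.0

    def __post_init__(self) -> None:
        self.hu = np.asarray(self.hu)
        if self.hu.ndim != 3:
            raise ValueError("CT volume must be a 3-D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive mm/voxel values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.hu.shape  # type: ignore[return-value]

    def contains(self, point) -> bool:
        """True if the continuous ``(x, y, z)`` point lies inside the grid."""
        return all(0 <= p <= n - 1 for p, n in zip(point, self.shape))

    def save(self, path) -> Path:
        """Write the volume to a single ``.npz`` container."""
        path = Path(path)
        np.savez_compressed(
            path,
            hu=self.hu,
            spacing=np.asarray(self.spacing, dtype=float),
            patient_id=np.asarray(self.patient_id),
            rescale=np.asarray([self.rescale_slope, self.rescale_intercept]),
        )
        # np.savez appends .npz when missing; normalise the return value
        return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")

    @classmethod
    def load(cls, path) -> "CTVolume":
        with np.load(path, allow_pickle=False) as f:
            return cls(
                hu=f["hu"],
                spacing=tuple(f["spacing"]),
                patient_id=str(f["patient_id"]),
                rescale_slope=float(f["rescale"][0]),
                rescale_intercept=float(f["rescale"][1]),
            )
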