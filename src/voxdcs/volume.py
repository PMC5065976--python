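"""Voxel lattices: grid geometry, label volumes, conductivity volumes, I/O.

Axis convention: axis 0 = x (mediolateral), axis 1 = y (dorsoventral,
anterior toward +y), axis 2 = z (longitudinal / cranio-caudal, cranial toward
+z).  Voxel indices are 0-based; physical coordinates refer to voxel centers,
``coord = origin + index * spacing`` (mm).  Spacing is uniform and identical
across axes within a volume.

Label volumes serialise to NIfTI-1 (int16) with a JSON sidecar carrying the
ID->tissue-name map plus any named landmarks and longitudinal segment bounds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .catalogue import TissueCatalogue, default_catalogue

__all__ = [
    "GridSpec",
    "LabelVolume",
    "ConductivityVolume",
    "build_sigma_volume",
    "tissue_volume",
]


@dataclass(frozen=True)
class GridSpec:
    """Uniform rectilinear voxel grid.

    Parameters
    ----------
    shape :
        Voxel counts per axis (3 positive integers).
    spacing :
        Voxel edge length in mm, identical across axes.
    origin :
        Physical coordinate (mm) of the center of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) <= 0 for n in self.shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")
        if self.spacing <= 0:
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))

    @property
    def voxel_volume_mm3(self) -> float:
        return self.spacing**3

    def coords(self, axis: int) -> np.ndarray:
        """Physical center coordinates (mm) along ``axis``."""
        return self.origin[axis] + self.spacing * np.arange(self.shape[axis])

    def affine(self) -> np.ndarray:
        aff = np.diag([self.spacing] * 3 + [1.0])
        aff[:3, 3] = self.origin
        return aff


@dataclass
class LabelVolume:
    """Lattice of integer tissue IDs on a :class:`GridSpec`.

    ``labels`` is int16 with ID 0 reserved for exterior air.  ``landmarks``
    maps named anatomical points (e.g. ``"inion"``, ``"t10"``) to voxel
    indices; ``segments`` maps named longitudinal segments (e.g.
    ``"thoracic"``) to inclusive z-index ranges ``(z0, z1)``.
    """

    grid: GridSpec
    labels: np.ndarray
    catalogue: TissueCatalogue = field(default_factory=default_catalogue)
    landmarks: dict[str, tuple[int, int, int]] = field(default_factory=dict)
    segments: dict[str, tuple[int, int]] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int16)
        if self.labels.shape != self.grid.shape:
            raise ValueError(
                f"labels shape {self.labels.shape} != grid shape {self.grid.shape}"
            )

    def copy(self) -> "LabelVolume":
        return LabelVolume(
            grid=self.grid,
            labels=self.labels.copy(),
            catalogue=self.catalogue,
            landmarks=dict(self.landmarks),
            segments=dict(self.segments),
            meta=dict(self.meta),
        )

    def mask(self, name: str) -> np.ndarray:
        """Boolean mask of voxels labeled with tissue ``name``."""
        return self.labels == self.catalogue.tissue_id(name)

    def present_tissues(self) -> list[str]:
        ids = np.unique(self.labels)
        names = self.catalogue.id_map()
        return [names[int(i)] for i in ids]

    # --- I/O ----------------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write NIfTI label volume plus JSON sidecar (ids, landmarks, segments)."""
        path = Path(path)
        img = nib.Nifti1Image(self.labels.astype(np.int16), self.grid.affine())
        img.header.set_zooms((self.grid.spacing,) * 3)
        nib.save(img, path)
        sidecar = {
            "id_map": {str(k): v for k, v in self.catalogue.id_map().items()},
            "landmarks": {k: list(v) for k, v in self.landmarks.items()},
            "segments": {k: list(v) for k, v in self.segments.items()},
            "meta": self.meta,
        }
        _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "LabelVolume":
        path = Path(path)
        img = nib.load(path)
        labels = np.asarray(img.dataobj, dtype=np.int16)
        aff = img.affine
        spacing = float(aff[0, 0])
        grid = GridSpec(shape=labels.shape, spacing=spacing, origin=tuple(aff[:3, 3]))
        landmarks: dict[str, tuple[int, int, int]] = {}
        segments: dict[str, tuple[int, int]] = {}
        meta: dict = {}
        sc = _sidecar_path(path)
        if sc.exists():
            side = json.loads(sc.read_text())
            landmarks = {k: tuple(v) for k, v in side.get("landmarks", {}).items()}
            segments = {k: tuple(v) for k, v in side.get("segments", {}).items()}
            meta = side.get("meta", {})
        return cls(grid=grid, labels=labels, landmarks=landmarks,
                   segments=segments, meta=meta)


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


@dataclass
class ConductivityVolume:
    """Per-voxel DC conductivity sigma (S/m) on a :class:`GridSpec`."""

    grid: GridSpec
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, dtype=np.float64)
        if self.sigma.shape != self.grid.shape:
            raise ValueError(
                f"sigma shape {self.sigma.shape} != grid shape {self.grid.shape}"
            )
        if np.any(self.sigma < 0):
            raise ValueError("negative conductivity in volume")

    def save(self, path: str | Path) -> None:
        img = nib.Nifti1Image(self.sigma.astype(np.float32), self.grid.affine())
        img.header.set_zooms((self.grid.spacing,) * 3)
        nib.save(img, path)


def build_sigma_volume(
    labels: LabelVolume, catalogue: TissueCatalogue | None = None
) -> ConductivityVolume:
    """Map tissue IDs to per-voxel conductivity.

    Exterior air (ID 0) and internal air tissues map to sigma = 0.

    Raises
    ------
    KeyError
        If the lattice contains IDs absent from the catalogue, listing them.
    """
    catalogue = catalogue or labels.catalogue
    sigma_by_id = catalogue.sigma_by_id()
    present = np.unique(labels.labels)
    missing = [int(i) for i in present if int(i) not in sigma_by_id]
    if missing:
        raise KeyError(f"label IDs without catalogue entry: {missing}")
    lut = np.zeros(max(sigma_by_id) + 1, dtype=np.float64)
    for tid, s in sigma_by_id.items():
        lut[tid] = s
    return ConductivityVolume(grid=labels.grid, sigma=lut[labels.labels])


def tissue_volume(labels: LabelVolume, name: str) -> float:
    """Volume (cm³) of tissue ``name``: voxel count times voxel volume.

    An absent tissue returns 0.
    """
    try:
        tid = labels.catalogue.tissue_id(name)
    except KeyError:
        return 0.0
    count = int(np.count_nonzero(labels.labels == tid))
    return count * labels.grid.voxel_volume_mm3 / 1000.0
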