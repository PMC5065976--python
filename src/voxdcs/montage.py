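"""Pad + sponge electrode model and montage construction.

An electrode is a thin metallic pad (default 1 mm, sigma = 5.9e7 S/m) on a
saline sponge (default 5 mm, sigma = 0.3 S/m) of the same footprint.  The
stack is placed conformally: for each footprint column along the outward
surface-normal axis, the sponge layers start at the outermost skin voxel and
the pad layers sit on the sponge, so the electrode follows the curved scalp
or back.  The pad voxels form the Dirichlet set handed to the solver; the
sponge is an ordinary conducting tissue.

Footprint membership uses the voxel-center rule: a surface column belongs to
the footprint if its center falls inside the (possibly rotated) rectangle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .catalogue import PAD, SPONGE
from .volume import LabelVolume

__all__ = [
    "ElectrodeSpec",
    "Placement",
    "Montage",
    "place_electrode",
    "build_montage",
    "plate_electrodes",
    "CTDCS_CURRENT",
    "TSDCS_CURRENT",
]

CTDCS_CURRENT = 2e-3  # A, cerebellar montage
TSDCS_CURRENT = 3e-3  # A, spinal montage

_AXES = {"+x": (0, 1), "-x": (0, -1), "+y": (1, 1), "-y": (1, -1),
         "+z": (2, 1), "-z": (2, -1)}


class MontageError(ValueError):
    """Electrode placement inconsistent with the phantom surface."""


@dataclass(frozen=True)
class ElectrodeSpec:
    """Rectangular pad + sponge electrode (dimensions in mm)."""

    width: float = 50.0
    height: float = 50.0
    pad_thickness: float = 1.0
    sponge_thickness: float = 5.0
    pad_conductivity: float = 5.9e7
    sponge_conductivity: float = 0.3
    role: str = "active"

    def __post_init__(self) -> None:
        for name in ("width", "height", "pad_thickness", "sponge_thickness",
                     "pad_conductivity", "sponge_conductivity"):
            if getattr(self, name) <= 0:
                raise MontageError(f"{name} must be positive")


@dataclass(frozen=True)
class Placement:
    """Where an electrode sits on the body surface.

    ``anchor`` is a landmark name defined by the phantom or an explicit voxel
    index triple; ``normal_axis`` is the outward surface-normal direction
    (one of ``+x -x +y -y +z -z``); ``orientation_deg`` rotates the footprint
    in the surface plane.
    """

    anchor: str | tuple[int, int, int]
    normal_axis: str
    orientation_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.normal_axis not in _AXES:
            raise MontageError(f"normal_axis must be one of {sorted(_AXES)}")


@dataclass(frozen=True)
class Montage:
    """Active + reference electrode pair and the target injected current (A)."""

    active: ElectrodeSpec
    active_placement: Placement
    reference: ElectrodeSpec
    reference_placement: Placement
    target_current: float = CTDCS_CURRENT

    def __post_init__(self) -> None:
        if self.target_current <= 0:
            raise MontageError("target current must be positive")


def _resolve_anchor(labels: LabelVolume, anchor) -> tuple[int, int, int]:
    if isinstance(anchor, str):
        if anchor not in labels.landmarks:
            raise MontageError(
                f"unknown landmark {anchor!r}; phantom defines "
                f"{sorted(labels.landmarks)}"
            )
        return tuple(labels.landmarks[anchor])
    return tuple(int(v) for v in anchor)


def place_electrode(
    labels: LabelVolume, spec: ElectrodeSpec, placement: Placement
) -> tuple[LabelVolume, np.ndarray]:
    """Place one electrode; returns (new volume, pad voxel mask).

    Raises :class:`MontageError` if any footprint column misses the skin
    surface or the stack would collide with the body or another electrode.
    """
    out = labels.copy()
    cat = out.catalogue
    skin_ids = {cat.tissue_id("Skin"), cat.tissue_id("Ear skin")}
    pad_id, sponge_id = cat.tissue_id(PAD), cat.tissue_id(SPONGE)
    air_id = 0
    grid = out.grid
    h = grid.spacing

    n_axis, n_sign = _AXES[placement.normal_axis]
    u_axis, v_axis = [a for a in range(3) if a != n_axis]
    anchor = _resolve_anchor(out, placement.anchor)

    # footprint membership in the (u, v) plane, rotated by orientation
    theta = np.deg2rad(placement.orientation_deg)
    cu = np.arange(grid.shape[u_axis])[:, None]
    cv = np.arange(grid.shape[v_axis])[None, :]
    du = (cu - anchor[u_axis]) * h
    dv = (cv - anchor[v_axis]) * h
    ru = du * np.cos(theta) + dv * np.sin(theta)
    rv = -du * np.sin(theta) + dv * np.cos(theta)
    inside = (np.abs(ru) <= spec.width / 2) & (np.abs(rv) <= spec.height / 2)

    lab = np.moveaxis(out.labels, (u_axis, v_axis, n_axis), (0, 1, 2))
    if n_sign < 0:  # make "outward" the +index direction of the view
        lab = lab[:, :, ::-1]
    nz = lab.shape[2]
    n_sponge = max(1, round(spec.sponge_thickness / h))
    n_pad = max(1, round(spec.pad_thickness / h))

    body = (lab != air_id) & (lab != pad_id) & (lab != sponge_id)
    electrode = (lab == pad_id) | (lab == sponge_id)
    cols = np.argwhere(inside)
    pad_mask_view = np.zeros_like(lab, dtype=bool)
    for iu, iv in cols:
        col_body = np.nonzero(body[iu, iv])[0]
        if col_body.size == 0:
            raise MontageError(
                "electrode footprint extends beyond the body surface"
            )
        top = int(col_body.max())
        if lab[iu, iv, top] not in skin_ids:
            raise MontageError(
                "electrode footprint over a non-skin surface voxel"
            )
        lo, hi = top + 1, top + 1 + n_sponge + n_pad
        if hi > nz:
            raise MontageError("electrode stack exceeds the bounding box")
        seg = lab[iu, iv, lo:hi]
        if np.any(electrode[iu, iv, lo:hi]):
            raise MontageError("electrode overlaps an existing electrode")
        if np.any(seg != air_id):
            raise MontageError("electrode stack collides with the body")
        lab[iu, iv, lo : lo + n_sponge] = sponge_id
        lab[iu, iv, lo + n_sponge : hi] = pad_id
        pad_mask_view[iu, iv, lo + n_sponge : hi] = True

    if n_sign < 0:
        lab = lab[:, :, ::-1]
        pad_mask_view = pad_mask_view[:, :, ::-1]
    out.labels = np.moveaxis(lab, (0, 1, 2), (u_axis, v_axis, n_axis)).copy()
    pad_mask = np.moveaxis(pad_mask_view, (0, 1, 2), (u_axis, v_axis, n_axis)).copy()
    return out, pad_mask


def build_montage(
    labels: LabelVolume, montage: Montage
) -> tuple[LabelVolume, np.ndarray, np.ndarray, float]:
    """Place both electrodes; returns (volume, anode mask, cathode mask, I_target).

    The anode is the active pad (current enters the body there), the cathode
    the reference pad.
    """
    vol, anode = place_electrode(labels, montage.active, montage.active_placement)
    vol, cathode = place_electrode(
        vol, montage.reference, montage.reference_placement
    )
    if np.any(anode & cathode):
        raise MontageError("anode and cathode overlap")
    return vol, anode, cathode, montage.target_current


def plate_electrodes(
    labels: LabelVolume, axis: int = 2
) -> tuple[LabelVolume, np.ndarray, np.ndarray]:
    """Full-face plate electrodes on the two opposite faces along ``axis``.

    Calibration helper: adds one pad layer over every conducting voxel of the
    first and last slice along ``axis`` (grown by one slice), giving the
    uniform-field and layered-slab fixtures their ideal plate boundary.
    Returns (volume, anode mask on the high face, cathode mask on the low face).
    """
    out = labels.copy()
    cat = out.catalogue
    pad_id = cat.tissue_id(PAD)
    shape = list(out.grid.shape)
    shape[axis] += 2
    new = np.zeros(shape, dtype=np.int16)
    sl = [slice(None)] * 3
    sl[axis] = slice(1, -1)
    new[tuple(sl)] = out.labels

    def face(idx_new, idx_old):
        sl_old = [slice(None)] * 3
        sl_old[axis] = idx_old
        conducting = out.labels[tuple(sl_old)] != 0
        sl_new = [slice(None)] * 3
        sl_new[axis] = idx_new
        plate = np.zeros(shape, dtype=bool)
        plane = np.zeros(shape[:axis] + shape[axis + 1 :], dtype=bool)
        plane |= conducting
        plate[tuple(sl_new)] = plane
        return plate

    cathode = face(0, 0)
    anode = face(shape[axis] - 1, out.grid.shape[axis] - 1)
    new[cathode] = pad_id
    new[anode] = pad_id
    from .volume import GridSpec

    o = list(out.grid.origin)
    o[axis] -= out.grid.spacing
    grid = GridSpec(shape=tuple(shape), spacing=out.grid.spacing, origin=tuple(o))
    vol = LabelVolume(grid=grid, labels=new, catalogue=cat,
                      landmarks={}, segments=dict(out.segments))
    return vol, anode, cathode
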