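"""Parametric synthetic phantoms.

The study anatomies are layered voxel bodies built from ellipsoids and
cylinders whose *control parameters* are published child anthropometrics
(cerebellar antero-posterior length, cerebellar CSF volume, occipital skull
thickness, per-segment spinal cord lengths/volumes and CSF volumes).  They
reproduce the anatomy -> field dependencies under study — CSF shunting,
skull resistance, electrode-to-cord distance — without licensed imaging data.

Three families:

* calibration phantoms (cube, slab, concentric spheres) with closed-form
  solutions, used to validate the solver;
* a head phantom: scalp/skull/CSF/gray/white ellipsoidal shells with a
  cerebellum, a cerebellar CSF shell tuned to a target volume, a brainstem
  stack (midbrain/pons/medulla), an occipital-cortex patch, deep nuclei, and
  an arm-stub appendage providing the distal return path;
* a trunk phantom: skin/fat/muscle elliptic cylinder with a vertebral column,
  CSF sheath, spinal cord segmented cervical/thoracic/lumbar/sacral, optional
  nerve roots and cauda equina, and a heart ellipsoid.

Voxelisation rule: a voxel takes the label of the compartment containing its
center.  All randomness (CSF-defect patch placement) is driven by the seed
field of the phantom spec; generation is deterministic given spec + seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .catalogue import TissueCatalogue, default_catalogue
from .volume import GridSpec, LabelVolume

__all__ = [
    "HeadPhantomSpec",
    "TrunkPhantomSpec",
    "make_calibration_phantom",
    "make_cube",
    "make_slab",
    "make_spheres",
    "make_head_phantom",
    "make_trunk_phantom",
    "HEAD_PRESETS",
    "TRUNK_PRESETS",
]


class PhantomError(ValueError):
    """Geometrically inconsistent phantom specification."""


def _grid_coords(grid: GridSpec):
    """Open-mesh physical center coordinates (mm) for each axis."""
    x = grid.coords(0)[:, None, None]
    y = grid.coords(1)[None, :, None]
    z = grid.coords(2)[None, None, :]
    return x, y, z


def _ellipsoid(grid: GridSpec, center, semiaxes) -> np.ndarray:
    x, y, z = _grid_coords(grid)
    cx, cy, cz = center
    ax, ay, az = semiaxes
    return (
        ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2
    ) <= 1.0


def _cylinder_z(grid: GridSpec, center_xy, radius, z0, z1) -> np.ndarray:
    """Solid cylinder along z, physical z in [z0, z1] (mm)."""
    x, y, z = _grid_coords(grid)
    cx, cy = center_xy
    return (
        ((x - cx) ** 2 + (y - cy) ** 2 <= radius**2) & (z >= z0) & (z <= z1)
    )


def _elliptic_cylinder_z(grid: GridSpec, center_xy, semis, z0, z1) -> np.ndarray:
    x, y, z = _grid_coords(grid)
    cx, cy = center_xy
    ax, ay = semis
    return (
        (((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 <= 1.0) & (z >= z0) & (z <= z1)
    )


# ---------------------------------------------------------------------------
# Calibration phantoms
# ---------------------------------------------------------------------------


def make_cube(
    shape: tuple[int, int, int],
    spacing: float,
    tissue: str = "Muscle",
    catalogue: TissueCatalogue | None = None,
) -> LabelVolume:
    """Homogeneous block of one tissue filling the whole grid."""
    catalogue = catalogue or default_catalogue()
    grid = GridSpec(shape=shape, spacing=spacing)
    labels = np.full(grid.shape, catalogue.tissue_id(tissue), dtype=np.int16)
    return LabelVolume(grid=grid, labels=labels, catalogue=catalogue)


def make_slab(
    layers: list[tuple[str, float]],
    cross_mm: tuple[float, float],
    spacing: float,
    catalogue: TissueCatalogue | None = None,
) -> LabelVolume:
    """Stack of tissue layers along z.

    ``layers`` is an ordered list of (tissue, thickness in mm), bottom first.
    The cross-section is ``cross_mm`` (mm) in x and y with no air margin, so
    plate electrodes on the two z faces drive a strictly one-dimensional
    current that has a series-conductance closed form.
    """
    catalogue = catalogue or default_catalogue()
    nx = round(cross_mm[0] / spacing)
    ny = round(cross_mm[1] / spacing)
    nz_layers = [round(t / spacing) for _, t in layers]
    if any(n <= 0 for n in nz_layers) or nx <= 0 or ny <= 0:
        raise PhantomError("layer thickness or cross-section below one voxel")
    nz = sum(nz_layers)
    grid = GridSpec(shape=(nx, ny, nz), spacing=spacing)
    labels = np.zeros(grid.shape, dtype=np.int16)
    z = 0
    for (tissue, _), n in zip(layers, nz_layers):
        labels[:, :, z : z + n] = catalogue.tissue_id(tissue)
        z += n
    return LabelVolume(grid=grid, labels=labels, catalogue=catalogue)


def make_spheres(
    radii_mm: list[float],
    tissues: list[str],
    spacing: float,
    margin_mm: float = 4.0,
    catalogue: TissueCatalogue | None = None,
) -> LabelVolume:
    """Concentric spherical shells, innermost first; exterior air outside."""
    catalogue = catalogue or default_catalogue()
    if len(radii_mm) != len(tissues):
        raise PhantomError("radii and tissues must have equal length")
    if sorted(radii_mm) != list(radii_mm):
        raise PhantomError("radii must be ascending")
    r_out = radii_mm[-1]
    n = 2 * round((r_out + margin_mm) / spacing) + 1
    grid = GridSpec(shape=(n, n, n), spacing=spacing)
    c = (n - 1) / 2 * spacing
    labels = np.zeros(grid.shape, dtype=np.int16)
    # assign outermost shell first, inner shells overwrite
    for r, tissue in zip(radii_mm[::-1], tissues[::-1]):
        mask = _ellipsoid(grid, (c, c, c), (r, r, r))
        labels[mask] = catalogue.tissue_id(tissue)
    return LabelVolume(grid=grid, labels=labels, catalogue=catalogue)


def make_calibration_phantom(kind: str, params: dict) -> LabelVolume:
    """Dispatch to :func:`make_cube`, :func:`make_slab` or :func:`make_spheres`."""
    makers = {"cube": make_cube, "slab": make_slab, "spheres": make_spheres}
    if kind not in makers:
        raise PhantomError(f"unknown calibration phantom kind: {kind!r}")
    return makers[kind](**params)


# ---------------------------------------------------------------------------
# Head phantom
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HeadPhantomSpec:
    """Parameters of the layered head phantom.

    Lengths in mm, volumes in cm³.  ``skull_thickness`` is the *maximum
    occipital* skull thickness: the vault keeps ``vault_thickness`` and the
    bone thickens toward the occipital pole (an outward boss under the active
    electrode), so the parameter controls exactly the bone the cerebellar
    current must cross without altering the rest of the return path.
    Published anthropometric tables report a single skull-thickness figure
    per model, described elsewhere as the occipital-bone maximum; this
    phantom treats it as the occipital maximum.  ``csf_defect`` is the
    fraction of the cerebellar CSF shell replaced by brain-skull contact
    patches (segmentation-artifact emulation); patch placement is
    reproducible per ``seed``.
    """

    brain_semiaxes: tuple[float, float, float] = (54.0, 68.0, 62.0)
    scalp_thickness: float = 5.0
    skull_thickness: float = 8.4       # maximum occipital thickness
    vault_thickness: float = 6.0       # base thickness of the rest of the vault
    csf_thickness: float = 3.0
    gray_thickness: float = 4.0
    cerebellum_ap_length: float = 66.0
    cerebellar_csf_volume: float = 30.7
    include_brainstem: bool = True
    include_occipital: bool = True
    include_deep_structures: bool = True
    arm_stub_length: float = 60.0
    arm_stub_radius: float = 30.0
    csf_defect: float = 0.0
    seed: int = 0
    spacing: float = 1.0
    margin: float = 10.0

    def __post_init__(self) -> None:
        for name in ("scalp_thickness", "skull_thickness", "csf_thickness",
                     "gray_thickness", "cerebellum_ap_length"):
            if getattr(self, name) <= 0:
                raise PhantomError(f"{name} must be positive")
        if not 0.0 <= self.csf_defect <= 1.0:
            raise PhantomError("csf_defect must be in [0, 1]")
        if min(self.brain_semiaxes) <= self.gray_thickness:
            raise PhantomError("gray-matter shell exceeds the brain semi-axes")
        if self.vault_thickness <= 0:
            raise PhantomError("vault_thickness must be positive")

    @property
    def occipital_extra(self) -> float:
        """Occipital thickening beyond the base vault (mm)."""
        return max(0.0, self.skull_thickness - self.vault_thickness)

    @property
    def outer_semiaxes(self) -> tuple[float, float, float]:
        """Scalp surface semi-axes: brain chamber grown by the shell layers.

        Built inside-out so a skull- or CSF-thickness sweep leaves the brain
        geometry (and the cerebellum within it) untouched.  Excludes the
        occipital boss, which bulges beyond these semi-axes posteriorly.
        """
        t = (
            self.csf_thickness
            + min(self.skull_thickness, self.vault_thickness)
            + self.scalp_thickness
        )
        return tuple(s + t for s in self.brain_semiaxes)


def make_head_phantom(spec: HeadPhantomSpec) -> LabelVolume:
    """Build the layered head phantom; see module docstring for anatomy."""
    cat = default_catalogue()
    a, b, c = spec.outer_semiaxes
    h = spec.spacing
    m = spec.margin
    stub_len = spec.arm_stub_length
    stub_r = spec.arm_stub_radius
    stub_cx = 0.45 * a

    extra = spec.occipital_extra
    boss = (0.0, -0.8 * extra, -0.6 * extra)  # posterior-inferior unit shift
    x0, x1 = -a - m, max(a, stub_cx + stub_r) + m
    y0, y1 = -b - extra - m, b + m
    z0, z1 = -c - stub_len - m, c + m
    shape = (
        int(np.ceil((x1 - x0) / h)) + 1,
        int(np.ceil((y1 - y0) / h)) + 1,
        int(np.ceil((z1 - z0) / h)) + 1,
    )
    grid = GridSpec(shape=shape, spacing=h, origin=(x0, y0, z0))
    labels = np.zeros(shape, dtype=np.int16)

    def put(mask, tissue):
        labels[mask] = cat.tissue_id(tissue)

    # head shells, inside-out; the occipital boss is a second copy of the
    # scalp/skull surfaces shifted posterior-inferiorly, thickening the bone
    # under the cerebellar electrode by up to ``extra`` mm
    def shell(semis):
        e = _ellipsoid(grid, (0, 0, 0), semis)
        if extra > 0:
            e |= _ellipsoid(grid, boss, semis)
        return e

    semis = np.array([a, b, c], dtype=float)
    put(shell(semis), "Skin")
    semis -= spec.scalp_thickness
    put(shell(semis), "Skull")
    semis -= min(spec.skull_thickness, spec.vault_thickness)
    skull_inner = _ellipsoid(grid, (0, 0, 0), semis)
    put(skull_inner, "Cerebro spinal fluid (CSF)")
    semis -= spec.csf_thickness
    brain = _ellipsoid(grid, (0, 0, 0), semis)
    put(brain, "Brain gray matter")
    put(_ellipsoid(grid, (0, 0, 0), semis - spec.gray_thickness), "Brain white matter")
    b_in = tuple(semis)  # brain outer semi-axes

    # occipital cortex: posterior-superior wedge of the cortical shell
    if spec.include_occipital:
        gray = labels == cat.tissue_id("Brain gray matter")
        x, y, z = _grid_coords(grid)
        wedge = (y < -0.35 * b_in[1]) & (z > -0.15 * b_in[2]) & (z < 0.55 * b_in[2])
        put(gray & np.broadcast_to(wedge, shape), "Occipital cortex")

    # cerebellum: posterior-inferior ellipsoid, AP extent = cerebellum_ap_length
    ap = spec.cerebellum_ap_length
    cb_semi = (0.62 * ap, ap / 2.0, 0.36 * ap)
    cb_center = _fit_posterior_inferior(b_in, cb_semi)
    cb = _ellipsoid(grid, cb_center, cb_semi)
    if not np.array_equal(cb & brain, cb):
        raise PhantomError(
            "cerebellum does not fit inside the brain compartment; "
            "reduce cerebellum_ap_length or grow the outer semi-axes"
        )

    # cerebellar CSF shell: thickness tuned by bisection to the target volume.
    # The shell is the layer between the cerebellum surface and whatever lies
    # around it (cortex, white matter, vault CSF), clipped to the skull cavity.
    target_mm3 = spec.cerebellar_csf_volume * 1000.0
    vox = grid.voxel_volume_mm3

    def shell_mask(t: float) -> np.ndarray:
        outer = _ellipsoid(
            grid, cb_center, (cb_semi[0] + t, cb_semi[1] + t, cb_semi[2] + t)
        )
        return outer & ~cb & skull_inner

    def shell_vol(t: float) -> float:
        return float(np.count_nonzero(shell_mask(t))) * vox

    t_lo, t_hi = 0.0, 0.45 * min(cb_semi)
    v_hi = shell_vol(t_hi)
    if target_mm3 > v_hi or target_mm3 < shell_vol(h):
        raise PhantomError(
            f"cerebellar CSF target {spec.cerebellar_csf_volume:.1f} cm³ "
            f"unachievable; achievable range [{shell_vol(h) / 1000:.1f}, "
            f"{v_hi / 1000:.1f}] cm³ at this geometry"
        )
    for _ in range(40):
        t_mid = 0.5 * (t_lo + t_hi)
        if shell_vol(t_mid) < target_mm3:
            t_lo = t_mid
        else:
            t_hi = t_mid
    shell = shell_mask(t_hi)
    put(shell, "Cerebro spinal fluid (CSF)")
    put(cb, "Cerebellum")

    # brainstem stack anterior-inferior to the cerebellum: midbrain over pons
    # over medulla, a vertical cylinder descending to the base of the brain
    if spec.include_brainstem:
        bs_cy = cb_center[1] + cb_semi[1] + 9.0
        bs_r = 9.0
        z_top = cb_center[2] + cb_semi[2] * 0.8
        z_bot = cb_center[2] - cb_semi[2] * 1.1
        seg = (z_top - z_bot) / 3.0
        stack = [("Midbrain", z_top - seg, z_top),
                 ("Pons", z_bot + seg, z_top - seg),
                 ("Medulla oblongata", z_bot, z_bot + seg)]
        for tissue, lo, hi in stack:
            mask = _cylinder_z(grid, (0.0, bs_cy), bs_r, lo, hi) & brain & ~cb & ~shell
            put(mask, tissue)

    # deep nuclei: thalamus, hypothalamus, hippocampi
    if spec.include_deep_structures:
        put(_ellipsoid(grid, (0, 5, 15), (14, 9, 9)) & brain, "Thalamus")
        put(_ellipsoid(grid, (0, 8, 3), (7, 6, 5)) & brain, "Hypothalamus")
        for sx in (-1, 1):
            put(
                _ellipsoid(grid, (sx * 22, -5, 8), (6, 14, 6)) & brain,
                "Hippocampus",
            )

    # CSF-defect patches: relabel shell voxels to cerebellum around seed points
    # that touch the skull, emulating segmentation gaps with brain-skull contact
    if spec.csf_defect > 0:
        _apply_csf_defect(labels, grid, shell, cat, spec.csf_defect, spec.seed)

    # arm stub: skin-wrapped muscle-equivalent cylinder hanging below the head
    stub_z1 = -c + 0.4 * c  # overlaps the lower head to guarantee contact
    stub_z0 = -c - stub_len
    stub_outer = _cylinder_z(grid, (stub_cx, 0.0), stub_r, stub_z0, stub_z1)
    stub_core = _cylinder_z(
        grid, (stub_cx, 0.0), stub_r - 3.0, stub_z0 + 3.0, stub_z1
    )
    air = labels == 0
    put(stub_outer & air, "Skin")
    air = labels == cat.tissue_id("Skin")  # only overwrite freshly painted skin
    put(stub_core & air & stub_outer, "Arm stub")

    vol = LabelVolume(grid=grid, labels=labels, catalogue=cat)
    shell_final = shell & (labels == cat.tissue_id("Cerebro spinal fluid (CSF)"))
    vol.meta["cerebellar_csf_cm3"] = float(
        np.count_nonzero(shell_final) * vox / 1000.0
    )
    vol.meta["cerebellar_csf_shell_mm"] = float(t_hi)
    vol.meta["cerebellum_ap_mm"] = float(
        (np.ptp(np.nonzero(cb.any(axis=(0, 2)))[0]) + 1) * h
    )
    _add_head_landmarks(vol, spec, cb_center, cb_semi)
    return vol


def _fit_posterior_inferior(brain_semi, cb_semi) -> tuple[float, float, float]:
    """Most posterior-inferior center at which the cerebellum ellipsoid fits.

    Bisects the offset scale along the (posterior, inferior) direction,
    checking continuous containment on a parametric sample of the cerebellum
    surface; voxel-center voxelisation then preserves containment.
    """
    A, B, C = brain_semi
    ax, ay, az = cb_semi
    if ax >= A or ay >= B or az >= C:
        raise PhantomError("cerebellum semi-axes exceed the brain compartment")
    th = np.linspace(0, np.pi, 60)
    ph = np.linspace(0, 2 * np.pi, 120)
    T, P = np.meshgrid(th, ph)
    sx = ax * np.sin(T) * np.cos(P)
    sy = ay * np.sin(T) * np.sin(P)
    sz = az * np.cos(T)

    def fits(s: float) -> bool:
        yc = -s * 0.85 * (B - ay)
        zc = -s * 0.75 * (C - az)
        val = (sx / A) ** 2 + ((sy + yc) / B) ** 2 + ((sz + zc) / C) ** 2
        return bool(val.max() <= 1.0)

    if not fits(0.0):
        raise PhantomError("cerebellum does not fit inside the brain compartment")
    lo, hi = 0.0, 1.0
    if fits(1.0):
        lo = 1.0
    else:
        for _ in range(30):
            mid = 0.5 * (lo + hi)
            if fits(mid):
                lo = mid
            else:
                hi = mid
    return (0.0, -lo * 0.85 * (B - ay), -lo * 0.75 * (C - az))


def _apply_csf_defect(labels, grid, shell, cat, fraction, seed) -> None:
    rng = np.random.default_rng(seed)
    csf_id = cat.tissue_id("Cerebro spinal fluid (CSF)")
    skull_id = cat.tissue_id("Skull")
    cb_id = cat.tissue_id("Cerebellum")
    shell_now = shell & (labels == csf_id)
    # shell voxels face-adjacent to skull: candidate defect centers
    skull = labels == skull_id
    adj = np.zeros_like(skull)
    for ax in range(3):
        for s in (1, -1):
            adj |= np.roll(skull, s, axis=ax)
    contact_cand = np.argwhere(shell_now & adj)
    if contact_cand.size == 0:
        return
    idx = np.argwhere(shell_now)
    total = len(idx)
    want = int(round(fraction * total))
    relabeled = np.zeros(labels.shape, dtype=bool)
    patch_r = max(5.0, 2.5 * grid.spacing)
    # first patch at a skull-adjacent site (guarantees brain-skull contact),
    # subsequent patches anywhere on the shell
    first = contact_cand[rng.integers(len(contact_cand))]
    centers = [first] + list(idx[rng.permutation(total)])
    for center in centers:
        if int(np.count_nonzero(relabeled)) >= want:
            break
        cx, cy, cz = center
        d2 = ((idx[:, 0] - cx) ** 2 + (idx[:, 1] - cy) ** 2 + (idx[:, 2] - cz) ** 2)
        patch = idx[d2 <= (patch_r / grid.spacing) ** 2]
        relabeled[patch[:, 0], patch[:, 1], patch[:, 2]] = True
    labels[relabeled] = cb_id


def _add_head_landmarks(vol: LabelVolume, spec, cb_center, cb_semi) -> None:
    """Inion, ctDCS active-electrode anchor (2 cm below inion), arm anchor."""
    grid, labels = vol.grid, vol.labels
    cat = vol.catalogue
    skin_id = cat.tissue_id("Skin")
    stub_id = cat.tissue_id("Arm stub")

    def posterior_skin(zmm: float):
        ix = int(round((0.0 - grid.origin[0]) / grid.spacing))
        iz = int(round((zmm - grid.origin[2]) / grid.spacing))
        col = labels[ix, :, iz]
        body = np.nonzero(col == skin_id)[0]
        if body.size == 0:
            raise PhantomError(f"no posterior skin surface at z={zmm} mm")
        return (ix, int(body.min()), iz)

    z_inion = cb_center[2] + cb_semi[2]
    vol.landmarks["inion"] = posterior_skin(z_inion)
    vol.landmarks["ctdcs_active"] = posterior_skin(z_inion - 20.0)
    # arm anchor: +x surface of the stub at mid-length below the head
    c = spec.outer_semiaxes[2]
    z_arm = -c - 0.5 * spec.arm_stub_length
    iz = int(round((z_arm - grid.origin[2]) / grid.spacing))
    iy = int(round((0.0 - grid.origin[1]) / grid.spacing))
    col = labels[:, iy, iz]
    body = np.nonzero((col == skin_id) | (col == stub_id))[0]
    if body.size == 0:
        raise PhantomError("arm stub surface not found")
    vol.landmarks["arm"] = (int(body.max()), iy, iz)


# ---------------------------------------------------------------------------
# Trunk phantom
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrunkPhantomSpec:
    """Parameters of the trunk phantom (lengths mm, volumes cm³).

    Per-segment cord radii and CSF sheath thicknesses are given directly; the
    preset constructors derive them from published per-segment cord and CSF
    volumes (``r = sqrt(V / pi L)`` for the cord, annulus closed form for the
    sheath).  ``nerve_segments`` lists the segments carrying paired nerve
    roots; a missing segment emulates absent nerve segmentation.
    ``cord_interruption`` is an optional physical z-interval (mm from the
    cranial cord end) where the cord is replaced by CSF.
    """

    cross_semiaxes: tuple[float, float] = (80.0, 55.0)
    segment_lengths: dict[str, float] = field(
        default_factory=lambda: {
            "cervical": 73.0, "thoracic": 170.0, "lumbar": 108.0, "sacral": 90.0
        }
    )
    cord_radius: dict[str, float] = field(
        default_factory=lambda: {
            "cervical": 4.5, "thoracic": 3.5, "lumbar": 3.1, "sacral": 2.5
        }
    )
    csf_thickness: dict[str, float] = field(
        default_factory=lambda: {
            "cervical": 1.9, "thoracic": 3.0, "lumbar": 2.5, "sacral": 2.5
        }
    )
    vertebra_thickness: float = 9.0
    skin_thickness: float = 2.0
    fat_thickness: float = 5.0
    muscle_thickness: float = 12.0
    vertebra_offset: float = 0.5  # posterior offset of the column, fraction of ay
    nerve_segments: tuple[str, ...] = ("cervical", "thoracic", "lumbar", "sacral")
    nerve_radius: float = 2.0
    nerve_z_step: float = 24.0
    cauda_equina: bool = True
    heart_center: tuple[float, float, float] | None = None  # None -> default
    heart_semiaxes: tuple[float, float, float] = (30.0, 24.0, 32.0)
    cord_interruption: tuple[float, float] | None = None
    seed: int = 0
    spacing: float = 1.0
    margin: float = 10.0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.segment_lengths.values()):
            raise PhantomError("segment lengths must be positive")
        shell = self.skin_thickness + self.fat_thickness + self.muscle_thickness
        if shell >= min(self.cross_semiaxes):
            raise PhantomError("shell layers exceed trunk cross-section")


_SEGMENT_ORDER = ("cervical", "thoracic", "lumbar", "sacral")


def make_trunk_phantom(spec: TrunkPhantomSpec) -> LabelVolume:
    """Build the trunk phantom; cranial end at high z."""
    cat = default_catalogue()
    ax, ay = spec.cross_semiaxes
    h = spec.spacing
    m = spec.margin
    total_len = sum(spec.segment_lengths[s] for s in _SEGMENT_ORDER)

    x0, x1 = -ax - m, ax + m
    y0, y1 = -ay - m, ay + m
    z0, z1 = -m, total_len + m
    shape = (
        int(np.ceil((x1 - x0) / h)) + 1,
        int(np.ceil((y1 - y0) / h)) + 1,
        int(np.ceil((z1 - z0) / h)) + 1,
    )
    grid = GridSpec(shape=shape, spacing=h, origin=(x0, y0, z0))
    labels = np.zeros(shape, dtype=np.int16)

    def put(mask, tissue):
        labels[mask] = cat.tissue_id(tissue)

    # segment z-extents, cranial (cervical) on top
    seg_z: dict[str, tuple[float, float]] = {}
    z_hi = total_len
    for s in _SEGMENT_ORDER:
        seg_z[s] = (z_hi - spec.segment_lengths[s], z_hi)
        z_hi -= spec.segment_lengths[s]

    vy = -spec.vertebra_offset * ay
    max_sheath = max(
        spec.cord_radius[s] + spec.csf_thickness[s] for s in _SEGMENT_ORDER
    )
    vert_r = max_sheath + spec.vertebra_thickness
    if vert_r + abs(vy) > ay - (spec.skin_thickness + spec.fat_thickness):
        raise PhantomError("vertebral column overlaps the trunk shell layers")

    # trunk shells: full elliptic cross-section up to the shoulder line
    # (thoracic top); the cervical segment sits in a narrow neck around the
    # vertebral column, which keeps the cervical canal away from the trunk
    # surface and the return electrode, as the shoulder line does in vivo
    shoulder_z = seg_z["thoracic"][1]
    neck_r = vert_r + spec.skin_thickness + spec.fat_thickness \
        + spec.muscle_thickness + 2.0
    ny = max(vy, -(ay - neck_r - 1.0))
    if abs(ny - vy) + vert_r > neck_r:
        raise PhantomError("neck does not enclose the vertebral column")

    def body(semis_xy, shrink):
        trunk = _elliptic_cylinder_z(grid, (0, 0), semis_xy, 0.0, shoulder_z)
        neck = _cylinder_z(
            grid, (0.0, ny), neck_r - shrink, shoulder_z, total_len
        )
        return trunk | neck

    semis = np.array([ax, ay], dtype=float)
    put(body(semis, 0.0), "Skin")
    semis -= spec.skin_thickness
    put(body(semis, spec.skin_thickness), "Fat")
    semis -= spec.fat_thickness
    put(body(semis, spec.skin_thickness + spec.fat_thickness), "Muscle")

    # vertebral column: bone cylinder enclosing the CSF sheath and cord
    put(_cylinder_z(grid, (0.0, vy), vert_r, 0.0, total_len), "Vertebrae")

    cord_id = cat.tissue_id("Spinal cord")
    for s in _SEGMENT_ORDER:
        lo, hi = seg_z[s]
        r_cord = spec.cord_radius[s]
        r_sheath = r_cord + spec.csf_thickness[s]
        put(_cylinder_z(grid, (0.0, vy), r_sheath, lo, hi),
            "Cerebro spinal fluid (CSF)")
        if spec.cauda_equina and s == "sacral":
            put(_cylinder_z(grid, (0.0, vy), r_cord * 0.8, lo, hi), "Cauda equina")
        else:
            put(_cylinder_z(grid, (0.0, vy), r_cord, lo, hi), "Spinal cord")

    # optional cord interruption (z measured down from the cranial cord end)
    if spec.cord_interruption is not None:
        d0, d1 = spec.cord_interruption
        gap = _cylinder_z(
            grid, (0.0, vy), max_sheath, total_len - d1, total_len - d0
        ) & (labels == cord_id)
        put(gap, "Cerebro spinal fluid (CSF)")

    # paired nerve roots: lateral cylinders through the bone into the muscle
    x, y, z = _grid_coords(grid)
    for s in spec.nerve_segments:
        if s not in _SEGMENT_ORDER:
            raise PhantomError(f"unknown nerve segment {s!r}")
        lo, hi = seg_z[s]
        r_cord = spec.cord_radius[s]
        zs = np.arange(lo + spec.nerve_z_step / 2, hi, spec.nerve_z_step)
        for zc in zs:
            tube = (
                ((z - zc) ** 2 + (y - vy) ** 2 <= spec.nerve_radius**2)
                & (np.abs(x) <= vert_r + 18.0)
                & (np.abs(x) >= r_cord * 0.5)
            )
            keep = (
                (labels == 0)
                | (labels == cat.tissue_id("Skin"))
                | (labels == cord_id)
                | (labels == cat.tissue_id("Cauda equina"))
            )
            put(tube & ~keep, "Nerve")

    # heart: anterior ellipsoid in the upper thoracic region, offset left
    t_lo, t_hi = seg_z["thoracic"]
    # default: just anterior to the vertebral column, upper thoracic, offset left
    hc = spec.heart_center or (
        -12.0, vy + vert_r + spec.heart_semiaxes[1] + 2.0, t_hi - 55.0
    )
    heart = _ellipsoid(grid, hc, spec.heart_semiaxes)
    if np.any(heart & (labels == cat.tissue_id("Vertebrae"))):
        raise PhantomError("heart overlaps the vertebral column")
    put(heart & (labels == cat.tissue_id("Muscle")), "Hearth muscle")

    vol = LabelVolume(grid=grid, labels=labels, catalogue=cat)
    for s in _SEGMENT_ORDER:
        lo, hi = seg_z[s]
        iz0 = int(np.ceil((lo - grid.origin[2]) / h))
        iz1 = int(np.floor((hi - grid.origin[2]) / h))
        vol.segments[s] = (iz0, min(iz1, shape[2] - 1))
    _add_trunk_landmarks(vol, spec, seg_z)
    return vol


def _add_trunk_landmarks(vol: LabelVolume, spec, seg_z) -> None:
    """T10 spinous-process anchor (posterior skin) and right-arm patch anchor."""
    grid, labels = vol.grid, vol.labels
    skin_id = vol.catalogue.tissue_id("Skin")
    t_lo, t_hi = seg_z["thoracic"]
    z_t10 = t_hi - (9.5 / 12.0) * (t_hi - t_lo)
    ix = int(round((0.0 - grid.origin[0]) / grid.spacing))
    iz = int(round((z_t10 - grid.origin[2]) / grid.spacing))
    col = labels[ix, :, iz]
    body = np.nonzero(col == skin_id)[0]
    if body.size == 0:
        raise PhantomError("no posterior skin surface at the T10 level")
    vol.landmarks["t10"] = (ix, int(body.min()), iz)
    # right-arm return patch: +x lateral surface just below the shoulder
    # line, where the right arm joins the trunk
    z_arm = t_hi - 35.0
    iy = int(round((0.0 - grid.origin[1]) / grid.spacing))
    iza = int(round((z_arm - grid.origin[2]) / grid.spacing))
    col = labels[:, iy, iza]
    body = np.nonzero(col == skin_id)[0]
    if body.size == 0:
        raise PhantomError("no lateral skin surface at the arm level")
    vol.landmarks["arm"] = (int(body.max()), iy, iza)


# ---------------------------------------------------------------------------
# Presets: published child anthropometrics as phantom control parameters
# ---------------------------------------------------------------------------

# cerebellar antero-posterior length (mm), cerebellar CSF volume (cm³),
# occipital skull thickness (mm)
HEAD_PRESETS: dict[str, HeadPhantomSpec] = {
    "roberta": HeadPhantomSpec(
        cerebellum_ap_length=66.0, cerebellar_csf_volume=30.7, skull_thickness=8.4
    ),
    "thelonious": HeadPhantomSpec(
        cerebellum_ap_length=68.0, cerebellar_csf_volume=34.6, skull_thickness=8.1
    ),
    "eartha": HeadPhantomSpec(
        cerebellum_ap_length=68.0, cerebellar_csf_volume=48.6, skull_thickness=10.9
    ),
    "dizzy": HeadPhantomSpec(
        cerebellum_ap_length=70.0, cerebellar_csf_volume=88.6, skull_thickness=8.7
    ),
}


def _trunk_preset(
    lengths_cm: dict[str, float],
    cord_vol_cm3: dict[str, float],
    csf_vol_cm3: dict[str, float],
    **overrides,
) -> TrunkPhantomSpec:
    """Derive cord radii and sheath thicknesses from per-segment volumes."""
    lengths = {s: v * 10.0 for s, v in lengths_cm.items()}
    lengths.setdefault("sacral", 90.0)
    radius, csf_t = {}, {}
    for s in _SEGMENT_ORDER:
        L = lengths[s]
        if s in cord_vol_cm3:
            radius[s] = float(np.sqrt(cord_vol_cm3[s] * 1000.0 / (np.pi * L)))
        else:
            radius[s] = 2.5
        if s in csf_vol_cm3:
            area = csf_vol_cm3[s] * 1000.0 / L  # annulus cross-section (mm²)
            csf_t[s] = float(np.sqrt(area / np.pi + radius[s] ** 2) - radius[s])
        else:
            csf_t[s] = 2.5
    return TrunkPhantomSpec(
        segment_lengths=lengths, cord_radius=radius, csf_thickness=csf_t, **overrides
    )


TRUNK_PRESETS: dict[str, TrunkPhantomSpec] = {
    "roberta": _trunk_preset(
        {"cervical": 7.3, "thoracic": 17.0, "lumbar": 10.8},
        {"cervical": 4.6, "thoracic": 6.6, "lumbar": 3.3},
        {"cervical": 4.8, "thoracic": 16.2, "lumbar": 7.4},
        cord_interruption=(290.0, 310.0),  # lumbar interruption
        cauda_equina=True,
    ),
    "thelonious": _trunk_preset(
        {"cervical": 8.7, "thoracic": 17.0, "lumbar": 11.4},
        {"cervical": 6.9, "thoracic": 16.8, "lumbar": 2.3},
        {"cervical": 9.5, "thoracic": 12.2, "lumbar": 6.1},
        cauda_equina=False,
    ),
    "eartha": _trunk_preset(
        {"cervical": 10.0, "thoracic": 17.9, "lumbar": 13.0},
        {"cervical": 7.1, "thoracic": 6.2, "lumbar": 1.1},
        {"cervical": 14.5, "thoracic": 21.4, "lumbar": 44.8},
        nerve_segments=("sacral",),  # nerves represented only in the sacral tract
        cauda_equina=False,
    ),
    "dizzy": _trunk_preset(
        {"cervical": 10.6, "thoracic": 21.4, "lumbar": 14.5},
        {"cervical": 5.9, "thoracic": 7.5, "lumbar": 5.9},
        {"cervical": 10.6, "thoracic": 20.3, "lumbar": 17.2},
        cauda_equina=False,
    ),
}
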