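"""Electric-field derivation and dose metrics.

From the solved potential this module derives the electric field E = -grad
phi (gradients restricted to same-tissue neighbors, one-sided at tissue
boundaries, so interface jumps do not leak across compartments) and the
current density J = sigma E, applies the regulatory 2 mm vector-averaging
convention (component-wise mean over a cubic window restricted to the voxel's
own tissue), and computes the exposure metrics:

* per-tissue descriptive statistics of |E| (min, quartiles, 99th percentile
  — the robust "peak" that filters staircase voxelisation artifacts);
* V50 / V70 focality: percentage of the target tissue at or above 50% / 70%
  of its own peak;
* spread-to-structure: percentage of a non-target structure above 70% of the
  target peak (strict inequality);
* per-slice coefficient of variation of |E| across cord cross-sections and
  its per-segment means (uniformity of stimulation);
* per-slice longitudinal/transverse ratio R = |E_z| / sqrt(E_x^2 + E_y^2)
  and per-segment means (alignment with the spinal axis);
* heart exposure and the safety margin against the 5 A/m^2 average cardiac
  fibrillation threshold.

Percentiles use linear interpolation on the sorted sample; CV uses the
population standard deviation.  Both choices are overridable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .volume import ConductivityVolume, GridSpec, LabelVolume
from .solver import PotentialField

__all__ = [
    "VectorField",
    "TissueStats",
    "SegmentProfile",
    "ExposureReport",
    "electric_field",
    "current_density",
    "icnirp_average",
    "tissue_stats",
    "spread_within",
    "spread_to_structure",
    "slice_cv",
    "longitudinal_ratio",
    "exposure_report",
    "match_peak_dose",
    "FIBRILLATION_THRESHOLD",
]

FIBRILLATION_THRESHOLD = 5.0  # A/m^2, average cardiac fibrillation threshold

CTDCS_TISSUES = (
    "Cerebellum", "Occipital cortex", "Brain white matter", "Pons",
    "Midbrain", "Medulla oblongata", "Thalamus", "Hypothalamus", "Hippocampus",
)
CTDCS_SPREAD_STRUCTURES = ("Occipital cortex", "Medulla oblongata")


class AnalysisError(ValueError):
    """Metric requested on an absent tissue or mismatched grids."""


@dataclass
class VectorField:
    """3-component vector field (V/m or A/m^2) with a validity mask."""

    grid: GridSpec
    components: tuple[np.ndarray, np.ndarray, np.ndarray]
    mask: np.ndarray

    def magnitude(self) -> np.ndarray:
        ex, ey, ez = self.components
        return np.sqrt(ex**2 + ey**2 + ez**2)

    def scaled(self, k: float) -> "VectorField":
        return VectorField(
            grid=self.grid,
            components=tuple(c * k for c in self.components),
            mask=self.mask,
        )


@dataclass
class TissueStats:
    """Descriptive statistics of a field magnitude over one tissue."""

    tissue: str
    min: float
    q25: float
    median: float
    q75: float
    p99: float
    voxel_count: int


@dataclass
class SegmentProfile:
    """Per-slice metric along z within a tissue plus per-segment means.

    ``values`` is NaN on slices where the metric is undefined (fewer than two
    tissue voxels for CV, all voxels transverse-degenerate for R); undefined
    slices are excluded from segment means.
    """

    metric: str
    slices: list[int]
    values: list[float]
    segment_means: dict[str, float]
    excluded_voxels: int = 0


def _shift(arr: np.ndarray, axis: int, step: int, fill) -> np.ndarray:
    """Array shifted by ``step`` along ``axis``; vacated cells get ``fill``."""
    out = np.full_like(arr, fill)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    if step > 0:
        src[axis] = slice(None, -step)
        dst[axis] = slice(step, None)
    elif step < 0:
        src[axis] = slice(-step, None)
        dst[axis] = slice(None, step)
    else:
        return arr.copy()
    out[tuple(dst)] = arr[tuple(src)]
    return out


def electric_field(
    phi: PotentialField,
    sigma: ConductivityVolume,
    labels: LabelVolume | None = None,
) -> VectorField:
    """E = -grad phi (V/m), differences restricted to same-tissue neighbors.

    Central differences where both same-tissue neighbors carry a defined
    potential, one-sided at tissue boundaries and next to masked voxels,
    zero where no same-tissue neighbor exists along the axis.
    """
    if labels is not None and labels.grid.shape != phi.grid.shape:
        raise AnalysisError("label grid does not match potential grid")
    h = phi.grid.spacing * 1e-3
    p = phi.phi
    valid = np.isfinite(p)
    tissue = labels.labels if labels is not None else sigma.sigma
    comps = []
    for axis in range(3):
        p_plus = _shift(p, axis, -1, np.nan)     # value at i+1
        p_minus = _shift(p, axis, +1, np.nan)    # value at i-1
        t_plus = _shift(tissue, axis, -1, -1)
        t_minus = _shift(tissue, axis, +1, -1)
        ok_plus = valid & np.isfinite(p_plus) & (t_plus == tissue)
        ok_minus = valid & np.isfinite(p_minus) & (t_minus == tissue)
        e = np.zeros_like(p)
        both = ok_plus & ok_minus
        e[both] = (p_minus[both] - p_plus[both]) / (2 * h)
        only_p = ok_plus & ~ok_minus
        e[only_p] = (p[only_p] - p_plus[only_p]) / h
        only_m = ok_minus & ~ok_plus
        e[only_m] = (p_minus[only_m] - p[only_m]) / h
        e[~valid] = 0.0
        comps.append(e)
    return VectorField(grid=phi.grid, components=tuple(comps), mask=valid)


def current_density(E: VectorField, sigma: ConductivityVolume) -> VectorField:
    """J = sigma E (A/m^2), per voxel."""
    if sigma.grid.shape != E.grid.shape:
        raise AnalysisError("conductivity grid does not match field grid")
    return VectorField(
        grid=E.grid,
        components=tuple(c * sigma.sigma for c in E.components),
        mask=E.mask & (sigma.sigma > 0),
    )


def _box_sum(arr: np.ndarray, bounds) -> np.ndarray:
    """Per-voxel sums of ``arr`` over each voxel's window box.

    ``bounds`` gives per-axis (start, stop) index arrays; the sum is computed
    with a 3-D summed-area table and 8-corner inclusion-exclusion.
    """
    sat = np.zeros(tuple(n + 1 for n in arr.shape))
    sat[1:, 1:, 1:] = arr.cumsum(0).cumsum(1).cumsum(2)
    (ax, bx), (ay, by), (az, bz) = bounds
    Ax, Bx = ax[:, None, None], bx[:, None, None]
    Ay, By = ay[None, :, None], by[None, :, None]
    Az, Bz = az[None, None, :], bz[None, None, :]
    return (
        sat[Bx, By, Bz] - sat[Ax, By, Bz] - sat[Bx, Ay, Bz] - sat[Bx, By, Az]
        + sat[Ax, Ay, Bz] + sat[Ax, By, Az] + sat[Bx, Ay, Az] - sat[Ax, Ay, Az]
    )


def icnirp_average(
    E: VectorField, labels: LabelVolume, window_mm: float = 2.0
) -> VectorField:
    """Component-wise vector average over a cubic same-tissue window.

    The window side is ``round(window_mm / spacing)`` voxels (2 at 1 mm,
    4 at 0.5 mm).  Each voxel's window is the contiguous cube of that side
    containing it, shifted inward at lattice edges so it never leaves the
    volume; only window voxels sharing the center voxel's tissue label
    contribute.  A vector average can cancel, so it never increases the
    magnitude within a tissue.
    """
    h = E.grid.spacing
    if window_mm < h:
        raise AnalysisError(
            f"averaging window {window_mm} mm is smaller than one voxel ({h} mm)"
        )
    s = round(window_mm / h)
    if s <= 1:
        comps = tuple(np.where(E.mask, c, 0.0) for c in E.components)
        return VectorField(grid=E.grid, components=comps, mask=E.mask)
    bounds = []
    for n in E.grid.shape:
        i = np.arange(n)
        a = np.clip(i - (s - 1) // 2, 0, max(0, n - s))
        bounds.append((a, np.minimum(a + s, n)))
    lab = labels.labels
    sums = [np.zeros(E.grid.shape) for _ in range(3)]
    count = np.ones(E.grid.shape)
    for tid in np.unique(lab):
        same = (lab == tid) & E.mask
        if not same.any():
            continue
        count[same] = _box_sum(same.astype(float), bounds)[same]
        for k in range(3):
            sums[k][same] = _box_sum(
                np.where(same, E.components[k], 0.0), bounds
            )[same]
    comps = tuple(
        np.where(E.mask, s_ / np.maximum(count, 1.0), 0.0) for s_ in sums
    )
    return VectorField(grid=E.grid, components=comps, mask=E.mask)


def _tissue_values(
    E: VectorField,
    labels: LabelVolume,
    tissue: str,
    z_range: tuple[int, int] | None = None,
) -> np.ndarray:
    mask = labels.mask(tissue) & E.mask
    if z_range is not None:
        zm = np.zeros(mask.shape, dtype=bool)
        zm[:, :, z_range[0] : z_range[1] + 1] = True
        mask &= zm
    vals = E.magnitude()[mask]
    if vals.size == 0:
        raise AnalysisError(f"tissue {tissue!r} absent"
                            + (f" in z-range {z_range}" if z_range else ""))
    return vals


def tissue_stats(
    E: VectorField,
    labels: LabelVolume,
    tissue: str,
    z_range: tuple[int, int] | None = None,
) -> TissueStats:
    """Min, quartiles and 99th percentile of |E| over one tissue.

    Percentiles use linear interpolation on the sorted sample; the 99th
    percentile is the reported "peak".
    """
    vals = _tissue_values(E, labels, tissue, z_range)
    q25, q50, q75, p99 = np.percentile(vals, [25, 50, 75, 99])
    return TissueStats(
        tissue=tissue, min=float(vals.min()), q25=float(q25),
        median=float(q50), q75=float(q75), p99=float(p99),
        voxel_count=int(vals.size),
    )


def spread_within(
    E: VectorField, labels: LabelVolume, tissue: str
) -> tuple[float, float]:
    """(V50, V70): % of the tissue at or above 50% / 70% of its own peak."""
    vals = _tissue_values(E, labels, tissue)
    peak = np.percentile(vals, 99)
    v50 = 100.0 * np.count_nonzero(vals >= 0.5 * peak) / vals.size
    v70 = 100.0 * np.count_nonzero(vals >= 0.7 * peak) / vals.size
    return float(v50), float(v70)


def spread_to_structure(
    E: VectorField, labels: LabelVolume, structure: str, reference_peak: float
) -> float:
    """% of ``structure`` strictly above 70% of the target-tissue peak."""
    if reference_peak <= 0:
        raise AnalysisError("reference peak must be positive")
    vals = _tissue_values(E, labels, structure)
    return float(100.0 * np.count_nonzero(vals > 0.7 * reference_peak) / vals.size)


def _slice_iter(E, labels, tissue, segments):
    mag = E.magnitude()
    mask = labels.mask(tissue) & E.mask
    for seg, (z0, z1) in segments.items():
        if not mask[:, :, z0 : z1 + 1].any():
            raise AnalysisError(f"segment {seg!r} contains no {tissue!r} voxels")
    for z in range(E.grid.shape[2]):
        m = mask[:, :, z]
        yield z, mag[:, :, z][m], m


def slice_cv(
    E: VectorField,
    labels: LabelVolume,
    tissue: str,
    segments: dict[str, tuple[int, int]],
) -> SegmentProfile:
    """Per-slice CV (%) of |E| across the tissue cross-section, and segment means.

    CV = 100 * population SD / mean.  Slices with fewer than two tissue
    voxels are excluded; segment means are unweighted over their slices.
    """
    values: dict[int, float] = {}
    for z, vals, _ in _slice_iter(E, labels, tissue, segments):
        if vals.size >= 2 and vals.mean() > 0:
            values[z] = float(100.0 * vals.std() / vals.mean())
    means = _segment_means(values, segments)
    return SegmentProfile(
        metric="cv", slices=sorted(values), values=[values[z] for z in sorted(values)],
        segment_means=means,
    )


def longitudinal_ratio(
    E: VectorField,
    labels: LabelVolume,
    tissue: str,
    segments: dict[str, tuple[int, int]],
    method: str = "voxelwise",
) -> SegmentProfile:
    """Per-slice longitudinal/transverse ratio R and segment means.

    ``voxelwise`` (default): R per voxel = |E_z| / sqrt(E_x^2 + E_y^2),
    averaged over the slice's tissue voxels; voxels with zero transverse
    magnitude are excluded and counted.  ``slice_mean``: ratio of the slice
    means of |E_z| and the transverse magnitude.  Slices where every voxel is
    excluded are undefined and left out of segment means.
    """
    if method not in ("voxelwise", "slice_mean"):
        raise AnalysisError(f"unknown R aggregation method {method!r}")
    ex, ey, ez = E.components
    mask = labels.mask(tissue) & E.mask
    for seg, (z0, z1) in segments.items():
        if not mask[:, :, z0 : z1 + 1].any():
            raise AnalysisError(f"segment {seg!r} contains no {tissue!r} voxels")
    trans = np.sqrt(ex**2 + ey**2)
    longi = np.abs(ez)
    values: dict[int, float] = {}
    excluded = 0
    for z in range(E.grid.shape[2]):
        m = mask[:, :, z]
        if not m.any():
            continue
        t = trans[:, :, z][m]
        l = longi[:, :, z][m]
        if method == "voxelwise":
            ok = t > 0
            excluded += int(np.count_nonzero(~ok))
            if ok.any():
                values[z] = float(np.mean(l[ok] / t[ok]))
        else:
            if t.mean() > 0:
                values[z] = float(l.mean() / t.mean())
    means = _segment_means(values, segments)
    return SegmentProfile(
        metric="r", slices=sorted(values), values=[values[z] for z in sorted(values)],
        segment_means=means, excluded_voxels=excluded,
    )


def _segment_means(values: dict[int, float], segments) -> dict[str, float]:
    means = {}
    for seg, (z0, z1) in segments.items():
        vs = [values[z] for z in values if z0 <= z <= z1]
        means[seg] = float(np.mean(vs)) if vs else float("nan")
    return means


def match_peak_dose(
    reference_peak: float, candidate_peak: float, candidate_current: float
) -> float:
    """Current that reproduces ``reference_peak`` in the candidate anatomy.

    By linearity of the volume-conductor problem the peak field scales with
    the injected current, so the equivalent dose is
    ``candidate_current * reference_peak / candidate_peak``.
    """
    if reference_peak <= 0 or candidate_peak <= 0:
        raise AnalysisError("peaks must be positive")
    return candidate_current * reference_peak / candidate_peak


# ---------------------------------------------------------------------------
# Exposure report
# ---------------------------------------------------------------------------


@dataclass
class ExposureReport:
    """Assembled per-run dosimetry report (JSON/CSV serialisable)."""

    mode: str                                   # "ctdcs" | "tsdcs"
    target_current_mA: float
    tissues_E: dict[str, TissueStats] = field(default_factory=dict)
    heart_E: TissueStats | None = None
    heart_J: TissueStats | None = None
    safety_margin: float | None = None          # 5 A/m^2 over heart J peak
    v50: float | None = None
    v70: float | None = None
    spread70: dict[str, float] = field(default_factory=dict)
    cord_segments_E: dict[str, TissueStats] = field(default_factory=dict)
    nerves_E: dict[str, TissueStats] = field(default_factory=dict)
    cauda_E: TissueStats | None = None
    cv_profile: SegmentProfile | None = None
    r_profile: SegmentProfile | None = None
    warnings: list[str] = field(default_factory=list)
    montage: dict = field(default_factory=dict)
    solver: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kw)

    @classmethod
    def from_dict(cls, d: dict) -> "ExposureReport":
        def stats(v):
            return TissueStats(**v) if v is not None else None

        def profile(v):
            return SegmentProfile(**v) if v is not None else None

        d = dict(d)
        d["tissues_E"] = {k: stats(v) for k, v in d.get("tissues_E", {}).items()}
        d["cord_segments_E"] = {
            k: stats(v) for k, v in d.get("cord_segments_E", {}).items()
        }
        d["nerves_E"] = {k: stats(v) for k, v in d.get("nerves_E", {}).items()}
        for key in ("heart_E", "heart_J", "cauda_E"):
            d[key] = stats(d.get(key))
        for key in ("cv_profile", "r_profile"):
            d[key] = profile(d.get(key))
        return cls(**d)

    @classmethod
    def from_json(cls, s: str) -> "ExposureReport":
        return cls.from_dict(json.loads(s))

    def save(self, directory: str | Path, stem: str = "report") -> None:
        """Write JSON plus CSV tables (per-tissue stats, per-slice profiles)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / f"{stem}.json").write_text(self.to_json(indent=1))
        rows = []
        for name, st in {
            **self.tissues_E,
            **{f"Spinal cord ({k})": v for k, v in self.cord_segments_E.items()},
            **{f"Nerve ({k})": v for k, v in self.nerves_E.items()},
        }.items():
            rows.append({"tissue": name, **asdict(st)})
        if self.heart_E:
            rows.append({"tissue": "Heart (E)", **asdict(self.heart_E)})
        if self.heart_J:
            rows.append({"tissue": "Heart (J)", **asdict(self.heart_J)})
        if self.cauda_E:
            rows.append({"tissue": "Cauda equina", **asdict(self.cauda_E)})
        if rows:
            pd.DataFrame(rows).to_csv(directory / f"{stem}_tissues.csv", index=False)
        prof_rows = []
        for prof in (self.cv_profile, self.r_profile):
            if prof:
                for z, v in zip(prof.slices, prof.values):
                    prof_rows.append({"metric": prof.metric, "slice_z": z, "value": v})
        if prof_rows:
            pd.DataFrame(prof_rows).to_csv(
                directory / f"{stem}_profiles.csv", index=False
            )


def exposure_report(
    E: VectorField,
    J: VectorField,
    labels: LabelVolume,
    mode: str,
    target_current: float,
    montage_info: dict | None = None,
    solver_info: dict | None = None,
    provenance: dict | None = None,
) -> ExposureReport:
    """Assemble the per-run exposure report for one montage mode.

    ctDCS mode reports cerebellar statistics, V50/V70 and spread toward the
    occipital cortex and medulla; tsDCS mode reports per-segment cord and
    nerve statistics, the CV and R profiles, and heart exposure with the
    fibrillation safety margin.  Missing tissues are listed as warnings and
    their statistics omitted.
    """
    if mode not in ("ctdcs", "tsdcs"):
        raise AnalysisError(f"unknown analysis mode {mode!r}")
    report = ExposureReport(
        mode=mode,
        target_current_mA=target_current * 1e3,
        montage=montage_info or {},
        solver=solver_info or {},
        provenance=provenance or {},
    )

    def try_stats(tissue, z_range=None):
        try:
            return tissue_stats(E, labels, tissue, z_range)
        except AnalysisError:
            report.warnings.append(f"tissue absent, stats omitted: {tissue}")
            return None

    if mode == "ctdcs":
        for tissue in CTDCS_TISSUES:
            st = try_stats(tissue)
            if st:
                report.tissues_E[tissue] = st
        cb = report.tissues_E.get("Cerebellum")
        if cb:
            report.v50, report.v70 = spread_within(E, labels, "Cerebellum")
            for structure in CTDCS_SPREAD_STRUCTURES:
                if structure in report.tissues_E:
                    report.spread70[structure] = spread_to_structure(
                        E, labels, structure, cb.p99
                    )
    else:
        segments = labels.segments
        if not segments:
            raise AnalysisError("tsDCS mode requires phantom segment bounds")
        for seg, zr in segments.items():
            st = try_stats("Spinal cord", zr)
            if st:
                report.cord_segments_E[seg] = st
            nerve = try_stats("Nerve", zr)
            if nerve:
                report.nerves_E[seg] = nerve
        try:
            report.cauda_E = tissue_stats(E, labels, "Cauda equina")
        except AnalysisError:
            report.warnings.append("tissue absent, stats omitted: Cauda equina")
        try:
            cord_segs = {
                s: zr for s, zr in segments.items()
                if s in report.cord_segments_E
            }
            report.cv_profile = slice_cv(E, labels, "Spinal cord", cord_segs)
            report.r_profile = longitudinal_ratio(E, labels, "Spinal cord", cord_segs)
        except AnalysisError as exc:
            report.warnings.append(f"cord profiles omitted: {exc}")

    heart_E = try_stats("Hearth muscle")
    if heart_E:
        report.heart_E = heart_E
        report.heart_J = tissue_stats(J, labels, "Hearth muscle")
        report.safety_margin = FIBRILLATION_THRESHOLD / report.heart_J.p99
    return report
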