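"""End-to-end orchestration: phantom -> montage -> solve -> metrics.

A :class:`RunConfig` (built in code, from YAML, or from a named preset)
drives one stimulation run and produces an :class:`ExposureReport` plus the
intermediate volumes (labels, sigma, phi, |E|) as NIfTI files.  Every output
embeds a provenance hash of the configuration, so identical config + seed
reproduces bit-identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import field_analysis as fa
from .montage import (
    CTDCS_CURRENT,
    TSDCS_CURRENT,
    ElectrodeSpec,
    Montage,
    Placement,
    build_montage,
)
from .phantoms import (
    HEAD_PRESETS,
    TRUNK_PRESETS,
    HeadPhantomSpec,
    TrunkPhantomSpec,
    make_head_phantom,
    make_trunk_phantom,
)
from .solver import SolverConfig, injected_current, scale_to_target, solve_potential
from .volume import LabelVolume, build_sigma_volume

__all__ = [
    "RunConfig",
    "RunArtifacts",
    "execute",
    "run",
    "validate_config",
    "sweep",
    "default_montage",
]

log = logging.getLogger("voxdcs")


@dataclass(frozen=True)
class RunConfig:
    """One stimulation run: phantom, montage, solver and metric options."""

    mode: str = "ctdcs"                       # "ctdcs" | "tsdcs"
    preset: str = "roberta"
    spacing: float = 1.0
    seed: int = 0
    phantom_overrides: dict = field(default_factory=dict)
    montage_overrides: dict = field(default_factory=dict)
    solver: SolverConfig = field(default_factory=SolverConfig)
    averaging_window_mm: float = 2.0
    r_method: str = "voxelwise"
    target_current: float | None = None       # None -> mode default

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValueError(f"unparseable config file: {path}")
        solver = SolverConfig(**raw.pop("solver", {}))
        return cls(solver=solver, **raw)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return d

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    def phantom_spec(self):
        presets = HEAD_PRESETS if self.mode == "ctdcs" else TRUNK_PRESETS
        if self.preset not in presets:
            raise ValueError(
                f"unknown preset {self.preset!r}; available: {sorted(presets)}"
            )
        spec = presets[self.preset]
        return replace(
            spec, spacing=self.spacing, seed=self.seed, **self.phantom_overrides
        )

    def current(self) -> float:
        if self.target_current is not None:
            return self.target_current
        return CTDCS_CURRENT if self.mode == "ctdcs" else TSDCS_CURRENT


def default_montage(mode: str, target_current: float, **overrides) -> Montage:
    """The study montages.

    ctDCS: 5x5 cm active pad over the cerebellar scalp (2 cm below the
    inion), 5x5 cm reference on the arm, 2 mA.  tsDCS: 5x3 cm active pad
    over the T10 spinous process, 5x5 cm reference on the arm, 3 mA.
    """
    if mode == "ctdcs":
        m = Montage(
            active=ElectrodeSpec(width=50, height=50, role="active"),
            active_placement=Placement(anchor="ctdcs_active", normal_axis="-y"),
            reference=ElectrodeSpec(width=50, height=50, role="reference"),
            reference_placement=Placement(anchor="arm", normal_axis="+x"),
            target_current=target_current,
        )
    else:
        m = Montage(
            active=ElectrodeSpec(width=50, height=30, role="active"),
            active_placement=Placement(anchor="t10", normal_axis="-y"),
            reference=ElectrodeSpec(width=50, height=50, role="reference"),
            reference_placement=Placement(anchor="arm", normal_axis="+x"),
            target_current=target_current,
        )
    return replace(m, **overrides) if overrides else m


def validate_config(config: RunConfig) -> list[str]:
    """Static config checks; returns findings (prefixed ``error:``/``warning:``)."""
    findings: list[str] = []
    if config.mode not in ("ctdcs", "tsdcs"):
        findings.append(f"error: unknown mode {config.mode!r}")
        return findings
    presets = HEAD_PRESETS if config.mode == "ctdcs" else TRUNK_PRESETS
    if config.preset not in presets:
        findings.append(
            f"error: preset {config.preset!r} not available for mode {config.mode}"
        )
    if config.averaging_window_mm < config.spacing:
        findings.append(
            f"error: averaging window {config.averaging_window_mm} mm smaller "
            f"than voxel spacing {config.spacing} mm"
        )
    if config.spacing > 2.0:
        findings.append(
            f"warning: spacing {config.spacing} mm is coarse for cord-scale "
            "structures"
        )
    if config.current() <= 0:
        findings.append("error: target current must be positive")
    try:
        config.phantom_spec()
    except Exception as exc:  # surface phantom spec errors without running
        findings.append(f"error: phantom spec invalid: {exc}")
    if config.r_method not in ("voxelwise", "slice_mean"):
        findings.append(f"error: unknown r_method {config.r_method!r}")
    return findings


def _build_phantom(config: RunConfig) -> LabelVolume:
    spec = config.phantom_spec()
    if isinstance(spec, HeadPhantomSpec):
        return make_head_phantom(spec)
    return make_trunk_phantom(spec)


@dataclass
class RunArtifacts:
    """Everything one stimulation run produces, kept in memory."""

    config: RunConfig
    labels: LabelVolume          # with electrodes placed
    sigma: Any
    phi: Any
    E: fa.VectorField            # raw field
    E_avg: fa.VectorField        # vector-averaged field (metrics input)
    J: fa.VectorField
    raw_current: float
    report: fa.ExposureReport


def execute(config: RunConfig) -> RunArtifacts:
    """Run phantom -> montage -> solve -> metrics, returning all artifacts."""
    findings = validate_config(config)
    errors = [f for f in findings if f.startswith("error:")]
    if errors:
        raise ValueError("; ".join(errors))

    t0 = time.perf_counter()
    log.info("building %s phantom (preset %s, %.2g mm)",
             config.mode, config.preset, config.spacing)
    labels = _build_phantom(config)

    montage = default_montage(
        config.mode, config.current(), **config.montage_overrides
    )
    labels_m, anode, cathode, i_target = build_montage(labels, montage)
    sigma = build_sigma_volume(labels_m)
    log.info("solving %d-voxel grid", int(np.count_nonzero(sigma.sigma > 0)))

    phi = solve_potential(sigma, anode, cathode, config.solver)
    i_raw = injected_current(phi, sigma, anode)
    phi = scale_to_target(phi, i_raw, i_target)
    log.info("solved in %d iterations (residual %.2e), I_raw=%.3g A",
             phi.iterations, phi.residual, i_raw)

    E = fa.electric_field(phi, sigma, labels_m)
    E_avg = fa.icnirp_average(E, labels_m, config.averaging_window_mm)
    J = fa.current_density(E_avg, sigma)

    report = fa.exposure_report(
        E_avg, J, labels_m, config.mode, i_target,
        montage_info={
            "active_size_mm": [montage.active.width, montage.active.height],
            "reference_size_mm": [montage.reference.width, montage.reference.height],
            "active_anchor": str(montage.active_placement.anchor),
            "reference_anchor": str(montage.reference_placement.anchor),
            "target_current_mA": i_target * 1e3,
        },
        solver_info={
            "iterations": phi.iterations,
            "residual": phi.residual,
            "raw_current_A": i_raw,
            "scale": phi.scale,
            "voltage_V": phi.voltage,
        },
        provenance={"config_hash": config.hash(), "config": config.to_dict()},
    )
    log.info("run complete in %.1f s (%d warnings)",
             time.perf_counter() - t0, len(report.warnings))
    return RunArtifacts(
        config=config, labels=labels_m, sigma=sigma, phi=phi,
        E=E, E_avg=E_avg, J=J, raw_current=i_raw, report=report,
    )


def run(
    config: RunConfig, outdir: str | Path | None = None
) -> fa.ExposureReport:
    """Execute one full run; optionally write all artifacts to ``outdir``."""
    art = execute(config)
    if outdir is not None:
        _write_artifacts(art, Path(outdir))
    return art.report


def _write_artifacts(art: RunArtifacts, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    art.labels.save(outdir / "labels.nii.gz")
    art.sigma.save(outdir / "sigma.nii.gz")
    # phi keeps NaN on undefined voxels so downstream stages can re-mask
    _save_scalar(art.phi.phi, art.labels, outdir / "phi.nii.gz", keep_nan=True)
    _save_scalar(art.E_avg.magnitude(), art.labels, outdir / "E_magnitude.nii.gz")
    art.report.save(outdir)
    (outdir / "solve.json").write_text(json.dumps({
        "mode": art.config.mode,
        "target_current_A": art.config.current(),
        "raw_current_A": art.raw_current,
        "residual": art.phi.residual,
        "iterations": art.phi.iterations,
        "averaging_window_mm": art.config.averaging_window_mm,
        "config_hash": art.config.hash(),
    }, indent=1))


def solve_stage(config: RunConfig, outdir: str | Path) -> RunArtifacts:
    """Run through the solve and write every artifact for later analysis."""
    art = execute(config)
    _write_artifacts(art, Path(outdir))
    return art


def analyze_stage(rundir: str | Path) -> fa.ExposureReport:
    """Recompute the exposure report from a solved run directory on disk."""
    import nibabel as nib

    from .solver import PotentialField
    from .volume import ConductivityVolume

    rundir = Path(rundir)
    labels = LabelVolume.load(rundir / "labels.nii.gz")
    meta = json.loads((rundir / "solve.json").read_text())
    sigma_img = nib.load(rundir / "sigma.nii.gz")
    sigma = ConductivityVolume(
        grid=labels.grid, sigma=np.asarray(sigma_img.dataobj, dtype=np.float64)
    )
    phi_img = nib.load(rundir / "phi.nii.gz")
    shape = labels.grid.shape
    phi = PotentialField(
        grid=labels.grid, phi=np.asarray(phi_img.dataobj, dtype=np.float64),
        anode=np.zeros(shape, bool), cathode=np.zeros(shape, bool),
        residual=meta["residual"], iterations=meta["iterations"],
        voltage=float("nan"),
    )
    E = fa.electric_field(phi, sigma, labels)
    E_avg = fa.icnirp_average(E, labels, meta["averaging_window_mm"])
    J = fa.current_density(E_avg, sigma)
    report = fa.exposure_report(
        E_avg, J, labels, meta["mode"], meta["target_current_A"],
        solver_info={k: meta[k] for k in ("residual", "iterations")},
        provenance={"config_hash": meta["config_hash"]},
    )
    report.save(rundir)
    return report


def _save_scalar(
    arr: np.ndarray, labels: LabelVolume, path: Path, keep_nan: bool = False
) -> None:
    import nibabel as nib

    data = arr if keep_nan else np.nan_to_num(arr)
    img = nib.Nifti1Image(data.astype(np.float32), labels.grid.affine())
    img.header.set_zooms((labels.grid.spacing,) * 3)
    nib.save(img, path)


def _get_path(obj: Any, path: str) -> Any:
    cur: Any = obj
    for part in path.split("."):
        if isinstance(cur, dict):
            cur = cur[part]
        else:
            cur = getattr(cur, part)
    return cur


def sweep(
    base: RunConfig,
    parameter: str,
    values: list,
    metrics: list[str],
) -> "pd.DataFrame":
    """Run once per parameter value and tabulate the requested metrics.

    ``parameter`` is a dotted config path (``spacing``, ``seed`` or
    ``phantom.<field>`` which targets ``phantom_overrides``); ``metrics`` are
    dotted report paths such as ``tissues_E.Cerebellum.median`` or ``v50``.
    Failed runs are recorded with an ``error`` column and the sweep continues.
    """
    import pandas as pd

    rows = []
    for value in values:
        if parameter.startswith("phantom."):
            overrides = dict(base.phantom_overrides)
            overrides[parameter.split(".", 1)[1]] = value
            cfg = replace(base, phantom_overrides=overrides)
        else:
            cfg = replace(base, **{parameter: value})
        row: dict[str, Any] = {parameter: value}
        try:
            report = run(cfg)
            for metric in metrics:
                row[metric] = _get_path(report, metric)
        except Exception as exc:
            row["error"] = str(exc)
            log.warning("sweep value %r failed: %s", value, exc)
        rows.append(row)
    return pd.DataFrame(rows)
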