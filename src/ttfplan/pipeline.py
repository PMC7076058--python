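"""End-to-end orchestration: phantom -> layout -> solve -> metrics -> report.

``run_pipeline`` is the programmatic entry point mirrored by the ``ttfp
run`` command: it builds (or loads) the head volume, realizes the
requested montage configurations, solves both channels per configuration,
computes EVH/CDVH curves and PQM records for the GTV and cerebellum, and
assembles the cross-configuration comparison report. Every artifact is
written under the output directory together with a manifest (config hash,
seed, package versions) so a run is reproducible from its outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .grids import VoxelGrid
from .layout import CONFIGURATIONS, named_configuration, rasterize_electrodes, save_layout
from .metrics import PQMRecord, compute_evh, pqm
from .phantom import (
    ConductivityTable,
    LabelVolume,
    PhantomSpec,
    ROIMask,
    assign_conductivity,
    build_phantom,
    read_label_volume,
    write_label_volume,
    write_mask,
)
from .report import ComparisonReport, build_report, export_overlay
from .solver import ChannelSolution, SolveSettings, combine_channels, solve_channel

log = logging.getLogger("ttfplan")

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "make_fixtures", "solve_configuration"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Declarative description of one full planning run."""

    phantom: PhantomSpec | str | Path = field(default_factory=PhantomSpec)
    configurations: tuple[str, ...] = CONFIGURATIONS
    layout_params: dict = field(default_factory=dict)
    conductivity: ConductivityTable = field(default_factory=ConductivityTable)
    settings: SolveSettings = field(default_factory=SolveSettings)
    out_dir: str | Path = "ttfplan_out"
    seed: int = 0
    write_fields: bool = True
    write_overlays: bool = False

    def __post_init__(self) -> None:
        if not self.configurations:
            raise ValueError("at least one configuration is required")
        unknown = set(self.configurations) - set(CONFIGURATIONS)
        if unknown:
            raise ValueError(f"unknown configurations: {sorted(unknown)}")

    def content_hash(self) -> str:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (tuple, list)):
                return [enc(v) for v in obj]
            if isinstance(obj, dict):
                return {str(k): enc(v) for k, v in obj.items()}
            if isinstance(obj, Path):
                return str(obj)
            return obj

        doc = json.dumps(enc(self), sort_keys=True, default=str)
        return hashlib.sha256(doc.encode()).hexdigest()[:16]


def _load_phantom(config: RunConfig) -> tuple[LabelVolume, dict[str, ROIMask]]:
    if isinstance(config.phantom, (str, Path)):
        volume = read_label_volume(config.phantom)
        from .phantom import Tissue

        masks = {
            "GTV": ROIMask(volume.grid, "GTV", volume.mask(Tissue.GTV, Tissue.NECROTIC_CORE)),
            "CEREBELLUM": ROIMask(volume.grid, "CEREBELLUM", volume.mask(Tissue.CEREBELLUM)),
        }
        return volume, masks
    spec = dataclasses.replace(config.phantom, seed=config.seed)
    return build_phantom(spec)


def solve_configuration(
    volume: LabelVolume,
    name: str,
    *,
    layout_params: dict | None = None,
    conductivity: ConductivityTable | None = None,
    settings: SolveSettings | None = None,
):
    """Realize and solve one named montage on a labeled head volume.

    Returns ``(layout, model, ap_pa_solution, left_right_solution)``.
    """
    settings = settings or SolveSettings()
    layout = named_configuration(name, volume, layout_params)
    model = rasterize_electrodes(layout, volume)
    sigma = assign_conductivity(model.volume, conductivity)
    solutions = {}
    for channel in ("AP_PA", "LEFT_RIGHT"):
        anode_arr, cathode_arr = layout.channel_arrays(channel)
        solutions[channel] = solve_channel(
            sigma, volume.grid,
            model.electrode_indices(anode_arr.array_id),
            model.electrode_indices(cathode_arr.array_id),
            settings, channel=channel,
        )
    return layout, model, solutions["AP_PA"], solutions["LEFT_RIGHT"]


def _write_field(arr: np.ndarray, grid: VoxelGrid, path: Path) -> None:
    import nibabel as nib

    img = nib.Nifti1Image(arr.astype(np.float32), grid.affine)
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


def run_pipeline(config: RunConfig) -> tuple[ComparisonReport, list[PQMRecord]]:
    """Run the full comparison pipeline and write all artifacts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "phantom"
    try:
        volume, masks = _load_phantom(config)
        write_label_volume(volume, out / "phantom_labels.nii.gz")
        for name, mask in masks.items():
            write_mask(mask, out / f"mask_{name.lower()}.nii.gz")

        records: list[PQMRecord] = []
        for name in config.configurations:
            stage = f"configuration {name}"
            log.info("solving configuration %s", name)
            cfg_dir = out / name.lower()
            cfg_dir.mkdir(exist_ok=True)
            layout, model, sol_ap, sol_lr = solve_configuration(
                volume, name,
                layout_params=config.layout_params,
                conductivity=config.conductivity,
                settings=config.settings,
            )
            save_layout(layout, cfg_dir / "layout.json")
            e_mag = combine_channels(sol_ap, sol_lr, config.settings.combine_mode, "E")
            cd_mag = combine_channels(sol_ap, sol_lr, config.settings.combine_mode, "CD")
            if config.settings.combine_mode == "per_channel":
                e_mag = 0.5 * (e_mag[0] + e_mag[1])
                cd_mag = 0.5 * (cd_mag[0] + cd_mag[1])
            if config.write_fields:
                _write_field(e_mag, volume.grid, cfg_dir / "E_magnitude.nii.gz")
                _write_field(cd_mag, volume.grid, cfg_dir / "J_magnitude.nii.gz")
            solver_log = {
                ch: {
                    "iterations": s.iterations,
                    "residual": s.residual,
                    "applied_voltage_V": s.applied_voltage,
                    "delivered_current_A": s.current,
                    "current_balance": abs(s.anode_current + s.cathode_current)
                    / abs(s.anode_current),
                }
                for ch, s in (("AP_PA", sol_ap), ("LEFT_RIGHT", sol_lr))
            }
            (cfg_dir / "solver.json").write_text(json.dumps(solver_log, indent=2, sort_keys=True))
            for roi_name, mask in masks.items():
                if mask.voxel_count == 0:
                    log.warning("skipping empty ROI %s", roi_name)
                    continue
                for tag, fld in (("E", e_mag), ("CD", cd_mag)):
                    curve = compute_evh(fld, mask, quantity=tag)
                    curve.to_frame().to_csv(
                        cfg_dir / f"{tag.lower()}vh_{roi_name.lower()}.csv", index=False
                    )
                records.append(pqm(e_mag, cd_mag, mask, name, roi=roi_name))
            if config.write_overlays:
                k = int(np.rint(volume.grid.world_to_voxel(
                    np.array([0.0, 0.0, 0.0]))[2]))
                export_overlay(volume, e_mag, "sagittal",
                               volume.grid.shape[0] // 2, cfg_dir / "overlay_sagittal.png")
                export_overlay(volume, e_mag, "axial", max(k, 0),
                               cfg_dir / "overlay_axial.png")

        stage = "report"
        baseline = (
            "SUPRATENTORIAL" if "SUPRATENTORIAL" in config.configurations
            else config.configurations[0]
        )
        report = build_report(records, baseline=baseline)
        report.to_csv(out)
        (out / "report.json").write_text(json.dumps(report.to_json(), indent=2, sort_keys=True))
        manifest = {
            "package": "ttfplan",
            "version": __version__,
            "config_hash": config.content_hash(),
            "seed": config.seed,
            "configurations": list(config.configurations),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return report, records
    except Exception as exc:
        raise PipelineError(f"pipeline failed during stage '{stage}': {exc}") from exc


# ----------------------------------------------------------------------
# Analytic fixtures
# ----------------------------------------------------------------------

def make_fixtures(seed: int = 0) -> dict:
    """Deterministic small test volumes.

    * ``slab`` — homogeneous cuboid with full opposite-face electrodes
      (parallel-plate analytic case).
    * ``two_layer`` — series slab with a 2:1 conductivity step.
    * ``random_phi`` — random potential on an 8^3 grid (stencil oracle).
    * ``mini_phantom`` — reduced head for fast end-to-end tests.
    """
    rng = np.random.default_rng(seed)
    grid = VoxelGrid(shape=(11, 8, 8), spacing=(10.0, 10.0, 10.0), origin=(0.0, 0.0, 0.0))
    sigma = np.full(grid.shape, 0.3)
    anode = np.array([(0, j, k) for j in range(8) for k in range(8)])
    cathode = np.array([(10, j, k) for j in range(8) for k in range(8)])

    sigma2 = np.full(grid.shape, 0.2)
    sigma2[:5] = 0.4  # layer 1 twice as conductive as layer 2

    from .phantom import mini_spec

    fixtures = {
        "slab": {"grid": grid, "sigma": sigma, "anode": anode, "cathode": cathode},
        "two_layer": {"grid": grid, "sigma": sigma2, "anode": anode, "cathode": cathode},
        "random_phi": {
            "grid": VoxelGrid((8, 8, 8), (5.0, 5.0, 5.0), (0.0, 0.0, 0.0)),
            "phi": rng.normal(size=(8, 8, 8)),
        },
        "mini_phantom_spec": mini_spec(),
    }
    return fixtures
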