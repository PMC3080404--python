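"""Config-driven orchestration of the full flexibility report.

Assembles the analyses into one deterministic output bundle: per-residue
RMSD-to-mean profile, crystallographic vs trajectory B-factor overlay,
quasiharmonic mode table with extreme-conformation PDB pairs, loop
displacement summary, and the conserved-residue fractional-ASA table.
Every number in every table comes from one library operation; this layer
only wires them together and writes files.
"""

from __future__ import annotations

import dataclasses
import datetime
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .flexprofile import compare_profiles, mainchain_b_profile, normalize_b
from .quasiharmonic import (
    analyze_trajectory,
    extreme_conformations,
    loop_displacement_summary,
    variance_fraction,
)
from .sasa import AsaParams, conserved_residue_report
from .structure_io import (
    Conformer,
    Trajectory,
    build_ensemble,
    read_pdb,
    read_xyz_trajectory,
    write_pdb,
)
from .superpose import ensemble_superpose, per_residue_rmsd, superpose_trajectory

__all__ = ["RunConfig", "load_config", "run_flexibility_report"]

# Petal-like loop boundaries and family-conserved residues of the
# H. pylori MotB peptidoglycan-binding domain (author numbering).
DEFAULT_LOOP_RANGES: dict[str, tuple[int, int]] = {
    "beta1alpha1": (126, 133),
    "beta2alpha2": (163, 174),
    "beta3beta4": (207, 225),
}
DEFAULT_CONSERVED_RESIDUES: list[tuple[int, str]] = [
    (161, "GLY"),
    (164, "ASP"),
    (179, "LEU"),
    (183, "ARG"),
    (226, "ARG"),
]


@dataclasses.dataclass
class RunConfig:
    """Inputs and parameters for one flexibility report."""

    structures: list[str]
    output_dir: str
    chains: list[str] | None = None  # keep only these chain ids (None: all)
    excluded_ranges: list[tuple[int, int]] = dataclasses.field(default_factory=list)
    trajectory: str | None = None
    trajectory_format: str = "pdb_models"  # or "xyz"
    trajectory_topology: str | None = None  # PDB supplying atom metadata for xyz
    frame_interval: float = 5.0  # ps
    loop_ranges: dict[str, tuple[int, int]] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_LOOP_RANGES)
    )
    conserved_residues: list[tuple[int, str]] = dataclasses.field(
        default_factory=lambda: list(DEFAULT_CONSERVED_RESIDUES)
    )
    probe_radius: float = 1.4
    asa_n_points: int = 960
    pca_interval_ps: float = 5.0
    temperature_K: float = 310.0
    energy_kT: float = 2.0
    n_modes_report: int = 3
    run_asa: bool = True
    make_plot: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.structures and self.trajectory is None:
            raise ValueError("config needs at least one structure or a trajectory")
        for lo, hi in list(self.excluded_ranges) + list(self.loop_ranges.values()):
            if lo > hi:
                raise ValueError(f"malformed residue range {lo}-{hi}")


def load_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from a YAML key-value file."""
    raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
    if "loop_ranges" in raw:
        raw["loop_ranges"] = {k: tuple(v) for k, v in raw["loop_ranges"].items()}
    if "excluded_ranges" in raw:
        raw["excluded_ranges"] = [tuple(v) for v in raw["excluded_ranges"]]
    if "conserved_residues" in raw:
        spec = raw["conserved_residues"]
        if isinstance(spec, str):  # compact "161:GLY,164:ASP" form
            spec = [item.split(":") for item in spec.split(",") if item.strip()]
        raw["conserved_residues"] = [(int(n), str(c).strip()) for n, c in spec]
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


class _Bundle:
    """Tracks files written during a run so failures leave no partial bundle."""

    def __init__(self, outdir: Path):
        self.outdir = outdir
        self.written: list[Path] = []

    def path(self, name: str) -> Path:
        p = self.outdir / name
        self.written.append(p)
        return p

    def cleanup(self) -> None:
        for p in self.written:
            p.unlink(missing_ok=True)


def _load_conformers(config: RunConfig) -> list[Conformer]:
    conformers: list[Conformer] = []
    for path in config.structures:
        conformers.extend(read_pdb(path, model_policy="all_models"))
    if config.chains is not None:
        keep = set(config.chains)
        conformers = [c for c in conformers if c.atoms[0].chain_id in keep]
    if not conformers:
        raise ValueError("no conformers remain after chain selection")
    return conformers


def _load_trajectory(config: RunConfig) -> Trajectory:
    if config.trajectory_format == "pdb_models":
        frames = read_pdb(config.trajectory, model_policy="all_models")
        coords = np.stack([f.coords for f in frames])
        meta = frames[0].atoms
        return Trajectory(
            coords=coords,
            frame_interval=config.frame_interval,
            masses=frames[0].masses,
            atom_meta=meta,
        )
    if config.trajectory_format == "xyz":
        if config.trajectory_topology is None:
            raise ValueError("xyz trajectories need trajectory_topology (a PDB file)")
        meta = read_pdb(config.trajectory_topology)[0].atoms
        return read_xyz_trajectory(config.trajectory, config.frame_interval, meta)
    raise ValueError(f"unknown trajectory_format {config.trajectory_format!r}")


def run_flexibility_report(config: RunConfig) -> dict[str, Path]:
    """Run every analysis the config enables and write the output bundle.

    Returns a mapping from output name to file path.  On failure in any
    stage the files written so far are removed and the error is re-raised
    with the stage name.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = _Bundle(outdir)
    outputs: dict[str, Path] = {}
    log_lines: list[str] = [
        f"flexscan {__version__} flexibility report",
        f"generated: {datetime.datetime.now().isoformat(timespec='seconds')}",
        "config:",
    ]
    for f in dataclasses.fields(config):
        log_lines.append(f"  {f.name}: {getattr(config, f.name)!r}")
    log_lines.append(
        "conventions: Calpha superposition to converged mean (tol 1e-6 A); "
        "main-chain B over N,CA,C,O; population-variance normalization; "
        "Chothia-style vdW radii; Gly-X-Gly extended reference state"
    )

    stage = "load_structures"
    try:
        conformers = _load_conformers(config) if config.structures else []

        if len(conformers) >= 2:
            stage = "rmsd_profile"
            ensemble = build_ensemble(
                conformers, selection=("CA",), excluded_ranges=config.excluded_ranges
            )
            fit = ensemble_superpose(ensemble)
            profile = per_residue_rmsd(fit, ensemble)
            p = bundle.path("rmsd_profile.tsv")
            profile.to_tsv(p)
            outputs["rmsd_profile"] = p
            peak = int(np.argmax(profile.values))
            log_lines.append(
                f"rmsd_profile: {ensemble.n_conformers} conformers, "
                f"{len(profile.values)} residues, converged={fit.converged} "
                f"in {fit.iterations} iterations; peak residue "
                f"{profile.residue_numbers[peak]} at {profile.values[peak]:.2f} A"
            )
        else:
            log_lines.append("rmsd_profile: skipped (fewer than 2 conformers)")

        trajectory = None
        fitted = None
        if config.trajectory is not None:
            stage = "load_trajectory"
            trajectory = _load_trajectory(config)
            fitted = superpose_trajectory(trajectory)

        stage = "bfactor_overlay"
        cryst_norm = traj_norm = None
        if conformers:
            try:
                cryst_norm = normalize_b(mainchain_b_profile(conformers))
            except ValueError as exc:
                log_lines.append(f"bfactor_overlay: no crystallographic series ({exc})")
        if trajectory is not None:
            traj_norm = normalize_b(mainchain_b_profile(trajectory, fitted))
        if cryst_norm is not None or traj_norm is not None:
            p = bundle.path("bfactor_overlay.tsv")
            _write_overlay(p, cryst_norm, traj_norm)
            outputs["bfactor_overlay"] = p
            if cryst_norm is not None and traj_norm is not None:
                cmp_ = compare_profiles(cryst_norm, traj_norm)
                log_lines.append(
                    f"bfactor_overlay: pearson_r={cmp_.pearson_r:.3f} over "
                    f"{cmp_.n_shared} shared residues"
                )
            if config.make_plot:
                plot = bundle.path("bfactor_overlay.png")
                _plot_overlay(plot, cryst_norm, traj_norm)
                outputs["bfactor_plot"] = plot

        if trajectory is not None:
            stage = "quasiharmonic"
            modes = analyze_trajectory(trajectory, fitted, config.pca_interval_ps)
            p = bundle.path("modes.tsv")
            modes.to_tsv(p)
            outputs["modes"] = p
            k = min(config.n_modes_report, modes.n_modes)
            log_lines.append(
                f"quasiharmonic: {modes.n_frames_used} frames at "
                f"{modes.stride_ps:.1f} ps; top-{k} variance fraction "
                f"{variance_fraction(modes, k):.3f}"
            )
            for mode in range(k):
                plus, minus = extreme_conformations(
                    modes, mode, config.energy_kT, config.temperature_K
                )
                p = bundle.path(f"mode_{mode + 1}_extremes.pdb")
                write_pdb([plus, minus], p)
                outputs[f"mode_{mode + 1}_extremes"] = p
            stage = "loop_summary"
            p = bundle.path("loop_summary.tsv")
            _write_loop_summary(p, modes, k, config)
            outputs["loop_summary"] = p
        else:
            log_lines.append("quasiharmonic: skipped (no trajectory input)")

        if config.run_asa and conformers:
            stage = "asa_table"
            params = AsaParams(
                probe_radius=config.probe_radius, n_points=config.asa_n_points
            )
            table = conserved_residue_report(
                conformers, config.conserved_residues, params
            )
            p = bundle.path("asa_table.tsv")
            table.to_csv(p, sep="\t", index=False, float_format="%.4f")
            outputs["asa_table"] = p
            log_lines.append(
                "asa_table: "
                + ", ".join(
                    f"{r.residue_name}{r.residue_number}="
                    f"{r.fractional_asa_rounded:.2f}"
                    for r in table.itertuples()
                )
            )
    except Exception as exc:
        bundle.cleanup()
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    log = bundle.path("run.log")
    log.write_text("\n".join(log_lines) + "\n")
    outputs["run_log"] = log
    return outputs


def _write_overlay(path: Path, cryst, traj) -> None:
    residues = sorted(
        set(cryst.residue_numbers if cryst else [])
        | set(traj.residue_numbers if traj else [])
    )
    d_c = cryst.as_dict() if cryst else {}
    d_t = traj.as_dict() if traj else {}
    with open(path, "w") as fh:
        fh.write("residue_number\tcrystallographic_B_norm\ttrajectory_B_norm\n")
        for rn in residues:
            c = f"{d_c[rn]:.6f}" if rn in d_c else "NA"
            t = f"{d_t[rn]:.6f}" if rn in d_t else "NA"
            fh.write(f"{rn}\t{c}\t{t}\n")


def _plot_overlay(path: Path, cryst, traj) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3))
    if cryst is not None:
        ax.plot(cryst.residue_numbers, cryst.values, "-", label="crystallographic")
    if traj is not None:
        ax.plot(traj.residue_numbers, traj.values, ":", label="trajectory")
    ax.set_xlabel("residue number")
    ax.set_ylabel("normalized main-chain B")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _write_loop_summary(path: Path, modes, n_modes: int, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write("mode\tloop\tdisplacement_A\tdirection_cosines\n")
        for mode in range(n_modes):
            summary = loop_displacement_summary(
                modes, mode, config.loop_ranges, config.energy_kT
            )
            for i, name in enumerate(summary.names):
                cos = ",".join(
                    f"{other}:{summary.direction_cosines[i, j]:+.3f}"
                    for j, other in enumerate(summary.names)
                    if j != i
                )
                fh.write(
                    f"{mode + 1}\t{name}\t{summary.magnitudes[i]:.4f}\t{cos}\n"
                )
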