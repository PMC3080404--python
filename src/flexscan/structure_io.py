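"""Structure and trajectory I/O.

Reads protein chains out of PDB-format files into light-weight
:class:`Conformer` objects, builds the atom correspondence
(:class:`Ensemble`) that the superposition and profiling code relies on,
and reads/writes plain-text XYZ-frame trajectories.

Author residue numbering is preserved throughout; hydrogens, waters and
hetero groups are dropped on input.  Alternate locations are resolved to
the highest-occupancy record (ties broken by file order).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "Conformer",
    "Ensemble",
    "Trajectory",
    "PdbParseError",
    "read_pdb",
    "write_pdb",
    "build_ensemble",
    "read_xyz_trajectory",
    "write_xyz_trajectory",
    "element_mass",
    "ELEMENT_MASSES",
]

# Atomic masses (amu) for elements found in protein heavy-atom models.
# Unknown elements raise rather than defaulting silently.
ELEMENT_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "SE": 78.971,
    "F": 18.998,
    "CL": 35.45,
    "BR": 79.904,
    "I": 126.904,
    "FE": 55.845,
    "ZN": 65.38,
    "MG": 24.305,
    "MN": 54.938,
    "CU": 63.546,
    "NA": 22.990,
    "K": 39.098,
}

_MAINCHAIN_NAMES = ("N", "CA", "C", "O")


class PdbParseError(ValueError):
    """Raised for unparseable PDB content; carries file/line context."""


def element_mass(element: str) -> float:
    """Atomic mass in amu for an element symbol; unknown symbol is an error."""
    try:
        return ELEMENT_MASSES[element.strip().upper()]
    except KeyError:
        raise PdbParseError(f"no mass tabulated for element {element!r}") from None


@dataclasses.dataclass
class AtomRecord:
    """One atom of a protein chain (PDB column conventions)."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    xyz: np.ndarray  # (3,) Å
    occupancy: float = 1.0
    b_iso: float = 0.0
    mass: float = 0.0

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.mass <= 0.0:
            self.mass = element_mass(self.element)


@dataclasses.dataclass
class Conformer:
    """An ordered list of atoms from one chain (one monomer)."""

    label: str
    atoms: list[AtomRecord]

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array, Å."""
        return np.array([a.xyz for a in self.atoms], dtype=float)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    @property
    def residue_numbers(self) -> list[int]:
        return [a.residue_number for a in self.atoms]

    def atom_index(self) -> dict[tuple[int, str], int]:
        """(residue_number, atom_name) → position in ``atoms``."""
        return {(a.residue_number, a.name): i for i, a in enumerate(self.atoms)}

    def with_coords(self, coords: np.ndarray, label: str | None = None) -> "Conformer":
        """Copy of this conformer with replaced coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(
                f"coordinate array shape {coords.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        atoms = [dataclasses.replace(a, xyz=coords[i].copy()) for i, a in enumerate(self.atoms)]
        return Conformer(label=label or self.label, atoms=atoms)


@dataclasses.dataclass
class Ensemble:
    """N conformers with a common (residue_number, atom_name) correspondence."""

    conformers: list[Conformer]
    atom_map: list[tuple[int, str]]
    excluded_residues: list[tuple[int, int]] = dataclasses.field(default_factory=list)

    @property
    def n_conformers(self) -> int:
        return len(self.conformers)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_map)

    @property
    def mapped_residue_numbers(self) -> list[int]:
        """Sorted distinct residue numbers present in the atom map."""
        return sorted({rn for rn, _ in self.atom_map})

    def coords(self) -> np.ndarray:
        """(n_conformers, n_mapped_atoms, 3) coordinate array, Å."""
        out = np.empty((self.n_conformers, self.n_atoms, 3), dtype=float)
        for k, conf in enumerate(self.conformers):
            idx = conf.atom_index()
            for j, key in enumerate(self.atom_map):
                out[k, j] = conf.atoms[idx[key]].xyz
        return out

    def mapped_masses(self) -> np.ndarray:
        idx = self.conformers[0].atom_index()
        return np.array(
            [self.conformers[0].atoms[idx[key]].mass for key in self.atom_map], dtype=float
        )


@dataclasses.dataclass
class Trajectory:
    """Cartesian coordinate trajectory with a fixed frame interval."""

    coords: np.ndarray  # (n_frames, n_atoms, 3) Å
    frame_interval: float  # ps
    masses: np.ndarray  # (n_atoms,) amu
    atom_meta: list[AtomRecord]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (frames, atoms, 3)")
        if self.coords.shape[0] < 2:
            raise ValueError("a trajectory needs at least 2 frames")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive (ps)")
        if self.coords.shape[1] != len(self.masses) or len(self.masses) != len(self.atom_meta):
            raise ValueError("atom count mismatch between coords, masses and atom_meta")

    @property
    def n_frames(self) -> int:
        return int(self.coords.shape[0])

    @property
    def n_atoms(self) -> int:
        return int(self.coords.shape[1])


# ---------------------------------------------------------------------------
# PDB reading


def _resolve_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """One atom per name: highest occupancy wins, ties go to file order."""
    best: dict[str, gemmi.Atom] = {}
    for atom in residue:
        prev = best.get(atom.name)
        if prev is None or atom.occ > prev.occ + 1e-12:
            best[atom.name] = atom
    # preserve file order of the winning records
    chosen = set(id(a) for a in best.values())
    return [a for a in residue if id(a) in chosen]


def read_pdb(
    path: str | Path,
    model_policy: str = "first_model",
    keep_hydrogens: bool = False,
) -> list[Conformer]:
    """Read protein chains from a PDB file.

    Parameters
    ----------
    path:
        PDB-format text file.
    model_policy:
        ``"first_model"`` reads only the first MODEL block; ``"all_models"``
        yields one conformer per (MODEL, chain).
    keep_hydrogens:
        Hydrogens are dropped by default (heavy-atom analyses only).

    Returns
    -------
    One :class:`Conformer` per (model, chain) containing protein ATOM
    records; waters and hetero groups are dropped.
    """
    if model_policy not in ("first_model", "all_models"):
        raise ValueError(f"unknown model_policy {model_policy!r}")
    path = Path(path)
    try:
        st = gemmi.read_pdb(str(path), split_chain_on_ter=False)
    except (RuntimeError, ValueError) as exc:
        raise PdbParseError(f"{path}: {exc}") from exc

    label_base = path.stem.upper()
    conformers: list[Conformer] = []
    models = list(st)
    if model_policy == "first_model":
        models = models[:1]
    multi = len(models) > 1
    for model in models:
        for chain in model:
            atoms: list[AtomRecord] = []
            for residue in chain:
                if residue.het_flag != "A":
                    continue  # waters / hetero groups
                if residue.is_water():
                    continue
                for atom in _resolve_altlocs(residue):
                    element = atom.element.name.upper()
                    if element == "H" and not keep_hydrogens:
                        continue
                    if atom.is_hydrogen() and not keep_hydrogens:
                        continue
                    atoms.append(
                        AtomRecord(
                            serial=atom.serial,
                            name=atom.name,
                            element=element,
                            residue_name=residue.name,
                            residue_number=residue.seqid.num,
                            chain_id=chain.name or " ",
                            xyz=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                            occupancy=atom.occ,
                            b_iso=atom.b_iso,
                        )
                    )
            if atoms:
                label = f"{label_base}:{chain.name}"
                if multi:
                    label += f":m{model.num}"
                conformers.append(Conformer(label=label, atoms=atoms))
    if not conformers:
        raise PdbParseError(f"{path}: no protein ATOM records found")
    return conformers


# ---------------------------------------------------------------------------
# PDB writing


def _format_atom_line(a: AtomRecord, serial: int) -> str:
    for v in a.xyz:
        if not np.isfinite(v):
            raise ValueError(f"non-finite coordinate on atom {a.name} {a.residue_number}")
        if abs(v) >= 10000.0:
            raise ValueError(
                f"coordinate {v:.1f} Å on atom {a.name} {a.residue_number} "
                "overflows fixed-width PDB columns"
            )
    name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
    return (
        f"ATOM  {serial:5d} {name:4s} {a.residue_name:>3s} {a.chain_id:1s}"
        f"{a.residue_number:4d}    "
        f"{a.xyz[0]:8.3f}{a.xyz[1]:8.3f}{a.xyz[2]:8.3f}"
        f"{a.occupancy:6.2f}{a.b_iso:6.2f}          {a.element:>2s}"
    )


def write_pdb(conformers: Conformer | Sequence[Conformer], path: str | Path) -> None:
    """Write conformers as fixed-column PDB; >1 conformer → MODEL blocks.

    Round-trips through :func:`read_pdb` on names, residue numbers and
    coordinates to 3 decimals.
    """
    if isinstance(conformers, Conformer):
        conformers = [conformers]
    if not conformers:
        raise ValueError("nothing to write")
    lines: list[str] = []
    multi = len(conformers) > 1
    for m, conf in enumerate(conformers, start=1):
        if multi:
            lines.append(f"MODEL     {m:4d}")
        serial = 0
        for a in conf.atoms:
            serial += 1
            lines.append(_format_atom_line(a, serial))
        lines.append("TER")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Ensemble construction


def _in_ranges(residue_number: int, ranges: Iterable[tuple[int, int]]) -> bool:
    return any(lo <= residue_number <= hi for lo, hi in ranges)


def build_ensemble(
    conformers: Sequence[Conformer],
    selection: Sequence[str] | None = ("CA",),
    excluded_ranges: Sequence[tuple[int, int]] = (),
) -> Ensemble:
    """Build the common atom correspondence across conformers.

    ``atom_map`` is the intersection of (residue_number, atom_name) keys
    over all conformers, restricted to ``selection`` atom names (default:
    Cα only; ``None`` keeps every name) and with ``excluded_ranges``
    (inclusive residue-number ranges) removed.  Ordering is deterministic:
    by residue number, then atom name.
    """
    if len(conformers) < 2:
        raise ValueError("an ensemble needs at least 2 conformers")
    excluded = [(int(lo), int(hi)) for lo, hi in excluded_ranges]

    keysets = []
    for conf in conformers:
        keys = {
            (a.residue_number, a.name)
            for a in conf.atoms
            if (selection is None or a.name in selection)
            and not _in_ranges(a.residue_number, excluded)
        }
        keysets.append(keys)
    common = set.intersection(*keysets)
    if not common:
        sizes = [len(k) for k in keysets]
        culprit = conformers[int(np.argmin(sizes))].label
        raise ValueError(
            "empty atom correspondence across conformers; "
            f"first conformer lacking coverage: {culprit!r}"
        )
    atom_map = sorted(common)
    return Ensemble(conformers=list(conformers), atom_map=atom_map, excluded_residues=excluded)


# ---------------------------------------------------------------------------
# XYZ-frame trajectories


def read_xyz_trajectory(
    path: str | Path,
    frame_interval: float,
    atom_meta: Sequence[AtomRecord],
) -> Trajectory:
    """Read a plain-text XYZ trajectory (repeated natoms/comment/atom blocks).

    Masses are looked up from the element symbols in ``atom_meta``; the
    element column in the file must agree with ``atom_meta`` in count.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    frames: list[np.ndarray] = []
    i = 0
    frame_idx = 0
    n_expected = len(atom_meta)
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        frame_idx += 1
        try:
            natoms = int(lines[i].split()[0])
        except (ValueError, IndexError):
            raise PdbParseError(
                f"{path}: frame {frame_idx}: expected an atom count, got {lines[i]!r}"
            ) from None
        if natoms != n_expected:
            raise ValueError(
                f"{path}: frame {frame_idx} declares {natoms} atoms, "
                f"atom_meta has {n_expected}"
            )
        block = lines[i + 2 : i + 2 + natoms]
        if len(block) < natoms:
            raise ValueError(f"{path}: frame {frame_idx} is truncated")
        coords = np.empty((natoms, 3), dtype=float)
        for j, line in enumerate(block):
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{path}: frame {frame_idx}: bad atom line {line!r}")
            coords[j] = [float(parts[1]), float(parts[2]), float(parts[3])]
        frames.append(coords)
        i += 2 + natoms
    if len(frames) < 2:
        raise ValueError(f"{path}: fewer than 2 frames")
    masses = np.array([element_mass(a.element) for a in atom_meta])
    return Trajectory(
        coords=np.stack(frames),
        frame_interval=float(frame_interval),
        masses=masses,
        atom_meta=list(atom_meta),
    )


def write_xyz_trajectory(trajectory: Trajectory, path: str | Path) -> None:
    """Write a trajectory as repeated XYZ frames (element x y z, Å)."""
    lines: list[str] = []
    for f in range(trajectory.n_frames):
        lines.append(str(trajectory.n_atoms))
        lines.append(f"frame {f} t={f * trajectory.frame_interval:.3f} ps")
        for a, atom in enumerate(trajectory.atom_meta):
            x, y, z = trajectory.coords[f, a]
            lines.append(f"{atom.element:<2s} {x:12.6f} {y:12.6f} {z:12.6f}")
    Path(path).write_text("\n".join(lines) + "\n")
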