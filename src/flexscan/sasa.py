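"""Solvent-accessible surface area (Shrake–Rupley) and fractional
side-chain accessibility.

ASA is computed by rolling a 1.4 Å probe over van der Waals spheres:
each atom's sphere of expanded radius r + probe is sampled with a
deterministic golden-spiral point set and the fraction of points outside
every neighbour's expanded sphere gives the exposed area.  Fractional
side-chain accessibility divides a residue's side-chain ASA in the
structure by the side-chain ASA of the same residue type X in an
extended Gly-X-Gly reference tripeptide computed with identical
parameters (glycine's "side chain" is its Cα) — a buried residue scores
near 0, a fully exposed one near 1.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure_io import AtomRecord, Conformer
from .superpose import kabsch

__all__ = [
    "AsaParams",
    "VDW_RADII",
    "sphere_points",
    "atom_asa",
    "sidechain_fraction",
    "conserved_residue_report",
    "build_reference_tripeptide",
    "reference_sidechain_asa",
]

# Chothia-style van der Waals radii (Å), keyed by element symbol.
VDW_RADII: dict[str, float] = {
    "C": 1.80,
    "N": 1.65,
    "O": 1.40,
    "S": 1.85,
    "P": 1.90,
    "SE": 1.90,
    "H": 1.00,
}

_BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})


@dataclasses.dataclass(frozen=True)
class AsaParams:
    """Parameters of the Shrake–Rupley calculation."""

    probe_radius: float = 1.4  # Å
    n_points: int = 960
    radii_set: str = "chothia"

    def __post_init__(self) -> None:
        if self.probe_radius <= 0:
            raise ValueError("probe_radius must be positive")
        if self.n_points < 100:
            raise ValueError("n_points must be at least 100")

    def radius_of(self, atom: AtomRecord) -> float:
        try:
            return VDW_RADII[atom.element.upper()]
        except KeyError:
            raise ValueError(
                f"no van der Waals radius for atom {atom.name} "
                f"(element {atom.element!r}, residue {atom.residue_name} "
                f"{atom.residue_number})"
            ) from None


def sphere_points(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors on the sphere (deterministic golden spiral)."""
    if n < 1:
        raise ValueError("n must be at least 1")
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    golden_angle = math.pi * (3.0 - math.sqrt(5.0))
    phi = golden_angle * i
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def atom_asa(conformer: Conformer, params: AsaParams | None = None) -> np.ndarray:
    """Per-atom accessible surface area, Å² (Shrake–Rupley).

    For atom i with expanded radius R_i = r_i + probe, the ASA is
    4πR_i² times the fraction of sample points on its expanded sphere
    that fall inside no neighbour's expanded sphere.  The result is
    independent of atom order.
    """
    params = params or AsaParams()
    coords = conformer.coords
    radii = np.array([params.radius_of(a) for a in conformer.atoms])
    expanded = radii + params.probe_radius
    n = len(conformer.atoms)
    unit = sphere_points(params.n_points)
    tree = cKDTree(coords)
    r_max = expanded.max()
    asa = np.empty(n)
    for i in range(n):
        pts = coords[i] + expanded[i] * unit
        neighbors = [j for j in tree.query_ball_point(coords[i], expanded[i] + r_max)
                     if j != i and np.linalg.norm(coords[j] - coords[i]) < expanded[i] + expanded[j]]
        accessible = np.ones(params.n_points, dtype=bool)
        for j in neighbors:
            d2 = ((pts - coords[j]) ** 2).sum(axis=1)
            accessible &= d2 >= expanded[j] ** 2
        asa[i] = 4.0 * math.pi * expanded[i] ** 2 * accessible.mean()
    return asa


# ---------------------------------------------------------------------------
# Reference tripeptide (extended Gly-X-Gly) for fractional accessibility

_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_BOND_C_O = 1.231
_ANGLE_N_CA_C = 111.2
_ANGLE_CA_C_N = 116.2
_ANGLE_C_N_CA = 121.7
_ANGLE_CA_C_O = 120.8


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place a new atom from three parents (natural-extension reference frame)."""
    angle = math.radians(angle_deg)
    dihedral = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([
        -bond * math.cos(angle),
        bond * math.sin(angle) * math.cos(dihedral),
        bond * math.sin(angle) * math.sin(dihedral),
    ])
    return c + d[0] * bc + d[1] * m + d[2] * n


_STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP "
    "TYR VAL".split()
)


def _ideal_residue_heavy(residue_name: str) -> tuple[list[str], list[str], np.ndarray]:
    """Heavy-atom names, elements and ideal coordinates for a residue type."""
    from biotite.structure.info import residue as ccd_residue

    if residue_name.upper() not in _STANDARD_AA:
        raise ValueError(f"unknown residue type {residue_name!r}")
    tmpl = ccd_residue(residue_name.upper())
    if tmpl is None:
        raise ValueError(f"unknown residue type {residue_name!r}")
    keep = (tmpl.element != "H") & (tmpl.atom_name != "OXT")
    return (
        list(tmpl.atom_name[keep]),
        list(tmpl.element[keep]),
        np.asarray(tmpl.coord[keep], dtype=float),
    )


def build_reference_tripeptide(residue_name: str) -> Conformer:
    """Extended Gly-X-Gly tripeptide with ideal geometry for residue type X.

    The backbone is built at phi = psi = omega = 180° with standard bond
    lengths and angles; side-chain atoms take the ideal geometry of the
    chemical-component dictionary, rigidly fitted onto each residue's
    (N, Cα, C) frame.  Serves as the fully-exposed reference state for
    fractional side-chain accessibility.
    """
    seq = ["GLY", residue_name.upper(), "GLY"]
    # backbone trace via NeRF, extended conformation
    bb: list[dict[str, np.ndarray]] = []
    n0 = np.zeros(3)
    ca0 = np.array([_BOND_N_CA, 0.0, 0.0])
    ang = math.radians(_ANGLE_N_CA_C)
    c0 = ca0 + _BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    bb.append({"N": n0, "CA": ca0, "C": c0})
    for _ in range(1, 3):
        prev = bb[-1]
        n_next = _nerf(prev["N"], prev["CA"], prev["C"], _BOND_C_N, _ANGLE_CA_C_N, 180.0)
        ca_next = _nerf(prev["CA"], prev["C"], n_next, _BOND_N_CA, _ANGLE_C_N_CA, 180.0)
        c_next = _nerf(prev["C"], n_next, ca_next, _BOND_CA_C, _ANGLE_N_CA_C, 180.0)
        bb.append({"N": n_next, "CA": ca_next, "C": c_next})
    for i, frame in enumerate(bb):
        # carbonyl O anti to the following amide nitrogen (dihedral 0 at psi=180)
        frame["O"] = _nerf(frame["N"], frame["CA"], frame["C"], _BOND_C_O, _ANGLE_CA_C_O, 0.0)

    atoms: list[AtomRecord] = []
    serial = 0
    for i, resname in enumerate(seq):
        names, elements, coords = _ideal_residue_heavy(resname)
        idx = {nm: k for k, nm in enumerate(names)}
        frame = bb[i]
        tmpl_frame = np.array([coords[idx["N"]], coords[idx["CA"]], coords[idx["C"]]])
        built_frame = np.array([frame["N"], frame["CA"], frame["C"]])
        rot, trans, _ = kabsch(built_frame, tmpl_frame)
        placed = coords @ rot.T + trans
        for k, nm in enumerate(names):
            serial += 1
            if nm in ("N", "CA", "C", "O"):
                xyz = frame[nm]
            else:
                xyz = placed[k]
            atoms.append(
                AtomRecord(
                    serial=serial,
                    name=nm,
                    element=elements[k],
                    residue_name=resname,
                    residue_number=i + 1,
                    chain_id="A",
                    xyz=np.asarray(xyz, dtype=float),
                )
            )
    return Conformer(label=f"GLY-{seq[1]}-GLY", atoms=atoms)


def _sidechain_names(residue_name: str, atom_names: Sequence[str]) -> list[str]:
    """Side-chain atom names; glycine's side chain is its Cα by convention."""
    if residue_name.upper() == "GLY":
        return ["CA"]
    return [n for n in atom_names if n not in _BACKBONE_NAMES]


_REFERENCE_CACHE: dict[tuple[str, float, int, str], float] = {}


def reference_sidechain_asa(residue_name: str, params: AsaParams | None = None) -> float:
    """Side-chain ASA (Å²) of residue X in the extended Gly-X-Gly reference."""
    params = params or AsaParams()
    key = (residue_name.upper(), params.probe_radius, params.n_points, params.radii_set)
    if key not in _REFERENCE_CACHE:
        tri = build_reference_tripeptide(residue_name)
        asa = atom_asa(tri, params)
        sc = set(_sidechain_names(residue_name, [a.name for a in tri.atoms]))
        total = sum(
            asa[i]
            for i, a in enumerate(tri.atoms)
            if a.residue_number == 2 and a.name in sc
        )
        _REFERENCE_CACHE[key] = float(total)
    return _REFERENCE_CACHE[key]


def sidechain_fraction(
    conformer: Conformer,
    residue_number: int,
    params: AsaParams | None = None,
    precomputed_asa: np.ndarray | None = None,
) -> float:
    """Fractional side-chain accessibility of one residue in a structure.

    Ratio of the residue's side-chain ASA in the full structure to its
    side-chain ASA in the extended Gly-X-Gly reference state.  Values can
    slightly exceed 1 for conformations more exposed than the reference.
    """
    params = params or AsaParams()
    res_atoms = [a for a in conformer.atoms if a.residue_number == residue_number]
    if not res_atoms:
        raise ValueError(f"residue {residue_number} not present in {conformer.label!r}")
    resname = res_atoms[0].residue_name
    asa = atom_asa(conformer, params) if precomputed_asa is None else precomputed_asa
    sc = set(_sidechain_names(resname, [a.name for a in res_atoms]))
    numer = sum(
        asa[i]
        for i, a in enumerate(conformer.atoms)
        if a.residue_number == residue_number and a.name in sc
    )
    denom = reference_sidechain_asa(resname, params)
    return float(numer / denom)


def conserved_residue_report(
    conformers: Sequence[Conformer],
    residue_list: Sequence[tuple[int, str]],
    params: AsaParams | None = None,
) -> pd.DataFrame:
    """Mean fractional side-chain accessibility over subunits.

    ``residue_list`` holds (residue_number, expected 3-letter code) pairs;
    a code mismatch in any conformer is a hard error.  Residues missing
    from some conformers are averaged over the conformers containing them,
    with the count reported.

    Returns a DataFrame with columns residue_number, residue_name,
    fractional_asa (mean), fractional_asa_rounded (2 decimals) and
    n_subunits.
    """
    params = params or AsaParams()
    per_conf_asa = [atom_asa(c, params) for c in conformers]
    rows = []
    for residue_number, expected in residue_list:
        fractions = []
        for conf, asa in zip(conformers, per_conf_asa):
            res_atoms = [a for a in conf.atoms if a.residue_number == residue_number]
            if not res_atoms:
                continue
            found = res_atoms[0].residue_name.upper()
            if found != expected.upper():
                raise ValueError(
                    f"residue {residue_number} in {conf.label!r} is {found}, "
                    f"expected {expected.upper()}"
                )
            fractions.append(
                sidechain_fraction(conf, residue_number, params, precomputed_asa=asa)
            )
        if not fractions:
            raise ValueError(f"residue {residue_number} absent from every conformer")
        mean = float(np.mean(fractions))
        rows.append(
            {
                "residue_number": residue_number,
                "residue_name": expected.upper(),
                "fractional_asa": mean,
                "fractional_asa_rounded": round(mean, 2),
                "n_subunits": len(fractions),
            }
        )
    return pd.DataFrame(rows)
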