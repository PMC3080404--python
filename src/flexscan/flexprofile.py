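"""B-factor (temperature-factor) profiles from crystals and trajectories.

The crystallographic B-factor relates to the mean-square displacement of
an atom about its mean position by B = (8/3)·π²·⟨u²⟩, which lets a
simulated trajectory be compared directly with deposited B values.  Both
kinds of profile are averaged over main-chain atoms (N, Cα, C, O) per
residue, averaged over monomers, normalized to zero mean and unit
variance, and compared by Pearson correlation.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import stats

from .structure_io import Conformer, Trajectory
from .superpose import FlexProfile

__all__ = [
    "BProfile",
    "ProfileComparison",
    "B_FROM_MSD_FACTOR",
    "msd_about_mean",
    "b_from_msd",
    "mainchain_b_profile",
    "normalize_b",
    "compare_profiles",
]

#: B = (8/3)·π²·u² conversion constant, ≈ 26.3189
B_FROM_MSD_FACTOR: float = 8.0 * np.pi**2 / 3.0

_MAINCHAIN = ("N", "CA", "C", "O")


@dataclasses.dataclass
class BProfile(FlexProfile):
    """Per-residue main-chain B-factor profile (Å² raw, unitless normalized)."""

    normalized: bool = False
    source: str = "crystallographic"  # or "trajectory"


@dataclasses.dataclass
class ProfileComparison:
    """Similarity report between two normalized profiles."""

    pearson_r: float
    n_shared: int
    residue_numbers: list[int]
    difference: np.ndarray  # p1 − p2 on shared residues


def msd_about_mean(fitted_coords: np.ndarray) -> np.ndarray:
    """Per-atom mean-square displacement about the mean position, Å².

    ``fitted_coords`` is a (frames, atoms, 3) array that has already been
    superposed (rigid-body motion removed); u²_i = ⟨|x_i − x̄_i|²⟩ over
    frames.
    """
    coords = np.asarray(fitted_coords, dtype=float)
    if coords.ndim != 3 or coords.shape[0] < 2:
        raise ValueError("need a (frames, atoms, 3) array with at least 2 frames")
    mean = coords.mean(axis=0)
    return ((coords - mean[None]) ** 2).sum(axis=2).mean(axis=0)


def b_from_msd(msd: np.ndarray | float) -> np.ndarray | float:
    """Convert mean-square displacement u² (Å²) to B = (8/3)π²u² (Å²)."""
    msd = np.asarray(msd, dtype=float)
    if np.any(msd < 0):
        raise ValueError("mean-square displacement must be nonnegative")
    out = B_FROM_MSD_FACTOR * msd
    return float(out) if out.ndim == 0 else out


def _residue_mainchain_mean(
    names: Sequence[str],
    residue_numbers: Sequence[int],
    values: np.ndarray,
) -> dict[int, float]:
    """Mean over main-chain atoms per residue; Cα fallback when N/C/O absent."""
    per_res: dict[int, dict[str, float]] = {}
    for name, rn, v in zip(names, residue_numbers, values):
        per_res.setdefault(rn, {})[name] = v
    out: dict[int, float] = {}
    for rn, atom_values in per_res.items():
        main = [atom_values[n] for n in _MAINCHAIN if n in atom_values]
        if main:
            out[rn] = float(np.mean(main))
        # residues with no main-chain atoms are omitted
    return out


def mainchain_b_profile(
    source: Sequence[Conformer] | Trajectory,
    fitted_coords: np.ndarray | None = None,
) -> BProfile:
    """Per-residue main-chain B profile, averaged over monomers.

    For a list of conformers the deposited crystallographic B values are
    averaged over the main-chain atoms (N, Cα, C, O; Cα alone if the rest
    are absent) of each residue and then over the monomers carrying that
    residue number.  For a :class:`Trajectory` the theoretical B is
    computed from the mean-square displacement of each atom in
    ``fitted_coords`` (the frames after superposition; defaults to the raw
    trajectory coordinates if not given).
    """
    if isinstance(source, Trajectory):
        coords = source.coords if fitted_coords is None else np.asarray(fitted_coords)
        u2 = msd_about_mean(coords)
        b = b_from_msd(u2)
        names = [a.name for a in source.atom_meta]
        resnums = [a.residue_number for a in source.atom_meta]
        per_res = _residue_mainchain_mean(names, resnums, b)
        residues = sorted(per_res)
        return BProfile(
            residue_numbers=residues,
            values=np.array([per_res[rn] for rn in residues]),
            metric_name="B_A2",
            normalized=False,
            source="trajectory",
        )

    conformers = list(source)
    if not conformers:
        raise ValueError("no conformers given")
    accum: dict[int, list[float]] = {}
    for conf in conformers:
        names = [a.name for a in conf.atoms]
        resnums = [a.residue_number for a in conf.atoms]
        b = np.array([a.b_iso for a in conf.atoms], dtype=float)
        for rn, v in _residue_mainchain_mean(names, resnums, b).items():
            accum.setdefault(rn, []).append(v)
    residues = sorted(accum)
    values = np.array([np.mean(accum[rn]) for rn in residues])
    return BProfile(
        residue_numbers=residues,
        values=values,
        metric_name="B_A2",
        normalized=False,
        source="crystallographic",
    )


def normalize_b(profile: BProfile) -> BProfile:
    """Normalize a B profile to zero mean and unit (population) variance."""
    values = np.asarray(profile.values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least 2 residues to normalize")
    sigma = values.std()  # population standard deviation
    if sigma <= 0:
        raise ValueError("profile has zero variance; cannot normalize")
    return BProfile(
        residue_numbers=list(profile.residue_numbers),
        values=(values - values.mean()) / sigma,
        metric_name="B_normalized",
        normalized=True,
        source=profile.source,
    )


def compare_profiles(p1: BProfile, p2: BProfile) -> ProfileComparison:
    """Pearson correlation and per-residue difference on shared residues.

    Both profiles should be normalized; they are aligned by an inner join
    on residue number.
    """
    d1 = p1.as_dict()
    d2 = p2.as_dict()
    shared = sorted(set(d1) & set(d2))
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared residues; need at least 3")
    v1 = np.array([d1[rn] for rn in shared])
    v2 = np.array([d2[rn] for rn in shared])
    r = float(stats.pearsonr(v1, v2).statistic)
    return ProfileComparison(
        pearson_r=r,
        n_shared=len(shared),
        residue_numbers=shared,
        difference=v1 - v2,
    )
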