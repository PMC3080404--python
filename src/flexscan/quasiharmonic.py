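"""Quasiharmonic analysis (mass-weighted PCA) of trajectories.

The mass-weighted Cartesian covariance of a superposed trajectory is
diagonalised into principal modes of collective motion.  Each eigenvalue
λ (amu·Å²) is the mass-weighted variance along its mode; the
quasiharmonic approximation maps it to an effective harmonic frequency
via ω² = k_B·T/λ, which gives the amplitude a mode reaches at a chosen
energy above its ground state.  The classic visualisation displaces the
mean structure to the two ±2kT extremes along a mode.

Note that with ω² = k_B·T/λ the thermal amplitude at energy E = c·kT is
q = √(2cλ) — the temperature cancels, so the extreme conformations depend
only on the eigenvalue and the energy expressed in kT units.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.linalg

from .structure_io import AtomRecord, Conformer, Trajectory

__all__ = [
    "ModeSet",
    "LoopDisplacement",
    "mass_weighted_covariance",
    "diagonalize",
    "analyze_trajectory",
    "variance_fraction",
    "extreme_conformations",
    "mode_overlap",
    "loop_displacement_summary",
]


@dataclasses.dataclass
class ModeSet:
    """Principal modes of a mass-weighted trajectory covariance."""

    eigenvalues: np.ndarray  # descending, amu·Å²
    eigenvectors: np.ndarray  # (3N, n_modes), orthonormal in mass-weighted coords
    mean_coords: np.ndarray  # (N, 3) Å
    masses: np.ndarray  # (N,) amu
    atom_meta: list[AtomRecord]
    n_frames_used: int
    stride_ps: float

    @property
    def n_atoms(self) -> int:
        return len(self.masses)

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)

    def to_tsv(self, path: str | Path) -> None:
        total = float(self.eigenvalues.sum())
        with open(path, "w") as fh:
            fh.write("mode\teigenvalue_amu_A2\tvariance_fraction\tcumulative_fraction\n")
            cum = 0.0
            for i, lam in enumerate(self.eigenvalues, start=1):
                frac = lam / total if total > 0 else 0.0
                cum += frac
                fh.write(f"{i}\t{lam:.6f}\t{frac:.6f}\t{cum:.6f}\n")


@dataclasses.dataclass
class LoopDisplacement:
    """Mean Cα displacement of each residue range between two mode extremes."""

    names: list[str]
    mean_vectors: np.ndarray  # (n_ranges, 3) Å
    magnitudes: np.ndarray  # (n_ranges,) Å
    direction_cosines: np.ndarray  # (n_ranges, n_ranges), signed


def mass_weighted_covariance(
    trajectory: Trajectory,
    fitted_coords: np.ndarray | None = None,
    target_interval_ps: float = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Mass-weighted covariance of a superposed trajectory.

    C = (1/F) Σ_f y_f y_fᵀ with y_f = M^{1/2}(x_f − x̄) and
    M^{1/2} = diag(√m_i) applied per Cartesian coordinate.  Frames are
    strided so the sampled interval is at least ``target_interval_ps``
    (default 5 ps).

    Parameters
    ----------
    trajectory:
        Trajectory whose rigid-body motion has been removed.
    fitted_coords:
        Optional superposed coordinates to use instead of
        ``trajectory.coords``.
    target_interval_ps:
        Desired sampling interval; the stride is
        ``round(target / frame_interval)`` clipped to ≥ 1.

    Returns
    -------
    (covariance, mean_coords): a (3N, 3N) amu·Å² matrix and the (N, 3)
    mean of the sampled frames.
    """
    coords = trajectory.coords if fitted_coords is None else np.asarray(fitted_coords)
    stride = max(1, int(round(target_interval_ps / trajectory.frame_interval)))
    sampled = coords[::stride]
    if sampled.shape[0] < 2:
        raise ValueError(
            f"stride {stride} leaves {sampled.shape[0]} frames; need at least 2"
        )
    n_frames, n_atoms, _ = sampled.shape
    mean = sampled.mean(axis=0)
    sqrt_m = np.repeat(np.sqrt(trajectory.masses), 3)
    y = (sampled - mean[None]).reshape(n_frames, 3 * n_atoms) * sqrt_m[None, :]
    cov = y.T @ y / n_frames
    return cov, mean


def diagonalize(
    covariance: np.ndarray,
    mean_coords: np.ndarray,
    masses: np.ndarray,
    atom_meta: Sequence[AtomRecord],
    n_frames_used: int = 0,
    stride_ps: float = 0.0,
) -> ModeSet:
    """Extract principal modes from a mass-weighted covariance matrix.

    Eigenvalues are sorted descending and clamped at zero (small negative
    round-off is tolerated to −1e-8); each eigenvector's sign is fixed by
    making its largest-magnitude component positive, so the mode set is
    deterministic.
    """
    cov = np.asarray(covariance, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError("covariance must be a square matrix")
    asym = np.abs(cov - cov.T).max()
    if asym > 1e-8:
        raise ValueError(f"covariance is asymmetric (max deviation {asym:.2e})")
    evals, evecs = scipy.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    if evals.min() < -1e-8:
        raise ValueError(f"covariance has a negative eigenvalue {evals.min():.3e}")
    evals = np.clip(evals, 0.0, None)
    # deterministic sign convention
    for i in range(evecs.shape[1]):
        j = int(np.argmax(np.abs(evecs[:, i])))
        if evecs[j, i] < 0:
            evecs[:, i] = -evecs[:, i]
    return ModeSet(
        eigenvalues=evals,
        eigenvectors=evecs,
        mean_coords=np.asarray(mean_coords, dtype=float),
        masses=np.asarray(masses, dtype=float),
        atom_meta=list(atom_meta),
        n_frames_used=int(n_frames_used),
        stride_ps=float(stride_ps),
    )


def analyze_trajectory(
    trajectory: Trajectory,
    fitted_coords: np.ndarray | None = None,
    target_interval_ps: float = 5.0,
) -> ModeSet:
    """Convenience: covariance + diagonalization in one call."""
    cov, mean = mass_weighted_covariance(trajectory, fitted_coords, target_interval_ps)
    stride = max(1, int(round(target_interval_ps / trajectory.frame_interval)))
    n_used = len(range(0, trajectory.n_frames, stride))
    return diagonalize(
        cov,
        mean,
        trajectory.masses,
        trajectory.atom_meta,
        n_frames_used=n_used,
        stride_ps=stride * trajectory.frame_interval,
    )


def variance_fraction(modes: ModeSet, k: int) -> float:
    """Fraction of the total mass-weighted variance in the top k modes."""
    if not 1 <= k <= modes.n_modes:
        raise ValueError(f"k must be in [1, {modes.n_modes}]")
    total = float(modes.eigenvalues.sum())
    if total <= 0:
        raise ValueError("all eigenvalues are zero; variance fraction undefined")
    return float(modes.eigenvalues[:k].sum() / total)


def extreme_conformations(
    modes: ModeSet,
    mode_index: int,
    energy_kT: float = 2.0,
    temperature: float = 310.0,
) -> tuple[Conformer, Conformer]:
    """The two extreme conformations of one mode at a given thermal energy.

    Under the quasiharmonic relation ω² = k_B·T/λ a mode at energy
    E = energy_kT·k_B·T reaches the mass-weighted amplitude
    q = √(2·energy_kT·λ); for the conventional 2kT "artificial heating"
    this is q = 2√λ.  The Cartesian extremes are x̄ ± M^{−1/2} v q, emitted
    as a pair of conformers.  A zero eigenvalue yields two copies of the
    mean.  The temperature argument is retained for interface completeness
    but cancels out of the amplitude.
    """
    if energy_kT < 0:
        raise ValueError("energy_kT must be nonnegative")
    if not 0 <= mode_index < modes.n_modes:
        raise ValueError(f"mode_index must be in [0, {modes.n_modes})")
    lam = float(modes.eigenvalues[mode_index])
    q = np.sqrt(2.0 * energy_kT * lam)
    v = modes.eigenvectors[:, mode_index]
    inv_sqrt_m = np.repeat(1.0 / np.sqrt(modes.masses), 3)
    displacement = (inv_sqrt_m * v * q).reshape(-1, 3)
    template = Conformer(label="mean", atoms=list(modes.atom_meta))
    plus = template.with_coords(modes.mean_coords + displacement,
                                label=f"mode{mode_index + 1}_plus")
    minus = template.with_coords(modes.mean_coords - displacement,
                                 label=f"mode{mode_index + 1}_minus")
    return plus, minus


def mode_overlap(modes_a: ModeSet, i: int, modes_b: ModeSet, j: int) -> float:
    """Absolute cosine between mode i of one set and mode j of another."""
    va = modes_a.eigenvectors[:, i]
    vb = modes_b.eigenvectors[:, j]
    if va.shape != vb.shape:
        raise ValueError("mode sets have different dimensions")
    return float(abs(va @ vb) / (np.linalg.norm(va) * np.linalg.norm(vb)))


def loop_displacement_summary(
    modes: ModeSet,
    mode_index: int,
    residue_ranges: dict[str, tuple[int, int]],
    energy_kT: float = 2.0,
) -> LoopDisplacement:
    """Per-loop mean Cα displacement between the two mode extremes.

    For each named residue range the mean displacement vector of its Cα
    atoms between the plus and minus extreme conformations is reported,
    with its magnitude and the signed pairwise direction cosines between
    loop vectors — positive cosine: the loops move together; negative:
    in opposition.  Ranges with no mapped Cα are omitted with a warning.
    """
    import warnings

    plus, minus = extreme_conformations(modes, mode_index, energy_kT=energy_kT)
    delta = plus.coords - minus.coords  # (N, 3)
    names: list[str] = []
    vectors: list[np.ndarray] = []
    for name, (lo, hi) in residue_ranges.items():
        mask = np.array(
            [a.name == "CA" and lo <= a.residue_number <= hi for a in modes.atom_meta]
        )
        if not mask.any():
            warnings.warn(f"range {name} ({lo}-{hi}) has no mapped Cα atoms; omitted",
                          stacklevel=2)
            continue
        names.append(name)
        vectors.append(delta[mask].mean(axis=0))
    vecs = np.array(vectors) if vectors else np.empty((0, 3))
    mags = np.linalg.norm(vecs, axis=1) if len(vecs) else np.empty(0)
    n = len(names)
    cosines = np.eye(n)
    for a in range(n):
        for b in range(a + 1, n):
            denom = mags[a] * mags[b]
            c = float(vecs[a] @ vecs[b] / denom) if denom > 0 else 0.0
            cosines[a, b] = cosines[b, a] = c
    return LoopDisplacement(
        names=names,
        mean_vectors=vecs,
        magnitudes=mags,
        direction_cosines=cosines,
    )
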