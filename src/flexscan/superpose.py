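"""Rigid-body superposition and per-residue flexibility profiles.

Implements the Kabsch algorithm (weighted least-squares rotation with the
reflection excluded) and an iterative ensemble superposition that fits
every conformer to the running mean structure until the mean converges.
Per-residue RMSD to the mean structure — the standard measure of
conformational variability across crystallographically independent
monomers — is computed from the converged fit.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np

from .structure_io import Ensemble

__all__ = [
    "SuperpositionResult",
    "FlexProfile",
    "kabsch",
    "ensemble_superpose",
    "per_residue_rmsd",
    "superpose_trajectory",
]


@dataclasses.dataclass
class FlexProfile:
    """Per-residue flexibility values (RMSD in Å, B in Å², or unitless)."""

    residue_numbers: list[int]
    values: np.ndarray
    metric_name: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.residue_numbers) != len(self.values):
            raise ValueError("residue_numbers and values must have equal length")

    def as_dict(self) -> dict[int, float]:
        return dict(zip(self.residue_numbers, self.values.tolist()))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"residue_number\t{self.metric_name}\n")
            for rn, v in zip(self.residue_numbers, self.values):
                fh.write(f"{rn}\t{v:.6f}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FlexProfile":
        residues: list[int] = []
        values: list[float] = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            metric = header[1] if len(header) > 1 else "value"
            for line in fh:
                rn, v = line.split("\t")
                residues.append(int(rn))
                values.append(float(v))
        return cls(residues, np.array(values), metric)


@dataclasses.dataclass
class SuperpositionResult:
    """Outcome of iterative ensemble superposition to the mean structure."""

    rotations: np.ndarray  # (n_conf, 3, 3) proper rotations
    translations: np.ndarray  # (n_conf, 3) Å
    mean_coords: np.ndarray  # (n_atoms, 3) Å
    fitted_coords: np.ndarray  # (n_conf, n_atoms, 3) Å
    iterations: int
    converged: bool


def _check_pointset(coords: np.ndarray, name: str) -> None:
    if coords.shape[0] < 3:
        raise ValueError(f"{name}: need at least 3 points, got {coords.shape[0]}")
    centered = coords - coords.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] <= 1e-9 * max(s[0], 1.0):
        raise ValueError(f"{name}: degenerate (collinear) point set")


def kabsch(
    ref_coords: np.ndarray,
    mov_coords: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid fit of ``mov_coords`` onto ``ref_coords``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mov @ rotation.T + translation`` minimizes the weighted RMSD to
    ``ref``.  The rotation is proper (det = +1): the reflection branch is
    excluded by flipping the sign of the smallest singular value when
    needed.

    Parameters
    ----------
    ref_coords, mov_coords:
        (n, 3) arrays with n ≥ 3 non-collinear points.
    weights:
        Optional nonnegative per-point weights (not all zero).
    """
    ref = np.asarray(ref_coords, dtype=float)
    mov = np.asarray(mov_coords, dtype=float)
    if ref.shape != mov.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("coordinate arrays must both be (n, 3) with equal n")
    _check_pointset(ref, "ref_coords")
    _check_pointset(mov, "mov_coords")
    if weights is None:
        w = np.ones(ref.shape[0])
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (ref.shape[0],) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be nonnegative, not all zero, one per point")
    wsum = w.sum()
    ref_c = (w[:, None] * ref).sum(axis=0) / wsum
    mov_c = (w[:, None] * mov).sum(axis=0) / wsum
    p = mov - mov_c
    q = ref - ref_c
    h = (w[:, None] * p).T @ q  # 3×3 cross-covariance
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rotation = vt.T @ diag @ u.T
    translation = ref_c - rotation @ mov_c
    fitted = mov @ rotation.T + translation
    rmsd = float(np.sqrt((w * ((fitted - ref) ** 2).sum(axis=1)).sum() / wsum))
    return rotation, translation, rmsd


def ensemble_superpose(
    ensemble: Ensemble,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> SuperpositionResult:
    """Superpose all conformers onto their converged mean structure.

    Starting from the first conformer as the reference, iterate: fit every
    conformer to the current mean with :func:`kabsch`, recompute the mean
    of the fitted coordinates, stop when the maximum per-atom shift of the
    mean drops below ``tol`` (Å) or after ``max_iter`` rounds.  The mean
    squared deviation to the mean is non-increasing across iterations.

    Non-convergence produces a warning and ``converged=False``, not an
    exception.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    coords = ensemble.coords()
    n_conf, n_atoms, _ = coords.shape
    mean = coords[0].copy()
    rotations = np.tile(np.eye(3), (n_conf, 1, 1))
    translations = np.zeros((n_conf, 3))
    fitted = np.empty_like(coords)
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        for k in range(n_conf):
            r, t, _ = kabsch(mean, coords[k])
            rotations[k] = r
            translations[k] = t
            fitted[k] = coords[k] @ r.T + t
        new_mean = fitted.mean(axis=0)
        shift = float(np.abs(np.linalg.norm(new_mean - mean, axis=1)).max())
        mean = new_mean
        if shift < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"ensemble superposition did not converge in {max_iter} iterations",
            stacklevel=2,
        )
    return SuperpositionResult(
        rotations=rotations,
        translations=translations,
        mean_coords=mean,
        fitted_coords=fitted,
        iterations=iterations,
        converged=converged,
    )


def superpose_trajectory(
    trajectory,
    selection: str | None = "CA",
    max_iter: int = 100,
    tol: float = 1e-6,
) -> np.ndarray:
    """Remove rigid-body motion from a trajectory.

    Each frame is fitted to the running mean structure (Kabsch on the
    ``selection`` atoms, default Cα; all atoms if no Cα present), iterated
    until the mean converges — the standard essential-dynamics
    preprocessing step before computing covariances or mean-square
    displacements.  Returns the fitted (frames, atoms, 3) coordinates.
    """
    coords = trajectory.coords
    if selection is not None:
        fit_idx = np.array([a.name == selection for a in trajectory.atom_meta])
        if fit_idx.sum() < 3:
            fit_idx = np.ones(coords.shape[1], dtype=bool)
    else:
        fit_idx = np.ones(coords.shape[1], dtype=bool)
    mean_sub = coords[0, fit_idx].copy()
    fitted = coords.copy()
    for _ in range(max_iter):
        for f in range(coords.shape[0]):
            r, t, _ = kabsch(mean_sub, coords[f, fit_idx])
            fitted[f] = coords[f] @ r.T + t
        new_mean = fitted[:, fit_idx].mean(axis=0)
        shift = float(np.linalg.norm(new_mean - mean_sub, axis=1).max())
        mean_sub = new_mean
        if shift < tol:
            break
    return fitted


def per_residue_rmsd(result: SuperpositionResult, ensemble: Ensemble) -> FlexProfile:
    """RMSD to the mean structure per residue, in Å.

    For each mapped residue the value is
    sqrt( mean over conformers (and over the residue's mapped atoms) of
    |x − x̄|² ).  With the default Cα-only atom map this is the per-residue
    Cα RMSD-to-mean profile.  Residues absent from the atom map are absent
    from the profile.
    """
    dev2 = ((result.fitted_coords - result.mean_coords[None]) ** 2).sum(axis=2)
    mean_dev2 = dev2.mean(axis=0)  # per mapped atom
    by_residue: dict[int, list[float]] = {}
    for j, (rn, _name) in enumerate(ensemble.atom_map):
        by_residue.setdefault(rn, []).append(mean_dev2[j])
    residues = sorted(by_residue)
    values = np.array([np.sqrt(np.mean(by_residue[rn])) for rn in residues])
    return FlexProfile(residue_numbers=residues, values=values, metric_name="rmsd_A")
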