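# Methods

This note records the models, conventions and numerical choices behind
each analysis, what the synthetic generators do and do not emulate, and
the known limitations.

## Ensemble superposition and RMSD profiles

Pairwise superposition is the Kabsch algorithm: weighted centroids are
removed, the 3×3 cross-covariance is decomposed by SVD, and the sign of
the smallest singular value is flipped when needed so the returned
matrix is a proper rotation (det = +1); reflections are never admitted.
Point sets with fewer than three points, or whose centered coordinates
are rank-deficient (collinear), are rejected — the rotation would be
underdetermined.

Ensemble superposition iterates "fit every conformer to the current
mean, recompute the mean", starting from the first conformer in input
order, until the maximum per-atom shift of the mean is below 1e-6 Å
(default) or 100 iterations.  Each half-step of this block-coordinate
scheme cannot increase the mean squared deviation to the mean, so the
objective is non-increasing; non-convergence returns a flagged result
with a warning rather than raising, because a nearly-converged fit is
still usable.  This is plain unweighted least-squares, not
maximum-likelihood (covariance-weighted) superposition: for ensembles
whose variability is confined to a few loops the two agree on peak
positions and agree on peak heights to roughly the 0.1 Å level, which is
why the acceptance band for published peak displacements is ±0.3 Å
rather than print precision.

The per-residue profile is the RMSD of each mapped residue's Cα to the
ensemble mean over conformers.  Crystal ensembles are superposed on Cα
only; residues excluded as disordered (inclusive residue-number ranges)
are removed from the atom correspondence before fitting, and residues
absent from the correspondence are absent from the profile rather than
zero-filled.  Author residue numbering is preserved everywhere.

Alternate locations resolve to the highest-occupancy record, ties broken
by file order.  Hydrogens, waters and hetero groups are dropped on
input: all quantities here are heavy-atom or Cα quantities.

## B-factor profiles

`B = (8/3) π² ⟨u²⟩` converts the mean-square displacement of an atom
about its mean position (computed from a superposed trajectory) into a
temperature factor.  "Main-chain" means N, Cα, C and O, with a Cα-only
fallback for Cα-trace inputs.  Averaging over monomers happens on raw B
values *before* normalization; normalization subtracts the mean and
divides by the *population* standard deviation, so a normalized profile
has exactly zero mean and unit variance.  Profiles are compared after an
inner join on residue numbers, by Pearson correlation — the published
comparison is qualitative ("very similar trend"), so a single similarity
number plus a per-residue difference profile is a reporting choice, not
a claim of a specific statistic.  Trajectory B profiles are computed per
chain, not over a dimer jointly.

## Quasiharmonic analysis

Rigid-body motion is removed first: each frame is fitted to the running
trajectory mean on Cα (all atoms if no Cα), iterated to convergence —
the standard essential-dynamics preprocessing.  The mass-weighted
covariance `C = (1/F) Σ_f y_f y_fᵀ`, `y_f = M^{1/2}(x_f − x̄)`, is
accumulated over frames strided to a 5 ps sampling interval by default
(`stride = round(target/frame_interval)`, minimum 1).  `C` is
diagonalised with a symmetric eigensolver; eigenvalues are sorted
descending, round-off negatives (≥ −1e-8) are clamped to zero, and each
eigenvector's sign is fixed by making its largest-magnitude component
positive, so mode sets are deterministic and reproducible bit-for-bit.

The extreme-conformation amplitude uses the quasiharmonic relation
`ω² = k_B T / λ`: at energy `E = c·k_B T` above the ground state a mode
reaches the mass-weighted amplitude `q = √(2cλ)`, i.e. `q = 2√λ` for the
conventional 2kT device.  The temperature cancels out of this
expression; the parameter is kept on the interface for completeness and
documented as inert.  A zero eigenvalue gives two copies of the mean,
not an error.  Cartesian extremes are `x̄ ± M^{−1/2} v q`.

Loop-displacement summaries average, per named residue range, the Cα
displacement vectors between the two extremes and report magnitudes plus
*signed* pairwise direction cosines: positive means two loops move in
concert, negative in opposition.  Mode similarity across mode sets is
the absolute cosine of the eigenvectors.

The per-mode variance percentages published for the original 126.5 ns
simulation are not recomputable without that trajectory, which was not
deposited; the package instead validates the whole chain by parameter
recovery on trajectories drawn from planted harmonic models (below).

## Solvent accessibility

Shrake–Rupley: every atom's sphere of expanded radius `r_vdw + probe`
(probe 1.4 Å) is sampled with a deterministic golden-spiral point set
(default 960 points, nearest-neighbour spacing CV < 0.2), and the
fraction of points outside all neighbours' expanded spheres gives the
exposed area.  Neighbours come from a k-d tree, so results are
independent of atom order.  Van der Waals radii are a fixed
Chothia-style table keyed by element (C 1.80, N 1.65, O 1.40, S 1.85,
P/Se 1.90 Å); a missing radius is a hard error naming the atom.  At 960
points the method agrees with the analytic two-sphere spherical-cap
formula within 2% over the full overlap range and total ASA moves by
less than 1% when the point count doubles.

Fractional side-chain accessibility divides by the side-chain ASA of the
same residue type X in an extended Gly-X-Gly tripeptide computed with
identical parameters.  The tripeptide backbone is built at
φ = ψ = ω = 180° with standard bond geometry; side-chain atoms take the
ideal geometry of the chemical-component dictionary, rigidly fitted onto
each residue's (N, Cα, C) frame.  Glycine's "side chain" is its Cα, so
glycine rows are computable.  Values slightly above 1 are possible when
a conformation is more exposed than the reference and are reported as
is.  Reference values are cached per (residue, parameters).  The
reference state behind the published fractional values is not specified
beyond the program name, so agreement is expected at the table's
2-decimal resolution, not beyond.

## Synthetic data: what it emulates

`make_helix` produces an ideal α-helical Cα trace (rise 1.5 Å, 100° per
residue, radius 2.3 Å; consecutive Cα–Cα ≈ 3.8 Å).

`make_flex_ensemble` plants a per-residue displacement amplitude `a_r`:
each conformer adds independent Gaussian noise with per-coordinate σ =
`a_r/√3` (so the expected RMSD-to-mean converges to `a_r`), then a
random rigid motion so the superposition stage does real work.

`make_mode_trajectory` samples frames `base + M^{−1/2} Σ_i v_i z_i`,
`z_i ~ N(0, λ_i)`, from planted orthonormal modes — exactly the model
quasiharmonic analysis assumes, so recovery is a sharp correctness test:
at 10,000 frames, planted eigenvalues are recovered within 10%,
eigenvector overlaps exceed 0.95 for modes separated by a variance ratio
of ≥ 3, and variance fractions land within ±0.02.

All generators are pure functions of (inputs, seed); there is no hidden
global RNG state.

What the generators do **not** emulate: anharmonic and multi-basin
dynamics, correlated (non-diagonal) crystal-packing distortions,
side-chain rotamer changes, and solvent structure.  Passing the recovery
tests therefore demonstrates the estimators are correct under the
harmonic model they assume, not that real loop dynamics are harmonic.

## Problem sizes and tolerances

Default validation sizes — 16–64 conformers of 24-residue traces,
10,000-frame trajectories of 24 atoms, 960 sphere points — were chosen
so each estimator's Monte-Carlo error sits comfortably inside the
tolerance being checked (e.g. per-residue RMSD at N = 64 has ≈ 6%
relative noise against a 15% band).  The acceptance script re-runs the
same recoveries end to end from a single seed.

## Known limitations

- PDB and XYZ-frame text are the only I/O formats; binary MD formats and
  mmCIF are out of scope.
- Least-squares (not maximum-likelihood) ensemble superposition; peak
  RMSD values can differ from covariance-weighted results at the
  ~0.1–0.3 Å level.
- The Gly-X-Gly reference state is one of several conventions in use;
  fractional values are comparable within this package, not across
  programs, beyond ~2 decimal places.
- Analyses are per chain; inter-chain (dimer) covariance is not modelled.
- Accession-based comparisons require the user to supply the deposited
  coordinate files; the package performs no downloads.
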