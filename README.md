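# flexscan

Conformational-flexibility analysis of protein structures, built around
the question of how mobile surface loops can mask and unmask a buried
functional site — the situation of the peptidoglycan-binding domain of
the bacterial flagellar stator protein MotB, whose five family-conserved
binding residues are completely shielded by three "petal-like" loops in
every crystal form.

`flexscan` packages the four analyses that together make that case:

1. **Ensemble superposition and per-residue RMSD.**  The independent
   monomers of one or more crystal asymmetric units are superposed onto
   their converged mean structure by iterated least-squares Kabsch
   rotations, and flexibility is read off as the per-residue Cα RMSD to
   the mean,
   `RMSD_r = sqrt( (1/N) Σ_k |x_{k,r} − x̄_r|² )`.

2. **B-factor profiles.**  Crystallographic temperature factors relate
   to the mean-square displacement of an atom about its mean position by
   `B = (8/3) π² ⟨u²⟩`, so a simulated trajectory yields a *theoretical*
   B profile directly comparable with the deposited one.  Main-chain
   (N, Cα, C, O) values are averaged per residue and over monomers, then
   normalized to zero mean and unit variance; profiles are compared by
   Pearson correlation.

3. **Quasiharmonic analysis (mass-weighted PCA).**  The mass-weighted
   covariance `C = ⟨M^{1/2}(x − x̄)(x − x̄)ᵀ M^{1/2}⟩` of a superposed
   trajectory is diagonalised into principal modes of concerted motion.
   The fraction of total fluctuation in the top *k* modes is
   `Σ_{i≤k} λ_i / Σ_i λ_i`.  With the quasiharmonic relation
   `ω² = k_B T / λ`, the amplitude a mode reaches at energy `2 k_B T`
   above its ground state is `q = 2 √λ` in mass-weighted coordinates, and
   the two "artificially heated" extreme conformations `x̄ ± M^{−1/2} v q`
   visualise the motion.

4. **Fractional side-chain accessibility.**  Shrake–Rupley ASA with a
   1.4 Å probe, expressed as the ratio of a residue's side-chain ASA in
   the structure to the same quantity in an extended Gly-X-Gly reference
   tripeptide — near 0 for a loop-masked binding residue, near 1 for a
   fully exposed one.

A synthetic-data module generates all inputs with *planted* ground truth
(ideal helices, ensembles with chosen per-residue amplitudes, Gaussian
trajectories drawn from a chosen mass-weighted harmonic model), so every
analysis can be validated by parameter recovery.

## Worked example

`examples/rmsd_profile.py` plants a 2.0 Å displacement amplitude at
residue 13 of a 24-residue helix (0.3 Å elsewhere), builds 16 conformers
under random rigid motions, superposes them and recovers the profile:

```
superposition converged in 5 iterations
most flexible residue: 13 (RMSD to mean 2.10 A; planted 2.0 A)
correlation with the planted amplitude profile: r = 0.997
```

The peak localises the planted mobile residue and its height estimates
the displacement amplitude.  `examples/quasiharmonic_modes.py` does the
same for the trajectory side — three planted modes with variances
9 / 3 / 1 amu·Å² recovered from 10,000 frames:

```
recovered eigenvalues (amu A^2), planted 9 / 3 / 1:
  8.89  3.07  0.99
mode 1: overlap with planted direction = 1.0000
...
direction cosine between segments: -0.61
```

A negative direction cosine between two segments means they move in
opposition along that mode — the signature of loops opening a cleft
between them.  The other examples cover the B-factor overlay
(`bfactor_overlay.py`), fractional accessibility of an exposed versus a
loop-buried side chain (`sasa_conserved.py`), and the full config-driven
report bundle (`full_report.py`).

## Command line

```sh
flexscan synth ensemble --seed 1 --out fixtures/      # planted ensemble
flexscan synth trajectory --seed 1 --out fixtures/    # planted trajectory
flexscan report --config run.yaml                     # full report bundle
```

The report bundle contains `rmsd_profile.tsv`, `bfactor_overlay.tsv`
(+ optional plot), `modes.tsv`, a `mode_k_extremes.pdb` pair per
reported mode, `loop_summary.tsv`, `asa_table.tsv` and a `run.log` that
echoes every setting, so a bundle is self-describing and bit-identically
re-runnable.

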