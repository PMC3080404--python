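"""Per-residue RMSD-to-mean profile from an ensemble of conformers.

Builds a 16-member ensemble of a toy helix in which residue 13 was given
a planted displacement amplitude of 2.0 Å (0.3 Å elsewhere), superposes
all members onto their converged mean structure, and prints the recovered
flexibility profile.  In real use the conformers would be the independent
monomers of one or more crystal asymmetric units, read with
``flexscan.read_pdb``.
"""

import numpy as np

import flexscan as fs

base = fs.make_helix(24)
amplitudes = np.full(24, 0.3)
amplitudes[12] = 2.0  # residue 13

spec = fs.FlexSpec(n_residues=24, amplitude_profile=amplitudes,
                   n_conformers=16, seed=1)
ensemble = fs.make_flex_ensemble(base, spec)

result = fs.ensemble_superpose(ensemble)
profile = fs.per_residue_rmsd(result, ensemble)

print(f"superposition converged in {result.iterations} iterations")
peak = int(np.argmax(profile.values))
print(f"most flexible residue: {profile.residue_numbers[peak]} "
      f"(RMSD to mean {profile.values[peak]:.2f} A; planted 2.0 A)")
r = np.corrcoef(profile.values, amplitudes)[0, 1]
print(f"correlation with the planted amplitude profile: r = {r:.3f}")
# The profile localises flexibility per residue: a peak marks a mobile
# loop, the flat baseline the rigid core.
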