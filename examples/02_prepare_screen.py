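"""From a docking score table to a labeled, balanced training set.

A virtual screen starts from (SMILES, binding free energy) rows. Hits are
the molecules in the low-energy tail: the threshold is the 20% quantile of
the *training* energies (more negative = tighter binding), so validation
and test labels never leak their own distribution. The training split is
then rebalanced to 50/50 by randomly duplicating hits.
"""

from nfpscreen import SynthConfig, assign_energies, generate_molecules
from nfpscreen import oversample_training, prepare_dataset

# synthetic stand-in for a docked compound library
cfg = SynthConfig(n_molecules=1000, seed=7)
pairs = assign_energies(generate_molecules(cfg), cfg)
print(f"{len(pairs)} molecules, energies "
      f"{min(e for _, e in pairs):.2f} .. {max(e for _, e in pairs):.2f} kcal/mol")

ds = prepare_dataset(pairs, hit_fraction=0.20, seed=7)
print(f"split sizes (train/val/test): {ds.split_counts}")
print(f"hit threshold: {ds.energy_threshold:.3f} kcal/mol "
      f"(20% training quantile)")

train = ds.subset("train")
n_hits = sum(r.label for r in train)
print(f"training split: {n_hits} hits / {len(train) - n_hits} non-hits")

balanced = oversample_training(train, seed=7)
n_hits = sum(r.label for r in balanced)
print(f"after oversampling: {n_hits} hits / {len(balanced) - n_hits} non-hits "
      f"(exact 50/50 balance)")
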