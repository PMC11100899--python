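"""Build a molecular graph and its trainable neural fingerprint.

The fingerprint is a differentiable analog of the Morgan/ECFP circular
fingerprint: at each convolutional layer every atom's features are combined
with its neighborhood (a sigmoid replaces the hash), routed through a
softmax (replacing the array indexing), and summed. Because each softmax
row sums to one, the entries of the fingerprint always sum to
n_atoms x (depth + 1) — a built-in normalization check.
"""

import numpy as np

from nfpscreen import init_params, neural_fingerprint, smiles_to_graph

aspirin = "CC(=O)Oc1ccccc1C(=O)O"
graph = smiles_to_graph(aspirin)
print(f"aspirin: {graph.n_atoms} heavy atoms, {graph.n_bonds} bonds")
print(f"atom feature matrix {graph.atom_features.shape}, "
      f"bond feature matrix {graph.bond_features.shape}")

params = init_params(n_layers=3, fp_length=16, seed=0)
fp = neural_fingerprint(graph, params)
print("\nfingerprint (length 16, depth 3):")
print(np.array2string(fp.values, precision=3))
print(f"entry sum = {fp.values.sum():.6f} "
      f"(= n_atoms x (L+1) = {graph.n_atoms} x 4 = {graph.n_atoms * 4})")
# Unlike a hashed ECFP these values move smoothly with the weights, so the
# fingerprint itself can be optimized for a screening task by gradient descent.
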