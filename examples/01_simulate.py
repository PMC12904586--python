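"""Generate a synthetic two-modality dataset and inspect its ground truth.

The generator draws cells of several types in a shared latent space and
observes them through modality-specific loadings, optionally recording true
cross-modality cell pairings.
"""

from bialign import SyntheticSpec, generate

spec = SyntheticSpec(n_cells_1=300, n_cells_2=280, n_types=3, pairing_ratio=0.5, seed=0)
ds = generate(spec)

print(f"modality 1: {ds.mod1.n_cells} cells x {ds.mod1.n_features} features ({ds.mod1.modality})")
print(f"modality 2: {ds.mod2.n_cells} cells x {ds.mod2.n_features} features ({ds.mod2.modality})")
print(f"true pairs: {len(ds.true_pairs)} (pairing_ratio x min cell count)")
print(f"shared features with one-to-one correspondence: {len(ds.feature_map)}")
print(f"cell types: {sorted(set(ds.true_types_1))}")
# Every true pair joins two cells of the same type; these pairings are what
# FOSCTTM evaluates and what anchors_from_true_pairs can feed the model.
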