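"""The 187-D ligand descriptor vector.

Computes physicochemical descriptors for two contrasting molecules — a
long-chain fatty acid and a small aromatic — and prints a few entries.
The full 187-vector is the 'ligand half' of every model input.
"""

from nrpcm import Compound, default_manifest, ligand_descriptor

manifest = default_manifest()
print(f"manifest: {len(manifest)} descriptors, toolkit {manifest.toolkit_version}")

for name, smiles in [
    ("docosapentaenoic-like chain", "CCCCCCCCCCCCCCCCCCCCCC(=O)O"),
    ("3,4-dimethoxytoluene", "Cc1ccc(OC)c(OC)c1"),
]:
    desc = ligand_descriptor(Compound(name, smiles), manifest)
    print(f"\n{name}  ({smiles})")
    for key in ("MolWt", "MolLogP", "NumRotatableBonds", "RingCount", "HeavyAtomCount"):
        idx = manifest.names.index(key)
        print(f"  {key}: {desc.values[idx]:.2f}")

# The chain scores high on rotatable bonds and logP with zero rings; the
# aromatic is the mirror image — exactly the contrasts the classifier uses.
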