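"""Grade how well two molecule records correspond, on the five-level scale.

A structure-side ligand and a registry-side molecule rarely share a
verbatim string; the grade says how much chemistry they share:
5/4 identical, 3 stereo-distinct, 2/1 potentially identical (same
connectivity, different hydrogens/stereo/isotopes), 0 unrelated.
"""

from bioactlink.molecules import compute_forms, match_level, truncate_inchi

reference = compute_forms("C[C@H](O)CC(C)=O")   # (S)-4-hydroxypentan-2-one
print("reference InChI:", reference.inchi)
print("truncated after connections:", truncate_inchi(reference.inchi, "connection"))

pairs = {
    "same molecule": "C[C@H](O)CC(C)=O",
    "enantiomer": "C[C@@H](O)CC(C)=O",
    "enol tautomer": "C[C@H](O)C=C(C)O",
    "unrelated (phenol)": "Oc1ccccc1",
}
for name, smiles in pairs.items():
    level = match_level(reference, compute_forms(smiles))
    print(f"  vs {name:<22s} -> level {int(level)} ({level.name})")

# Levels 5 and 4 mean the bioactivity was measured on exactly this compound;
# level 3 flags a stereochemistry difference (a different isomer); levels
# 2 and 1 mean the records may describe the same compound but differ in
# hydrogen placement, stereo annotation or isotopes.
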