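"""Compute the two descriptor vectors for one complex.

Pockets get 147 CTD values (7 physicochemical properties x 21 numbers:
class composition, transition frequencies, and distribution quantiles of
the amino-acid sequence).  Ligands get 196 frozen 2D descriptors
evaluated with RDKit.
"""

from deeplip import SyntheticSpec, generate_dataset, ligand_descriptors, pocket_ctd

(sample,), _ = generate_dataset(SyntheticSpec(n_samples=1, seed=3))

ctd = pocket_ctd(sample.pocket.sequence)
print(f"pocket sequence ({len(sample.pocket.sequence)} aa): "
      f"{sample.pocket.sequence}")
print(f"CTD vector length: {len(ctd)}")
for name in ("hydrophobicity.C1", "hydrophobicity.C2", "hydrophobicity.C3",
             "charge.T12", "polarity.D1.p50"):
    print(f"  {name:24s} {ctd.as_dict()[name]:7.2f}")

lig = ligand_descriptors(sample.ligand)
print(f"\nligand ({len(sample.ligand.atoms)} heavy atoms), "
      f"descriptor length: {len(lig)} (registry {lig.registry_version})")
for name in ("MolWt", "HeavyAtomCount", "NumHAcceptors", "MolLogP",
             "RingCount"):
    print(f"  {name:24s} {lig.as_dict()[name]:7.2f}")
# Composition values are percentages that sum to 100 within each
# property; the ligand values are plain RDKit 2D descriptors, so MolWt
# is the molecular weight in g/mol and RingCount the number of rings.
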