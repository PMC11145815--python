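"""Generate a small synthetic complex collection and inspect its labels.

The generator plants a known affinity function: pK grows with ligand
size, pocket hydrophobicity, and the number of close ligand-pocket
contacts, plus 0.3 pK of Gaussian noise, squashed into the realistic
[2, 12] pK window.
"""

import numpy as np

from deeplip import SyntheticSpec, generate_dataset
from deeplip.synthetic_data import interaction_contacts

spec = SyntheticSpec(n_samples=50, seed=7)
samples, manifest = generate_dataset(spec, out_dir="example_output/dataset")

labels = np.array([s.label for s in samples])
contacts = [interaction_contacts(s.ligand, s.pocket, spec.contact_threshold)
            for s in samples]
print(f"generated {len(samples)} complexes "
      f"(pocket {spec.pocket_length} residues, "
      f"ligand {spec.ligand_size} heavy atoms)")
print(f"labels: mean {labels.mean():.2f} pK, sd {labels.std():.2f} pK "
      f"(declared construction sd {manifest['declared_label_sd']:.2f})")
print(f"contacts per complex: median {int(np.median(contacts))}, "
      f"range {min(contacts)}-{max(contacts)}")
print("files written to example_output/dataset (PDB + SDF + index.csv)")
# The label sd close to its declared value confirms the planted signal
# survived the squash; contacts >= 1 everywhere means the interaction
# term is active in every sample.
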