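"""Write a labelled phantom dataset to disk.

Produces 8-bit PNG ROIs, a labels.csv, and a truth/ folder with each
phantom's injected bias field as 32-bit TIFF.
"""

from pathlib import Path

from sonodae import make_dataset, write_dataset

out = Path("scratch/example_dataset")
split = make_dataset(n_benign=10, n_malignant=12, test_fraction=0.25, seed=3)
write_dataset(split, out)

n_train, n_test = len(split.train), len(split.test)
print(f"wrote {n_train + n_test} phantoms to {out}/ ({n_train} train, {n_test} test)")
print(f"first file: {split.train[0].name}, label {split.train[0].label} (1 = malignant)")
# The truth/ bias fields let downstream code score how much of the
# injected inhomogeneity a correction method recovers.
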