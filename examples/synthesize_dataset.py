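"""Generate the synthetic texture benchmark and write it as a PNG tree.

Eight classes of oriented band-pass noise span smooth/low-contrast through
coarse/high-contrast surfaces; that spread of apparent sharpness across
classes is what gives the decile thresholds of the equalization framework
their dynamic range.  Same seed, same pixels -- the tree is reproducible.
"""

import blurtex as bt
from blurtex.data import save_dataset

spec = bt.SyntheticDatasetSpec(n_classes=8, n_per_class=4, patch_size=128, seed=7)
ds = bt.generate_dataset(spec)
print(f"{len(ds)} patches, {ds.n_classes} classes")
print(f"{'class':>7}  {'orientation':>11}  {'freq':>6}  {'contrast':>8}")
for name, p in zip(ds.class_names, spec.class_params):
    print(f"{name:>7}  {p.orientation:11.3f}  {p.frequency:6.3f}  {p.contrast:8.2f}")

save_dataset(ds, "scratch/example_tree")
print("wrote scratch/example_tree/ (one directory per class + manifest.csv)")
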