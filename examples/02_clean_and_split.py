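"""Screen gross errors with the Dixon Q test and split 80/20.

Injects large instrument-style errors into a few condition groups, shows how
many groups the Dixon criterion removes (whole-group deletion when any
replicate is flagged), then partitions the surviving condition means into
training and verification sets.
"""

import qgarbf as q

params = q.GroundTruthParams(noise_sd=0.2, seed=7)
records = q.generate_dataset(q.ExperimentDesign(), params)

# corrupt 20 groups with +/- 200x the replicate noise (unambiguous outliers)
corrupted, manifest = q.inject_gross_errors(records, 20, 200 * params.noise_sd, seed=8)

result = q.clean(corrupted)
removed = set(result.removed)
caught = len(removed & set(manifest.groups))
print(f"groups removed: {result.removed_count} "
      f"({caught}/20 injected caught, {len(removed) - caught} Dixon false positives)")

ds = q.split(result.groups, 0.8, seed=9)
print(f"split: {ds.n_train} training / {ds.n_verify} verification groups")
print(f"fitted Pn range on training set: "
      f"[{ds.norm.mins['pn']:.2f}, {ds.norm.maxs['pn']:.2f}] umol m-2 s-1")
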