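"""Generate a study-scale synthetic expression dataset and write it as TSV.

The preset emulates a 2322-gene array profiled over 33 two-color
hybridizations (11 substrate x growth-phase conditions, 3 biological
replicates) with 13 planted co-expression modules totalling 614 genes, 20
negative-control probes and 2% unquantifiable (SNR < 2) spots.
"""

import glyconet as g
from glyconet.synthetic import annotations_for, write_dataset

spec = g.study_preset(seed=1)
x, truth = g.simulate(spec)
anns = annotations_for(spec, truth)
paths = write_dataset(x, truth, "example_output/dataset", annotations=anns)

print(f"genes x samples: {x.n_genes} x {x.n_samples}")
print(f"conditions: {len(x.design.conditions())}, planted modules: {len(spec.modules)}")
print(f"planted module genes: {len(truth.planted_genes())}")
print(f"quantifiable spots: {100 * x.mask.mean():.1f}%")
for name, path in paths.items():
    print(f"wrote {name}: {path}")
# The expression table holds log2(sample/reference) ratios; the truth table
# maps each gene to its planted module (NA = background), the ground truth
# that the network-recovery examples score against.
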