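"""Spatial cohesion of catalytic sites.

For each enzyme, measures every residue's Euclidean distance to the
nearest catalytic residue (catalytic residues measure the distance to the
nearest *other* catalytic residue). Catalytic sites are spatial clusters,
so their internal distances are far smaller.
"""

import numpy as np
from scipy.stats import mannwhitneyu

from screenkit import distance_to_nearest_catalytic, summarize_distances
from screenkit.synthetic import GeneratorConfig, generate_dataset

cfg = GeneratorConfig(n_enzymes=20, seed=0)
records, _ = generate_dataset(cfg, as_graphs=False)

cat_d, non_d = [], []
for r in records:
    mask = r.catalytic_mask.astype(bool)
    cat_d.append(distance_to_nearest_catalytic(r.ca_coords, mask, subset=mask))
    non_d.append(distance_to_nearest_catalytic(r.ca_coords, mask, subset=~mask))

cat_s = summarize_distances(cat_d)
non_s = summarize_distances(non_d)
p = mannwhitneyu(np.concatenate(cat_d), np.concatenate(non_d),
                 alternative="less").pvalue

print(f"catalytic -> nearest other catalytic: median {cat_s['median']:.1f} A "
      f"(IQR {cat_s['q1']:.1f}-{cat_s['q3']:.1f})")
print(f"non-catalytic -> nearest catalytic:   median {non_s['median']:.1f} A "
      f"(IQR {non_s['q1']:.1f}-{non_s['q3']:.1f})")
print(f"one-sided rank test p = {p:.2e}")
# Catalytic residues cluster within a few Angstroms of each other while
# the rest of the chain sits much further from the site.
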