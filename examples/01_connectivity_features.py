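"""From regional time series to fixed-length connectivity features.

Simulates a small two-site cohort, computes each subject's Pearson
functional-connectivity matrix and flattens its upper triangle into the
fixed-length feature vector the downstream models consume.
"""

import numpy as np

from fcgan import (FixtureConfig, connectivity_matrix, edge_pair,
                   extract_features, make_dataset, vectorize_upper)

config = FixtureConfig(
    regions=16,
    sites=(("SITE_A", 10, 10), ("SITE_B", 5, 5)),
    timepoints=(80, 120),
    effect=0.4,   # ASD class carries +0.4 correlation on the planted pairs
    seed=7,
)
series, phenotype = make_dataset(config)
print(f"simulated {len(series)} subjects; scan lengths vary: "
      f"{sorted({ts.n_timepoints for ts in series})[:5]} ...")

one = series[0]
cm = connectivity_matrix(one)
vec = vectorize_upper(cm)
print(f"subject {one.subject_id}: {one.n_timepoints}x{one.n_regions} series "
      f"-> {cm.n_regions}x{cm.n_regions} correlation matrix "
      f"-> {vec.shape[0]}-dim feature vector")

table = extract_features(series, phenotype)
print(f"feature table: {len(table)} subjects x {table.dim} features "
      f"(R(R-1)/2 for R={config.regions})")

# the planted class difference is visible in the mean feature gap
y = table.label_ints()
gap = table.values[y == 1].mean(axis=0) - table.values[y == 0].mean(axis=0)
top = np.argsort(gap)[-3:][::-1]
print("largest ASD-HC mean correlation gaps (edge -> gap):")
for idx in top:
    i, j = edge_pair(idx, config.regions)
    print(f"  regions ({i:2d},{j:2d}) -> {gap[idx]:+.3f}")
print("gaps near +0.4 sit on planted region pairs; background edges are ~0.")
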