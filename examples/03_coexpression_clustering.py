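"""Cluster DE features on arcsin-root expression profiles with ICL.

Profiles are per-feature expression proportions, arcsin(sqrt(p))
transformed; a diagonal Gaussian mixture is fitted for each K in a sweep
and the integrated completed likelihood picks the number of clusters.
Clusters are then grouped into the six expression-tendency families.
"""

import numpy as np
from sklearn.metrics import adjusted_rand_score

from floraleaf import clustering, diffexpr, simulate

design = diffexpr.SampleDesign.default()
profiles = np.array([
    [50, 200, 200, 50], [50, 100, 200, 400],
    [400, 200, 100, 50], [100, 100, 100, 100],
], dtype=float)
features = [f"f{i:04d}" for i in range(600)]
counts, truth = simulate.make_counts(features, design, profiles,
                                     dispersion=0.1, seed=11)
de = diffexpr.run_de(counts, design)
de_feats = diffexpr.de_features(de["table"])

prof = clustering.profile_transform(de["filtered_counts"].loc[de_feats],
                                    de["effective_libsizes"])
model, icl_table = clustering.select_k(prof, range(2, 8), n_restarts=5, seed=3)
print(icl_table.round(1).to_string(index=False))
print(f"ICL selects K = {model.k}")

labels_true = [truth.planted_cluster_of_feature[f] for f in prof.index]
print(f"adjusted Rand index vs planted clusters: "
      f"{adjusted_rand_score(labels_true, model.labels):.3f}")

families = clustering.assign_families(model, design.timepoint_order,
                                      design.timepoints)
print(families[["cluster", "family", "tendency", "margin"]].round(3)
      .to_string(index=False))
# ARI 1.0 means the mixture recovered the planted co-expression groups
# exactly; families summarize each cluster's tendency relative to T0.
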