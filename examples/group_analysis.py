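"""Two-group cohort analysis: BNI comparison, seizure-driving ROIs, MVPA.

Creates a synthetic cohort in which group b's edge weights are scaled by
1.3 (planting higher seizure propensity), compares per-subject BNI between
groups with a Mann-Whitney U test, then illustrates the node-level
statistics — the bootstrap test for seizure-driving ROIs and multivariate
pattern analysis of NI spatial profiles — on the same cohort at a reduced
simulation horizon so the whole script runs in a few minutes.
"""

import numpy as np

from ictonet import BNIGrid, ModelParams, bni, node_ictogenicity
from ictonet._rng import derive_seed
from ictonet.stats import mann_whitney, mvpa_auc, mvpa_permutation, nni_bootstrap
from ictonet.synth import CohortSpec, make_group_dataset

SEED = 5
spec = CohortSpec(n_group_a=12, n_group_b=12, n_rois=16, effect=1.3, seed=SEED)
cohort = make_group_dataset(spec)
grid = BNIGrid(n_points=7)

# --- network-level seizure propensity, full desk-scale precision
params = ModelParams(i0=-1.0, k=10.0, sigma=6.0, n_steps=100_000, burn_in=5_000)
labels = np.array(cohort.labels)
bni_vals = np.array([
    bni(net, grid, params, derive_seed(SEED, "subject", i)).bni
    for i, net in enumerate(cohort.networks)
])
a, b = bni_vals[labels == "a"], bni_vals[labels == "b"]
r = mann_whitney(a, b)
print(f"median BNI: group a = {np.median(a):.4f}, group b = {np.median(b):.4f}")
print(f"Mann-Whitney: U = {r.u:.0f}, z = {r.z:.2f}, p = {r.p:.4f}")
print("(group b carries the planted 1.3x coupling effect: higher median BNI,")
print(" and the test should be significant at conventional levels)\n")

# --- node-level statistics, illustrative (shorter simulations)
params_fast = ModelParams(i0=-1.0, k=10.0, sigma=6.0, n_steps=30_000, burn_in=1_500)
ni_rows = [
    node_ictogenicity(net, grid, params_fast, derive_seed(SEED, "ni", i)).ni
    for i, net in enumerate(cohort.networks)
]
features = np.vstack(ni_rows)

nni = features[labels == "b"]
nni = nni / nni.sum(axis=1, keepdims=True)
boot = nni_bootstrap(nni, n_boot=1000, seed=SEED)
print(f"bootstrap seizure-driving ROIs in group b: "
      f"{int(boot.significant.sum())} significant at FDR 0.05")
print("(uniform-random cohorts have no planted spatial structure, so few or")
print(" no ROIs should exceed the homogeneous null)\n")

mv = mvpa_auc(features, labels, n_reps=5, seed=SEED)
p_perm, _ = mvpa_permutation(features, labels, n_perm=200, seed=SEED,
                             n_reps=5, result=mv)
print(f"MVPA on NI profiles: AUC = {mv.auc_mean:.3f} +- {mv.auc_sd:.3f}, "
      f"permutation p = {p_perm:.3f}")
print("(at this illustrative scale the NI profiles are noisy, so the MVPA")
print(" may or may not separate the groups; the BNI contrast above is the")
print(" powered comparison)")
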