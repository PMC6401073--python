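"""Fit correlated component analysis and check recovery of the planted
topography.

CorrCA pools within- and between-subject covariances over segments and
solves R_b w = lambda R_w w; forward-model columns A are the scalp maps of
the components, and ISC is the mean pairwise Pearson correlation of the
projected time courses.
"""

import numpy as np

from iscmusic import fit_model, isc_per_subject, pooled_covariances, project
from iscmusic.synthetic import default_snr_table, simulate_segment_stacks

flat = default_snr_table(
    1, familiar_by_repeat=(1.0,), unfamiliar_by_repeat=(1.0,),
    training_scale={"trained": 1.0, "untrained": 1.0},
)
stacks, truth, meta = simulate_segment_stacks(
    n_subjects=10, n_pieces=2, n_repeats=1, duration_s=30.0, n_channels=32,
    k=2, signal_amp=10.0, component_scales=(5.0, 3.0), noise_sd=10.0,
    snr_by_cell=flat, seed=0,
)

cov = pooled_covariances(stacks)
model = fit_model(cov, k_max=6)
print("eigenvalues:", np.round(model.eigenvalues, 3))

comps = np.concatenate([project(s, model.W) for s in stacks], axis=2)
isc = isc_per_subject(comps).mean(axis=0)
print("group ISC per component:", np.round(isc, 4))

for j in range(2):
    cos = abs(model.A[:, j] @ truth.mixing[:, j]) / np.linalg.norm(model.A[:, j])
    print(f"component {j + 1}: |cosine| between forward model and "
          f"planted topography = {cos:.3f}")
# Two components stand far above the rest in both eigenvalue and ISC, and
# their scalp maps align with the planted mixing columns: the model found
# the shared activity, not noise.
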