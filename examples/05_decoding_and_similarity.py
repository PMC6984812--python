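"""Per-depth decoding and pattern-similarity inference in auditory cortex.

On a noisy synthetic subject, a linear SVC (C=1, leave-one-run-out)
discriminates audiovisual from auditory blocks at each depth — the planted
crossmodal-modulation field alters the pattern, so accuracy is above
chance even though the mean [AV-A] response is ~0.  The attentional gain
is pattern-preserving, so attention pairs correlate more strongly than
stimulus pairs; the exact sign-permutation test across subjects quantifies
that ordering.
"""

import numpy as np

from lamfmri.design import build_run_design
from lamfmri.mvpa import (ATTENTION_PAIRS, STIMULUS_PAIRS, decode_per_depth,
                          exact_sign_permutation, fit_accuracy_shape,
                          make_pattern_dataset, pattern_similarity)
from lamfmri.synth import (default_ground_truth, make_cortical_patch,
                           simulate_vertex_betas)

patch = make_cortical_patch({"A1": 100, "PT": 70, "V1": 100, "V23": 70},
                            rng_seed=0)
design = build_run_design(rng_seed=0)
datasets = simulate_vertex_betas(patch, default_ground_truth(), design,
                                 n_subjects=6, rng_seed=0)

prof = decode_per_depth(make_pattern_dataset(datasets[0], "A1", ("AV", "A")))
shape = fit_accuracy_shape(prof)
print("[AV vs A] decoding accuracy per depth (WM -> CSF):",
      np.array2string(prof.accuracies, precision=2))
print(f"accuracy shape: C = {shape.C:+.3f} above chance, "
      f"L = {shape.L:+.3f} per depth step")

contrasts = []
for ds in datasets:
    sim = pattern_similarity(ds, "A1", ATTENTION_PAIRS, STIMULUS_PAIRS)
    contrasts.append(sim.contrast)
print("\nper-subject Fisher-z similarity contrasts "
      "(attention pairs minus stimulus pairs):")
print(np.array2string(np.array(contrasts), precision=3))
p = exact_sign_permutation(contrasts)
print(f"exact sign-permutation p = {p:.4f} "
      f"(granularity 2/2^{len(contrasts)}; positive contrast means "
      "attention rescales the pattern the other modality alters)")
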