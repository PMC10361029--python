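"""Learn EasyMKL source weights on a cohort with a planted group effect.

The generator plants a gamma-band amplitude difference over the occipital
ROI (ROI 8) in positive-valence trials of the positive-class group.  One
RBF kernel is built per (ROI, band) source of the positive valence and
EasyMKL learns a nonnegative weight per kernel; the top-weighted source
should be the planted one — the weights are the analysis's relevance
readout.
"""

import numpy as np

from erpmkl import (EffectSpec, KernelSet, SynthConfig, build_feature_table,
                    easymkl_fit, rbf_kernel, sigma_heuristic, synth_cohort,
                    zscore_fit_apply)

config = SynthConfig(
    n_pos=8, n_neg=10, fs=125.0, n_blocks=2, stimuli_per_valence=20,
    artifact_rate=0.0,
    effects=(EffectSpec(roi=8, band="gamma", valence="positive", effect_size=2.0),),
    seed=21,
)
table = build_feature_table(synth_cohort(config))

sources = table.sources_for_valence("positive")
mats = []
for s in sources:
    X, _, _ = zscore_fit_apply(table.source_block(s), table.source_block(s))
    mats.append(rbf_kernel(X, X, sigma_heuristic(X)))

model = easymkl_fit(KernelSet(source_ids=sources, matrices=mats),
                    table.labels, lam=0.2)

print("top 5 sources by kernel weight (valence, ROI, band):")
for i in np.argsort(model.eta)[::-1][:5]:
    print(f"  {sources[i]}  eta = {model.eta[i]:.3f}")
# The planted source (positive, 8, gamma) should lead with a clear margin;
# the remaining weights form a flat background set by the shared kernel
# diagonal.
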