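"""Extract the wavelet band / ROI feature table from a synthetic cohort.

Each subject's per-valence ERP is resampled to 125 Hz, decomposed with a
4-level Symlet-8 DWT into the five classical EEG bands, summarized with
eight statistics per band and channel, and averaged within eight scalp
ROIs.  The printed shape is subjects x (3 valences x 8 ROIs x 5 bands x
8 statistics); each contiguous (valence, ROI, band) block of width 8 is
one kernel source.
"""

from erpmkl import SynthConfig, build_feature_table, collapse_valences, synth_cohort

config = SynthConfig(n_pos=2, n_neg=3, fs=125.0, n_blocks=1,
                     stimuli_per_valence=10, artifact_rate=0.0, seed=3)
table = build_feature_table(synth_cohort(config))

print(f"feature table: {table.df.shape[0]} subjects x {table.df.shape[1]} features")
print(f"sources per valence: {len(table.sources_for_valence('positive'))}")

block = table.source_block(("positive", 8, "gamma"))
print(f"block (positive, ROI 8, gamma): {block.shape[0]} subjects x "
      f"{block.shape[1]} statistics")

collapsed = collapse_valences(table)
w = collapsed.source_block(collapsed.source_ids[0]).shape[1]
print(f"collapsed sources: {len(collapsed.source_ids)}, width {w} "
      "(8 statistics x 3 valences)")
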