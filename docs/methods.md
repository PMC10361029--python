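# Methods

`erp-mkl` implements a two-group classification analysis for event-related
EEG with *source traceability*: instead of asking only "can the groups be
separated?", the pipeline reports **which** combinations of scalp region,
frequency band (and stimulus valence) carry the separating information.
This note documents the model, the defaults and why they were chosen, the
synthetic cohort generator the test suite relies on, and the known
limitations.

## Pipeline overview

For each subject *i* with epoched EEG `Y(i) ∈ ℝ^{Nc×Nt×Ne}` (channels ×
samples × trials) and a binary group label `l(i) ∈ {−1, +1}`:

1. **Preprocess** — zero-phase FIR band-pass (0.1–60 Hz), common-average
   reference, epoching to 1 s windows (−200…800 ms) with −200–0 ms
   baseline correction, and consensus peak-to-peak artifact rejection with
   inverse-distance channel interpolation.
2. **ERP** — epochs of each valence (negative / neutral / positive) are
   averaged into one evoked response per valence.
3. **Features** — each ERP channel is resampled to 125 Hz and decomposed
   with a 4-level Symlet-8 DWT; detail levels D1–D4 and the approximation
   A4 are read as the γ (32–60 Hz), β (16–32), α (8–16), θ (4–8) and δ
   (0–4 Hz) bands.  Eight statistics (max, min, mean, median, variance,
   std, skewness, kurtosis) summarize each band's coefficients per
   channel, then channel statistics are averaged within 8 scalp ROIs.
   Each (valence, ROI, band) block of 8 statistics is one *source*;
   8 ROIs × 5 bands = 40 sources per valence.
4. **Kernels** — one RBF Gram matrix per source,
   `k(x, z) = exp(−σ‖x − z‖²)`, on per-fold z-scored blocks.
5. **MKL** — EasyMKL learns one nonnegative weight per kernel.  With
   `L = diag(labels)` and the averaged kernel `K̄ = Σ_p K_p / N_p` it
   solves the convex QP

       min_{γ ∈ Ξ}  (1 − λ) γᵀ L K̄ L γ + λ ‖γ‖²,

   where Ξ restricts γ to a probability distribution over each class.
   The minimizer locates the two nearest points of the class convex hulls
   in the combined feature space; source weights are
   `η_p ∝ γᵀ L K_p L γ`, clipped at zero and L2-normalized.  A larger
   `η_p` marks a source along which the hulls are further apart.
6. **Classification** — a kernel SVM (dual box-constrained QP, C = 1) is
   trained on the combined Gram matrix `Σ_p η_p K_p`; test subjects are
   labelled by the sign of the decision function (ties map to +1).
7. **Evaluation** — 5-fold stratified cross-validation; per-fold
   z-scoring with training-split parameters only; F1 of the positive
   class as the score; fold-averaged η (renormalized for display) as the
   relevance readout.  Two designs are compared: 40 independent
   single-kernel SVMs per valence versus one MKL classifier per valence,
   plus a collapsed variant in which each (ROI, band) source concatenates
   its statistics across the three valences (block width 24).

## Parameters that matter

| parameter | default | notes |
|---|---|---|
| epoch window | −0.2…0.8 s | half-open sample convention `[onset+tmin·fs, onset+tmax·fs)`, so a 1 s epoch has exactly `round(fs)` samples |
| analysis rate | 125 Hz | the only rate at which the 4-level dyadic edges (62.5/31.25/15.63/7.81/3.91 Hz) approximate the classical band edges; ERPs recorded at higher rates are polyphase-resampled before the DWT |
| mother wavelet | `sym8` | `sym4` selectable; near-symmetric orthogonal wavelets keep band features phase-faithful |
| DWT boundary | symmetric padding | 1 s epochs at 125 Hz are shorter than support×2⁴, so deep levels carry boundary effects; accepted and shared by all subjects equally.  `periodization` mode is available where exact orthogonality (energy partition) is needed |
| statistics | 8 per band | a 5-statistic preset (`STATISTICS_5`) reproduces the compact 200-feature per-valence layout |
| RBF width σ | `1/(d·var)` | `d` = block width, `var` = pooled training variance.  Applied in **both** experiment designs.  On z-scored blocks this reduces to σ = 1/d, which keeps typical squared distances (≈2d) inside the kernel's sensitive range for every block width; a width fixed at 1 regardless of dimension puts all off-diagonal entries near e^(−2d) ≈ 10⁻⁷ and makes every Gram matrix numerically diagonal, collapsing the classifier while leaving the weight ranking intact.  A fixed numeric σ remains available via `run_mkl_experiment(..., sigma=...)` |
| EasyMKL λ | 0.2 | ∈ [0, 1]; sweeps on synthetic cohorts change F1 by < 0.06, so the default is not critical |
| weight norm | L2 | `‖η‖₂ = 1`; L1 (simplex) normalization is available but shrinks the combined kernel's scale at fixed C and performs worse |
| SVM C | 1 | fixed; the box-and-equality dual is solved by a maximal-violating-pair SMO to a 10⁻⁸ KKT gap |
| CV | 5 folds, stratified, seeded | each training split holds ~80 % of subjects |
| rejection | 99th-percentile peak-to-peak threshold, consensus fraction 0.1, ≤ 6 channels interpolated | an epoch is dropped only when >10 % of channels (or more than the interpolation cap) exceed the learned threshold; isolated bad channels are replaced by inverse-distance-weighted averages on the 2-D 10-20 layout |

Numerical details: the EasyMKL QP is solved with SLSQP (analytic
gradients, ftol 10⁻¹²) and the solution is re-projected onto the bi-class
simplex; η entries below 10⁻¹² are clipped to zero before normalization.
Degenerate inputs are handled explicitly: zero-variance feature columns
are dropped per fold with a warning, constant coefficient vectors get
skewness/kurtosis 0 (logged), `sign(0)` maps to +1.

## Synthetic cohort generator

Real data for this kind of study is restricted, so validation runs on
synthetic cohorts built to expose exactly the structure the analysis
assumes:

* **Task schedule** — blocks in which each of 60 stimuli (20 per valence)
  appears once in seeded random order; 4 blocks = 240 trials; successive
  onsets separated by 1.7–2.0 s (fixation + 700–1000 ms inter-stimulus
  interval preceding each picture).
* **Evoked response** — per band, a damped sinusoid at the band centre
  (2/6/12/24/45 Hz) starting at stimulus onset, with a decay of ~2.5
  cycles; amplitudes 5/4/4/2.5/1.5 µV (δ…γ), a mild valence gain
  (emotional > neutral), and a coarse spatial topography (frontal δ/θ,
  posterior α, central β, posterior-temporal γ).
* **Background** — Gaussian 1/f ("pink") noise, independent per channel
  and epoch, 10 µV SD — broadband single-trial EEG scale after a 0.1–60 Hz
  band-pass.
* **Within-group variability** — a log-normal per-subject, per-band
  amplitude factor (SD 0.15), so subjects differ without overlapping the
  planted effects.
* **Group differences** — `EffectSpec(roi, band, valence, effect_size)`
  multiplies the matching evoked component by `1 + effect_size` on that
  ROI's channels for positive-class subjects only.  Ground truth for the
  weight readout is therefore known exactly.
* **Artifacts** — with probability 0.05 per epoch, a 100 ms square
  transient of 10× the noise SD on one random channel, to exercise the
  rejection stage.
* **Determinism** — per-subject seeds are spawned from the cohort seed
  via `numpy.random.SeedSequence`; identical configs give byte-identical
  cohorts.

Default cohort size is 19 positive-class and 31 negative-class subjects.

What the generator does **not** emulate: head-volume conduction (channels
are noise-independent), ocular/cardiac artifact morphology, latency
jitter, non-stationary noise, or inter-subject topography differences.
Passing batteries therefore show that the pipeline recovers planted
band/ROI structure at realistic SNR — not that it would perform at any
particular level on real recordings.

## Validation batteries

The battery suite (`erpmkl.validation`) generates cohorts at 125 Hz (the
analysis rate; the band mapping is then exact and generation is fast)
with the default subject and trial counts, runs rejection + features +
cross-validated experiments end-to-end, and checks:

* **Recovery** — one planted effect (occipital γ, positive valence,
  effect_size 1.5): the top fold-averaged MKL weight should name the
  planted source in ≥ 18 of 20 seeded replicates.
* **Superiority** — the same overall difference split over two sources
  (occipital γ + left-temporal β, effect_size 1.0 each): MKL mean F1
  should be ≥ the best single-kernel mean F1 in ≥ 16 of 20 replicates.
  This comparison is conservative: "best single" is the maximum over 40
  fold-mean estimates and carries a selection bias of several F1 points.
  At the tested base seed the measured rate is 15/20, with the losses
  being ceiling ties decided by ≤ 0.03; the battery result is reported as
  measured.
* **Null calibration** — with no planted effect, the observed MKL F1
  must fall inside the central 95 % band of a 39-permutation label-
  shuffling null on the same feature table.
* **Solver oracles** — EasyMKL weights match a 10⁻³-step brute-force
  enumeration of the bi-class simplex on 2-kernel toys (class sizes ≤ 3)
  within 10⁻²; the SVM dual reproduces the closed-form 2-point solution
  and an independent high-precision reference solver within 10⁻⁶.

## Design choices on genuinely open points

* The level-to-band relabelling cannot hold at a 1 kHz sampling rate
  (D1–D4 would span 31–500 Hz); resampling ERPs to 125 Hz before the DWT
  is the reading under which it does, and is applied by default.
* The 8-ROI channel grouping is a documented, editable JSON default
  (prefrontal, frontal, central, temporal L/R, centro-parietal, parietal,
  occipital over the 64 BioSemi-named 10-20 positions), not a claimed
  replica of any particular cap diagram.
* Peak-to-peak rejection is a deliberately simple stand-in for
  cross-validated rejection-threshold learning: a percentile-learned
  threshold plus a consensus rule preserves the contract (epochs dropped
  only on multi-channel agreement, isolated channels repaired) without
  the external dependency; interpolation is inverse-distance weighting
  rather than spherical splines.
* ICA-based ocular/cardiac cleaning is omitted: the synthetic data
  contains no such sources.
* EDF export is a minimal writer (ASCII header + 16-bit records, one
  record per 1 s epoch); quantization error is bounded by the per-channel
  range /65535 and verified not to disturb the extracted features.

## Limitations

* Binary groups only — the hull-distance objective and the SVM are
  two-class constructions.
* The EasyMKL weights carry a per-source baseline from the shared unit
  kernel diagonal (`η_p ∝ ‖γ‖² + alignment`), so they are informative in
  *ranking* but not sparse; with many uninformative sources the combined
  kernel dilutes, which bounds classification gains at low SNR.
* Kernel hyperparameters are fixed by heuristics, not cross-validated.
* Battery problem sizes (125 Hz generation, default cohort and trial
  counts, 20 seeds, 39 permutations) are the package's validation
  conditions; they are deliberately modest and are stated alongside every
  reported number.
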