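"""End-to-end validation batteries on synthetic cohorts.

These routines run the whole pipeline — cohort generation with planted
(ROI, band, valence) effects, artifact rejection, feature extraction,
kernel learning, cross-validated scoring — and measure properties that
must hold if every stage is correct:

* *recovery*: a single planted effect should surface as the top-weighted
  MKL source;
* *superiority*: with the group difference split across two sources, the
  MKL combination should score at least as well as the best single-kernel
  classifier;
* *null calibration*: with no planted effect, the observed score should
  fall inside the band of a label-permutation null.

The batteries run at a 125 Hz generation rate (the analysis rate of the
wavelet band mapping), with the full default cohort size and trial count.
A brute-force grid enumeration of the EasyMKL simplex program is also
provided as an independent oracle for small problems.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluate import make_folds, run_mkl_experiment, run_single_kernel_experiment
from .features import FeatureTable, build_feature_table
from .mkl import KernelSet
from .preprocess import learn_rejection_threshold, reject_and_interpolate
from .synth import EffectSpec, EpochedRecording, SynthConfig, synth_cohort

__all__ = [
    "easymkl_grid_oracle", "easymkl_toy_problems", "clean_cohort",
    "planted_feature_table", "recovery_battery", "superiority_battery",
    "null_calibration", "BatteryResult",
]


def easymkl_toy_problems(seed: int = 77) -> list[tuple[KernelSet, np.ndarray]]:
    """Deterministic 2-kernel toy problems small enough for the grid oracle.

    Class sizes are kept at <= (2, 2) free simplex dimensions so the
    1e-3-step enumeration stays tractable; kernels are random unit-diagonal
    PSD matrices.
    """
    rng = np.random.default_rng(seed)
    problems = []
    for n_pos, n_neg in [(1, 1), (2, 1), (1, 2), (2, 2), (3, 1), (1, 3)]:
        n = n_pos + n_neg
        y = np.array([+1] * n_pos + [-1] * n_neg)
        mats = []
        for _ in range(2):
            A = rng.standard_normal((n, n + 2))
            K = A @ A.T
            d = np.sqrt(np.diag(K))
            mats.append(K / np.outer(d, d))
        problems.append((KernelSet(source_ids=["k1", "k2"], matrices=mats), y))
    return problems


def _class_grid(size: int, step: float) -> np.ndarray:
    """All probability vectors of the given size on a grid of the simplex."""
    if size == 1:
        return np.ones((1, 1))
    if size == 2:
        t = np.arange(0.0, 1.0 + step / 2, step)
        return np.column_stack([t, 1.0 - t])
    if size == 3:
        t = np.arange(0.0, 1.0 + step / 2, step)
        a, b = np.meshgrid(t, t, indexing="ij")
        ok = a + b <= 1.0 + 1e-12
        return np.column_stack([a[ok], b[ok], 1.0 - a[ok] - b[ok]])
    raise ValueError("grid enumeration supports class sizes up to 3")


def easymkl_grid_oracle(
    kernels: KernelSet, labels: np.ndarray, lam: float, step: float = 1e-3
) -> tuple[np.ndarray, np.ndarray]:
    """Brute-force minimizer of the EasyMKL objective on a simplex grid.

    Enumerates the bi-class probability simplex with the given step and
    returns ``(gamma, eta)`` at the grid minimum of
    ``(1-λ) γᵀL K̄ Lγ + λ‖γ‖²``.  Only small problems (each class of size
    at most 3) are supported; this is a reference oracle, not a solver.
    """
    y = np.asarray(labels, dtype=float)
    pos = np.flatnonzero(y > 0)
    neg = np.flatnonzero(y < 0)
    Kbar = sum(kernels.matrices) / len(kernels)
    Q = (1 - lam) * (y[:, None] * y[None, :]) * Kbar + lam * np.eye(y.size)

    grid_pos = _class_grid(pos.size, step)
    grid_neg = _class_grid(neg.size, step)
    best_val, best_gamma = np.inf, None
    # evaluate in blocks over the positive grid to bound memory
    for gp in np.array_split(grid_pos, max(1, grid_pos.shape[0] // 256)):
        G = np.zeros((gp.shape[0], grid_neg.shape[0], y.size))
        G[:, :, pos] = gp[:, None, :]
        G[:, :, neg] = grid_neg[None, :, :]
        flat = G.reshape(-1, y.size)
        vals = np.einsum("ij,jk,ik->i", flat, Q, flat)
        k = int(np.argmin(vals))
        if vals[k] < best_val:
            best_val = float(vals[k])
            best_gamma = flat[k].copy()
    Lg = y * best_gamma
    raw = np.array([float(Lg @ K @ Lg) for K in kernels.matrices])
    raw[raw < 0] = 0.0
    eta = raw / np.linalg.norm(raw)
    return best_gamma, eta


def clean_cohort(cohort: list[EpochedRecording]) -> list[EpochedRecording]:
    """Per-subject learned-threshold rejection + interpolation."""
    cleaned = []
    for rec in cohort:
        policy = learn_rejection_threshold(rec)
        out, _ = reject_and_interpolate(rec, policy)
        cleaned.append(out)
    return cleaned


def planted_feature_table(
    seed: int,
    effects: tuple[EffectSpec, ...],
    fs: float = 125.0,
    reject: bool = True,
) -> FeatureTable:
    """Generate a default-size cohort with the given planted effects and
    extract its feature table (with the rejection stage by default)."""
    config = SynthConfig(fs=fs, effects=effects, seed=seed)
    cohort = synth_cohort(config)
    if reject:
        cohort = clean_cohort(cohort)
    return build_feature_table(cohort)


def _battery_seeds(base_seed: int, n_seeds: int) -> list[int]:
    root = np.random.SeedSequence(base_seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in root.spawn(n_seeds)]


@dataclass
class BatteryResult:
    """Outcome of a multi-seed battery."""

    successes: int
    n_seeds: int
    details: list[dict] = field(default_factory=list)

    @property
    def rate(self) -> float:
        return self.successes / self.n_seeds


#: Default planted effect for the recovery battery: gamma band over the
#: occipital ROI in the positive valence, amplitude scaled by 2.5x
#: (effect_size 1.5) in the positive-class group.
RECOVERY_EFFECT = EffectSpec(roi=8, band="gamma", valence="positive", effect_size=1.5)

#: Split effect for the superiority battery: a group difference of the
#: recovery battery's overall strength divided over two distinct
#: (ROI, band) sources, so the evidence the classifier needs is spread
#: across kernels instead of concentrated in one.
SPLIT_EFFECTS = (
    EffectSpec(roi=8, band="gamma", valence="positive", effect_size=1.0),
    EffectSpec(roi=4, band="beta", valence="positive", effect_size=1.0),
)


def recovery_battery(
    n_seeds: int = 20,
    base_seed: int = 0,
    effect: EffectSpec = RECOVERY_EFFECT,
    lam: float = 0.2,
) -> BatteryResult:
    """Does the top fold-averaged MKL weight identify the planted source?"""
    successes, details = 0, []
    target = (effect.valence, effect.roi, effect.band)
    for seed in _battery_seeds(base_seed, n_seeds):
        table = planted_feature_table(seed, (effect,))
        plan = make_folds(table.labels, k=5, seed=seed)
        rep = run_mkl_experiment(table, effect.valence, plan, lam=lam)
        top = rep.source_ids[int(np.argmax(rep.mean_eta))]
        hit = tuple(top) == target
        successes += hit
        details.append({"seed": seed, "top_source": list(top), "hit": bool(hit),
                        "f1_mean": rep.f1_mean})
    return BatteryResult(successes=successes, n_seeds=n_seeds, details=details)


def superiority_battery(
    n_seeds: int = 20,
    base_seed: int = 0,
    effects: tuple[EffectSpec, ...] = SPLIT_EFFECTS,
    lam: float = 0.2,
    valence: str = "positive",
) -> BatteryResult:
    """Is MKL mean F1 >= the best single-kernel mean F1 per seed?"""
    successes, details = 0, []
    for seed in _battery_seeds(base_seed, n_seeds):
        table = planted_feature_table(seed, effects)
        plan = make_folds(table.labels, k=5, seed=seed)
        mkl = run_mkl_experiment(table, valence, plan, lam=lam)
        single = run_single_kernel_experiment(table, valence, plan)
        best_single = max(
            float(np.mean(v)) for v in single.per_source.values()
        )
        win = mkl.f1_mean >= best_single - 1e-12
        successes += win
        details.append({"seed": seed, "mkl_f1": mkl.f1_mean,
                        "best_single_f1": best_single, "win": bool(win)})
    return BatteryResult(successes=successes, n_seeds=n_seeds, details=details)


def null_calibration(
    seed: int = 0,
    n_permutations: int = 39,
    lam: float = 0.2,
    valence: str = "positive",
) -> dict:
    """Observed MKL F1 on an effect-free cohort vs. a permutation null.

    The same feature table is rescored after randomly permuting the
    subject group labels; the observed mean F1 should fall inside the
    central 95% band of the permutation distribution.
    """
    rep_seed = _battery_seeds(seed, 1)[0]
    table = planted_feature_table(rep_seed, effects=())
    y = table.labels
    plan = make_folds(y, k=5, seed=rep_seed)
    observed = run_mkl_experiment(table, valence, plan, lam=lam).f1_mean

    rng = np.random.default_rng(rep_seed)
    null_means = []
    for _ in range(n_permutations):
        perm = rng.permutation(y.size)
        permuted = FeatureTable(df=table.df, groups=table.groups.iloc[perm].set_axis(table.groups.index),
                                collapsed=table.collapsed)
        pplan = make_folds(permuted.labels, k=5, seed=rep_seed)
        null_means.append(run_mkl_experiment(permuted, valence, pplan, lam=lam).f1_mean)
    lo, hi = np.percentile(null_means, [2.5, 97.5])
    return {
        "observed_f1": float(observed),
        "null_band": (float(lo), float(hi)),
        "null_means": [float(v) for v in null_means],
        "inside": bool(lo - 1e-12 <= observed <= hi + 1e-12),
    }
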