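"""Cleaning and epoching: FIR band-pass, average reference, baseline
correction, and consensus peak-to-peak artifact rejection.

The rejection stage is a deliberately simple data-driven scheme: a
channel-level peak-to-peak threshold is learned as a high percentile of
the observed per-epoch-per-channel distribution, an epoch is dropped only
when the fraction of channels exceeding it passes a consensus fraction,
and isolated bad channels are replaced by an inverse-distance-weighted
average of the remaining good channels on the 2-D scalp layout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .layout import channel_positions_2d
from .synth import EpochedRecording

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterSpec:
    """Zero-phase FIR band-pass specification.

    ``n_taps`` (odd, for linear phase) is derived from the transition
    width with the Hamming-window rule (≈3.3 / normalized transition)
    when not given explicitly.
    """

    low_cut: float = 0.1
    high_cut: float = 60.0
    transition: float = 1.0
    n_taps: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.low_cut < self.high_cut:
            raise ValueError("need 0 < low_cut < high_cut")
        if self.transition <= 0:
            raise ValueError("transition must be positive")
        if self.n_taps is not None and self.n_taps % 2 == 0:
            raise ValueError("n_taps must be odd (linear phase)")

    def taps(self, fs: float) -> np.ndarray:
        if self.high_cut >= fs / 2:
            raise ValueError(
                f"high_cut {self.high_cut} Hz is at or above Nyquist ({fs / 2} Hz)"
            )
        n = self.n_taps
        if n is None:
            # the realized transition is ~3.3*fs/n (Hamming); it must also
            # fit below the low cutoff or DC leaks through
            width = min(self.transition, 2 * self.low_cut)
            n = int(np.ceil(3.3 * fs / width))
            n += 1 - n % 2
        return signal.firwin(
            n, [self.low_cut, self.high_cut], pass_zero=False, fs=fs,
            window="hamming",
        )


def filter_response(spec: FilterSpec, fs: float, n_points: int = 8192) -> dict:
    """Passband ripple and stopband attenuation (dB) of the designed filter."""
    h = spec.taps(fs)
    freqs, resp = signal.freqz(h, worN=n_points, fs=fs)
    mag = np.abs(resp)
    passband = (freqs >= spec.low_cut + spec.transition) & (
        freqs <= spec.high_cut - spec.transition
    )
    stopband = (freqs <= max(spec.low_cut - spec.transition, 0)) | (
        freqs >= spec.high_cut + spec.transition
    )
    report = {
        "n_taps": h.size,
        "passband_ripple_db": float(
            20 * np.log10(mag[passband].max() / max(mag[passband].min(), 1e-12))
        ) if passband.any() else float("nan"),
        "stopband_attenuation_db": float(
            -20 * np.log10(max(mag[stopband].max(), 1e-12))
        ) if stopband.any() else float("nan"),
    }
    logger.debug("FIR design: %s", report)
    return report


def bandpass_filter(data, fs: float | None = None, spec: FilterSpec | None = None):
    """Apply a zero-phase FIR band-pass along the last (time) axis.

    A single forward pass of the odd-length linear-phase kernel with
    group-delay compensation (centred convolution) leaves zero net phase
    shift.  Accepts an array (..., samples) with ``fs``, or an
    :class:`EpochedRecording` (filtered per epoch).
    """
    spec = spec or FilterSpec()
    if isinstance(data, EpochedRecording):
        out = data.copy()
        out.data = bandpass_filter(data.data, data.fs, spec)
        return out
    if fs is None:
        raise ValueError("fs is required for array input")
    x = np.asarray(data, dtype=float)
    h = spec.taps(fs)
    if x.shape[-1] <= h.size:
        raise ValueError(
            f"signal length {x.shape[-1]} must exceed the filter order "
            f"({h.size} taps); widen the transition band or pass n_taps"
        )
    return np.apply_along_axis(lambda v: np.convolve(v, h, mode="same"), -1, x)


def rereference_average(data: np.ndarray) -> np.ndarray:
    """Subtract the instantaneous mean over channels (common average).

    Accepts (channels, samples) or (trials, channels, samples); the
    channel axis is the second-to-last.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim < 2 or x.shape[-2] < 2:
        raise ValueError("average reference needs at least 2 channels")
    return x - x.mean(axis=-2, keepdims=True)


def epoch_and_baseline(
    continuous: np.ndarray,
    fs: float,
    schedule: pd.DataFrame,
    window: tuple[float, float] = (-0.2, 0.8),
    baseline: tuple[float, float] = (-0.2, 0.0),
    subject_id: str = "sub-001",
    group: int = -1,
) -> EpochedRecording:
    """Cut epochs around stimulus onsets and subtract the baseline mean.

    Sample convention is half-open: epoch k covers samples
    ``[onset + round(tmin*fs), onset + round(tmax*fs))`` so every epoch has
    exactly ``round(fs * (tmax - tmin))`` samples.  Events too close to the
    recording edge are skipped with a logged warning.
    """
    x = np.atleast_2d(np.asarray(continuous, dtype=float))
    tmin, tmax = window
    bmin, bmax = baseline
    if not (tmin <= bmin < bmax <= tmax):
        raise ValueError("baseline must be contained in the epoch window")
    n = int(round(fs * (tmax - tmin)))
    pre = int(round(tmin * fs))
    b0 = int(round((bmin - tmin) * fs))
    b1 = int(round((bmax - tmin) * fs))
    epochs, kept = [], []
    for _, ev in schedule.iterrows():
        start = int(ev["onset_sample"]) + pre
        stop = start + n
        if start < 0 or stop > x.shape[-1]:
            logger.warning(
                "skipping trial %s: epoch [%d, %d) outside recording of length %d",
                ev["trial_index"], start, stop, x.shape[-1],
            )
            continue
        ep = x[:, start:stop].copy()
        ep -= ep[:, b0:b1].mean(axis=1, keepdims=True)
        epochs.append(ep)
        kept.append(ev)
    if not epochs:
        raise ValueError("no events produced a full epoch")
    return EpochedRecording(
        subject_id=subject_id,
        group=group,
        data=np.stack(epochs),
        fs=fs,
        channel_names=tuple(f"ch{i}" for i in range(x.shape[0])),
        events=pd.DataFrame(kept).reset_index(drop=True),
        window=window,
    )


@dataclass(frozen=True)
class RejectionPolicy:
    """Consensus peak-to-peak rejection parameters.

    An epoch is dropped when more than ``consensus_fraction`` of the
    channels exceed ``channel_threshold`` peak-to-peak (or when more than
    ``max_interpolate`` channels would need repair); otherwise the bad
    channels are interpolated.
    """

    channel_threshold: float
    consensus_fraction: float = 0.1
    max_interpolate: int = 6

    def __post_init__(self) -> None:
        if self.channel_threshold <= 0:
            raise ValueError("channel_threshold must be positive")
        if not 0 < self.consensus_fraction <= 1:
            raise ValueError("consensus_fraction must lie in (0, 1]")
        if self.max_interpolate < 0:
            raise ValueError("max_interpolate must be >= 0")


def learn_rejection_threshold(
    epochs: EpochedRecording,
    percentile: float = 99.0,
    consensus_fraction: float = 0.1,
    max_interpolate: int = 6,
) -> RejectionPolicy:
    """Learn the channel threshold from the data.

    The threshold is the given percentile of the pooled per-epoch,
    per-channel peak-to-peak amplitude distribution; with mostly clean
    data and rare large transients the 99th percentile falls between the
    clean bulk and the artifact tail.
    """
    if epochs.n_trials < 10:
        raise ValueError(
            "need at least 10 epochs to learn a threshold; use a fixed "
            "RejectionPolicy instead"
        )
    ptp = epochs.data.max(axis=-1) - epochs.data.min(axis=-1)
    thr = float(np.percentile(ptp, percentile))
    if thr <= 0:
        raise ValueError("degenerate (constant) epochs: cannot learn a threshold")
    return RejectionPolicy(
        channel_threshold=thr,
        consensus_fraction=consensus_fraction,
        max_interpolate=max_interpolate,
    )


def _idw_weights(positions: np.ndarray, bad: np.ndarray, power: float = 2.0) -> np.ndarray:
    """Inverse-distance weights (n_bad, n_good) on the 2-D layout."""
    good = ~bad
    d = np.linalg.norm(
        positions[bad][:, None, :] - positions[good][None, :, :], axis=-1
    )
    w = 1.0 / np.maximum(d, 1e-6) ** power
    return w / w.sum(axis=1, keepdims=True)


def reject_and_interpolate(
    epochs: EpochedRecording,
    policy: RejectionPolicy,
    positions: np.ndarray | None = None,
) -> tuple[EpochedRecording, list[dict]]:
    """Apply the consensus rejection rule; returns cleaned epochs + a log.

    Per epoch: channels whose peak-to-peak exceeds the threshold are
    *bad*.  If their fraction exceeds ``consensus_fraction`` (or all
    channels are bad, or more than ``max_interpolate`` need repair) the
    epoch is dropped; otherwise each bad channel is replaced by the
    inverse-distance-weighted average of the good channels.
    """
    if positions is None:
        positions = channel_positions_2d(tuple(epochs.channel_names))
    n_ch = len(epochs.channel_names)
    ptp = epochs.data.max(axis=-1) - epochs.data.min(axis=-1)
    bad = ptp > policy.channel_threshold

    keep_idx, log = [], []
    data = epochs.data.copy()
    for i in range(epochs.n_trials):
        nbad = int(bad[i].sum())
        if nbad == 0:
            keep_idx.append(i)
            continue
        frac = nbad / n_ch
        if frac > policy.consensus_fraction or nbad == n_ch or nbad > policy.max_interpolate:
            log.append({"trial": i, "action": "drop",
                        "bad_channels": [epochs.channel_names[c] for c in np.flatnonzero(bad[i])]})
            continue
        w = _idw_weights(positions, bad[i])
        data[i, bad[i], :] = w @ data[i, ~bad[i], :]
        log.append({"trial": i, "action": "interpolate",
                    "bad_channels": [epochs.channel_names[c] for c in np.flatnonzero(bad[i])]})
        keep_idx.append(i)

    cleaned = EpochedRecording(
        subject_id=epochs.subject_id,
        group=epochs.group,
        data=data[keep_idx],
        fs=epochs.fs,
        channel_names=tuple(epochs.channel_names),
        events=epochs.events.iloc[keep_idx].reset_index(drop=True),
        window=epochs.window,
    )
    return cleaned, log
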