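"""ERP feature extraction: wavelet band decomposition and ROI statistics.

The pipeline turns each subject's cleaned epochs into a single feature
vector grouped by *sources*:

1. epochs of each valence are averaged into an ERP (channels x samples);
2. the ERP is resampled to an analysis rate of 125 Hz so that the dyadic
   band edges of a 4-level discrete wavelet transform (62.5 / 31.25 /
   15.63 / 7.81 / 3.91 Hz) approximate the classical EEG bands;
3. each channel is decomposed with a 4-level DWT (Symlet-8 by default);
   detail levels D1..D4 and the final approximation A4 are read as the
   gamma (32-60 Hz), beta (16-32), alpha (8-16), theta (4-8) and delta
   (0-4 Hz) bands;
4. summary statistics of each band's coefficients are computed per channel
   and averaged within the eight ROIs of the layout.

The result is a table indexed by (valence, roi, band, statistic); each
(valence, roi, band) block is one *source* feeding one kernel downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
import pywt
from scipy import signal

from .layout import ROILayout
from .synth import BANDS, VALENCES, EpochedRecording

logger = logging.getLogger(__name__)

#: Fixed statistic order; "variance"/"std" use the population convention,
#: kurtosis is the plain standardized fourth moment (not excess).
STATISTICS: tuple[str, ...] = (
    "max", "min", "mean", "median", "variance", "std", "skewness", "kurtosis",
)

#: Five-statistic preset reproducing the compact feature array some
#: analyses use (3 valences x 8 ROIs x 5 bands x 5 stats -> 200 per valence
#: when flattened with 5 statistics).
STATISTICS_5: tuple[str, ...] = ("max", "min", "mean", "variance", "skewness")

#: Nominal EEG band edges in Hz, delta..gamma.
BAND_EDGES_HZ: dict[str, tuple[float, float]] = {
    "delta": (0.0, 4.0), "theta": (4.0, 8.0), "alpha": (8.0, 16.0),
    "beta": (16.0, 32.0), "gamma": (32.0, 60.0),
}


class MissingValenceError(ValueError):
    """Raised when a recording has no surviving epochs of a valence."""


@dataclass(frozen=True)
class BandMap:
    """Mapping between DWT components and EEG bands.

    A ``levels``-deep dyadic cascade at ``analysis_fs`` produces detail
    components D1..Dlevels and an approximation; with the defaults the
    component pass-bands land within 25% of the nominal EEG band edges,
    which is the reading under which the level-to-band relabelling holds.
    """

    analysis_fs: float = 125.0
    wavelet: str = "sym8"
    levels: int = 4

    def __post_init__(self) -> None:
        if self.levels != 4:
            raise ValueError("the band mapping is defined for 4 levels")
        # D_k spans fs/2^(k+1) .. fs/2^k ; A4 spans 0 .. fs/32.
        nominal_upper = {
            "gamma": self.analysis_fs / 2,
            "beta": self.analysis_fs / 4,
            "alpha": self.analysis_fs / 8,
            "theta": self.analysis_fs / 16,
            "delta": self.analysis_fs / 32,
        }
        for band in BANDS:
            stated = BAND_EDGES_HZ[band][1]
            # gamma's stated top (60 Hz) is the filter edge, checked against
            # the Nyquist of the analysis rate.
            if abs(nominal_upper[band] - stated) > 0.25 * stated:
                raise ValueError(
                    f"analysis_fs={self.analysis_fs}: dyadic edge "
                    f"{nominal_upper[band]:.2f} Hz for {band} is more than 25% "
                    f"from the stated edge {stated} Hz"
                )

    @property
    def component_names(self) -> dict[str, str]:
        return {"delta": "A4", "theta": "D4", "alpha": "D3", "beta": "D2", "gamma": "D1"}


def average_erp(epochs: EpochedRecording, valence: str) -> np.ndarray:
    """Average the epochs of one valence into an ERP (channels x samples)."""
    mask = epochs.valences == valence
    if not mask.any():
        raise MissingValenceError(
            f"{epochs.subject_id}: no epochs of valence {valence!r}"
        )
    return epochs.data[mask].mean(axis=0)


def resample_to_analysis_fs(erp: np.ndarray, fs_in: float, fs_out: float = 125.0) -> np.ndarray:
    """Polyphase-resample an ERP (channels x samples, time last) downward."""
    if fs_out > fs_in:
        raise ValueError("upsampling is not supported; fs_out must be <= fs_in")
    if fs_out == fs_in:
        return np.asarray(erp, dtype=float)
    frac = Fraction(fs_out / fs_in).limit_denominator(10000)
    return signal.resample_poly(np.asarray(erp, dtype=float), frac.numerator,
                                frac.denominator, axis=-1)


def _min_length(wavelet: str, levels: int) -> int:
    """Smallest signal length whose deepest coefficient vector has >= 4
    entries (so that kurtosis is defined)."""
    flen = pywt.Wavelet(wavelet).dec_len
    n = 4
    for _ in range(levels):
        n = 2 * n - flen + 1  # inverse of the symmetric-mode length recursion
    return max(n, 4)


def dwt_band_decompose(
    x: np.ndarray, wavelet: str = "sym8", levels: int = 4,
    bandmap: BandMap | None = None, mode: str = "symmetric",
) -> dict[str, np.ndarray]:
    """Decompose a 1-D signal into band-labelled DWT coefficient vectors.

    Returns ``{"delta": A4, "theta": D4, "alpha": D3, "beta": D2,
    "gamma": D1}`` using symmetric boundary padding by default.  Signals
    shorter than the wavelet support times ``2**levels`` incur boundary
    effects in the deepest levels; this is accepted for 1 s epochs at the
    analysis rate.  ``mode="periodization"`` gives an exactly orthogonal
    (energy-preserving) cascade for dyadic lengths.
    """
    if bandmap is not None:
        wavelet, levels = bandmap.wavelet, bandmap.levels
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("dwt_band_decompose expects a 1-D signal")
    minlen = 4 * 2**levels if mode == "periodization" else _min_length(wavelet, levels)
    if x.size < minlen:
        raise ValueError(
            f"signal of length {x.size} too short for a {levels}-level "
            f"{wavelet} decomposition; minimum length is {minlen}"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # boundary-effect notice
        coeffs = pywt.wavedec(x, wavelet, level=levels, mode=mode)
    # coeffs = [A4, D4, D3, D2, D1] -> delta..gamma in fixed band order.
    return dict(zip(BANDS, coeffs))


def _stats_matrix(c: np.ndarray, statistic_set: tuple[str, ...]) -> np.ndarray:
    """Vectorized statistics over the last axis of a (..., n) array."""
    mu = c.mean(axis=-1)
    var = c.var(axis=-1)
    sd = np.sqrt(var)
    safe = np.where(sd > 0, sd, 1.0)
    z = (c - mu[..., None]) / safe[..., None]
    nonconst = var > 0
    values = {
        "max": c.max(axis=-1),
        "min": c.min(axis=-1),
        "mean": mu,
        "median": np.median(c, axis=-1),
        "variance": var,
        "std": sd,
        # standardized 3rd/4th moments; 0 (not NaN) on constant vectors
        "skewness": np.where(nonconst, (z**3).mean(axis=-1), 0.0),
        "kurtosis": np.where(nonconst, (z**4).mean(axis=-1), 0.0),
    }
    return np.stack([values[s] for s in statistic_set], axis=-1)


def band_statistics(
    coeffs: np.ndarray, statistic_set: tuple[str, ...] = STATISTICS
) -> np.ndarray:
    """Summary statistics of a coefficient vector, in the declared order.

    Population variance/std; skewness and kurtosis are the standardized
    third and fourth moments (kurtosis of a Gaussian is 3, not 0).  On a
    constant vector both are undefined and are returned as 0 with a
    logged note.
    """
    c = np.asarray(coeffs, dtype=float)
    if c.ndim != 1 or c.size < 4:
        raise ValueError("need a 1-D vector of at least 4 coefficients")
    unknown = set(statistic_set) - set(STATISTICS)
    if unknown:
        raise ValueError(f"unknown statistics: {sorted(unknown)}")
    if c.var() == 0.0 and {"skewness", "kurtosis"} & set(statistic_set):
        logger.debug("constant coefficient vector: skewness/kurtosis set to 0")
    return _stats_matrix(c, statistic_set)


def roi_average(
    per_channel: np.ndarray, channel_names: tuple[str, ...], layout: ROILayout
) -> np.ndarray:
    """Average a (channels, bands, statistics) array within each ROI.

    Returns (n_rois, bands, statistics) in ascending ROI-id order.
    """
    per_channel = np.asarray(per_channel, dtype=float)
    index = {ch: i for i, ch in enumerate(channel_names)}
    unmapped = [ch for ch in layout.channels if ch not in index]
    if unmapped:
        raise ValueError(f"layout channels missing from data: {unmapped}")
    out = np.empty((len(layout.roi_ids),) + per_channel.shape[1:])
    for k, roi_id in enumerate(layout.roi_ids):
        rows = [index[ch] for ch in layout.rois[roi_id]]
        out[k] = per_channel[rows].mean(axis=0)
    return out


@dataclass
class FeatureTable:
    """Per-subject features indexed by (valence, roi, band, statistic).

    ``df`` has one row per subject and a 4-level column MultiIndex; in a
    collapsed table the level order is (roi, band, valence, statistic) and
    a source spans all valences.  ``groups`` maps subject_id to the class
    label (+1 / -1).
    """

    df: pd.DataFrame
    groups: pd.Series
    collapsed: bool = False

    def __post_init__(self) -> None:
        if not self.df.index.equals(self.groups.index):
            raise ValueError("feature rows and group labels must share an index")
        if self.df.isna().any().any():
            raise ValueError("feature table contains missing cells")

    @property
    def subject_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def labels(self) -> np.ndarray:
        return self.groups.to_numpy(dtype=int)

    @property
    def source_ids(self) -> list[tuple]:
        """Ordered source identifiers: (valence, roi, band), or (roi, band)
        for a collapsed table."""
        n_levels = 2 if self.collapsed else 3
        seen: list[tuple] = []
        for col in self.df.columns:
            key = tuple(col[:n_levels])
            if not seen or seen[-1] != key:
                if key in seen:
                    raise ValueError("source blocks are not contiguous")
                seen.append(key)
        return seen

    def source_block(self, source_id: tuple) -> np.ndarray:
        """Feature matrix (subjects x block width) for one source."""
        k = len(source_id)
        mask = np.array([tuple(col[:k]) == tuple(source_id) for col in self.df.columns])
        if not mask.any():
            raise KeyError(f"unknown source {source_id!r}")
        return self.df.to_numpy(dtype=float)[:, mask]

    def sources_for_valence(self, valence: str) -> list[tuple]:
        if self.collapsed:
            raise ValueError("collapsed tables have no per-valence sources")
        return [s for s in self.source_ids if s[0] == valence]

    def to_tsv(self, path) -> None:
        flat = self.df.copy()
        flat.columns = ["|".join(str(x) for x in col) for col in self.df.columns]
        flat.insert(0, "group", self.groups)
        flat.to_csv(path, sep="\t", index_label="subject_id")

    @classmethod
    def from_tsv(cls, path, collapsed: bool = False) -> "FeatureTable":
        flat = pd.read_csv(path, sep="\t", index_col="subject_id")
        groups = flat.pop("group").astype(int)
        cols = [tuple(c.split("|")) for c in flat.columns]
        if collapsed:
            tuples = [(int(r), b, v, s) for r, b, v, s in cols]
            names = ["roi", "band", "valence", "statistic"]
        else:
            tuples = [(v, int(r), b, s) for v, r, b, s in cols]
            names = ["valence", "roi", "band", "statistic"]
        df = pd.DataFrame(flat.to_numpy(), index=flat.index,
                          columns=pd.MultiIndex.from_tuples(tuples, names=names))
        return cls(df=df, groups=groups, collapsed=collapsed)


def subject_features(
    epochs: EpochedRecording,
    layout: ROILayout,
    bandmap: BandMap,
    statistic_set: tuple[str, ...] = STATISTICS,
    valences: tuple[str, ...] = VALENCES,
) -> np.ndarray:
    """One subject's (valence, roi, band, statistic) feature array."""
    out = np.empty((len(valences), len(layout.roi_ids), len(BANDS), len(statistic_set)))
    for vi, valence in enumerate(valences):
        erp = average_erp(epochs, valence)
        erp = resample_to_analysis_fs(erp, epochs.fs, bandmap.analysis_fs)
        # decompose all channels at once (time on the last axis)
        _ = dwt_band_decompose(erp[0], bandmap=bandmap)  # length validation
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            coeffs = pywt.wavedec(erp, bandmap.wavelet, level=bandmap.levels,
                                  mode="symmetric", axis=-1)
        per_channel = np.stack(
            [_stats_matrix(c, statistic_set) for c in coeffs], axis=1
        )  # bands already in delta..gamma order: [A4, D4, D3, D2, D1]
        out[vi] = roi_average(per_channel, epochs.channel_names, layout)
    return out


def build_feature_table(
    cohort: list[EpochedRecording],
    layout: ROILayout | None = None,
    bandmap: BandMap | None = None,
    statistic_set: tuple[str, ...] = STATISTICS,
    valences: tuple[str, ...] = VALENCES,
) -> FeatureTable:
    """Extract the full cohort feature table.

    Columns are ordered valence-major, then ROI (1..8), band
    (delta..gamma) and statistic, so each contiguous
    (valence, roi, band) block of width ``len(statistic_set)`` is one
    kernel source (8 ROIs x 5 bands = 40 sources per valence).
    """
    if not cohort:
        raise ValueError("empty cohort")
    layout = layout or ROILayout()
    bandmap = bandmap or BandMap()
    ref_channels = cohort[0].channel_names
    for rec in cohort:
        if rec.channel_names != ref_channels:
            raise ValueError(
                f"inconsistent channel sets across subjects ({rec.subject_id})"
            )
    columns = pd.MultiIndex.from_tuples(
        [
            (v, roi, band, stat)
            for v in valences
            for roi in layout.roi_ids
            for band in BANDS
            for stat in statistic_set
        ],
        names=["valence", "roi", "band", "statistic"],
    )
    rows, index, groups = [], [], []
    for rec in cohort:
        feats = subject_features(rec, layout, bandmap, statistic_set, valences)
        rows.append(feats.reshape(-1))
        index.append(rec.subject_id)
        groups.append(rec.group)
    df = pd.DataFrame(np.vstack(rows), index=pd.Index(index, name="subject_id"),
                      columns=columns)
    return FeatureTable(df=df, groups=pd.Series(groups, index=df.index, name="group"))


def collapse_valences(table: FeatureTable) -> FeatureTable:
    """Concatenate each (roi, band) source's statistics across the three
    valences (negative, neutral, positive), tripling the block width while
    keeping 40 sources."""
    if table.collapsed:
        raise ValueError("table is already collapsed")
    present = set(table.df.columns.get_level_values("valence"))
    missing = set(VALENCES) - present
    if missing:
        raise ValueError(f"cannot collapse: missing valences {sorted(missing)}")
    reordered = table.df.reorder_levels(["roi", "band", "valence", "statistic"], axis=1)
    rois = sorted(set(reordered.columns.get_level_values("roi")))
    bands = [b for b in BANDS if b in set(reordered.columns.get_level_values("band"))]
    stats_order = [c[3] for c in table.df.columns[: len(table.df.columns) // len(table.source_ids)]]
    columns = pd.MultiIndex.from_tuples(
        [
            (roi, band, v, s)
            for roi in rois
            for band in bands
            for v in VALENCES
            for s in stats_order
        ],
        names=["roi", "band", "valence", "statistic"],
    )
    df = reordered[columns]
    return FeatureTable(df=df, groups=table.groups, collapsed=True)
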