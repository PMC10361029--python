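"""64-channel 10-20 electrode layout and region-of-interest (ROI) groupings.

The analysis averages channel-level features within eight scalp regions so
that kernel weights can be traced back to interpretable areas (prefrontal,
frontal, central, temporal, parietal, occipital).  The default layout uses
the 64 extended 10-20 names of the BioSemi64 cap, for which standard 3-D
template positions ship with MNE.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

#: The 64 extended 10-20 channel names used by default (BioSemi64 order).
CHANNEL_NAMES_64: tuple[str, ...] = (
    "Fp1", "AF7", "AF3", "F1", "F3", "F5", "F7", "FT7", "FC5", "FC3", "FC1",
    "C1", "C3", "C5", "T7", "TP7", "CP5", "CP3", "CP1", "P1", "P3", "P5",
    "P7", "P9", "PO7", "PO3", "O1", "Iz", "Oz", "POz", "Pz", "CPz", "Fpz",
    "Fp2", "AF8", "AF4", "AFz", "Fz", "F2", "F4", "F6", "F8", "FT8", "FC6",
    "FC4", "FC2", "FCz", "Cz", "C2", "C4", "C6", "T8", "TP8", "CP6", "CP4",
    "CP2", "P2", "P4", "P6", "P8", "P10", "PO8", "PO4", "O2",
)

# Eight disjoint scalp regions covering all 64 channels.  The grouping
# follows the usual anatomical reading of the extended 10-20 labels; it is
# a documented, editable default, not a replica of any particular cap
# diagram.
DEFAULT_ROI_CHANNELS: dict[int, tuple[str, ...]] = {
    1: ("Fp1", "Fpz", "Fp2", "AF7", "AF3", "AFz", "AF4", "AF8"),          # prefrontal
    2: ("F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8"),            # frontal
    3: ("FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6",
        "C5", "C3", "C1", "Cz", "C2", "C4", "C6"),                        # central
    4: ("FT7", "T7", "TP7"),                                              # temporal left
    5: ("FT8", "T8", "TP8"),                                              # temporal right
    6: ("CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6"),                 # centro-parietal
    7: ("P9", "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8", "P10"),  # parietal
    8: ("PO7", "PO3", "POz", "PO4", "PO8", "O1", "Oz", "O2", "Iz"),       # occipital
}

ROI_LABELS: dict[int, str] = {
    1: "prefrontal",
    2: "frontal",
    3: "central",
    4: "temporal-left",
    5: "temporal-right",
    6: "centro-parietal",
    7: "parietal",
    8: "occipital",
}


@dataclass(frozen=True)
class ROILayout:
    """Mapping from ROI id (1..n) to the 10-20 channel names it contains.

    ROIs must be disjoint; their union defines the set of scalp channels
    used for feature extraction.
    """

    rois: dict[int, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_ROI_CHANNELS)
    )
    labels: dict[int, str] = field(default_factory=lambda: dict(ROI_LABELS))

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for roi_id, chans in self.rois.items():
            if not chans:
                raise ValueError(f"ROI {roi_id} has no channels")
            overlap = seen.intersection(chans)
            if overlap:
                raise ValueError(f"ROIs are not disjoint: {sorted(overlap)}")
            seen.update(chans)

    @property
    def roi_ids(self) -> list[int]:
        return sorted(self.rois)

    @property
    def channels(self) -> list[str]:
        """All channels covered by the layout, in ROI order."""
        return [ch for roi in self.roi_ids for ch in self.rois[roi]]

    def roi_of(self, channel: str) -> int:
        for roi_id, chans in self.rois.items():
            if channel in chans:
                return roi_id
        raise KeyError(f"channel {channel!r} not assigned to any ROI")

    def to_json(self) -> str:
        return json.dumps(
            {
                "rois": {str(k): list(v) for k, v in self.rois.items()},
                "labels": {str(k): v for k, v in self.labels.items()},
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ROILayout":
        obj = json.loads(text)
        return cls(
            rois={int(k): tuple(v) for k, v in obj["rois"].items()},
            labels={int(k): v for k, v in obj.get("labels", {}).items()},
        )


@lru_cache(maxsize=4)
def channel_positions_2d(channel_names: tuple[str, ...] = CHANNEL_NAMES_64) -> np.ndarray:
    """Return (n_channels, 2) scalp positions for the given 10-20 names.

    Positions come from MNE's template montages projected onto the x/y
    plane; they are used for inverse-distance channel interpolation and
    layout plots, where only relative geometry matters.
    """
    import mne

    montage = mne.channels.make_standard_montage("biosemi64")
    pos3d = montage.get_positions()["ch_pos"]
    missing = [ch for ch in channel_names if ch not in pos3d]
    if missing:
        montage = mne.channels.make_standard_montage("standard_1020")
        pos3d = montage.get_positions()["ch_pos"]
        missing = [ch for ch in channel_names if ch not in pos3d]
        if missing:
            raise KeyError(f"no template position for channels: {missing}")
    xy = np.array([pos3d[ch][:2] for ch in channel_names], dtype=float)
    return xy
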