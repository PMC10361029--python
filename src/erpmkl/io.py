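"""Cohort I/O: EDF recordings, BIDS-style events TSV, and JSON sidecars.

A cohort is written as one directory per run:

    cohort/
      cohort.json            group labels + generation-config echo
      sub-001.edf            epoched EEG, one EDF data record per epoch
      sub-001_events.tsv     onset, duration, trial_type, stimulus_id, block
      ...

The EDF writer is intentionally minimal: standard EDF with an ASCII
header and 16-bit little-endian samples, one data record per epoch (the
record duration equals the epoch length).  Files written here are read
back by any EDF reader; :func:`read_edf_raw` uses MNE.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import EpochedRecording, SynthConfig

_EDF_EPOCH_ANNOT = "epoch"


def _pad(text: str, width: int) -> bytes:
    s = text[:width]
    return s.ljust(width).encode("ascii")


def _fmt_float(value: float, width: int = 8) -> str:
    """Format a float into an EDF numeric field of fixed ASCII width."""
    for fmt in (f"{{:.{width - 2}g}}", "{:.3g}", "{:.2g}", "{:.1g}"):
        s = fmt.format(value)
        if len(s) <= width:
            return s
    raise ValueError(f"cannot format {value} in {width} chars")


def write_edf(path, recording: EpochedRecording) -> None:
    """Write an epoched recording as an EDF file, one record per epoch.

    Per-channel physical scaling spans the observed amplitude range; the
    16-bit quantization step is range/65535 (≈0.01 uV for typical EEG).
    """
    path = Path(path)
    data = recording.data  # trials x channels x samples
    n_rec, n_ch, n_samp = data.shape
    duration = n_samp / recording.fs

    pmins, pmaxs, dmin, dmax = [], [], -32768, 32767
    for c in range(n_ch):
        lo = float(data[:, c, :].min())
        hi = float(data[:, c, :].max())
        if hi <= lo:
            hi = lo + 1.0
        # re-parse the formatted header strings so the scaling used for
        # quantization matches what a reader reconstructs
        lo = float(_fmt_float(lo))
        hi = float(_fmt_float(hi))
        if hi <= lo:
            hi = lo + 1.0
        pmins.append(lo)
        pmaxs.append(hi)

    header_bytes = 256 + 256 * n_ch
    with open(path, "wb") as fh:
        fh.write(_pad("0", 8))
        fh.write(_pad(f"X X X {recording.subject_id}", 80))
        fh.write(_pad(f"Startdate X X X X group={recording.group:+d}", 80))
        fh.write(_pad("01.01.00", 8))
        fh.write(_pad("00.00.00", 8))
        fh.write(_pad(str(header_bytes), 8))
        fh.write(_pad("", 44))
        fh.write(_pad(str(n_rec), 8))
        fh.write(_pad(_fmt_float(duration), 8))
        fh.write(_pad(str(n_ch), 4))
        for ch in recording.channel_names:
            fh.write(_pad(ch, 16))
        for _ in range(n_ch):
            fh.write(_pad("", 80))  # transducer
        for _ in range(n_ch):
            fh.write(_pad("uV", 8))
        for lo in pmins:
            fh.write(_pad(_fmt_float(lo), 8))
        for hi in pmaxs:
            fh.write(_pad(_fmt_float(hi), 8))
        for _ in range(n_ch):
            fh.write(_pad(str(dmin), 8))
        for _ in range(n_ch):
            fh.write(_pad(str(dmax), 8))
        for _ in range(n_ch):
            fh.write(_pad("", 80))  # prefiltering
        for _ in range(n_ch):
            fh.write(_pad(str(n_samp), 8))
        for _ in range(n_ch):
            fh.write(_pad("", 32))

        scale = [(pmaxs[c] - pmins[c]) / (dmax - dmin) for c in range(n_ch)]
        for r in range(n_rec):
            rec = np.empty((n_ch, n_samp), dtype="<i2")
            for c in range(n_ch):
                dig = (data[r, c, :] - pmins[c]) / scale[c] + dmin
                rec[c] = np.clip(np.round(dig), dmin, dmax).astype("<i2")
            fh.write(rec.tobytes())


def read_edf_raw(path):
    """Read an EDF file with MNE; returns the ``Raw`` object (uV scale is
    MNE's native volts — multiply by 1e6 to compare with written data)."""
    import mne

    return mne.io.read_raw_edf(path, preload=True, verbose="error")


def write_events_tsv(path, recording: EpochedRecording) -> None:
    """BIDS-style events table: onset (s), duration, trial_type,
    stimulus_id, block."""
    ev = recording.events
    df = pd.DataFrame(
        {
            "onset": ev["onset_sample"] / recording.fs,
            "duration": 0.5,
            "trial_type": ev["valence"],
            "stimulus_id": ev["stimulus_id"],
            "block": ev["block"],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_events_tsv(path, fs: float) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    out = pd.DataFrame(
        {
            "trial_index": np.arange(len(df)),
            "block": df["block"],
            "stimulus_id": df["stimulus_id"],
            "valence": df["trial_type"],
            "onset_sample": np.round(df["onset"] * fs).astype(int),
        }
    )
    return out


def write_cohort(out_dir, cohort: list[EpochedRecording],
                 config: SynthConfig | None = None) -> Path:
    """Write a cohort directory (EDF + events TSV per subject + sidecar)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sidecar = {
        "subjects": [
            {
                "subject_id": rec.subject_id,
                "group": rec.group,
                "fs": rec.fs,
                "window": list(rec.window),
                "n_trials": rec.n_trials,
                "edf": f"{rec.subject_id}.edf",
                "events": f"{rec.subject_id}_events.tsv",
            }
            for rec in cohort
        ],
    }
    if config is not None:
        echo = asdict(config)
        echo["layout"] = {str(k): list(v) for k, v in config.layout.rois.items()}
        echo["channel_names"] = list(config.channel_names)
        echo["effects"] = [asdict(e) for e in config.effects]
        sidecar["config"] = echo
    (out_dir / "cohort.json").write_text(json.dumps(sidecar, indent=2))
    for rec in cohort:
        write_edf(out_dir / f"{rec.subject_id}.edf", rec)
        write_events_tsv(out_dir / f"{rec.subject_id}_events.tsv", rec)
    return out_dir


def read_cohort(in_dir) -> list[EpochedRecording]:
    """Read a cohort directory written by :func:`write_cohort`.

    Epoch boundaries are reconstructed from the fixed EDF record length
    recorded in the sidecar (one record per epoch).
    """
    in_dir = Path(in_dir)
    sidecar = json.loads((in_dir / "cohort.json").read_text())
    cohort = []
    for sub in sidecar["subjects"]:
        raw = read_edf_raw(in_dir / sub["edf"])
        fs = float(sub["fs"])
        data = raw.get_data() * 1e6  # volts -> uV
        n_samp = int(round(fs * (sub["window"][1] - sub["window"][0])))
        n_trials = sub["n_trials"]
        if data.shape[1] < n_trials * n_samp:
            raise ValueError(f"{sub['edf']}: unexpected length")
        epochs = data[:, : n_trials * n_samp].reshape(
            data.shape[0], n_trials, n_samp
        ).transpose(1, 0, 2)
        events = read_events_tsv(in_dir / sub["events"], fs)
        cohort.append(
            EpochedRecording(
                subject_id=sub["subject_id"],
                group=int(sub["group"]),
                data=epochs,
                fs=fs,
                channel_names=tuple(raw.ch_names),
                events=events,
                window=tuple(sub["window"]),
            )
        )
    return cohort
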