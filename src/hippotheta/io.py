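"""File formats: HDF5 signals, CSV event logs, TSV electrode tables, JSON.

Signals are stored in HDF5 with one dataset per channel plus a
``sampling_rate`` attribute.  EDF files are read through :mod:`mne` when it is
installed; writing uses HDF5 only.  Artifact masks are serialized as
run-length-encoded JSON.  All tabular outputs use a fixed float format so
identical runs are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from hippotheta.types import Epoch, ElectrodeRecord, Recording, TrialLog

FLOAT_FMT = "%.6g"

EVENT_COLUMNS = [
    "trial_id", "trial_type", "epoch_index", "t_start_s", "t_end_s",
    "speed_vru_s", "object_pos_vru", "response_pos_vru", "response_time_s",
]
ELECTRODE_COLUMNS = ["subject_id", "electrode_id", "hemisphere", "subregion", "ap_fraction"]


# ---------------------------------------------------------------------------
# recordings
# ---------------------------------------------------------------------------

def write_recording_h5(recording: Recording, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["sampling_rate"] = recording.sampling_rate
        f.attrs["start_time"] = recording.start_time
        for cid, chan in zip(recording.channel_ids, recording.data):
            f.create_dataset(cid, data=chan, compression="gzip", compression_opts=4)


def read_recording_h5(path: str | Path) -> Recording:
    with h5py.File(path, "r") as f:
        channel_ids = sorted(f.keys())
        data = np.vstack([f[c][()] for c in channel_ids])
        return Recording(
            data,
            float(f.attrs["sampling_rate"]),
            channel_ids,
            float(f.attrs.get("start_time", 0.0)),
        )


def read_recording_edf(path: str | Path) -> Recording:
    """Read an EDF recording (requires the optional mne dependency)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return Recording(raw.get_data(), float(raw.info["sfreq"]), list(raw.ch_names))


def read_recording(path: str | Path) -> Recording:
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return read_recording_edf(path)
    return read_recording_h5(path)


# ---------------------------------------------------------------------------
# behavior events
# ---------------------------------------------------------------------------

def trials_to_frame(trials: list[TrialLog]) -> pd.DataFrame:
    rows = []
    for tr in trials:
        for i, ep in enumerate(tr.epochs):
            rows.append(
                {
                    "trial_id": tr.trial_id,
                    "trial_type": tr.trial_type,
                    "epoch_index": i,
                    "t_start_s": ep.t_start_s,
                    "t_end_s": ep.t_end_s,
                    "speed_vru_s": ep.speed,
                    "object_pos_vru": tr.object_pos,
                    "response_pos_vru": tr.response_pos,
                    "response_time_s": tr.response_time_s,
                }
            )
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def frame_to_trials(df: pd.DataFrame) -> list[TrialLog]:
    trials = []
    for tid, g in df.groupby("trial_id", sort=True):
        g = g.sort_values("epoch_index")
        first = g.iloc[0]
        resp = first["response_pos_vru"]
        rt = first["response_time_s"]
        trials.append(
            TrialLog(
                trial_id=int(tid),
                trial_type=str(first["trial_type"]),
                epochs=[
                    Epoch(float(r.t_start_s), float(r.t_end_s), float(r.speed_vru_s))
                    for r in g.itertuples()
                ],
                object_pos=float(first["object_pos_vru"]),
                response_pos=None if pd.isna(resp) else float(resp),
                response_time_s=None if pd.isna(rt) else float(rt),
            )
        )
    return trials


def write_events_csv(trials: list[TrialLog], path: str | Path) -> None:
    trials_to_frame(trials).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_events_csv(path: str | Path) -> list[TrialLog]:
    return frame_to_trials(pd.read_csv(path))


# ---------------------------------------------------------------------------
# electrode metadata
# ---------------------------------------------------------------------------

def electrodes_to_frame(records: list[ElectrodeRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "subject_id": r.subject_id,
            "electrode_id": r.electrode_id,
            "hemisphere": r.hemisphere,
            "subregion": r.subregion,
            "ap_fraction": r.ap_fraction,
        }
        if r.oscillator_class is not None:
            row.update(
                region=r.region,
                oscillator_class=r.oscillator_class,
                band_lo_hz=";".join(FLOAT_FMT % b.f_lo for b in r.bands),
                band_hi_hz=";".join(FLOAT_FMT % b.f_hi for b in r.bands),
                peak_hz=";".join(FLOAT_FMT % b.peak_freq for b in r.bands),
                label=";".join(r.band_labels),
            )
        rows.append(row)
    return pd.DataFrame(rows)


def write_electrodes_tsv(records: list[ElectrodeRecord], path: str | Path) -> None:
    electrodes_to_frame(records).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_electrodes_tsv(path: str | Path) -> list[ElectrodeRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        ElectrodeRecord(
            subject_id=str(r.subject_id),
            electrode_id=str(r.electrode_id),
            hemisphere=str(r.hemisphere),
            subregion=str(r.subregion),
            ap_fraction=float(r.ap_fraction),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# masks and ground truth
# ---------------------------------------------------------------------------

def mask_to_rle(mask: np.ndarray) -> list[list[int]]:
    """Run-length encode a boolean mask as [start, length] pairs of True runs."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(np.int8))
    run_starts = np.flatnonzero(d == 1)
    run_ends = np.flatnonzero(d == -1)
    return [[int(s), int(e - s)] for s, e in zip(run_starts, run_ends)]


def rle_to_mask(rle: list[list[int]], n: int) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for start, length in rle:
        mask[start : start + length] = True
    return mask


def write_mask_json(masks: dict[str, np.ndarray], path: str | Path) -> None:
    payload = {
        cid: {"n": int(len(m)), "runs": mask_to_rle(m)} for cid, m in masks.items()
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_mask_json(path: str | Path) -> dict[str, np.ndarray]:
    payload = json.loads(Path(path).read_text())
    return {cid: rle_to_mask(v["runs"], v["n"]) for cid, v in payload.items()}


def ground_truth_to_dict(truth) -> dict:
    """JSON-serializable ground truth (bout-level summaries, not per-sample)."""
    out = {}
    for eid, et in truth.electrodes.items():
        out[eid] = {
            "bands": [list(b) for b in et.bands],
            "speed_coupled": list(et.speed_coupled),
            "bouts": [
                [
                    {
                        "start_s": round(b.start_s, 6),
                        "end_s": round(b.end_s, 6),
                        "mean_freq_hz": round(b.mean_freq, 6),
                        "n_cycles": round(b.n_cycles, 6),
                    }
                    for b in band_bouts
                ]
                for band_bouts in et.bouts
            ],
            "epoch_freq": {
                f"{tid}:{ei}": round(f, 6) for (tid, ei), f in sorted(et.epoch_freq.items())
            },
        }
    return out


def write_cohort(cohort, outdir: str | Path) -> dict[str, Path]:
    """Write a synthetic cohort to disk in the package's on-disk formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for subject_id, rec in cohort.recordings.items():
        p = outdir / f"{subject_id}_signals.h5"
        write_recording_h5(rec, p)
        paths[f"signals_{subject_id}"] = p
    for subject_id, subj_trials in cohort.trials.items():
        p = outdir / f"{subject_id}_events.csv"
        write_events_csv(subj_trials, p)
        paths[f"events_{subject_id}"] = p
    p = outdir / "electrodes.tsv"
    write_electrodes_tsv(cohort.electrodes, p)
    paths["electrodes"] = p
    p = outdir / "ground_truth.json"
    p.write_text(json.dumps(ground_truth_to_dict(cohort.truth), indent=1, sort_keys=True))
    paths["ground_truth"] = p
    return paths
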