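"""Reading and writing the on-disk formats.

Waveforms travel either as two-column CSV/TSV files (``time_s,value``, one
file per channel) or in a simple HDF5 layout ``/subjects/<id>/{ppg,abp}``
with an ``fs`` attribute per dataset.  Demographics are a CSV with header
``subject_id,age,weight,height,gender``.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .synth import SynthCohort
from .types import WaveformRecording


def write_waveform_csv(path, rec: WaveformRecording, sep: str = ",") -> None:
    df = pd.DataFrame({"time_s": rec.times, "value": rec.samples})
    df.to_csv(path, index=False, sep=sep)


def read_waveform_csv(path, subject_id: str = "", channel: str = "ppg") -> WaveformRecording:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    if not {"time_s", "value"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns time_s,value")
    t = df["time_s"].to_numpy(float)
    if t.size < 2:
        raise ValueError(f"{path}: need at least two samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-4):
        raise ValueError(f"{path}: non-uniform sampling")
    return WaveformRecording(df["value"].to_numpy(float), 1.0 / dt[0], subject_id, channel, float(t[0]))


def write_cohort_hdf5(path, cohort: SynthCohort) -> None:
    with h5py.File(path, "w") as h5:
        grp = h5.create_group("subjects")
        for rec in cohort.recordings:
            g = grp.create_group(rec.ppg.subject_id)
            for ch, wf in (("ppg", rec.ppg), ("abp", rec.abp)):
                ds = g.create_dataset(ch, data=wf.samples, compression="gzip")
                ds.attrs["fs"] = wf.fs


def read_subjects_hdf5(path) -> dict[str, dict[str, WaveformRecording]]:
    out: dict[str, dict[str, WaveformRecording]] = {}
    with h5py.File(path, "r") as h5:
        for sid, g in h5["subjects"].items():
            out[sid] = {
                ch: WaveformRecording(g[ch][...], float(g[ch].attrs["fs"]), sid, ch)
                for ch in g
            }
    return out


def write_demographics_csv(path, cohort: SynthCohort) -> None:
    pd.DataFrame([r.demographics for r in cohort.recordings])[
        ["subject_id", "age", "weight", "height", "gender"]
    ].to_csv(path, index=False)


def read_demographics_csv(path) -> dict[str, dict]:
    df = pd.read_csv(path)
    required = {"subject_id", "age", "weight", "height", "gender"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: expected header {sorted(required)}")
    return {str(r["subject_id"]): r.drop("subject_id").to_dict() for _, r in df.iterrows()}


def write_cohort(outdir, cohort: SynthCohort) -> None:
    """HDF5 waveforms + demographics CSV + ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_cohort_hdf5(outdir / "waveforms.h5", cohort)
    write_demographics_csv(outdir / "demographics.csv", cohort)
    truth = {}
    for rec in cohort.recordings:
        truth[rec.ppg.subject_id] = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in rec.truth.items()
        }
    (outdir / "ground_truth.json").write_text(json.dumps(truth))


def write_feature_table(path, table: pd.DataFrame) -> None:
    """Wide CSV plus a JSON sidecar naming the columns."""
    path = Path(path)
    table.to_csv(path, index=False)
    sidecar = path.with_suffix(".schema.json")
    sidecar.write_text(json.dumps({"columns": list(table.columns)}, indent=2))
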