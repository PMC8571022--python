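"""File IO: BrainVision / EDF ingestion, BrainVision export, CSV/JSON
serialization of templates, parameters and transitions.

Reading goes through mne (which honours DataOrientation, IEEE_FLOAT_32 and
INT_16-with-resolution BrainVision variants, and EDF/EDF+); writing emits a
minimal but standard-conforming BrainVision triplet (.vhdr/.vmrk/.eeg,
multiplexed IEEE float 32), which mne round-trips.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import EEGRecording, MicrostateParameters, TemplateSet, TransitionTable
from .montage import channel_positions
from .simulate import GroundTruth

__all__ = [
    "write_brainvision",
    "read_recording",
    "write_ground_truth",
    "read_ground_truth",
    "write_templates",
    "read_templates",
    "parameters_to_frame",
    "transitions_to_frame",
]

_VHDR_TEMPLATE = """Brain Vision Data Exchange Header File Version 1.0
; Written by eegstates

[Common Infos]
Codepage=UTF-8
DataFile={stem}.eeg
MarkerFile={stem}.vmrk
DataFormat=BINARY
DataOrientation=MULTIPLEXED
NumberOfChannels={n_channels}
SamplingInterval={sampling_interval_us}

[Binary Infos]
BinaryFormat=IEEE_FLOAT_32

[Channel Infos]
; Ch<nr>=<name>,<ref>,<resolution in uV>,<unit>
{channel_lines}
"""

_VMRK_TEMPLATE = """Brain Vision Data Exchange Marker File, Version 1.0

[Common Infos]
Codepage=UTF-8
DataFile={stem}.eeg

[Marker Infos]
; Mk<nr>=<type>,<description>,<position>,<points>,<channel>
Mk1=New Segment,,1,1,0
"""


def write_brainvision(recording: EEGRecording, path: str | Path) -> Path:
    """Write a BrainVision triplet; ``path`` is the .vhdr path (or stem)."""
    path = Path(path)
    if path.suffix == ".vhdr":
        stem_path = path.with_suffix("")
    else:
        stem_path = path
    stem = stem_path.name
    stem_path.parent.mkdir(parents=True, exist_ok=True)
    channel_lines = "\n".join(
        f"Ch{i + 1}={name},,1,µV" for i, name in enumerate(recording.channel_names)
    )
    vhdr = _VHDR_TEMPLATE.format(
        stem=stem,
        n_channels=recording.n_channels,
        sampling_interval_us=int(round(1e6 / recording.sampling_rate)),
        channel_lines=channel_lines,
    )
    stem_path.with_suffix(".vhdr").write_text(vhdr, encoding="utf-8")
    stem_path.with_suffix(".vmrk").write_text(_VMRK_TEMPLATE.format(stem=stem), encoding="utf-8")
    recording.data.T.astype("<f4").tofile(stem_path.with_suffix(".eeg"))
    return stem_path.with_suffix(".vhdr")


def read_recording(path: str | Path) -> EEGRecording:
    """Read a BrainVision (.vhdr) or EDF (.edf) file into an EEGRecording.

    Channel positions are looked up in the extended 10/20 montage by name;
    channels with unknown names are rejected.
    """
    import mne

    path = Path(path)
    if path.suffix.lower() == ".vhdr":
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    elif path.suffix.lower() in (".edf", ".bdf"):
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    else:
        raise ValueError(f"unsupported format: {path.suffix}")
    data_uv = raw.get_data() * 1e6  # mne loads volts
    names = list(raw.ch_names)
    return EEGRecording(
        data=data_uv,
        sampling_rate=float(raw.info["sfreq"]),
        channel_names=names,
        channel_positions=channel_positions(names),
        provenance=[f"read({path.name})"],
    )


def write_ground_truth(gt: GroundTruth, directory: str | Path, stem: str) -> None:
    """Ground truth as JSON (templates + labels) and a CSV segment table."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    payload = {
        "templates": gt.templates.tolist(),
        "label_sequence": gt.label_sequence.tolist(),
    }
    (directory / f"{stem}_ground_truth.json").write_text(json.dumps(payload))
    pd.DataFrame(
        gt.segment_table, columns=["state", "start_sample", "end_sample", "polarity"]
    ).to_csv(directory / f"{stem}_segments.csv", index=False)


def read_ground_truth(directory: str | Path, stem: str) -> GroundTruth:
    directory = Path(directory)
    payload = json.loads((directory / f"{stem}_ground_truth.json").read_text())
    seg = pd.read_csv(directory / f"{stem}_segments.csv")
    return GroundTruth(
        templates=np.array(payload["templates"]),
        label_sequence=np.array(payload["label_sequence"], dtype=np.int64),
        segment_table=[tuple(int(v) for v in row) for row in seg.itertuples(index=False)],
    )


def write_templates(templates: TemplateSet, path: str | Path) -> None:
    """Templates as CSV (channels x classes) plus a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = templates.labels or [f"class{i}" for i in range(templates.n_classes)]
    df = pd.DataFrame(templates.maps.T, columns=cols)
    if templates.channel_names:
        df.insert(0, "channel", templates.channel_names)
    df.to_csv(path, index=False)
    sidecar = {
        "labels": templates.labels,
        "gev_total": templates.gev_total,
        "gev_per_class": None
        if templates.gev_per_class is None
        else list(map(float, templates.gev_per_class)),
        "source": templates.source,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_templates(path: str | Path) -> TemplateSet:
    path = Path(path)
    df = pd.read_csv(path)
    chans = df["channel"].tolist() if "channel" in df.columns else []
    maps = df.drop(columns=["channel"], errors="ignore").to_numpy().T
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return TemplateSet(
        maps=maps,
        channel_names=chans,
        labels=sidecar.get("labels"),
        gev_total=sidecar.get("gev_total"),
        gev_per_class=None
        if sidecar.get("gev_per_class") is None
        else np.array(sidecar["gev_per_class"]),
        source=sidecar.get("source", ""),
    )


def parameters_to_frame(
    params_by_subject: dict[str, MicrostateParameters], class_names=("A", "B", "C", "D")
) -> pd.DataFrame:
    """Tidy per-subject x class parameter table (one row per subject-class)."""
    rows = []
    for sid, p in params_by_subject.items():
        for ci, cname in enumerate(class_names[: len(p.duration_ms)]):
            rows.append(
                {
                    "subject_id": sid,
                    "class": cname,
                    "duration_ms": p.duration_ms[ci],
                    "occurrence_per_s": p.occurrence_per_s[ci],
                    "coverage_pct": p.coverage_pct[ci],
                    "gev": None if p.gev_per_class is None else p.gev_per_class[ci],
                }
            )
    return pd.DataFrame(rows)


def transitions_to_frame(
    tables_by_subject: dict[str, TransitionTable], class_names=("A", "B", "C", "D")
) -> pd.DataFrame:
    """Tidy subject x ordered-pair observed/expected percentages."""
    rows = []
    for sid, t in tables_by_subject.items():
        K = t.n_classes
        for i in range(K):
            for j in range(K):
                if i == j:
                    continue
                rows.append(
                    {
                        "subject_id": sid,
                        "from": class_names[i],
                        "to": class_names[j],
                        "observed_pct": t.observed_pct[i, j],
                        "expected_pct": t.expected_pct[i, j],
                    }
                )
    return pd.DataFrame(rows)
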