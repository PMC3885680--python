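"""Plain-text I/O: delimited signal matrices with JSON headers, TSV event
and trial tables, and JSON configs/reports."""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import EventSet, Recording, TrialTable

__all__ = ["write_recording", "read_recording", "write_trial_table",
           "read_trial_table", "write_events", "read_events"]


def write_recording(recording: Recording, prefix: str | Path) -> None:
    """Write ``<prefix>.tsv`` (samples x channels, tab-delimited) and
    ``<prefix>.json`` (fs, labels, units, reference)."""
    prefix = Path(prefix)
    header = {"fs": recording.fs, "labels": list(recording.labels),
              "units": "uV", "reference": recording.reference}
    prefix.with_suffix(".json").write_text(json.dumps(header, indent=1))
    df = pd.DataFrame(recording.samples.T, columns=recording.labels)
    df.to_csv(prefix.with_suffix(".tsv"), sep="\t", index=False,
              float_format="%.6g")


def read_recording(prefix: str | Path) -> Recording:
    prefix = Path(prefix)
    header = json.loads(prefix.with_suffix(".json").read_text())
    df = pd.read_csv(prefix.with_suffix(".tsv"), sep="\t")
    if list(df.columns) != list(header["labels"]):
        raise ValueError("matrix columns do not match header labels")
    return Recording(df.to_numpy().T, float(header["fs"]),
                     list(header["labels"]),
                     header.get("reference", "original"))


def write_trial_table(table: TrialTable, path: str | Path) -> None:
    df = pd.DataFrame({
        "blank_onset_s": table.blank_onset_s,
        "fixation_onset_s": table.fixation_onset_s,
        "cue_onset_s": table.cue_onset_s,
        "cue_duration_s": table.cue_duration_s,
        "finger": table.finger,
    })
    df.to_csv(path, sep="\t", index=False)


def read_trial_table(path: str | Path) -> TrialTable:
    df = pd.read_csv(path, sep="\t")
    return TrialTable(df["blank_onset_s"].to_numpy(),
                      df["fixation_onset_s"].to_numpy(),
                      df["cue_onset_s"].to_numpy(),
                      df["cue_duration_s"].to_numpy(),
                      df["finger"].to_numpy(dtype=object))


def write_events(events: EventSet, path: str | Path) -> None:
    df = pd.DataFrame({"onset_s": events.times_s, "finger": events.fingers,
                       "trial": events.trials,
                       "amplitude": events.amplitudes})
    with open(path, "w") as fh:
        fh.write(f"# provenance: {events.provenance}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_events(path: str | Path) -> EventSet:
    provenance = "bipolar"
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# provenance:"):
            provenance = first.split(":", 1)[1].strip()
            df = pd.read_csv(fh, sep="\t")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t")
    return EventSet(df["onset_s"].to_numpy(),
                    df["finger"].to_numpy(dtype=object),
                    df["trial"].to_numpy(), df["amplitude"].to_numpy(),
                    provenance=provenance)
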