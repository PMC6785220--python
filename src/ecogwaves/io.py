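"""Dataset loading: EDF signals + electrode and event tables."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .edf import read_edf

ELECTRODE_COLUMNS = ("name", "x", "y", "z", "region", "stim_response")
EVENT_COLUMNS = ("onset", "duration", "hand", "orientation", "session")


class SchemaError(ValueError):
    """A required table column is missing or inconsistent."""


@dataclass
class Recording:
    data: np.ndarray  # (n_channels, n_samples)
    sample_rate: float
    labels: list[str]
    electrodes: pd.DataFrame  # indexed by electrode name
    events: pd.DataFrame

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.sample_rate

    def epochs(self, pre: float = 1.0, post: float = 2.0) -> tuple[np.ndarray, pd.DataFrame]:
        """Cut (n_trials, n_channels, n_samples) epochs around event onsets.

        ``pre`` seconds before onset through ``post`` seconds after; trials
        that do not fit inside the recording are dropped.
        """
        n_pre = int(round(pre * self.sample_rate))
        n_post = int(round(post * self.sample_rate))
        segs, kept = [], []
        for i, row in self.events.iterrows():
            s = int(round(row["onset"] * self.sample_rate))
            if s - n_pre < 0 or s + n_post > self.data.shape[1]:
                continue
            segs.append(self.data[:, s - n_pre : s + n_post])
            kept.append(i)
        return np.array(segs), self.events.loc[kept].reset_index(drop=True)


def read_recording(signal_path, electrodes_path, events_path) -> Recording:
    """Load and cross-validate the three dataset files."""
    edf = read_edf(signal_path)
    electrodes = pd.read_csv(electrodes_path, sep="\t")
    missing = [c for c in ELECTRODE_COLUMNS if c not in electrodes.columns]
    if missing:
        raise SchemaError(f"electrodes table missing columns: {missing}")
    events = pd.read_csv(events_path, sep="\t")
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise SchemaError(f"events table missing columns: {missing}")

    tab_names = list(electrodes["name"].astype(str))
    if tab_names != list(edf.labels):
        offenders = sorted(set(tab_names).symmetric_difference(edf.labels))
        raise SchemaError(f"channel names differ between EDF and electrode table: {offenders}")

    duration = edf.signals.shape[1] / edf.sample_rate
    bad = events[(events["onset"] < 0) | (events["onset"] + events["duration"] > duration)]
    if len(bad):
        raise SchemaError(
            f"{len(bad)} event(s) fall outside the recording (duration {duration:.2f} s)"
        )
    # snap onsets to the sample grid
    events = events.copy()
    events["onset"] = np.round(events["onset"] * edf.sample_rate) / edf.sample_rate
    return Recording(
        data=edf.signals,
        sample_rate=edf.sample_rate,
        labels=list(edf.labels),
        electrodes=electrodes.set_index("name"),
        events=events,
    )
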