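"""In-memory containers: multichannel recordings and condition manifests."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

TASKS = ("LA", "BA", "BUA")
BACKGROUNDS = ("PK", "MT", "HW", "FT")


@dataclass
class EEGRecording:
    """A channels x samples recording in microvolts.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    labels : list of str
        Unique channel labels (10-20 names plus auxiliaries).
    reference : str or None
        Label of the current reference electrode, if any.
    exclusions : set
        Channel labels or ``(start_s, stop_s)`` intervals flagged as bad by
        an external (manual) inspection step.
    """

    data: np.ndarray
    fs: float
    labels: list
    reference: Optional[str] = None
    exclusions: set = field(default_factory=set)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels/data channel count mismatch")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.labels.index(label)]

    def copy(self, **changes) -> "EEGRecording":
        out = replace(self, **changes)
        if "data" not in changes:
            out.data = self.data.copy()
        if "exclusions" not in changes:
            out.exclusions = set(self.exclusions)
        if "meta" not in changes:
            out.meta = dict(self.meta)
        return out


MANIFEST_COLUMNS = ("participant", "task", "background", "topic",
                    "start_s", "stop_s")


@dataclass
class ConditionManifest:
    """Ordered listening fragments of one (or more) recordings.

    Each row tags a time interval with (participant, task, background) and,
    for lecture fragments, the lecture topic the exam refers to.
    """

    fragments: pd.DataFrame

    def __post_init__(self):
        df = pd.DataFrame(self.fragments)
        missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"manifest missing columns: {missing}")
        bad_task = set(df["task"]) - set(TASKS)
        if bad_task:
            raise ValueError(f"unknown tasks: {bad_task}")
        bad_bg = set(df["background"]) - set(BACKGROUNDS)
        if bad_bg:
            raise ValueError(f"unknown backgrounds: {bad_bg}")
        la = df[df["task"] == "LA"]
        if la["topic"].isna().any():
            raise ValueError("LA fragments must carry a topic")
        if (df["stop_s"] <= df["start_s"]).any():
            raise ValueError("fragment stop must exceed start")
        # non-overlap per participant, fragments kept in time order
        for _, grp in df.groupby("participant"):
            g = grp.sort_values("start_s")
            if (g["start_s"].values[1:] < g["stop_s"].values[:-1]).any():
                raise ValueError("overlapping fragments in manifest")
        self.fragments = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.fragments)

    def for_participant(self, participant) -> pd.DataFrame:
        return self.fragments[self.fragments["participant"] == participant]

    def to_csv(self, path) -> None:
        self.fragments.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ConditionManifest":
        return cls(pd.read_csv(path))
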