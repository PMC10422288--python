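"""Core in-memory containers shared across the pipeline.

An :class:`EEGRecording` is one run (one temperature–humidity setting for
one participant): a ``channels × samples`` float array in microvolts with
10–20 channel names.  An :class:`SWBTrace` is the run's sequence of verbal
subjective well-being reports, an integer score 1–10 at fixed intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

#: 14-channel layout of the consumer headset emulated here (10–20 names).
HEADSET_CHANNELS: tuple[str, ...] = (
    "AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
    "O2", "P8", "T8", "FC6", "F4", "F8", "AF4",
)

#: Left/right anterior-frontal pair used for the asymmetry measure.
FAA_CHANNELS: tuple[str, str] = ("AF3", "AF4")


@dataclass
class SWBTrace:
    """Subjective well-being reports for one run.

    Parameters
    ----------
    report_times : array of float
        Times in seconds at which scores were given; strictly increasing,
        aligned to multiples of the report period.
    scores : array of int
        Integer scores, 1 (worst) to 10 (best), one per report time.
    participant_id, run_id : str
        Identifiers carried through to output tables.
    """

    report_times: np.ndarray
    scores: np.ndarray
    participant_id: str = "P000"
    run_id: str = "R00"

    def __post_init__(self) -> None:
        self.report_times = np.asarray(self.report_times, dtype=float)
        self.scores = np.asarray(self.scores, dtype=int)
        if self.report_times.ndim != 1 or self.scores.shape != self.report_times.shape:
            raise ValueError("report_times and scores must be 1-D and equal length")
        if len(self.report_times) and np.any(np.diff(self.report_times) <= 0):
            raise ValueError("report_times must be strictly increasing")
        if len(self.scores) and (self.scores.min() < 1 or self.scores.max() > 10):
            raise ValueError("SWB scores must lie in [1, 10]")

    def __len__(self) -> int:
        return len(self.report_times)

    @property
    def period_s(self) -> float:
        """Report period inferred from the time grid (requires uniform spacing)."""
        if len(self) < 2:
            raise ValueError("cannot infer period from fewer than two reports")
        diffs = np.diff(self.report_times)
        if not np.allclose(diffs, diffs[0]):
            raise ValueError("report times are not uniformly spaced")
        return float(diffs[0])


@dataclass
class EEGRecording:
    """One run of multichannel EEG in microvolts.

    ``data`` has shape ``(n_channels, n_samples)``; row *i* corresponds to
    ``channel_names[i]``.
    """

    channel_names: list[str]
    data: np.ndarray
    fs: float
    participant_id: str = "P000"
    run_id: str = "R00"
    handedness: str = "right"

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{self.data.shape[0]} data rows for {len(self.channel_names)} channel names"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("duplicate channel names")
        if self.handedness not in ("left", "right"):
            raise ValueError("handedness must be 'left' or 'right'")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, name: str) -> np.ndarray:
        """Return the sample series of a single named channel."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not present") from None
        return self.data[idx]

    def pick(self, names: Sequence[str]) -> "EEGRecording":
        """Sub-recording restricted to ``names`` (in the given order)."""
        idx = [self.channel_names.index(n) for n in names]
        return replace(self, channel_names=list(names), data=self.data[idx])

    def drop(self, names: Sequence[str]) -> "EEGRecording":
        keep = [n for n in self.channel_names if n not in set(names)]
        return self.pick(keep)
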