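"""Loading and gating of EEG runs.

The fixed stage order is: load (EEG channels only) → downsample to 128 Hz →
minimum-duration gate (≥ 15 s) → linear detrend → bad-channel detection →
AF3/AF4 guard.  A failed gate short-circuits: the run is excluded with a
machine-readable reason rather than partially processed.

Bad channels are detected from the z-score, across channels, of the average
log spectral power between 1 Hz and min(125 Hz, Nyquist): any channel more
than 3 standard deviations from the channel mean is flagged, flagged
channels are removed, and the detection is run a second time so that a
moderate outlier masked by an extreme one is still caught.  If either
anterior-frontal channel (AF3/AF4) is flagged the run is unusable for the
asymmetry measure and is dropped entirely.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import scipy.signal
from sklearn.base import BaseEstimator

from .edf import read_header_ids
from .types import EEGRecording, FAA_CHANNELS, HEADSET_CHANNELS

__all__ = [
    "PreprocessReport",
    "GateError",
    "load_recording",
    "downsample",
    "check_min_duration",
    "detrend",
    "detect_bad_channels",
    "assert_faa_channels",
    "Preprocessor",
]

#: Labels accepted as EEG after normalization (10–20 names of the headset).
KNOWN_EEG_LABELS = set(HEADSET_CHANNELS)


class GateError(RuntimeError):
    """A preprocessing gate rejected the run."""

    def __init__(self, reason: str, message: str):
        super().__init__(message)
        self.reason = reason


@dataclass
class PreprocessReport:
    """Outcome of preprocessing one run."""

    participant_id: str
    run_id: str
    kept_channels: list[str]
    bad_channels: list[str]
    original_fs: float
    final_fs: float
    duration_s: float
    passed: bool
    failure_reason: str | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def normalize_channel_name(raw: str) -> str:
    """Strip vendor decoration from a channel label (``'EEG AF3-REF'`` → ``'AF3'``)."""
    name = raw.strip().upper()
    name = re.sub(r"^EEG[ .:_-]*", "", name)
    name = re.sub(r"[-.](REF|LE|A1|A2|AVG)$", "", name)
    return name.strip()


def load_recording(
    path: str | Path, channel_aliases: dict[str, str] | None = None
) -> EEGRecording:
    """Read an EDF file, keeping only EEG channels, in microvolts.

    Channel labels are normalized to plain 10–20 names (optionally through
    ``channel_aliases``, raw label → canonical name); channels that do not
    normalize to a known EEG label (markers, gyros, quality flags) are
    dropped.  Participant/run identity and handedness are recovered from the
    EDF patient/recording header fields when present.
    """
    import mne

    path = Path(path)
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:
        raise ValueError(f"unreadable EDF file {path}: {exc}") from exc

    aliases = channel_aliases or {}
    keep_idx, keep_names = [], []
    for i, ch in enumerate(raw.ch_names):
        name = aliases.get(ch, normalize_channel_name(ch))
        if name in KNOWN_EEG_LABELS:
            keep_idx.append(i)
            keep_names.append(name)
    if not keep_idx:
        raise ValueError(f"{path}: no EEG channels found among {raw.ch_names}")

    data_uv = raw.get_data(picks=keep_idx) * 1e6

    patient, recording = read_header_ids(path)
    tokens = patient.split()
    participant_id = tokens[0] if tokens else path.stem
    handedness = "right"
    for tok in tokens[1:]:
        if tok.startswith("handedness="):
            handedness = tok.split("=", 1)[1]
    run_id = recording.split()[0] if recording.strip() else "R00"

    return EEGRecording(keep_names, data_uv, float(raw.info["sfreq"]),
                        participant_id, run_id, handedness)


def downsample(rec: EEGRecording, target_fs: int = 128) -> EEGRecording:
    """Resample to ``target_fs`` (anti-alias + decimate by 2 for 256 Hz input)."""
    if abs(rec.fs - target_fs) < 1e-9:
        return rec
    if abs(rec.fs - 2 * target_fs) > 1e-9:
        raise ValueError(f"unsupported sampling rate {rec.fs} (expected {target_fs} or "
                         f"{2 * target_fs})")
    # zero-phase Butterworth low-pass at 0.9× the target Nyquist, then take
    # every second sample
    sos = scipy.signal.butter(8, 0.45 * target_fs, btype="low", fs=rec.fs, output="sos")
    filtered = scipy.signal.sosfiltfilt(sos, rec.data, axis=1)
    from dataclasses import replace

    return replace(rec, data=filtered[:, ::2], fs=float(target_fs))


def check_min_duration(rec: EEGRecording, min_s: float = 15.0) -> bool:
    """True iff the run lasts at least ``min_s`` seconds (inclusive)."""
    return rec.duration_s >= min_s


def detrend(rec: EEGRecording) -> EEGRecording:
    """Remove each channel's least-squares linear trend."""
    from dataclasses import replace

    return replace(rec, data=scipy.signal.detrend(rec.data, axis=1, type="linear"))


def _log_power_feature(data: np.ndarray, fs: float, nperseg: int = 256) -> np.ndarray:
    """Per-channel mean over 1→min(125, Nyquist) Hz of log Welch PSD."""
    nperseg = min(nperseg, data.shape[1])
    f, psd = scipy.signal.welch(data, fs=fs, window="hann", nperseg=nperseg, axis=1)
    mask = (f >= 1.0) & (f <= min(125.0, fs / 2.0))
    if not mask.any():
        raise ValueError("no frequency bins in the 1 Hz–Nyquist range")
    return np.mean(np.log(np.maximum(psd[:, mask], 1e-300)), axis=1)


def detect_bad_channels(
    rec: EEGRecording, z_thresh: float = 3.0, n_passes: int = 2
) -> set[str]:
    """Flag channels whose average log power is a > ``z_thresh``-SD outlier.

    Run ``n_passes`` times, removing flagged channels between passes; the
    union of all flags is returned.  Requires at least 4 channels at the
    start of each pass (the z-score is meaningless below that).
    """
    current = list(rec.channel_names)
    bad: set[str] = set()
    for _ in range(n_passes):
        if len(current) < 4:
            raise ValueError("fewer than 4 channels remaining for bad-channel detection")
        feats = _log_power_feature(rec.pick(current).data, rec.fs)
        sd = feats.std()
        if sd == 0:
            break
        z = (feats - feats.mean()) / sd
        flagged = {name for name, zi in zip(current, z) if abs(zi) > z_thresh}
        if not flagged:
            break
        bad |= flagged
        current = [c for c in current if c not in flagged]
    return bad


def assert_faa_channels(
    bad: set[str], guard: tuple[str, str] = FAA_CHANNELS
) -> bool:
    """True iff neither asymmetry channel (AF3/AF4) was flagged bad."""
    return not (set(guard) & set(bad))


class Preprocessor(BaseEstimator):
    """Stateless transformer applying the full gating chain to one recording.

    Parameters
    ----------
    target_fs : int
        Analysis sampling rate; 256 Hz input is anti-alias filtered and
        decimated, 128 Hz passes through.
    min_duration_s : float
        Runs shorter than this are excluded (reason ``too_short``).
    z_thresh, n_passes : float, int
        Bad-channel detection threshold (in SDs of the cross-channel average
        log-power distribution) and number of detection passes.

    After :meth:`process` (or :meth:`transform`) the report of the most
    recent run is available as ``report_``.
    """

    def __init__(
        self,
        target_fs: int = 128,
        min_duration_s: float = 15.0,
        z_thresh: float = 3.0,
        n_passes: int = 2,
        guard_channels: tuple[str, str] = FAA_CHANNELS,
    ):
        self.target_fs = target_fs
        self.min_duration_s = min_duration_s
        self.z_thresh = z_thresh
        self.n_passes = n_passes
        self.guard_channels = guard_channels

    def fit(self, X=None, y=None):  # stateless; present for sklearn composition
        return self

    def process(self, rec: EEGRecording) -> tuple[EEGRecording | None, PreprocessReport]:
        """Run the chain; on gate failure return ``(None, report)``."""
        original_fs = rec.fs
        rec = downsample(rec, self.target_fs)

        def report(passed, reason=None, bad=(), kept=None):
            return PreprocessReport(
                participant_id=rec.participant_id,
                run_id=rec.run_id,
                kept_channels=list(kept if kept is not None else rec.channel_names),
                bad_channels=sorted(bad),
                original_fs=original_fs,
                final_fs=rec.fs,
                duration_s=rec.duration_s,
                passed=passed,
                failure_reason=reason,
            )

        if not check_min_duration(rec, self.min_duration_s):
            self.report_ = report(False, "too_short")
            return None, self.report_

        rec = detrend(rec)
        bad = detect_bad_channels(rec, self.z_thresh, self.n_passes)
        if not assert_faa_channels(bad, self.guard_channels):
            self.report_ = report(False, "faa_channel_bad", bad=bad)
            return None, self.report_

        cleaned = rec.drop(sorted(bad)) if bad else rec
        self.report_ = report(True, bad=bad, kept=cleaned.channel_names)
        return cleaned, self.report_

    def transform(self, rec: EEGRecording) -> EEGRecording:
        """Like :meth:`process` but raising :class:`GateError` on exclusion."""
        cleaned, rep = self.process(rec)
        if cleaned is None:
            raise GateError(rep.failure_reason,
                            f"run {rep.participant_id}/{rep.run_id} excluded: "
                            f"{rep.failure_reason}")
        return cleaned
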