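"""Interval segmentation and frontal alpha asymmetry (FAA) extraction.

FAA over a time interval is computed from the two anterior-frontal channels
as the mean over Hann-tapered, 50 %-overlapping windows of

    FAA = ln(powR) − ln(powL)

where powR/powL are the mean alpha-band (8–13 Hz) power densities of AF4
(right) and AF3 (left) in that window.  The sign is kept: positive FAA
means relatively more right-side alpha power.

Three interval schemes associate each FAA value with an integer SWB score:

* analysis 1 — one interval of one report period, centred on each report;
* analysis 2 — an interval of length L per report, either ending at the
  report time (``side='end'``, [t−L, t]) or centred on it
  (``side='center'``, [t−L/2, t+L/2]);
* analysis 3 — non-overlapping length-L intervals tiling the whole run from
  ``tile_start_s`` (default half a period), each labelled with the
  duration-weighted, integer-rounded average of the scores whose validity
  blocks [t−P/2, t+P/2) it overlaps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import get_window
from sklearn.base import BaseEstimator

from .types import EEGRecording, SWBTrace

__all__ = [
    "IntervalSpec",
    "Interval",
    "make_intervals",
    "weighted_swb",
    "band_power_density",
    "compute_faa",
    "extract_pairs",
    "FaaExtractor",
]

ALPHA_BAND = (8.0, 13.0)
#: 2 s windows at 128 Hz: 0.5 Hz resolution, ≥2 windows even in 5 s intervals.
DEFAULT_NPERSEG = 256

PAIR_COLUMNS = ["participant_id", "run_id", "analysis", "L", "side",
                "t_start", "t_end", "swb", "faa"]


@dataclass(frozen=True)
class IntervalSpec:
    """Segmentation scheme: which analysis, interval length and alignment."""

    analysis: int
    length_s: float | None = None
    side: str = "end"
    tile_start_s: float | None = None

    def __post_init__(self) -> None:
        if self.analysis not in (1, 2, 3):
            raise ValueError("analysis must be 1, 2 or 3")
        if self.analysis != 1:
            if self.length_s is None or self.length_s <= 0:
                raise ValueError("length_s must be positive for analyses 2 and 3")
        if self.analysis == 2 and self.side not in ("end", "center"):
            raise ValueError("side must be 'end' or 'center'")


@dataclass(frozen=True)
class Interval:
    t_start: float
    t_end: float
    swb: int


def round_half_away(x: float) -> int:
    """Round to nearest integer, ties away from zero (5.5 → 6)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def weighted_swb(t_start: float, t_end: float, trace: SWBTrace, period: float) -> int:
    """Duration-weighted integer SWB for an interval spanning several reports.

    Each report at time t is valid on the block [t − P/2, t + P/2); the
    interval's score is the overlap-second-weighted mean of the scores of
    the blocks it touches, rounded to the nearest integer.
    """
    half = period / 2.0
    weights, scores = [], []
    for t, s in zip(trace.report_times, trace.scores):
        w = min(t_end, t + half) - max(t_start, t - half)
        if w > 1e-12:
            weights.append(w)
            scores.append(s)
    if not weights:
        raise ValueError(
            f"interval [{t_start}, {t_end}] overlaps no SWB block")
    w = np.asarray(weights)
    return round_half_away(float(np.dot(w, scores) / w.sum()))


def make_intervals(
    spec: IntervalSpec, trace: SWBTrace, duration_s: float
) -> list[Interval]:
    """Build the FAA intervals of one run under ``spec``.

    Intervals extending beyond [0, ``duration_s``] are dropped.
    """
    if len(trace) == 0:
        raise ValueError("empty SWB trace")
    P = trace.period_s
    out: list[Interval] = []
    if spec.analysis == 1:
        # one report-period interval centred on each report
        for t, s in zip(trace.report_times, trace.scores):
            t0, t1 = t - P / 2.0, t + P / 2.0
            if t0 >= -1e-9 and t1 <= duration_s + 1e-9:
                out.append(Interval(t0, t1, int(s)))
    elif spec.analysis == 2:
        L = float(spec.length_s)
        for t, s in zip(trace.report_times, trace.scores):
            t0, t1 = (t - L, t) if spec.side == "end" else (t - L / 2.0, t + L / 2.0)
            if t0 >= -1e-9 and t1 <= duration_s + 1e-9:
                out.append(Interval(t0, t1, int(s)))
    else:
        L = float(spec.length_s)
        start = P / 2.0 if spec.tile_start_s is None else float(spec.tile_start_s)
        k = 0
        while start + (k + 1) * L <= duration_s + 1e-9:
            t0 = start + k * L
            out.append(Interval(t0, t0 + L, weighted_swb(t0, t0 + L, trace, P)))
            k += 1
    return out


def band_power_density(
    signal: np.ndarray,
    fs: float,
    band: tuple[float, float] = ALPHA_BAND,
    nperseg: int = DEFAULT_NPERSEG,
    noverlap: int | None = None,
) -> np.ndarray:
    """Per-window mean power density in ``band``, one value per window.

    The signal is split into Hann-tapered windows of ``nperseg`` samples at
    50 % overlap (the Welch segmentation, kept per-window rather than
    averaged); each window's one-sided periodogram density is averaged over
    the frequency bins with band[0] ≤ f ≤ band[1] inclusive.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1:
        raise ValueError("signal must be one-dimensional")
    if noverlap is None:
        noverlap = nperseg // 2
    if len(signal) < nperseg:
        raise ValueError(
            f"signal of {len(signal)} samples shorter than one {nperseg}-sample window")
    hop = nperseg - noverlap
    frames = sliding_window_view(signal, nperseg)[::hop]
    win = get_window("hann", nperseg)
    spec = np.fft.rfft(frames * win, axis=1)
    psd = (np.abs(spec) ** 2) / (fs * np.dot(win, win))
    psd[:, 1:] *= 2.0
    if nperseg % 2 == 0:
        psd[:, -1] /= 2.0
    freqs = np.fft.rfftfreq(nperseg, d=1.0 / fs)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    return psd[:, mask].mean(axis=1)


def compute_faa(
    af3_segment: np.ndarray,
    af4_segment: np.ndarray,
    fs: float,
    band: tuple[float, float] = ALPHA_BAND,
    nperseg: int = DEFAULT_NPERSEG,
    noverlap: int | None = None,
    log_mode: str = "log_mean",
) -> float:
    """FAA of one interval: mean log-power difference, right minus left.

    ``log_mode='log_mean'`` (default) averages the per-window log-power
    differences; ``'mean_log'`` averages the band powers over windows first
    and takes one log ratio.
    """
    if len(af3_segment) != len(af4_segment):
        raise ValueError("AF3 and AF4 segments must have equal length")
    pow_l = band_power_density(af3_segment, fs, band, nperseg, noverlap)
    pow_r = band_power_density(af4_segment, fs, band, nperseg, noverlap)
    if np.any(pow_l <= 0) or np.any(pow_r <= 0):
        raise ValueError("zero band power in a window (degenerate input)")
    if log_mode == "log_mean":
        return float(np.mean(np.log(pow_r) - np.log(pow_l)))
    if log_mode == "mean_log":
        return float(np.log(pow_r.mean()) - np.log(pow_l.mean()))
    raise ValueError("log_mode must be 'log_mean' or 'mean_log'")


def extract_pairs(
    rec: EEGRecording,
    trace: SWBTrace,
    spec: IntervalSpec,
    band: tuple[float, float] = ALPHA_BAND,
    nperseg: int = DEFAULT_NPERSEG,
    noverlap: int | None = None,
    log_mode: str = "log_mean",
) -> pd.DataFrame:
    """One (FAA, SWB) pair per interval of ``spec`` over a preprocessed run.

    Returns a DataFrame with columns ``participant_id, run_id, analysis, L,
    side, t_start, t_end, swb, faa``.
    """
    af3, af4 = rec.channel("AF3"), rec.channel("AF4")
    intervals = make_intervals(spec, trace, rec.duration_s)
    side = spec.side if spec.analysis == 2 else ("center" if spec.analysis == 1 else "")
    length = trace.period_s if spec.analysis == 1 else float(spec.length_s)
    rows = []
    for iv in intervals:
        i0 = int(round(iv.t_start * rec.fs))
        i1 = int(round(iv.t_end * rec.fs))
        faa = compute_faa(af3[i0:i1], af4[i0:i1], rec.fs, band, nperseg,
                          noverlap, log_mode)
        rows.append((rec.participant_id, rec.run_id, spec.analysis, length,
                     side, iv.t_start, iv.t_end, iv.swb, faa))
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


class FaaExtractor(BaseEstimator):
    """Transformer turning a (recording, trace) run into a (FAA, SWB) table.

    Thin estimator wrapper over :func:`extract_pairs` so interval scheme and
    spectral settings travel as sklearn-style parameters.
    """

    def __init__(
        self,
        analysis: int = 2,
        length_s: float | None = 10.0,
        side: str = "end",
        tile_start_s: float | None = None,
        band: tuple[float, float] = ALPHA_BAND,
        nperseg: int = DEFAULT_NPERSEG,
        noverlap: int | None = None,
        log_mode: str = "log_mean",
    ):
        self.analysis = analysis
        self.length_s = length_s
        self.side = side
        self.tile_start_s = tile_start_s
        self.band = band
        self.nperseg = nperseg
        self.noverlap = noverlap
        self.log_mode = log_mode

    @property
    def interval_spec(self) -> IntervalSpec:
        return IntervalSpec(self.analysis, self.length_s, self.side, self.tile_start_s)

    def fit(self, X=None, y=None):
        return self

    def transform(self, rec: EEGRecording, trace: SWBTrace) -> pd.DataFrame:
        return extract_pairs(rec, trace, self.interval_spec, self.band,
                             self.nperseg, self.noverlap, self.log_mode)
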