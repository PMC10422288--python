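"""Synthetic EEG/SWB session generator.

Emulates the study design the analysis assumes: five-minute runs of
14-channel EEG during which the participant reports an integer subjective
well-being (SWB) score every ``report_period_s`` seconds.  The ground truth
is planted in the anterior-frontal pair: AF3 carries an alpha-band sinusoid
of fixed amplitude ``A_L`` while AF4's amplitude ``A_R`` is modulated
block-by-block so that the log alpha-power difference satisfies

    2·ln(A_R / A_L) = a + b·SWB + ε,      ε ~ N(0, noise_sd²),

i.e. the frontal alpha asymmetry FAA = ln powR − ln powL equals
``a + b·SWB`` up to the planted noise (power scales with amplitude squared).
A score reported at time t is taken to hold on the block
``[t − P/2, t + P/2)`` where ``P`` is the report period; the first block's
amplitude is extended back to t = 0 so the signal is defined everywhere.

All other channels are broadband noise.  Optional impairments: channels in
``bad_channel_list`` get 10× noise amplitude (to exercise bad-channel
detection) and, if ``artifact_enabled``, a high-amplitude noise burst is
centred on every report time (to emulate movement while speaking).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .edf import write_edf
from .types import EEGRecording, HEADSET_CHANNELS, SWBTrace

__all__ = [
    "SessionConfig",
    "sample_swb_trajectory",
    "synthesize_recording",
    "generate_session",
    "write_session",
    "simulate_cohort",
]


@dataclass
class SessionConfig:
    """Parameters of one synthetic run (defaults mirror the study conditions).

    ``coupling_intercept``/``coupling_slope`` are the ``a``/``b`` of the
    planted linear FAA–SWB relation, in log-power units; ``noise_sd`` is the
    standard deviation of the per-block log-power jitter ε.  ``alpha_amp``
    (μV) is the AF3 alpha amplitude ``A_L``; ``broadband_noise_amp`` (μV)
    the white-noise standard deviation on every channel.
    """

    n_runs: int = 10
    run_duration_s: float = 300.0
    report_period_s: float = 30.0
    fs: int = 128
    coupling_intercept: float = 0.0
    coupling_slope: float = 0.1
    noise_sd: float = 0.5
    alpha_freq: float = 10.0
    alpha_amp: float = 20.0
    broadband_noise_amp: float = 5.0
    artifact_enabled: bool = False
    artifact_duration_s: float = 2.0
    artifact_amp: float = 200.0
    bad_channel_list: tuple[str, ...] = ()
    channel_names: tuple[str, ...] = HEADSET_CHANNELS
    # SWB trajectory knobs: mean-reverting integer walk concentrated on the
    # upper-middle of the scale, or a constant score.
    swb_mode: str = "walk"
    swb_constant: int = 7
    swb_center: float = 7.0
    swb_max_step: int = 2
    swb_reversion: float = 0.35
    swb_step_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.run_duration_s < 15:
            raise ValueError("run_duration_s must be at least 15 s")
        if self.fs not in (128, 256):
            raise ValueError("fs must be 128 or 256 Hz")
        n = self.run_duration_s / self.report_period_s
        if abs(n - round(n)) > 1e-9 or n < 1:
            raise ValueError("report_period_s must divide run_duration_s")
        if not (8.0 <= self.alpha_freq <= 13.0):
            raise ValueError("alpha_freq must lie in the alpha band [8, 13] Hz")
        if self.swb_mode not in ("walk", "constant"):
            raise ValueError("swb_mode must be 'walk' or 'constant'")
        missing = {"AF3", "AF4"} - set(self.channel_names)
        if missing:
            raise ValueError(f"channel_names must include AF3 and AF4 (missing {missing})")

    @property
    def n_reports(self) -> int:
        return int(round(self.run_duration_s / self.report_period_s))

    @property
    def report_times(self) -> np.ndarray:
        return self.report_period_s * np.arange(1, self.n_reports + 1)


def sample_swb_trajectory(
    config: SessionConfig,
    rng: np.random.Generator,
    participant_id: str = "P000",
    run_id: str = "R00",
) -> SWBTrace:
    """Draw one run's SWB reports.

    In ``walk`` mode scores follow a mean-reverting integer random walk:
    each report moves by at most ``swb_max_step`` from the previous one,
    drifting back toward ``swb_center`` so the marginal distribution
    concentrates on the upper-middle scores (the imbalance the SMOTE stage
    later corrects).  ``constant`` mode repeats ``swb_constant``.
    """
    n = config.n_reports
    if config.swb_mode == "constant":
        scores = np.full(n, int(config.swb_constant))
    else:
        scores = np.empty(n, dtype=int)
        s = int(np.clip(np.rint(config.swb_center + rng.normal(0.0, 1.2)), 1, 10))
        scores[0] = s
        for i in range(1, n):
            drift = config.swb_reversion * (config.swb_center - s)
            step = int(np.clip(np.rint(rng.normal(drift, config.swb_step_sd)),
                               -config.swb_max_step, config.swb_max_step))
            s = int(np.clip(s + step, 1, 10))
            scores[i] = s
    return SWBTrace(config.report_times, scores, participant_id, run_id)


def _block_slices(config: SessionConfig) -> list[tuple[int, int]]:
    """Sample index ranges of each SWB block; first block extended to 0."""
    half = config.report_period_s / 2.0
    n_samp = int(round(config.run_duration_s * config.fs))
    out = []
    for k, t in enumerate(config.report_times):
        lo = 0 if k == 0 else int(round((t - half) * config.fs))
        hi = min(n_samp, int(round((t + half) * config.fs)))
        out.append((lo, hi))
    return out


def synthesize_recording(
    config: SessionConfig,
    trace: SWBTrace,
    rng: np.random.Generator,
    handedness: str = "right",
) -> EEGRecording:
    """Render one run of EEG consistent with ``trace`` under ``config``."""
    if len(trace) != config.n_reports or not np.allclose(
        trace.report_times, config.report_times
    ):
        raise ValueError("trace is not aligned to the config's report grid")

    n_samp = int(round(config.run_duration_s * config.fs))
    t = np.arange(n_samp) / config.fs
    carrier = np.sin(2 * np.pi * config.alpha_freq * t)

    eps = rng.normal(0.0, config.noise_sd, size=len(trace)) if config.noise_sd > 0 \
        else np.zeros(len(trace))
    log_ratio = config.coupling_intercept + config.coupling_slope * trace.scores + eps
    env = np.empty(n_samp)
    for (lo, hi), lr in zip(_block_slices(config), log_ratio):
        env[lo:hi] = config.alpha_amp * np.exp(lr / 2.0)

    names = list(config.channel_names)
    data = np.empty((len(names), n_samp))
    for i, name in enumerate(names):
        amp = config.broadband_noise_amp * (10.0 if name in config.bad_channel_list else 1.0)
        row = rng.normal(0.0, amp, size=n_samp) if amp > 0 else np.zeros(n_samp)
        if name == "AF3":
            row += config.alpha_amp * carrier
        elif name == "AF4":
            row += env * carrier
        data[i] = row

    if config.artifact_enabled:
        half = config.artifact_duration_s / 2.0
        for tr in trace.report_times:
            lo = max(0, int(round((tr - half) * config.fs)))
            hi = min(n_samp, int(round((tr + half) * config.fs)))
            if hi > lo:
                data[:, lo:hi] += rng.normal(0.0, config.artifact_amp,
                                             size=(len(names), hi - lo))

    return EEGRecording(names, data, float(config.fs),
                        trace.participant_id, trace.run_id, handedness)


def generate_session(
    config: SessionConfig,
    seed: int | np.random.SeedSequence | None = None,
    participant_id: str = "P000",
    run_id: str = "R00",
    handedness: str = "right",
) -> tuple[EEGRecording, SWBTrace]:
    """Convenience: draw a trajectory and render the matching recording."""
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    trace = sample_swb_trajectory(config, rng, participant_id, run_id)
    rec = synthesize_recording(config, trace, rng, handedness)
    return rec, trace


def write_session(
    recording: EEGRecording, trace: SWBTrace, out_dir: str | Path
) -> tuple[Path, Path]:
    """Write one session to disk: EDF for the EEG, CSV for the SWB trace."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = f"{recording.participant_id}_{recording.run_id}"
    edf_path = write_edf(
        out_dir / f"{stem}.edf",
        recording.data,
        int(recording.fs),
        recording.channel_names,
        patient_id=f"{recording.participant_id} handedness={recording.handedness}",
        recording_id=recording.run_id,
    )
    csv_path = out_dir / f"{stem}_swb.csv"
    pd.DataFrame(
        {
            "participant_id": recording.participant_id,
            "run_id": recording.run_id,
            "time_s": trace.report_times,
            "swb": trace.scores,
        }
    ).to_csv(csv_path, index=False)
    return edf_path, csv_path


def simulate_cohort(
    out_dir: str | Path,
    n_participants: int,
    config: SessionConfig | None = None,
    seed: int = 0,
    n_left_handed: int | None = None,
) -> Path:
    """Write a whole cohort to ``out_dir`` and return the manifest path.

    One master seed spawns independent substreams per (participant, run) so
    any single run is reproducible in isolation.  ``n_left_handed``
    participants (default: 2 in 30, rounded) are drawn at random and marked
    left-handed.
    """
    config = config or SessionConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    master = np.random.SeedSequence(seed)
    if n_left_handed is None:
        n_left_handed = int(round(2 / 30 * n_participants))
    pick_rng = np.random.default_rng(master.spawn(1)[0])
    left = set(pick_rng.choice(n_participants, size=n_left_handed, replace=False).tolist())

    participants = []
    p_seeds = master.spawn(n_participants)
    for p in range(n_participants):
        pid = f"P{p + 1:03d}"
        hand = "left" if p in left else "right"
        runs = []
        for r, r_seed in enumerate(p_seeds[p].spawn(config.n_runs)):
            run_id = f"R{r + 1:02d}"
            rec, trace = generate_session(config, r_seed, pid, run_id, hand)
            edf_path, csv_path = write_session(rec, trace, out_dir)
            runs.append({"edf": edf_path.name, "swb": csv_path.name})
        participants.append({"id": pid, "handedness": hand, "runs": runs})

    manifest = {
        "seed": seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "participants": participants,
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest_path
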