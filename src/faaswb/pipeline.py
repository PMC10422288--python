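"""Cohort-level orchestration: files → preprocessing → FAA pairs → inference.

A :class:`RunManifest` lists each participant's runs (EDF + SWB trace).
:func:`run_experiment` executes the full chain for every cell of an
interval-scheme grid and writes one summary row per cell (interval length,
sidedness, t, p, df, one-sided CI bound, mean pair count), plus
per-participant results, per-run preprocessing reports and a
machine-readable exclusion log.

Everything is deterministic under the manifest seed: one master seed
spawns per-cell, then per-participant substreams for the SMOTE repeats.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .faa import IntervalSpec, extract_pairs
from .preprocess import Preprocessor, load_recording
from .stats import (GroupResult, ParticipantResult, group_test,
                    participant_slope)
from .synth import SessionConfig, generate_session
from .types import EEGRecording, SWBTrace

__all__ = [
    "RunManifest",
    "run_experiment",
    "subsample_sensitivity",
    "run_synthetic_experiment",
    "analysis1_grid",
    "analysis2_grid",
    "analysis3_grid",
]

SUMMARY_COLUMNS = ["analysis", "L", "side", "n_participants", "df", "t_stat",
                   "p_value", "ci_lower", "mean_pairs"]


def analysis1_grid() -> list[IntervalSpec]:
    return [IntervalSpec(1)]


def analysis2_grid(lengths=(5.0, 10.0, 15.0), sides=("end", "center")) -> list[IntervalSpec]:
    return [IntervalSpec(2, L, side) for side in sides for L in lengths]


def analysis3_grid(lengths=(5.0, 10.0) + tuple(15.0 * k for k in range(1, 11))
                   ) -> list[IntervalSpec]:
    return [IntervalSpec(3, L) for L in lengths]


@dataclass
class ParticipantEntry:
    id: str
    handedness: str
    runs: list[tuple[Path, Path]]  # (edf_path, swb_trace_path)


@dataclass
class RunManifest:
    participants: list[ParticipantEntry]
    seed: int = 0
    base_dir: Path = Path(".")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunManifest":
        path = Path(path)
        doc = json.loads(path.read_text())
        base = path.parent
        participants = [
            ParticipantEntry(
                id=p["id"],
                handedness=p.get("handedness", "right"),
                runs=[(base / r["edf"], base / r["swb"]) for r in p["runs"]],
            )
            for p in doc["participants"]
        ]
        if not participants:
            raise ValueError("manifest lists no participants")
        for p in participants:
            for edf, swb in p.runs:
                if not edf.exists() or not swb.exists():
                    raise FileNotFoundError(f"manifest references missing file: {edf} / {swb}")
        return cls(participants=participants, seed=int(doc.get("seed", 0)), base_dir=base)


def read_swb_trace(path: str | Path) -> SWBTrace:
    """Read a SWB trace CSV (``participant_id,run_id,time_s,swb``)."""
    df = pd.read_csv(path)
    return SWBTrace(
        df["time_s"].to_numpy(float),
        df["swb"].to_numpy(int),
        str(df["participant_id"].iloc[0]),
        str(df["run_id"].iloc[0]),
    )


def _stats_chain(
    pairs_by_participant: dict[str, pd.DataFrame],
    handedness: dict[str, str],
    seedseq: np.random.SeedSequence,
    smote_repeats: int = 10,
    k_neighbors: int = 5,
    alpha: float = 0.05,
    exclude_left_handed: bool = True,
) -> tuple[list[ParticipantResult], GroupResult | None]:
    """Per-participant slopes then group test; participant order is fixed."""
    pids = list(pairs_by_participant)
    results = []
    for pid, child in zip(pids, seedseq.spawn(len(pids))):
        df = pairs_by_participant[pid]
        res = participant_slope(
            df["faa"].to_numpy(), df["swb"].to_numpy(),
            n_repeats=smote_repeats, k_neighbors=k_neighbors,
            random_state=np.random.default_rng(child),
            participant_id=pid, handedness=handedness.get(pid, "right"),
        )
        results.append(res)
    try:
        group = group_test(results, alpha=alpha,
                           exclude_left_handed=exclude_left_handed)
    except ValueError:
        group = None
    return results, group


def _summary_row(spec: IntervalSpec, pairs_L: float | None,
                 group: GroupResult | None, n_results: int) -> dict:
    return {
        "analysis": spec.analysis,
        "L": pairs_L if pairs_L is not None else spec.length_s,
        "side": spec.side if spec.analysis == 2 else ("center" if spec.analysis == 1 else ""),
        "n_participants": group.n_participants if group else 0,
        "df": group.df if group else np.nan,
        "t_stat": group.t_stat if group else np.nan,
        "p_value": group.p_value if group else np.nan,
        "ci_lower": group.ci_lower if group else np.nan,
        "mean_pairs": group.mean_pairs_per_participant if group else np.nan,
    }


def run_experiment(
    manifest: RunManifest | str | Path,
    grid: list[IntervalSpec],
    out_dir: str | Path | None = None,
    seed: int | None = None,
    smote_repeats: int = 10,
    k_neighbors: int = 5,
    alpha: float = 0.05,
    exclude_left_handed: bool = True,
    preprocessor: Preprocessor | None = None,
    log_mode: str = "log_mean",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Execute the full analysis over a cohort for every grid cell.

    Returns ``(summary, per_participant)`` DataFrames; if ``out_dir`` is
    given also writes ``summary.csv``, ``participants.csv``,
    ``preprocess_reports.jsonl`` and ``exclusions.jsonl`` there.
    """
    if not grid:
        raise ValueError("grid must contain at least one interval scheme")
    if not isinstance(manifest, RunManifest):
        manifest = RunManifest.from_json(manifest)
    if seed is None:
        seed = manifest.seed
    preprocessor = preprocessor or Preprocessor()

    # Stage 1: load + preprocess every run once (grid-independent).
    reports, exclusions = [], []
    runs_by_participant: dict[str, list[tuple[EEGRecording, SWBTrace]]] = {}
    handedness: dict[str, str] = {}
    for entry in manifest.participants:
        handedness[entry.id] = entry.handedness
        kept = []
        for edf_path, swb_path in entry.runs:
            rec = load_recording(edf_path)
            rec.participant_id, rec.handedness = entry.id, entry.handedness
            trace = read_swb_trace(swb_path)
            cleaned, report = preprocessor.process(rec)
            reports.append(report)
            if cleaned is None:
                exclusions.append({"stage": "preprocess", "participant_id": entry.id,
                                   "run_id": rec.run_id, "reason": report.failure_reason})
            else:
                kept.append((cleaned, trace))
        runs_by_participant[entry.id] = kept

    # Stage 2: per grid cell, extract pairs and run the stats chain.
    master = np.random.SeedSequence(seed)
    cell_seeds = master.spawn(len(grid))
    summary_rows, participant_rows = [], []
    for spec, cell_ss in zip(grid, cell_seeds):
        pairs_by_participant = {}
        for pid, runs in runs_by_participant.items():
            frames = [extract_pairs(rec, trace, spec, log_mode=log_mode)
                      for rec, trace in runs]
            frames = [f for f in frames if len(f)]
            if frames:
                pairs_by_participant[pid] = pd.concat(frames, ignore_index=True)
            else:
                exclusions.append({"stage": "extract", "participant_id": pid,
                                   "run_id": None, "reason": "no_intervals"})
        results, group = _stats_chain(
            pairs_by_participant, handedness, cell_ss, smote_repeats,
            k_neighbors, alpha, exclude_left_handed)
        pairs_L = None
        for df in pairs_by_participant.values():
            if len(df):
                pairs_L = float(df["L"].iloc[0])
                break
        summary_rows.append(_summary_row(spec, pairs_L, group, len(results)))
        for res in results:
            if res.excluded:
                exclusions.append({"stage": "stats", "participant_id": res.participant_id,
                                   "run_id": None, "reason": res.exclusion_reason})
            elif exclude_left_handed and res.handedness == "left":
                exclusions.append({"stage": "stats", "participant_id": res.participant_id,
                                   "run_id": None, "reason": "left_handed"})
            participant_rows.append({
                "analysis": spec.analysis, "L": pairs_L, "side": spec.side,
                "participant_id": res.participant_id, "n_pairs": res.n_pairs_used,
                "slope_mean": res.slope_mean, "intercept_mean": res.intercept_mean,
                "excluded": res.excluded, "reason": res.exclusion_reason or "",
            })

    summary = pd.DataFrame(summary_rows, columns=SUMMARY_COLUMNS)
    per_participant = pd.DataFrame(participant_rows)
    if not summary["n_participants"].gt(0).any():
        raise ValueError("empty cohort after exclusions in every grid cell")

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        summary.to_csv(out_dir / "summary.csv", index=False)
        per_participant.to_csv(out_dir / "participants.csv", index=False)
        with open(out_dir / "preprocess_reports.jsonl", "w") as fh:
            for rep in reports:
                fh.write(rep.to_json() + "\n")
        with open(out_dir / "exclusions.jsonl", "w") as fh:
            for exc in exclusions:
                fh.write(json.dumps(exc) + "\n")
    return summary, per_participant


def subsample_sensitivity(
    pairs_by_participant: dict[str, pd.DataFrame],
    handedness: dict[str, str],
    pair_cap: int | None = None,
    df_cap: int | None = None,
    seedseq: np.random.SeedSequence | int = 0,
    subsample_seed: int = 12345,
    smote_repeats: int = 10,
    k_neighbors: int = 5,
    alpha: float = 0.05,
    exclude_left_handed: bool = True,
) -> GroupResult:
    """Re-run the stats chain after capping pairs per participant and/or df.

    ``pair_cap`` caps every participant's pairs by random subsampling
    without replacement; ``df_cap`` caps the cohort to ``df_cap + 1``
    randomly chosen participants.  A cap equal to the available count is a
    no-op (the same pairs, in order, feed the same seeded stats chain), so
    results then match the uncapped experiment exactly.
    """
    if pair_cap is not None and pair_cap <= 0:
        raise ValueError("pair_cap must be positive")
    if df_cap is not None and df_cap < 1:
        raise ValueError("df_cap must be at least 1")
    sub_rng = np.random.default_rng(subsample_seed)

    pids = list(pairs_by_participant)
    if df_cap is not None and df_cap + 1 < len(pids):
        chosen = sorted(sub_rng.choice(len(pids), size=df_cap + 1, replace=False))
        pids = [pids[i] for i in chosen]
    elif df_cap is not None and df_cap + 1 > len(pids):
        raise ValueError("df_cap exceeds the number of available participants")

    capped: dict[str, pd.DataFrame] = {}
    for pid in pids:
        df = pairs_by_participant[pid]
        if pair_cap is not None:
            if pair_cap > len(df):
                raise ValueError(
                    f"pair_cap {pair_cap} exceeds participant {pid}'s {len(df)} pairs")
            if pair_cap < len(df):
                idx = np.sort(sub_rng.choice(len(df), size=pair_cap, replace=False))
                df = df.iloc[idx].reset_index(drop=True)
        capped[pid] = df

    if not isinstance(seedseq, np.random.SeedSequence):
        seedseq = np.random.SeedSequence(seedseq)
    _, group = _stats_chain(capped, handedness, seedseq, smote_repeats,
                            k_neighbors, alpha, exclude_left_handed)
    if group is None:
        raise ValueError("fewer than 2 usable participants after capping")
    return group


def run_synthetic_experiment(
    n_participants: int = 27,
    config: SessionConfig | None = None,
    spec: IntervalSpec | None = None,
    seed: int = 0,
    smote_repeats: int = 10,
    alpha: float = 0.05,
    log_mode: str = "log_mean",
    return_pairs: bool = False,
):
    """Generate an in-memory synthetic cohort and run the full stats chain.

    The fast path for simulation studies: sessions are generated with only
    the two asymmetry channels and fed clean (no file round-trip, no gates
    to trip) into extraction and inference.  Returns the
    :class:`GroupResult` (and the per-participant pair tables if
    ``return_pairs``).
    """
    config = config or SessionConfig(channel_names=("AF3", "AF4"))
    spec = spec or IntervalSpec(1)
    master = np.random.SeedSequence(seed)
    data_ss, stats_ss = master.spawn(2)

    pairs_by_participant: dict[str, pd.DataFrame] = {}
    handedness: dict[str, str] = {}
    for p, p_ss in enumerate(data_ss.spawn(n_participants)):
        pid = f"P{p + 1:03d}"
        handedness[pid] = "right"
        frames = []
        for r, r_ss in enumerate(p_ss.spawn(config.n_runs)):
            rec, trace = generate_session(config, r_ss, pid, f"R{r + 1:02d}")
            frames.append(extract_pairs(rec, trace, spec, log_mode=log_mode))
        pairs_by_participant[pid] = pd.concat(frames, ignore_index=True)

    _, group = _stats_chain(pairs_by_participant, handedness, stats_ss,
                            smote_repeats, alpha=alpha)
    if group is None:
        raise ValueError("cohort unusable after exclusions")
    return (group, pairs_by_participant, handedness) if return_pairs else group
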