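"""CSV / JSON input-output for trial data, cohorts, fits and selection traces.

Trial CSV dialect: header ``subject,trial,condition,action,outcome`` with
condition in {go_gain, nogo_gain, go_avoid, nogo_avoid}, action in
{go, nogo}, outcome in {-1, 0, 1}. The reader validates the schema and
reports offending rows by number; reader and writer round-trip losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .fitting import FitResult
from .task import ACTION_FROM_LABEL, ACTION_LABELS, CONDITION_FROM_LABEL, Condition, DataError, TrialRecord

__all__ = [
    "write_trials_csv", "read_trials_csv",
    "write_ground_truth", "read_ground_truth",
    "write_manifest", "read_manifest",
    "export_fit", "write_selection_trace",
]

TRIAL_COLUMNS = ["subject", "trial", "condition", "action", "outcome"]


def write_trials_csv(sessions: dict[str, list[TrialRecord]], path) -> None:
    rows = [
        {
            "subject": sid,
            "trial": tr.index,
            "condition": Condition(tr.condition).label,
            "action": ACTION_LABELS[tr.action],
            "outcome": tr.outcome,
        }
        for sid, trials in sessions.items()
        for tr in trials
    ]
    pd.DataFrame(rows, columns=TRIAL_COLUMNS).to_csv(path, index=False)


def read_trials_csv(path) -> dict[str, list[TrialRecord]]:
    """Read a trial CSV into per-subject ordered trial lists, validating the schema."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"missing column(s) {missing} in {path}")
    sessions: dict[str, list[TrialRecord]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        cond = CONDITION_FROM_LABEL.get(row.condition)
        if cond is None:
            raise DataError(f"{path}:{i}: unknown condition {row.condition!r}")
        act = ACTION_FROM_LABEL.get(row.action)
        if act is None:
            raise DataError(f"{path}:{i}: unknown action {row.action!r}")
        try:
            trial = int(row.trial)
            outcome = int(row.outcome)
        except ValueError:
            raise DataError(f"{path}:{i}: non-integer trial or outcome") from None
        try:
            rec = TrialRecord(index=trial, condition=cond, action=act, outcome=outcome)
        except DataError as exc:
            raise DataError(f"{path}:{i}: {exc}") from None
        sessions.setdefault(row.subject, []).append(rec)
    for sid, trials in sessions.items():
        trials.sort(key=lambda t: t.index)
    return sessions


def write_ground_truth(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)


def read_ground_truth(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())


def export_fit(result: FitResult, out_dir, subject_ids=None) -> None:
    """Write per-subject natural-scale parameters (CSV) and hyperparameters + trace (JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frame = result.params_frame()
    if subject_ids is not None:
        frame["subject"] = list(subject_ids)
    frame.to_csv(out / "params.csv", index=False)
    (out / "fit.json").write_text(json.dumps(result.to_json_dict(), indent=2) + "\n")


def write_selection_trace(trace, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "selection.json").write_text(json.dumps(trace.to_json_dict(), indent=2) + "\n")
    (out / "selection_table.txt").write_text(trace.table() + "\n")
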