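"""On-disk subject containers: one ``.npz`` array file + JSON manifest each.

A subject directory holds ``<subject_id>.npz`` with the ``(n, ch, Ts)`` trial
array and optional label vector, alongside ``<subject_id>.json`` carrying the
metadata (subject id, channel/sample counts, sampling rate, class names).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .exceptions import InvalidInputError
from .spd import TrialSet

__all__ = ["save_subject", "load_subject", "save_subjects", "load_subjects"]


def save_subject(trialset: TrialSet, directory: str | Path) -> Path:
    """Write one subject container; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sid = trialset.subject_id or "subject"
    arrays = {"trials": trialset.trials}
    if trialset.labels is not None:
        arrays["labels"] = trialset.labels
    np.savez(directory / f"{sid}.npz", **arrays)
    n, ch, ts = trialset.trials.shape
    manifest = {
        "subject_id": sid,
        "n_trials": int(n),
        "ch": int(ch),
        "Ts": int(ts),
        "sampling_rate": float(trialset.sampling_rate),
        "classes": (
            sorted(int(c) for c in np.unique(trialset.labels))
            if trialset.labels is not None
            else None
        ),
    }
    path = directory / f"{sid}.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def load_subject(directory: str | Path, subject_id: str) -> TrialSet:
    """Read one subject container back into a TrialSet."""
    directory = Path(directory)
    npz_path = directory / f"{subject_id}.npz"
    json_path = directory / f"{subject_id}.json"
    if not npz_path.exists() or not json_path.exists():
        raise InvalidInputError(f"no container for subject {subject_id!r} in {directory}")
    manifest = json.loads(json_path.read_text())
    with np.load(npz_path) as data:
        trials = data["trials"]
        labels = data["labels"] if "labels" in data else None
    return TrialSet(
        trials=trials,
        labels=labels,
        subject_id=manifest["subject_id"],
        sampling_rate=manifest.get("sampling_rate", 250.0),
    )


def save_subjects(subjects: list[TrialSet], directory: str | Path) -> list[Path]:
    return [save_subject(s, directory) for s in subjects]


def load_subjects(directory: str | Path) -> dict[str, TrialSet]:
    """Load every subject container found in ``directory``, keyed by id."""
    directory = Path(directory)
    out: dict[str, TrialSet] = {}
    for manifest in sorted(directory.glob("*.json")):
        meta = json.loads(manifest.read_text())
        sid = meta.get("subject_id") if isinstance(meta, dict) else None
        if sid is None or not (directory / f"{sid}.npz").exists():
            continue  # e.g. a sim_config.json living in the same directory
        out[sid] = load_subject(directory, sid)
    if not out:
        raise InvalidInputError(f"no subject containers found in {directory}")
    return out
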