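"""Shared readers/writers and the per-run manifest.

CSV dialects are plain UTF-8 with headers; parameter files are JSON with
explicit strategy and category orders; every CLI run records a manifest
(command, config hash, seed, paths, version, timestamp) next to its
outputs so that identical manifests imply identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .aggregate import ResponseSequence
from .puzzle import CATEGORY_LABELS, ResponseCategory
from .strategy import AggregateParams

RESPONSE_COLUMNS = ["participant_id", "trial", "category", "digit", "correct"]


class ResponseTableError(ValueError):
    pass


def write_responses(df: pd.DataFrame, path) -> None:
    missing = [c for c in RESPONSE_COLUMNS if c not in df.columns]
    if missing:
        raise ResponseTableError(f"missing columns: {missing}")
    df[RESPONSE_COLUMNS].to_csv(path, index=False)


def read_responses(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in RESPONSE_COLUMNS if c not in df.columns]
    if missing:
        raise ResponseTableError(f"{path}: missing columns {missing}")
    if df.empty:
        return df
    bad = ~df["category"].isin(CATEGORY_LABELS)
    if bad.any():
        row = int(df.index[bad][0])
        raise ResponseTableError(
            f"{path}: invalid category {df.loc[row, 'category']!r} at row {row}"
        )
    dup = df.duplicated(subset=["participant_id", "trial"])
    if dup.any():
        row = int(df.index[dup][0])
        raise ResponseTableError(
            f"{path}: duplicate (participant_id, trial) key at row {row}"
        )
    df["trial"] = df["trial"].astype(int)
    df["correct"] = df["correct"].astype(int)
    return df


def responses_to_cohort(df: pd.DataFrame) -> list[ResponseSequence]:
    """Group a response table into per-participant ordered sequences."""
    cohort = []
    for pid, grp in df.sort_values("trial").groupby("participant_id", sort=True):
        cohort.append(
            ResponseSequence(
                participant_id=str(pid),
                categories=[ResponseCategory.from_label(c) for c in grp["category"]],
                digits=grp["digit"].tolist(),
                correct=[bool(v) for v in grp["correct"]],
            )
        )
    return cohort


def write_params(params: AggregateParams, path) -> None:
    with open(path, "w") as fh:
        json.dump(params.to_record(), fh, indent=1)


def read_params(path) -> AggregateParams:
    with open(path) as fh:
        return AggregateParams.from_record(json.load(fh))


def write_manifest(
    out_dir,
    command: str,
    seed: int | None,
    inputs: dict | None = None,
    outputs: dict | None = None,
    config: dict | None = None,
) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config_json = json.dumps(config or {}, sort_keys=True, default=str)
    manifest = {
        "command": command,
        "seed": seed,
        "config_hash": hashlib.sha256(config_json.encode()).hexdigest(),
        "config": json.loads(config_json),
        "inputs": inputs or {},
        "outputs": outputs or {},
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    path = out_dir / f"manifest_{command.replace(' ', '_')}.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return path
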