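"""Tidy-CSV session logs, results JSON, and run manifests.

The session log is one row per player-round with the canonical column set of
the round schema; CSV dialect is comma-separated, UTF-8, '.' decimal, header
row, no index column.  Reading re-validates the row-wise bookkeeping
invariants (points arithmetic, steal-outcome consistency, rating bounds) and
reports the first offending row index by name.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .engine import RECORD_FIELDS


class SchemaError(ValueError):
    """Raised when a session CSV is missing columns or violates invariants."""


_BOOL_COLUMNS = ("threshold_active", "below_threshold_flag", "active")
_INT_COLUMNS = ("set_id", "round_index", "player_id", "points_before",
                "trust_rating", "delta_points", "perturbation", "points_after")


def write_session_csv(dataset: pd.DataFrame, path) -> None:
    dataset.to_csv(path, index=False, encoding="utf-8")


def read_session_csv(path) -> pd.DataFrame:
    """Read a session log, enforcing schema and row-wise invariants."""
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in RECORD_FIELDS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {missing}")
    for col in _INT_COLUMNS:
        try:
            df[col] = df[col].astype(int)
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"column {col!r} is not integer-typed: {exc}")
    for col in _BOOL_COLUMNS:
        df[col] = df[col].astype(bool)
    validate_records(df)
    return df


def validate_records(df: pd.DataFrame) -> None:
    """Check round-record invariants row-wise; name the first bad row."""
    bad = df.index[df["points_after"]
                   != df["points_before"] + df["delta_points"]
                   + df["perturbation"]]
    if len(bad):
        raise SchemaError(
            f"row {bad[0]}: points_after != points_before + delta_points + "
            "perturbation")
    is_steal = df["action"] == "steal"
    has_outcome = df["steal_outcome"].isin(["success", "caught", "no_target"])
    bad = df.index[is_steal != has_outcome]
    if len(bad):
        raise SchemaError(
            f"row {bad[0]}: steal_outcome must be n/a exactly when action "
            "is not steal")
    bad = df.index[(df["trust_rating"] < 1) | (df["trust_rating"] > 10)]
    if len(bad):
        raise SchemaError(f"row {bad[0]}: trust_rating outside 1..10")


def write_results_json(results: pd.DataFrame, path,
                       extras: Optional[dict] = None) -> None:
    """Serialize a prediction-suite table (plus optional extras) as JSON.

    Key order is stable, floats are written at 6 significant decimals, and
    Bayes factors above 1000 carry the capped display string.
    """
    if results is None or len(results) == 0:
        raise ValueError("results table is empty")
    records = []
    for _, row in results.iterrows():
        rec = {}
        for key in ("prediction", "subset", "term", "estimate", "sd",
                    "ci_low", "ci_high", "or_", "bf", "bf_display",
                    "category", "n_obs"):
            val = row.get(key)
            if isinstance(val, (float, np.floating)):
                val = None if not np.isfinite(val) else round(float(val), 6)
            elif isinstance(val, (np.integer,)):
                val = int(val)
            rec[key] = val
        records.append(rec)
    payload: dict = {"predictions": records}
    if extras:
        payload.update(extras)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def read_results_json(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)


@dataclass(frozen=True)
class RunManifest:
    """Everything needed to reproduce one simulation byte-for-byte."""

    master_seed: int
    study: int
    n_sets: int
    policy_preset: str
    params_hash: str
    config_hash: str
    version: str
    outputs: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self) | {"outputs": list(self.outputs)}


def _stable_hash(obj) -> str:
    blob = yaml.safe_dump(obj, sort_keys=True).encode("utf-8")
    return hashlib.sha256(blob).hexdigest()[:16]


def build_manifest(master_seed: int, study: int, n_sets: int,
                   policy_preset: str, params_dict: dict, config_dict: dict,
                   outputs=()) -> RunManifest:
    from . import __version__
    return RunManifest(
        master_seed=master_seed, study=study, n_sets=n_sets,
        policy_preset=policy_preset,
        params_hash=_stable_hash(params_dict),
        config_hash=_stable_hash(config_dict),
        version=__version__, outputs=tuple(str(o) for o in outputs),
    )


def write_manifest(manifest: RunManifest, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest.to_dict(), fh, sort_keys=False)
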