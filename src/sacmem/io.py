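"""Shared plumbing: table schemas, validation, run manifests, seeds."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SCHEMAS: dict[str, dict] = {
    "trials": {
        "required": ["participant", "frequency", "condition",
                     "final_correct", "wm_capacity"],
        "domains": {"frequency": {"HF", "LF"},
                    "condition": {"test", "restudy"},
                    "final_correct": {0, 1}},
    },
    "nback": {
        "required": ["participant", "level", "hits", "misses",
                     "false_alarms", "correct_rejections"],
        "domains": {},
    },
    "practice": {
        "required": ["participant", "frequency", "practice_correct"],
        "domains": {"frequency": {"HF", "LF"},
                    "practice_correct": {0, 1}},
    },
    "observed": {
        "required": ["participant", "wm_dprime", "frequency", "condition",
                     "observed_accuracy"],
        "domains": {"frequency": {"HF", "LF"},
                    "condition": {"test", "restudy"}},
    },
}


class SchemaError(ValueError):
    """Raised with an itemized report when a table violates its schema."""


def validate_table(
    table: pd.DataFrame | str | Path, schema_name: str
) -> pd.DataFrame:
    """Validate a table against a named schema; raise an itemized report.

    Checks required columns, categorical domains, and (for trials) the
    within-participant constancy of WM capacity.  Returns the validated
    DataFrame.
    """
    if schema_name not in SCHEMAS:
        raise ValueError(f"unknown schema {schema_name!r}")
    if not isinstance(table, pd.DataFrame):
        path = Path(table)
        if not path.exists():
            raise FileNotFoundError(path)
        table = pd.read_csv(path)
    schema = SCHEMAS[schema_name]
    problems: list[str] = []
    for col in schema["required"]:
        if col not in table.columns:
            problems.append(f"missing required column {col!r}")
    for col, domain in schema["domains"].items():
        if col not in table.columns:
            continue
        bad = ~table[col].isin(domain)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            problems.append(
                f"column {col!r}: value {table[col].iloc[row]!r} at row "
                f"{row} outside domain {sorted(map(str, domain))}")
    if schema_name == "trials" and not problems:
        var = table.groupby("participant").wm_capacity.nunique()
        if (var > 1).any():
            problems.append(
                "wm_capacity varies within participant(s): "
                f"{list(var[var > 1].index[:3])}")
        if table.wm_capacity.isna().any():
            problems.append("wm_capacity contains missing values")
    if problems:
        raise SchemaError(
            f"{schema_name} table failed validation "
            f"({len(table)} rows, {len(table.columns)} cols):\n  - "
            + "\n  - ".join(problems))
    return table


def spawn_seeds(root_seed: int, n: int) -> list[int]:
    """Deterministic child seeds (< 2^31) from one root seed."""
    return [int(s.generate_state(1)[0] % (2**31))
            for s in np.random.SeedSequence(root_seed).spawn(n)]


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Traceability record for one pipeline run."""

    config_hash: str
    seed: int
    stage: str
    inputs: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    timestamp: str = field(
        default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S"))

    @classmethod
    def create(cls, config_dict: dict, seed: int, stage: str) -> "RunManifest":
        blob = json.dumps(config_dict, sort_keys=True).encode()
        return cls(config_hash=hashlib.sha256(blob).hexdigest()[:16],
                   seed=seed, stage=stage)

    def record_input(self, path: str | Path) -> None:
        self.inputs[str(path)] = _digest(Path(path))

    def record_output(self, path: str | Path) -> None:
        self.outputs[str(path)] = _digest(Path(path))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))
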