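"""Table persistence and run manifests.

Experiment tables are plain CSV with full-precision floats; undefined
metrics (e.g. a relative risk whose low-risk class had no infections)
travel as empty cells and come back as NaN.  A :class:`RunManifest`
snapshots everything needed to reproduce an experiment bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from .config import ScenarioConfig, STAGES

__all__ = ["write_table", "read_table", "RunManifest"]


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write an experiment table as CSV (lossless float round-trip)."""
    # pandas' default float formatting is the shortest exact repr
    table.to_csv(path, index=False)


def read_table(path: str | Path, expect_columns: list[str] | None = None) -> pd.DataFrame:
    """Read a CSV experiment table; empty cells become NaN.

    ``expect_columns`` (if given) must match the header exactly.
    """
    try:
        table = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:  # pragma: no cover - message passthrough
        raise ValueError(f"malformed table {path}: {exc}") from exc
    if expect_columns is not None and list(table.columns) != list(expect_columns):
        raise ValueError(
            f"table header mismatch in {path}: got {list(table.columns)}"
        )
    return table


@dataclass
class RunManifest:
    """Reproducibility record for one experiment invocation."""

    config: ScenarioConfig
    outcome: str
    master_seed: int
    outputs: dict[str, str] = field(default_factory=dict)
    software_version: str = ""
    created: str = ""

    def __post_init__(self) -> None:
        if not self.created:
            self.created = datetime.now(timezone.utc).isoformat()
        if not self.software_version:
            from . import __version__

            self.software_version = __version__

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "config": self.config.to_dict(),
            "outcome": self.outcome,
            "master_seed": self.master_seed,
            "stage_streams": list(STAGES),
            "outputs": self.outputs,
            "software_version": self.software_version,
            "created": self.created,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "RunManifest":
        payload = json.loads(Path(path).read_text())
        return cls(
            config=ScenarioConfig.from_dict(payload["config"]),
            outcome=payload["outcome"],
            master_seed=payload["master_seed"],
            outputs=payload.get("outputs", {}),
            software_version=payload.get("software_version", ""),
            created=payload.get("created", ""),
        )
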