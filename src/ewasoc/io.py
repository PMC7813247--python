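"""Dataset readers/writers, configuration files and run manifests.

All tabular artefacts are tidy CSV with a single ``#``-prefixed header
comment carrying the schema version; configs and manifests are YAML.
Write-then-read round-trips are lossless for every schema.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .environment import ExperimentConfig

SCHEMA_VERSION = "ewasoc-schema-v1"

log = logging.getLogger("ewasoc")


def setup_logging(level: int = logging.INFO) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("ewasoc")
    if not root.handlers:
        root.addHandler(handler)
    root.setLevel(level)


def write_table(df: pd.DataFrame, path, kind: str = "observations") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# {SCHEMA_VERSION} {kind}\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#"):
            fh.seek(0)
        return pd.read_csv(fh)


def load_config(path) -> ExperimentConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        return ExperimentConfig.from_dict(raw)
    except TypeError as err:
        raise ValueError(f"malformed config {path}: {err}") from err


def save_config(config: ExperimentConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


@dataclass
class RunManifest:
    """Reproducibility record emitted once per CLI run."""

    command: str
    seed: int
    config: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)
    version: str = __version__

    def write(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(
                dict(
                    command=self.command,
                    seed=self.seed,
                    config=self.config,
                    inputs={k: str(v) for k, v in self.inputs.items()},
                    outputs={k: str(v) for k, v in self.outputs.items()},
                    diagnostics=self.diagnostics,
                    version=self.version,
                ),
                fh,
                sort_keys=False,
            )
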