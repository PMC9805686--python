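"""Run logs, deterministic writers and analysis configuration.

Output tables are TSV and output summaries JSON; both are deterministic
given (inputs, configuration, seed).  The run log carries timestamps and
is the only non-reproducible artifact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import DataError

PACKAGE_LOGGER = "phenocompare"


@dataclass
class RunLog:
    """Timestamped events plus warning counts and input checksums."""

    seed: int | None = None
    events: list = field(default_factory=list)
    checksums: dict = field(default_factory=dict)

    def _add(self, level: str, message: str) -> None:
        self.events.append((time.strftime("%Y-%m-%dT%H:%M:%S"), level, message))

    def info(self, message: str) -> None:
        self._add("INFO", message)

    def warning(self, message: str) -> None:
        self._add("WARNING", message)

    @property
    def n_warnings(self) -> int:
        return sum(1 for _, lvl, _ in self.events if lvl == "WARNING")

    def checksum_input(self, path) -> None:
        path = Path(path)
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.checksums[str(path)] = digest
        self.info(f"input {path} sha256={digest[:12]}")

    @contextmanager
    def capture(self):
        """Route package log records (e.g. dropped-gene warnings) into this log."""
        log = self

        class _Handler(logging.Handler):
            def emit(self, record):
                log._add(record.levelname, record.getMessage())

        handler = _Handler(level=logging.INFO)
        logger = logging.getLogger(PACKAGE_LOGGER)
        previous = logger.level
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
        try:
            yield self
        finally:
            logger.removeHandler(handler)
            logger.setLevel(previous)

    def write(self, path) -> None:
        lines = [f"# seed: {self.seed}"]
        lines += [f"{ts}\t{lvl}\t{msg}" for ts, lvl, msg in self.events]
        Path(path).write_text("\n".join(lines) + "\n")


def write_json(obj, path) -> None:
    """Deterministic JSON writer (sorted keys, fixed float repr)."""
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def write_tsv(df, path) -> None:
    df.to_csv(path, sep="\t", index=False)


@dataclass
class DbSpec:
    """One database registry entry: NAME=PATH:DIALECT[:KIND]."""

    name: str
    path: str
    dialect: str
    kind: str = "phenotype"

    @classmethod
    def parse(cls, text: str) -> "DbSpec":
        try:
            name, rest = text.split("=", 1)
            parts = rest.rsplit(":", 2)
            if len(parts) == 3 and parts[2] in ("phenotype", "disease"):
                path, dialect, kind = parts
            else:
                path, dialect = rest.rsplit(":", 1)
                kind = "phenotype"
        except ValueError:
            raise DataError(
                f"cannot parse database spec {text!r} (expected NAME=PATH:DIALECT[:KIND])"
            ) from None
        return cls(name=name, path=path, dialect=dialect, kind=kind)


@dataclass
class AnalysisConfig:
    """Mirror of the CLI flags; values from a YAML file, flags override."""

    databases: list = field(default_factory=list)  # of DbSpec
    universe: str | None = None
    organism: str = "human"
    alpha: float = 0.05
    criterion: str = "raw"
    mode: str = "upper_tail"
    method: str = "jaccard"
    permutations: int = 1000
    seed: int = 0
    out_prefix: str = "phenocompare"

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise DataError(f"unknown config keys: {sorted(unknown)}")
        dbs = [DbSpec.parse(d) if isinstance(d, str) else DbSpec(**d)
               for d in data.pop("databases", [])]
        return cls(databases=dbs, **data)

    def merged(self, **overrides) -> "AnalysisConfig":
        """New config with non-None overrides applied (flags beat file)."""
        out = dataclasses.replace(self)
        for key, value in overrides.items():
            if value is not None and value != ():
                setattr(out, key, value)
        return out
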