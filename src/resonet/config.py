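"""Run configuration, seeding, manifests and CSV output.

One master seed spawns named child streams (topology, initial conditions,
mutation/scoring, ...) so adding draws in one stage never perturbs another.
Configurations are YAML key-value files; unknown keys and out-of-range
values are configuration errors that name the offending key.  Results are
written as tidy CSV with a deterministic column order and full-precision
floats so that identical (config, seed) runs are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, fields

import numpy as np
import yaml

from .errors import ConfigError

__all__ = ["RunConfig", "load_config", "save_config", "child_rngs", "write_results", "RunManifest"]

log = logging.getLogger("resonet")


@dataclass
class RunConfig:
    """Validated experiment parameters with the study defaults."""

    n_nodes: int = 500
    gamma: float = 1.9
    seed: int = 0
    max_steps: int = 10_000
    # evolutionary-run parameters
    pop_size: int = 50
    mutants_per_parent: int = 3
    mutation_rate: float = 0.02
    generations: int = 100
    scheme: str = "driven"
    blocked_value: int = 1
    periods: list = field(default_factory=lambda: [6, 8, 10])
    input_kind: str = "square"
    target_lengths: list | None = None
    # explicit 0/1 strings pin the exact signals/targets instead of drawing
    # them from the seed
    input_patterns: list | None = None
    targets: list | None = None
    output_node: int | None = None
    # landscape / phase-diagram parameters
    n_init: int = 1000
    perturbation: float = 0.05
    t_max: int = 300
    n_networks: int = 20
    n_ics: int = 5
    driving_period: int = 4

    def validate(self) -> "RunConfig":
        checks = [
            ("n_nodes", self.n_nodes >= 2),
            ("gamma", self.gamma > 1.0),
            ("seed", self.seed >= 0),
            ("max_steps", self.max_steps >= 1),
            ("pop_size", self.pop_size >= 1),
            ("mutants_per_parent", self.mutants_per_parent >= 0),
            ("mutation_rate", 0.0 <= self.mutation_rate <= 1.0),
            ("generations", self.generations >= 0),
            ("scheme", self.scheme in ("driven", "blocked", "free")),
            ("blocked_value", self.blocked_value in (0, 1)),
            ("input_kind", self.input_kind in ("square", "pattern", "noise")),
            ("n_init", self.n_init >= 1),
            ("perturbation", 0.0 <= self.perturbation <= 1.0),
            ("t_max", self.t_max >= 1),
            ("n_networks", self.n_networks >= 1),
            ("n_ics", self.n_ics >= 1),
            ("driving_period", self.driving_period >= 1),
        ]
        if self.input_kind == "square":
            checks.append(("periods", all(p >= 2 and p % 2 == 0 for p in self.periods)))
        else:
            checks.append(("periods", all(p >= 2 for p in self.periods)))
        for key in ("input_patterns", "targets"):
            val = getattr(self, key)
            if val is not None:
                checks.append(
                    (key, all(isinstance(s, str) and s and set(s) <= {"0", "1"} for s in val))
                )
        for key, ok in checks:
            if not ok:
                raise ConfigError(f"configuration value out of range: {key} = {getattr(self, key)!r}")
        return self


def load_config(path) -> RunConfig:
    """Read and validate a YAML config; missing keys take the defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a key-value mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown configuration key(s): {', '.join(sorted(unknown))}")
    cfg = RunConfig(**raw).validate()
    log.info("loaded config from %s", path)
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True)


def child_rngs(seed: int, *names: str) -> dict:
    """Spawn one named, independent random stream per stage from a master seed."""
    base = np.random.SeedSequence(seed)
    children = base.spawn(len(names))
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


def write_results(records, path, columns=None) -> None:
    """Write records (list of dicts) as deterministic full-precision CSV.

    Column order is the order keys first appear (or the explicit ``columns``);
    an empty record list yields a header-only file.  Floats use ``repr``
    precision so parsing the file back reproduces the in-memory values.
    """
    if columns is None:
        columns = []
        for rec in records:
            for key in rec:
                if key not in columns:
                    columns.append(key)
    if not columns:
        raise ConfigError("cannot write a CSV with no columns (pass columns= for empty results)")

    def fmt(v):
        if isinstance(v, (float, np.floating)):
            return repr(float(v))
        return str(v)

    with open(path, "w") as fh:
        fh.write(",".join(columns) + "\n")
        for rec in records:
            fh.write(",".join(fmt(rec.get(c, "")) for c in columns) + "\n")


@dataclass
class RunManifest:
    """Record of one experiment: config snapshot, seed, outputs and warnings."""

    config: dict
    seed: int
    version: str
    outputs: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    def add_output(self, path) -> None:
        self.outputs.append(str(path))

    def warn(self, message: str) -> None:
        self.warnings.append(message)
        log.warning("%s", message)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=str)
            fh.write("\n")
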