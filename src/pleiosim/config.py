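"""Run-configuration loading for the command-line interface.

Configurations are flat YAML (JSON is a YAML subset and parses too) with
a ``scenario:`` block mirroring :class:`~pleiosim.power.ScenarioSpec`::

    scenario:
      scenario: S1
      k: 2
      n: 5000            # default
      replicates: 10000  # default
      alpha: 5.0e-8      # default, genome-wide significance
      maf: 0.3           # default
      seed: 0
      params: {r_min: -0.9, r_max: 0.9, step: 0.1}
    methods: [minP, TATES, SHom, SHet, MANOVA, CCA, CombinedPC, MultiPhen]
    out: results/
    workers: 1

Unknown keys are rejected with an error naming them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from ._exceptions import ConfigError
from .methods import METHOD_NAMES
from .power import GENOME_WIDE_ALPHA, ScenarioSpec

__all__ = ["RunConfig", "load_config", "dump_config"]

_SCENARIO_KEYS = {"scenario", "k", "n", "maf", "replicates", "alpha", "seed", "params"}
_TOP_KEYS = {"scenario", "methods", "out", "workers", "verbosity"}


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for one benchmarking run."""

    spec: ScenarioSpec
    methods: tuple = METHOD_NAMES
    out: str = "results"
    workers: int = 1
    verbosity: int = 1


def _reject_unknown(mapping: dict, allowed: set, where: str) -> None:
    unknown = sorted(set(mapping) - allowed)
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {', '.join(unknown)}")


def parse_config(raw: dict) -> RunConfig:
    """Build a :class:`RunConfig` from a parsed mapping, applying defaults."""
    if not isinstance(raw, dict):
        raise ConfigError("configuration must be a mapping")
    _reject_unknown(raw, _TOP_KEYS, "configuration")
    scen = raw.get("scenario")
    if not isinstance(scen, dict):
        raise ConfigError("configuration requires a 'scenario' block")
    _reject_unknown(scen, _SCENARIO_KEYS, "scenario block")
    if "scenario" not in scen or "k" not in scen:
        raise ConfigError("scenario block requires 'scenario' and 'k'")
    spec = ScenarioSpec(
        scenario=str(scen["scenario"]),
        k=int(scen["k"]),
        n=int(scen.get("n", 5_000)),
        maf=float(scen.get("maf", 0.3)),
        n_replicates=int(scen.get("replicates", 10_000)),
        alpha=float(scen.get("alpha", GENOME_WIDE_ALPHA)),
        seed=int(scen.get("seed", 0)),
        params=dict(scen.get("params", {})),
    )
    methods = tuple(raw.get("methods", METHOD_NAMES))
    unknown = [m for m in methods if m not in METHOD_NAMES]
    if unknown:
        raise ConfigError(f"unknown method(s): {', '.join(map(str, unknown))}; "
                          f"choose from {', '.join(METHOD_NAMES)}")
    workers = int(raw.get("workers", 1))
    if workers < 1:
        raise ConfigError("workers must be >= 1")
    return RunConfig(spec=spec, methods=methods, out=str(raw.get("out", "results")),
                     workers=workers, verbosity=int(raw.get("verbosity", 1)))


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON configuration file."""
    with open(path) as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse {path}: {exc}") from exc
    return parse_config(raw)


def dump_config(config: RunConfig) -> dict:
    """Normalized mapping such that ``parse_config(dump_config(c)) == c``."""
    spec = config.spec
    return {
        "scenario": {
            "scenario": spec.scenario, "k": spec.k, "n": spec.n,
            "maf": spec.maf, "replicates": spec.n_replicates,
            "alpha": spec.alpha, "seed": spec.seed, "params": dict(spec.params),
        },
        "methods": list(config.methods),
        "out": config.out,
        "workers": config.workers,
        "verbosity": config.verbosity,
    }
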