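"""Run configuration: YAML round-trip, validation and defaults.

The defaults are the published study conditions: a 50-type network split
evenly between functional and informational polymers with link probability
0.05, aggregation threshold D=5 with cost scale delta=0.005, a population of
100,000 protocells, one million proposed mutations and seven trajectories.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .growth import AggregationParams
from .evolution import EvolutionParams


class ConfigError(ValueError):
    """A configuration file that fails validation; names the bad field."""


@dataclass
class RunConfig:
    # network generation
    n_functional: int = 25
    n_informational: int = 25
    n_ribosome: int = 1
    n_polymerase: int = 1
    link_prob: float = 0.05
    length_min: int = 5
    length_max: int = 25
    initial_copies: int = 1
    # protocell kinetics
    k_F: float = 1.0
    k_I: float = 1.0
    v_F: float = 1.0
    v_I: float = 1.0
    # aggregation
    threshold_D: int = 5
    delta: float = 0.005
    # evolution
    pop_size: int = 100_000
    n_mutations: int = 1_000_000
    neutral_eps: float = 1e-12
    n_trajectories: int = 7
    # bookkeeping
    seed: int = 0
    out_dir: str = "piinet_run"
    log_level: str = "INFO"
    write_trajectory_csv: bool = True

    def validate(self) -> "RunConfig":
        checks = [
            ("n_functional", self.n_functional >= 1),
            ("n_informational", self.n_informational >= 1),
            ("n_ribosome", self.n_ribosome >= 1),
            ("n_polymerase", self.n_polymerase >= 1),
            (
                "n_ribosome",
                self.n_ribosome + self.n_polymerase <= self.n_functional,
            ),
            ("link_prob", 0.0 <= self.link_prob <= 1.0),
            ("length_min", self.length_min >= 1),
            ("length_max", self.length_max >= self.length_min),
            ("initial_copies", self.initial_copies >= 1),
            ("k_F", self.k_F > 0),
            ("k_I", self.k_I > 0),
            ("v_F", self.v_F > 0),
            ("v_I", self.v_I > 0),
            ("threshold_D", self.threshold_D >= 1),
            ("delta", self.delta >= 0),
            ("pop_size", self.pop_size >= 2),
            ("n_mutations", self.n_mutations >= 1),
            ("neutral_eps", self.neutral_eps > 0),
            ("n_trajectories", self.n_trajectories >= 1),
        ]
        for name, ok in checks:
            if not ok:
                raise ConfigError(
                    f"invalid value for '{name}': {getattr(self, name)!r}"
                )
        return self

    # -- derived parameter bundles ----------------------------------------

    def generator_params(self) -> dict:
        return dict(
            n_functional=self.n_functional,
            n_informational=self.n_informational,
            link_prob=self.link_prob,
            length_range=(self.length_min, self.length_max),
            n_ribosome=self.n_ribosome,
            n_polymerase=self.n_polymerase,
            initial_copies=self.initial_copies,
        )

    def state_params(self) -> dict:
        return dict(k_F=self.k_F, k_I=self.k_I, v_F=self.v_F, v_I=self.v_I)

    def evolution_params(self, rng_seed: int | None = None) -> EvolutionParams:
        return EvolutionParams(
            pop_size=self.pop_size,
            n_mutations=self.n_mutations,
            neutral_eps=self.neutral_eps,
            rng_seed=self.seed if rng_seed is None else rng_seed,
            aggregation=AggregationParams(
                threshold_D=self.threshold_D, delta=self.delta
            ),
        )

    # -- serialization -----------------------------------------------------

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def load_config(path) -> RunConfig:
    """Read a YAML config; unset fields fall back to the study defaults."""
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except FileNotFoundError as exc:
        raise ConfigError(f"config file not found: {path}") from exc
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config {path}: {exc}") from exc
    raw = raw or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
    return RunConfig(**raw).validate()
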