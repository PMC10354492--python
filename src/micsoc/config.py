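"""Game configuration: per-study point values, payout rates and condition schemes.

Four study variants of the same eight-player microsociety game are supported.
Studies 1-2 (UK, GBP) use a desperation threshold of 100 energy points, a
+20/-40 steal gamble and per-round Gaussian perturbations of the points level;
studies 3-4 (US, USD) raise the threshold to 200, soften the gamble to
+10/-15 (or -30 under harsh punishment in study 3) and remove the random
perturbations.  Stealing always has a negative expected return: the config
validator rejects any parameterisation where the fair-coin gamble would pay
off on average.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional

import yaml


class ConfigError(ValueError):
    """Raised when a game configuration violates a structural invariant."""


@dataclass(frozen=True)
class GameConfig:
    """All point values, rates and procedural parameters for one study."""

    study_label: int
    cooperate_gain: int = 5
    stolen_loss: int = -5
    steal_gain: int = 20
    steal_penalty_lenient: int = -40
    steal_penalty_harsh: Optional[int] = None
    work_alone_payoff: int = 0
    steal_success_prob: float = 0.5
    threshold_level: int = 100
    perturbation_sd: float = 3.0
    conversion_rate: float = 0.02      # currency units per point
    below_round_penalty: float = 0.50  # currency units per below-threshold round
    n_mock_rounds: int = 5
    real_round_rule: str = "uniform_8_16"  # or "fixed_12"
    set_size: int = 8
    group_size: int = 4
    currency: str = "GBP"
    # Victim allocation when >=1 steal succeeds: "all_cooperators_once" charges
    # every cooperator the stolen_loss exactly once per round; the alternative
    # "random_victim_per_success" charges one uniformly chosen cooperator per
    # successful stealer (losses can stack).
    victim_rule: str = "all_cooperators_once"

    def steal_penalty(self, punishment_level: str) -> int:
        if punishment_level == "harsh":
            if self.steal_penalty_harsh is None:
                raise ConfigError(
                    f"study {self.study_label} has no harsh punishment level"
                )
            return self.steal_penalty_harsh
        return self.steal_penalty_lenient


@dataclass(frozen=True)
class ConditionScheme:
    """How experimental factors are assigned to sets/players in one study."""

    threshold_assignment: str = "all_threshold"  # between_sets | within_set
    punishment_assignment: str = "none"          # within_set | fixed_lenient
    inequality_assignment: str = "none"          # between_sets


def validate_config(config: GameConfig) -> list[str]:
    """Return a list of violated invariants (empty when valid)."""
    problems: list[str] = []
    p = config.steal_success_prob
    penalties = [config.steal_penalty_lenient]
    if config.steal_penalty_harsh is not None:
        penalties.append(config.steal_penalty_harsh)
    for pen in penalties:
        ev = p * config.steal_gain + (1.0 - p) * pen
        if ev >= 0:
            problems.append(
                f"stealing must have negative expected return: "
                f"{p}*{config.steal_gain} + {1 - p}*{pen} = {ev} >= 0"
            )
    if config.set_size % config.group_size != 0:
        problems.append(
            f"set_size ({config.set_size}) must be an exact multiple of "
            f"group_size ({config.group_size})"
        )
    if config.study_label in (3, 4) and config.perturbation_sd != 0:
        problems.append(
            f"perturbation_sd must be 0 for study {config.study_label} "
            f"(random point fluctuations removed), got {config.perturbation_sd}"
        )
    if config.real_round_rule not in ("uniform_8_16", "fixed_12"):
        problems.append(f"unknown real_round_rule {config.real_round_rule!r}")
    if config.victim_rule not in ("all_cooperators_once", "random_victim_per_success"):
        problems.append(f"unknown victim_rule {config.victim_rule!r}")
    if not 0.0 <= p <= 1.0:
        problems.append(f"steal_success_prob must be a probability, got {p}")
    return problems


def check_config(config: GameConfig) -> GameConfig:
    """Validate, raising :class:`ConfigError` listing every violation."""
    problems = validate_config(config)
    if problems:
        raise ConfigError("; ".join(problems))
    return config


_STUDY_CONFIGS: dict[int, GameConfig] = {
    1: GameConfig(study_label=1),
    2: GameConfig(study_label=2),
    3: GameConfig(
        study_label=3,
        steal_gain=10,
        steal_penalty_lenient=-15,
        steal_penalty_harsh=-30,
        threshold_level=200,
        perturbation_sd=0.0,
        conversion_rate=0.01,
        below_round_penalty=0.20,
        n_mock_rounds=4,
        real_round_rule="uniform_8_16",
        currency="USD",
    ),
    4: GameConfig(
        study_label=4,
        steal_gain=10,
        steal_penalty_lenient=-15,
        steal_penalty_harsh=None,
        threshold_level=200,
        perturbation_sd=0.0,
        conversion_rate=0.01,
        below_round_penalty=0.20,
        n_mock_rounds=4,
        real_round_rule="fixed_12",
        currency="USD",
    ),
}

_STUDY_SCHEMES: dict[int, ConditionScheme] = {
    1: ConditionScheme("all_threshold", "none", "none"),
    2: ConditionScheme("between_sets", "none", "none"),
    3: ConditionScheme("within_set", "within_set", "none"),
    4: ConditionScheme("between_sets", "fixed_lenient", "between_sets"),
}


def study_config(study: int) -> tuple[GameConfig, ConditionScheme]:
    """Return the (validated) configuration and condition scheme for a study."""
    if study not in _STUDY_CONFIGS:
        raise ConfigError(f"unknown study id {study!r}; expected 1, 2, 3 or 4")
    return check_config(_STUDY_CONFIGS[study]), _STUDY_SCHEMES[study]


def config_to_dict(config: GameConfig) -> dict:
    return dataclasses.asdict(config)


def dump_config_yaml(config: GameConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump({f"study_{config.study_label}": config_to_dict(config)}, fh,
                       sort_keys=False)


def load_config_yaml(path) -> dict[str, GameConfig]:
    """Load a YAML file with one block per study; values override defaults."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    out: dict[str, GameConfig] = {}
    for name, block in raw.items():
        if not isinstance(block, dict) or "study_label" not in block:
            raise ConfigError(f"config block {name!r} must map fields and "
                              "include study_label")
        out[name] = GameConfig(**block)
    return out
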