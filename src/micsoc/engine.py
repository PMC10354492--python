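"""One microsociety session: group formation, action resolution, accounting.

Eight players (a *set*) play a variable number of rounds.  Each round the set
is partitioned uniformly at random into two interaction groups of four.  Every
player rates their trust in the others (1-10), then chooses ``cooperate``,
``steal`` or ``work_alone``.  Cooperation pays a small gain only if at least
one other group member cooperated and nobody attempted to steal; a steal
attempt, provided at least one cooperator is present to steal from, succeeds
or is caught with equal probability; working alone never gains or loses.
After a configurable number of unpaid mock rounds, points reset to the study's
starting allocation and real rounds begin.  At payout, points convert to cash
and — in threshold conditions — a fixed penalty is charged for every real
round the player ended below the desperation threshold, floored at zero.

All randomness flows through a single :class:`numpy.random.Generator`, so a
session is bit-reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .config import ConfigError, GameConfig, check_config

ACTIONS = ("cooperate", "steal", "work_alone")

#: Column order of the tidy per-player-round log.
RECORD_FIELDS = (
    "set_id", "session_seed", "round_index", "group_id", "player_id",
    "threshold_active", "punishment_level", "inequality_condition",
    "points_before", "trust_rating", "steal_likelihood_rating", "action",
    "steal_outcome", "delta_points", "perturbation", "points_after",
    "below_threshold_flag", "active",
)


@dataclass
class PlayerState:
    """Mutable per-player state carried across rounds of one session."""

    player_id: int
    set_id: int
    threshold_active: bool = True
    punishment_level: str = "n/a"       # lenient | harsh | n/a
    inequality_condition: str = "n/a"   # equal | unequal | n/a
    points: int = 0
    below_round_count: int = 0
    latent_trust: float = 0.5
    active: bool = True
    random_intercept: float = 0.0


@dataclass
class RoundRecord:
    """One tidy row per player-round (the universal log schema)."""

    set_id: int
    session_seed: str
    round_index: int
    group_id: str
    player_id: int
    threshold_active: bool
    punishment_level: str
    inequality_condition: str
    points_before: int
    trust_rating: int
    steal_likelihood_rating: Optional[int]
    action: str
    steal_outcome: str
    delta_points: int
    perturbation: int
    points_after: int
    below_threshold_flag: bool
    active: bool


def form_groups(set_members: Sequence, rng: np.random.Generator) -> tuple[list, list]:
    """Partition eight set members uniformly at random into two groups of four.

    The partition is independent across rounds and deterministic given the
    generator state.
    """
    if len(set_members) != 8:
        raise ConfigError(f"a set must have exactly 8 members, got {len(set_members)}")
    perm = rng.permutation(len(set_members))
    members = list(set_members)
    return [members[i] for i in perm[:4]], [members[i] for i in perm[4:]]


def draw_steal_outcomes(n_stealers: int, config: GameConfig,
                        rng: np.random.Generator) -> list[bool]:
    """Independent fair-gamble success flags, one per steal attempt."""
    if n_stealers < 0:
        raise ConfigError("n_stealers must be non-negative")
    return list(rng.random(n_stealers) < config.steal_success_prob)


def resolve_group(
    actions: Sequence[str],
    steal_success_flags: Sequence[bool],
    config: GameConfig,
    punishment_levels: Sequence[str],
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[int], list[str]]:
    """Resolve one interaction group's actions into per-player point deltas.

    Rules (the last two reflect the attempt-based reading of the game text):

    * work-alone always yields 0;
    * a cooperator gains ``cooperate_gain`` iff the group has >= 2 cooperators
      and zero steal *attempts*;
    * a cooperator incurs ``stolen_loss`` (once per round under the default
      victim rule) iff >= 1 steal attempt *succeeded*; a caught-only attempt
      costs cooperators nothing but still cancels the cooperation gain;
    * a stealer gambles only if >= 1 cooperator is present: success pays
      ``steal_gain``, capture costs that player's own punishment-level
      penalty; with no cooperator to steal from the attempt is a ``no_target``
      no-op with no punishment risk.

    Returns ``(delta_points, steal_outcome)`` aligned with ``actions``;
    ``steal_outcome`` is ``"n/a"`` for non-stealers.
    """
    if len(actions) != config.group_size:
        raise ConfigError(
            f"expected {config.group_size} actions, got {len(actions)}")
    if len(punishment_levels) != len(actions):
        raise ConfigError("one punishment level required per player")
    for a in actions:
        if a not in ACTIONS:
            raise ConfigError(f"unknown action {a!r}")
    stealer_idx = [i for i, a in enumerate(actions) if a == "steal"]
    if len(steal_success_flags) != len(stealer_idx):
        raise ConfigError(
            f"expected {len(stealer_idx)} steal flags, got {len(steal_success_flags)}")

    coop_idx = [i for i, a in enumerate(actions) if a == "cooperate"]
    n_coop = len(coop_idx)
    n_attempts = len(stealer_idx)
    targets_exist = n_coop >= 1
    n_successes = sum(bool(f) for f in steal_success_flags) if targets_exist else 0

    deltas = [0] * len(actions)
    outcomes = ["n/a"] * len(actions)

    for pos, i in enumerate(stealer_idx):
        if not targets_exist:
            outcomes[i] = "no_target"
        elif steal_success_flags[pos]:
            deltas[i] = config.steal_gain
            outcomes[i] = "success"
        else:
            deltas[i] = config.steal_penalty(punishment_levels[i])
            outcomes[i] = "caught"

    if n_coop >= 2 and n_attempts == 0:
        for i in coop_idx:
            deltas[i] = config.cooperate_gain
    if n_successes >= 1:
        if config.victim_rule == "all_cooperators_once":
            for i in coop_idx:
                deltas[i] = config.stolen_loss
        else:  # random_victim_per_success
            if rng is None:
                raise ConfigError(
                    "victim_rule 'random_victim_per_success' needs an rng")
            for _ in range(n_successes):
                victim = coop_idx[int(rng.integers(len(coop_idx)))]
                deltas[victim] += config.stolen_loss
    return deltas, outcomes


def apply_perturbation(points: int, config: GameConfig,
                       rng: np.random.Generator) -> tuple[int, int]:
    """Apply the per-round random shock to an energy-points level.

    The shock is a discretised Gaussian: a continuous Normal(0, sd) draw
    rounded to the nearest integer (which inflates the variance by ~1/12).
    Identically zero when ``perturbation_sd`` is 0 (studies 3-4).
    """
    if config.perturbation_sd == 0:
        return points, 0
    pert = int(np.rint(rng.normal(0.0, config.perturbation_sd)))
    return points + pert, pert


def settle_payout(final_points: int, below_round_count: int,
                  threshold_active: bool, config: GameConfig) -> float:
    """Convert final points to cash, applying the desperation penalty.

    In threshold conditions every real round ended below the threshold costs
    ``below_round_penalty`` currency units off the converted sum; the result
    is floored at zero (a few bad rounds can wipe out earnings entirely, but
    payment is never negative).
    """
    if below_round_count < 0:
        raise ConfigError("below_round_count must be non-negative")
    amount = final_points * config.conversion_rate
    if threshold_active:
        amount -= below_round_count * config.below_round_penalty
    return round(max(0.0, amount), 2)


def draw_n_real_rounds(config: GameConfig, rng: np.random.Generator) -> int:
    """Number of real rounds: fixed at 12, or uniform on 8..16 inclusive."""
    if config.real_round_rule == "fixed_12":
        return 12
    return int(rng.integers(8, 17))


@dataclass
class Session:
    """A set of 8 players, their policies, and the session log."""

    config: GameConfig
    players: list[PlayerState]
    policies: list
    session_seed: str = ""
    inactivity_prob: float = 0.0
    records: list[RoundRecord] = field(default_factory=list)
    n_real_rounds: Optional[int] = None
    payouts: Optional[list[float]] = None

    def __post_init__(self):
        if len(self.players) != self.config.set_size:
            raise ConfigError(
                f"session needs {self.config.set_size} players, got {len(self.players)}")
        if len(self.policies) != len(self.players):
            raise ConfigError("one policy per player required")


def run_round(session: Session, round_index: int,
              rng: np.random.Generator) -> list[RoundRecord]:
    """Play one round (mock if ``round_index <= 0``) and append its records.

    Order of play: optional dropout draw, group formation, then per player a
    trust rating followed by an action (inactive players are forced to work
    alone), group resolution, the points perturbation (real rounds of studies
    with a nonzero shock), below-threshold accounting on the post-shock level,
    and finally each policy observes its own group's aggregate outcome.
    """
    cfg = session.config
    players = session.players
    is_real = round_index >= 1

    if session.inactivity_prob > 0:
        for p in players:
            if p.active and rng.random() < session.inactivity_prob:
                p.active = False

    group_a, group_b = form_groups(list(range(len(players))), rng)
    records: list[RoundRecord] = []
    for group_id, group in (("A", group_a), ("B", group_b)):
        ratings: list[tuple[int, Optional[int]]] = []
        actions: list[str] = []
        for idx in group:
            pl = players[idx]
            pol = session.policies[idx]
            ratings.append(pol.ratings(pl, rng))
            if pl.active:
                actions.append(pol.decide(pl, round_index, rng))
            else:
                actions.append("work_alone")
        stealers = [i for i, a in enumerate(actions) if a == "steal"]
        flags = draw_steal_outcomes(len(stealers), cfg, rng)
        deltas, outcomes = resolve_group(
            actions, flags, cfg, [players[i].punishment_level for i in group],
            rng=rng)
        n_attempts = len(stealers)
        for pos, idx in enumerate(group):
            pl = players[idx]
            points_before = pl.points
            after_delta = points_before + deltas[pos]
            if is_real:
                points_after, pert = apply_perturbation(after_delta, cfg, rng)
            else:
                points_after, pert = after_delta, 0
            pl.points = points_after
            below = points_after < cfg.threshold_level
            if is_real and below:
                pl.below_round_count += 1
            records.append(RoundRecord(
                set_id=pl.set_id,
                session_seed=session.session_seed,
                round_index=round_index,
                group_id=group_id,
                player_id=pl.player_id,
                threshold_active=pl.threshold_active,
                punishment_level=pl.punishment_level,
                inequality_condition=pl.inequality_condition,
                points_before=points_before,
                trust_rating=ratings[pos][0],
                steal_likelihood_rating=ratings[pos][1],
                action=actions[pos],
                steal_outcome=outcomes[pos],
                delta_points=deltas[pos],
                perturbation=pert,
                points_after=points_after,
                below_threshold_flag=below,
                active=pl.active,
            ))
        # outcome page: each player sees the other group members' decisions
        for pos, idx in enumerate(group):
            own_attempt = 1 if actions[pos] == "steal" else 0
            session.policies[idx].observe(
                players[idx], n_attempts - own_attempt, cfg.group_size - 1)
    session.records.extend(records)
    return records


def run_session(
    config: GameConfig,
    players: list[PlayerState],
    policies: list,
    seed,
    starting_points_fn: Callable[[np.random.Generator], Sequence[int]],
    inactivity_prob: float = 0.0,
    session_seed_label: str = "",
) -> Session:
    """Run one full session: mock rounds, points reset, real rounds, payouts.

    ``seed`` may be an int or a :class:`numpy.random.SeedSequence`.  The
    number of real rounds R is drawn first (uniform on 8..16, or fixed at 12),
    then mock rounds are played on a throwaway allocation, points are reset to
    an independently drawn starting allocation, and R real rounds follow.
    ``starting_points_fn`` draws one allocation of ``set_size`` values and is
    called once for the mock phase and once for the real phase.
    """
    check_config(config)
    rng = np.random.default_rng(seed)
    session = Session(config=config, players=players, policies=policies,
                      session_seed=session_seed_label or str(seed),
                      inactivity_prob=inactivity_prob)

    n_real = draw_n_real_rounds(config, rng)
    session.n_real_rounds = n_real

    mock_start = starting_points_fn(rng)
    for p, pts in zip(players, mock_start):
        p.points = int(pts)
    for mock_i in range(config.n_mock_rounds):
        run_round(session, mock_i - config.n_mock_rounds + 1, rng)

    real_start = starting_points_fn(rng)
    for p, pts in zip(players, real_start):
        p.points = int(pts)
        p.below_round_count = 0
    for r in range(1, n_real + 1):
        run_round(session, r, rng)

    session.payouts = [
        settle_payout(p.points, p.below_round_count, p.threshold_active, config)
        for p in players
    ]
    return session
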