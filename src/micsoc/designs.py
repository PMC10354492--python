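"""The four study designs: starting allocations, condition assignment,
multi-set orchestration into one tidy dataset, and analysis exclusions.

Design summary:

* study 1 — every set in the threshold condition; everyone starts at 100
  points, exactly on the threshold, with per-round Gaussian shocks supplying
  the variation in who falls below.
* study 2 — as study 1 but half the sets (round-robin) get no threshold.
* study 3 — threshold presence and punishment severity (lenient/harsh) are
  crossed *within* each set, two players per cell; starting points are drawn
  i.i.d. from {180, 190, 200} so most players sit at or below the 200
  threshold.
* study 4 — threshold presence and starting-point inequality are crossed
  *between* sets (round-robin over the four cells); equal sets start everyone
  on 205, unequal sets stratify exactly two players on each of
  {180, 190, 220, 230} (same mean, half the set below threshold).
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .agents import CNCutoffs, CN_DEFAULT_CUTOFFS, PolicyParams, build_policy, \
    get_preset, make_population
from .config import ConfigError, GameConfig, study_config
from .engine import RECORD_FIELDS, PlayerState, run_session


def draw_starting_points(study: int, inequality_condition: str,
                         rng: np.random.Generator, n: int = 8) -> np.ndarray:
    """Draw one starting allocation of energy points for a set."""
    if study in (1, 2):
        return np.full(n, 100, dtype=int)
    if study == 3:
        return rng.choice([180, 190, 200], size=n)
    if study == 4:
        if inequality_condition == "equal":
            return np.full(n, 205, dtype=int)
        if inequality_condition == "unequal":
            if n != 8:
                raise ConfigError("study-4 unequal allocation is defined for 8 players")
            values = np.repeat([180, 190, 220, 230], 2)
            return rng.permutation(values)
        raise ConfigError(
            f"study 4 requires inequality condition 'equal' or 'unequal', "
            f"got {inequality_condition!r}")
    raise ConfigError(f"unknown study id {study!r}")


def assign_conditions(study: int, set_index: int,
                      rng: np.random.Generator) -> list[dict]:
    """Per-player condition labels for one set.

    Between-set factors are allocated deterministically round-robin by set
    index (guaranteeing exact halves for even set counts); study 3's
    within-set cells are balanced at two players per cell and shuffled over
    seats.
    """
    base = dict(punishment_level="n/a", inequality_condition="n/a")
    if study == 1:
        return [dict(base, threshold_active=True) for _ in range(8)]
    if study == 2:
        thr = set_index % 2 == 0
        return [dict(base, threshold_active=thr) for _ in range(8)]
    if study == 3:
        cells = [(thr, pun) for thr in (True, False)
                 for pun in ("lenient", "harsh")] * 2
        order = rng.permutation(8)
        out = []
        for seat in range(8):
            thr, pun = cells[order[seat]]
            out.append(dict(threshold_active=thr, punishment_level=pun,
                            inequality_condition="n/a"))
        return out
    if study == 4:
        ineq = "equal" if (set_index // 2) % 2 == 0 else "unequal"
        thr = set_index % 2 == 0
        return [dict(threshold_active=thr, punishment_level="lenient",
                     inequality_condition=ineq) for _ in range(8)]
    raise ConfigError(f"unknown study id {study!r}")


def _session_frame(session) -> pd.DataFrame:
    rows = [{f: getattr(r, f) for f in RECORD_FIELDS} for r in session.records]
    return pd.DataFrame(rows, columns=list(RECORD_FIELDS))


def run_study(
    study: int,
    n_sets: int,
    policy="paper_like",
    master_seed: int = 0,
    cutoffs: CNCutoffs = CN_DEFAULT_CUTOFFS,
    inactivity_prob: float = 0.0,
    config_override: Optional[GameConfig] = None,
) -> pd.DataFrame:
    """Simulate ``n_sets`` independent sessions and concatenate their logs.

    ``policy`` is a preset name (``paper_like``, ``null_agent``,
    ``cn_threshold``) or a :class:`PolicyParams` object.  Each session runs on
    an independent substream spawned from the master seed by set index
    (``SeedSequence(master_seed).spawn(n_sets)``), so any prefix of sets is
    reproducible regardless of ``n_sets``.
    """
    if n_sets < 1:
        raise ConfigError("n_sets must be >= 1")
    config, _scheme = study_config(study)
    if config_override is not None:
        config = config_override
    params = get_preset(policy) if isinstance(policy, str) else policy.validate()
    include_steal_rating = study in (3, 4)

    master = np.random.SeedSequence(master_seed)
    children = master.spawn(n_sets)
    frames = []
    for set_index in range(n_sets):
        assign_seed, session_seed = children[set_index].spawn(2)
        assign_rng = np.random.default_rng(assign_seed)
        conditions = assign_conditions(study, set_index, assign_rng)
        intercepts = make_population(8, params, assign_rng)
        ineq = conditions[0]["inequality_condition"]
        players = [
            PlayerState(
                player_id=set_index * 8 + seat,
                set_id=set_index,
                threshold_active=conditions[seat]["threshold_active"],
                punishment_level=conditions[seat]["punishment_level"],
                inequality_condition=conditions[seat]["inequality_condition"],
                latent_trust=params.initial_trust,
                random_intercept=float(intercepts[seat]),
            )
            for seat in range(8)
        ]
        policies = [
            build_policy(policy, config.threshold_level, include_steal_rating,
                         cutoffs)
            for _ in range(8)
        ]
        session = run_session(
            config, players, policies, session_seed,
            starting_points_fn=lambda rng, ineq=ineq: draw_starting_points(
                study, ineq, rng),
            inactivity_prob=inactivity_prob,
            session_seed_label=f"{master_seed}:{set_index}",
        )
        frames.append(_session_frame(session))
    return pd.concat(frames, ignore_index=True)


def apply_exclusions(dataset: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Drop mock rounds and players who completed fewer than 4 real rounds.

    A round counts as completed only if the player was still active.  Returns
    the filtered analysis view and a report of excluded player ids.
    """
    if dataset.empty:
        return dataset.copy(), {"excluded_players": [], "n_rows_removed": 0}
    real = dataset[dataset["round_index"] >= 1]
    completed = real[real["active"].astype(bool)].groupby("player_id").size()
    all_players = dataset["player_id"].unique()
    excluded = sorted(
        int(p) for p in all_players if completed.get(p, 0) < 4)
    keep = real[~real["player_id"].isin(excluded)].reset_index(drop=True)
    report = {
        "excluded_players": excluded,
        "n_rows_removed": int(len(dataset) - len(keep)),
    }
    return keep, report
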