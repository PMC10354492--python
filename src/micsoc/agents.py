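"""Synthetic participants.

Two policy families generate session data with the statistical structure the
analysis chain assumes:

* :class:`GenerativePolicy` — steal decisions follow a logistic model with a
  below-threshold effect, a threshold-condition interaction, a punishment
  effect, a round trend and a player-level random intercept; conditional on
  not stealing, the cooperate/work-alone choice is logistic in latent trust.
  Because it is exactly the model family the fitters estimate, it is the
  substrate for parameter recovery and null calibration.
* :class:`ThresholdPolicy` — a hard-threshold heuristic: steal with one
  probability when desperate (below the threshold in a threshold condition),
  another when not, otherwise cooperate iff latent trust clears a cutoff.

Latent trust lives on [0, 1] and evolves by an exponential moving average of
the observed share of non-stealers in the player's own interaction group; the
1-10 questionnaire ratings are a noisy affine readout of the latent state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .config import ConfigError
from .engine import PlayerState


@dataclass(frozen=True)
class PolicyParams:
    """Generative coefficients (log-odds) and trust-dynamics parameters."""

    beta0_steal: float = -2.2       # baseline steal log-odds (~10% baseline rate)
    beta_below: float = 0.54        # below-threshold effect absent a threshold (OR ~1.7)
    beta_thr_interact: float = 0.66 # extra below effect under a threshold (OR ~1.9)
    beta_punish: float = -0.63      # harsh-punishment effect (OR ~0.5)
    beta_round: float = 0.0         # per-round log-odds trend
    sigma_id: float = 1.0           # sd of player random intercepts
    gamma0: float = -1.0            # cooperate-vs-work-alone intercept
    gamma_trust: float = 3.0        # cooperate-vs-work-alone trust slope
    lambda_trust: float = 0.3       # EMA trust learning rate, in [0, 1]
    rho_ratings: float = 0.44       # |corr| target between the two ratings
    rating_noise_sd: float = 0.15   # sd of rating read-out noise (latent scale)
    initial_trust: float = 0.8      # latent trust at session start

    def validate(self) -> "PolicyParams":
        if self.sigma_id < 0:
            raise ConfigError("sigma_id must be >= 0")
        if not 0.0 <= self.lambda_trust <= 1.0:
            raise ConfigError("lambda_trust must lie in [0, 1]")
        if not -1.0 <= self.rho_ratings <= 1.0:
            raise ConfigError("rho_ratings must lie in [-1, 1]")
        return self


@dataclass(frozen=True)
class CNCutoffs:
    """Cutoffs for the hard-threshold heuristic policy."""

    tau: float = 0.5            # trust cutoff for cooperating
    p_steal_below: float = 0.15
    p_steal_above: float = 0.02


#: Named parameter presets.  ``null_agent`` has no effects at all (for
#: calibration); ``paper_like`` encodes a positive below-threshold effect that
#: roughly doubles again in threshold conditions, with a mild deterrent effect
#: of harsh punishment; ``cn_threshold`` selects the heuristic policy.
PRESETS: dict[str, PolicyParams] = {
    "paper_like": PolicyParams(),
    "null_agent": PolicyParams(
        beta0_steal=-2.2, beta_below=0.0, beta_thr_interact=0.0,
        beta_punish=0.0, beta_round=0.0, sigma_id=0.5,
        gamma0=0.0, gamma_trust=0.0,
    ),
    "cn_threshold": PolicyParams(),
}

CN_DEFAULT_CUTOFFS = CNCutoffs()


def get_preset(name: str) -> PolicyParams:
    if name not in PRESETS:
        raise ConfigError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return PRESETS[name]


def params_to_yaml_dict(params: PolicyParams) -> dict:
    import dataclasses
    return dataclasses.asdict(params)


def params_from_dict(d: dict) -> PolicyParams:
    return replace(PolicyParams(), **d).validate()


def make_population(n_players: int, params: PolicyParams,
                    rng: np.random.Generator, set_size: int = 8) -> np.ndarray:
    """Sample i.i.d. Normal(0, sigma_id^2) random intercepts for a population."""
    if n_players % set_size != 0:
        raise ConfigError(
            f"n_players ({n_players}) must be a multiple of set_size ({set_size})")
    return rng.normal(0.0, params.sigma_id, size=n_players)


def _sigmoid(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def steal_logit(state: PlayerState, round_index: int, params: PolicyParams,
                threshold_level: int) -> float:
    """Linear predictor of the generative steal model for one decision."""
    below = 1.0 if state.points < threshold_level else 0.0
    thr = 1.0 if state.threshold_active else 0.0
    harsh = 1.0 if state.punishment_level == "harsh" else 0.0
    return (params.beta0_steal
            + params.beta_below * below
            + params.beta_thr_interact * below * thr
            + params.beta_punish * harsh
            + params.beta_round * round_index
            + state.random_intercept)


def update_trust(latent_trust: float, n_stealers_observed: int,
                 n_others: int, params: PolicyParams) -> float:
    """EMA trust update from the observed share of non-stealing others."""
    if n_others <= 0:
        return latent_trust
    signal = 1.0 - n_stealers_observed / n_others
    new = (1.0 - params.lambda_trust) * latent_trust + params.lambda_trust * signal
    return min(1.0, max(0.0, new))


def emit_ratings(latent_trust: float, params: PolicyParams,
                 rng: np.random.Generator,
                 include_steal_rating: bool) -> tuple[int, int | None]:
    """Noisy 1-10 read-outs of latent trust (and, studies 3-4, steal likelihood).

    The two ratings' read-out noises are negatively correlated at
    ``rho_ratings`` so that, at a given latent trust, the trust and
    steal-likelihood ratings correlate at about that magnitude (10-level
    rounding attenuates it slightly).
    """
    sd = params.rating_noise_sd
    z1 = rng.standard_normal()
    t = min(1.0, max(0.0, latent_trust + sd * z1))
    trust_rating = int(round(1 + 9 * t))
    if not include_steal_rating:
        return trust_rating, None
    rho = params.rho_ratings
    z2 = -rho * z1 + math.sqrt(max(0.0, 1.0 - rho * rho)) * rng.standard_normal()
    s = min(1.0, max(0.0, (1.0 - latent_trust) + sd * z2))
    steal_rating = int(round(1 + 9 * s))
    return trust_rating, steal_rating


class _BasePolicy:
    """Shared ratings/trust machinery for both policy families."""

    def __init__(self, params: PolicyParams, threshold_level: int,
                 include_steal_rating: bool):
        self.params = params.validate()
        self.threshold_level = threshold_level
        self.include_steal_rating = include_steal_rating

    def ratings(self, state: PlayerState, rng: np.random.Generator):
        return emit_ratings(state.latent_trust, self.params, rng,
                            self.include_steal_rating)

    def observe(self, state: PlayerState, n_stealers_observed: int,
                n_others: int) -> None:
        state.latent_trust = update_trust(
            state.latent_trust, n_stealers_observed, n_others, self.params)


class GenerativePolicy(_BasePolicy):
    """Logistic generative policy (the model family the fitters estimate)."""

    def decide(self, state: PlayerState, round_index: int,
               rng: np.random.Generator) -> str:
        p_steal = _sigmoid(steal_logit(state, round_index, self.params,
                                       self.threshold_level))
        if rng.random() < p_steal:
            return "steal"
        p_coop = _sigmoid(self.params.gamma0
                          + self.params.gamma_trust * state.latent_trust)
        return "cooperate" if rng.random() < p_coop else "work_alone"


class ThresholdPolicy(_BasePolicy):
    """Hard-threshold heuristic: steal when desperate, else trust-gated."""

    def __init__(self, params: PolicyParams, threshold_level: int,
                 include_steal_rating: bool,
                 cutoffs: CNCutoffs = CN_DEFAULT_CUTOFFS):
        super().__init__(params, threshold_level, include_steal_rating)
        self.cutoffs = cutoffs

    def decide(self, state: PlayerState, round_index: int,
               rng: np.random.Generator) -> str:
        c = self.cutoffs
        desperate = state.threshold_active and state.points < self.threshold_level
        p_steal = c.p_steal_below if desperate else c.p_steal_above
        if rng.random() < p_steal:
            return "steal"
        return "cooperate" if state.latent_trust >= c.tau else "work_alone"


def build_policy(preset_or_params, threshold_level: int,
                 include_steal_rating: bool,
                 cutoffs: CNCutoffs = CN_DEFAULT_CUTOFFS):
    """Instantiate one policy from a preset name or a PolicyParams object."""
    if isinstance(preset_or_params, str):
        params = get_preset(preset_or_params)
        if preset_or_params == "cn_threshold":
            return ThresholdPolicy(params, threshold_level,
                                   include_steal_rating, cutoffs)
        return GenerativePolicy(params, threshold_level, include_steal_rating)
    return GenerativePolicy(preset_or_params, threshold_level,
                            include_steal_rating)
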