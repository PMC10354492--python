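"""Savage-Dickey Bayes factors and evidence-strength categories.

For a point null H0: theta = 0 nested in a model with prior theta ~
N(0, prior_sd^2), the Bayes factor in favour of a nonzero effect is the
ratio of prior to (approximate Gaussian) posterior density at zero.  Evidence
strength is labelled on the conventional 1 / 3 / 10 / 30 / 100 ladder
(anecdotal / moderate / strong / very strong / extreme), with reciprocal
bands reading as evidence for the null.
"""

from __future__ import annotations

import math

_LOG2PI = math.log(2.0 * math.pi)


def _norm_logpdf(x: float, mean: float, sd: float) -> float:
    z = (x - mean) / sd
    return -0.5 * z * z - math.log(sd) - 0.5 * _LOG2PI


def savage_dickey_bf(posterior_mean: float, posterior_sd: float,
                     prior_sd: float = 1.0) -> float:
    """Bayes factor for a nonzero effect: prior / posterior density at 0."""
    if posterior_sd <= 0 or prior_sd <= 0:
        raise ValueError("standard deviations must be positive")
    log_bf = _norm_logpdf(0.0, 0.0, prior_sd) \
        - _norm_logpdf(0.0, posterior_mean, posterior_sd)
    if log_bf > 700:
        return math.inf
    return math.exp(log_bf)


_BANDS = [(3.0, "anecdotal"), (10.0, "moderate"), (30.0, "strong"),
          (100.0, "very strong"), (math.inf, "extreme")]


def bf_band(bf: float) -> tuple[str, str]:
    """Return (strength, direction) with direction in {effect, null, none}."""
    if bf <= 0:
        raise ValueError("Bayes factor must be positive")
    if bf == 1.0:
        return "none", "none"
    direction = "effect" if bf > 1.0 else "null"
    mag = bf if bf > 1.0 else 1.0 / bf
    for bound, label in _BANDS:
        if mag < bound:
            return label, direction
    return "extreme", direction  # pragma: no cover


def categorize_bf(bf: float) -> str:
    """Human-readable evidence label, e.g. ``"strong supporting evidence"``."""
    strength, direction = bf_band(bf)
    if direction == "none":
        return "no evidence"
    if direction == "effect":
        return f"{strength} supporting evidence"
    return f"{strength} evidence for null"


def bf_display(bf: float) -> str:
    """Display string for a Bayes factor, capped at ``"> 1000"``."""
    if bf > 1000.0:
        return "> 1000"
    return f"{bf:.2f}"
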