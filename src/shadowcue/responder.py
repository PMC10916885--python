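"""Synthetic observer with known ground-truth cue weight.

The responder answers the congruent/incongruent question through the same
cue-combination machinery as the observer model, softened by logistic
decision noise in the incongruency domain: given the pooled incongruency
value ``v`` (degrees) at its current weight ``w(t)``, it answers
"incongruent" with probability sigma((v - 45) / tau).  As tau -> 0 this
recovers the model's hard 45-degree rule.  Lapses produce a fair coin flip,
and a small rate of invalid (missed) responses emulates the 1-second
response window.  An optional linear drift schedule on ``w`` emulates the
minutes-long reweighting seen when shadows are unreliable or absent.

Memory-task outcomes are Bernoulli with a fixed accuracy (0.5 = chance on
the two-alternative box-displacement question, ~0.75 = the threshold regime
of the dual task).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .observer import (
    DECISION_THRESHOLD_DEG,
    ModelTrialInput,
    RESPONSE_CONGRUENT,
    RESPONSE_INCONGRUENT,
    pooled_incongruency,
)

RESPONSE_INVALID = "invalid"
MEMORY_CORRECT = "correct"
MEMORY_INCORRECT = "incorrect"


@dataclass(frozen=True)
class ResponderParams:
    """Ground-truth parameters of one synthetic observer."""

    w_true: float = 0.5
    tau: float = 8.0  # deg; logistic softness of the 45-degree rule
    lapse_rate: float = 0.02
    invalid_rate: float = 0.03
    memory_accuracy: float = 0.75
    # optional linear drift: (w_start, w_end, onset_time_s)
    w_drift: Optional[tuple[float, float, float]] = None

    def __post_init__(self):
        for name in ("w_true", "lapse_rate", "invalid_rate", "memory_accuracy"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.tau < 0:
            raise ValueError("tau must be nonnegative")


def w_schedule(t: float, params: ResponderParams, block_duration: float = 300.0) -> float:
    """Cue weight at time ``t`` seconds into the block.

    Constant ``w_true`` without drift; otherwise linear interpolation from
    ``w_start`` to ``w_end`` between the onset time and the block end,
    clipped to [0, 1].
    """
    if params.w_drift is None:
        return params.w_true
    w_start, w_end, onset = params.w_drift
    if t <= onset:
        return float(np.clip(w_start, 0.0, 1.0))
    span = max(block_duration - onset, 1e-9)
    frac = min((t - onset) / span, 1.0)
    return float(np.clip(w_start + frac * (w_end - w_start), 0.0, 1.0))


def _coin(rng: np.random.Generator) -> str:
    return RESPONSE_INCONGRUENT if rng.random() < 0.5 else RESPONSE_CONGRUENT


def sensory_response(
    trial: ModelTrialInput,
    params: ResponderParams,
    t: float = 0.0,
    seed: int | np.random.Generator = 0,
    block_duration: float = 300.0,
) -> str:
    """One simulated response: congruent, incongruent or invalid.

    Model-excluded trials are answered by a coin flip (a human observer
    always has a decision variable even when the model does not).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if rng.random() < params.invalid_rate:
        return RESPONSE_INVALID
    if rng.random() < params.lapse_rate:
        return _coin(rng)
    w = w_schedule(t, params, block_duration)
    v = pooled_incongruency(trial, w)
    if np.isnan(v):
        return _coin(rng)
    if params.tau == 0:
        return RESPONSE_INCONGRUENT if v > DECISION_THRESHOLD_DEG else RESPONSE_CONGRUENT
    p_inc = 1.0 / (1.0 + np.exp(-(v - DECISION_THRESHOLD_DEG) / params.tau))
    return RESPONSE_INCONGRUENT if rng.random() < p_inc else RESPONSE_CONGRUENT


def memory_response(params: ResponderParams, seed: int | np.random.Generator = 0) -> str:
    """Two-alternative box-displacement outcome: Bernoulli(memory_accuracy)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return MEMORY_CORRECT if rng.random() < params.memory_accuracy else MEMORY_INCORRECT
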