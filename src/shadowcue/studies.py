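"""End-to-end simulation studies.

Two study designs are packaged here so tests, scripts and users run the
same code:

``parameter_recovery``
    Validates the cue-weight fit: a bank of fully rendered pipeline trials
    (scene -> insertion -> probe -> model statistics) is built once; each
    replicate draws trials from the bank (with replacement, stratified so a
    minimum fraction carries cue conflict), generates fresh responses from
    a responder with known ``w_true``, and refits ``w``.

``two_cohort_study``
    The qualitative signature of shadow-driven reweighting: a "reliable"
    cohort holds ``w = 0.45`` for the whole block while an "unreliable"
    cohort drifts linearly from 0.45 to 0.75, emulating the minutes-long
    departure of the absent/unreliable configurations.  Early in the block
    the two cohorts are indistinguishable (near-zero differential
    sensitivity); late in the block only the drifted cohort shows a
    positive image-minus-object d' difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .observer import ModelTrialInput, fit_w
from .responder import RESPONSE_INVALID, ResponderParams, sensory_response
from .session import BlockConfig, SessionConfig, SessionLog, run_block, run_session


@dataclass
class TrialBank:
    """Pooled differential statistics of rendered, non-excluded trials."""

    image_diff: np.ndarray
    object_diff: np.ndarray

    @property
    def conflict(self) -> np.ndarray:
        """Trials whose model decision depends on w (the 45-degree rule
        flips somewhere inside [0, 1])."""
        lo = np.minimum(self.image_diff, self.object_diff)
        hi = np.maximum(self.image_diff, self.object_diff)
        return (lo <= 45.0) & (hi > 45.0)

    def __len__(self) -> int:
        return self.image_diff.size


def build_trial_bank(
    n_blocks: int = 12, shadow_mode: str = "reliable", seed: int = 0
) -> TrialBank:
    """Render ``n_blocks`` full blocks and pool included-trial statistics."""
    di, do = [], []
    for b in range(n_blocks):
        block_seed = int(
            np.random.SeedSequence([seed, 0xBA2, b]).generate_state(1)[0] % (2**31)
        )
        log = run_block(
            BlockConfig(shadow_mode=shadow_mode, block_id=f"bank_b{b:02d}"),
            ResponderParams(),
            block_seed,
        )
        for t in log.trials:
            if not t.model_excluded:
                di.append(t.model_image_diff)
                do.append(t.model_object_diff)
    return TrialBank(image_diff=np.array(di), object_diff=np.array(do))


def draw_recovery_trials(
    bank: TrialBank,
    n_trials: int,
    params: ResponderParams,
    rng: np.random.Generator,
    min_conflict_fraction: float = 0.30,
) -> list[ModelTrialInput]:
    """Sample trials from the bank and answer them with the responder.

    Sampling is stratified so at least ``min_conflict_fraction`` of the
    drawn trials carry cue conflict (without conflict the data are
    uninformative about w).
    """
    conflict_idx = np.flatnonzero(bank.conflict)
    other_idx = np.flatnonzero(~bank.conflict)
    if conflict_idx.size == 0:
        raise ValueError("trial bank carries no cue-conflict trials")
    natural = conflict_idx.size / len(bank)
    p_conflict = max(natural, min_conflict_fraction)
    n_conflict = int(round(p_conflict * n_trials))
    idx = np.concatenate(
        [
            rng.choice(conflict_idx, n_conflict, replace=True),
            rng.choice(other_idx if other_idx.size else conflict_idx,
                       n_trials - n_conflict, replace=True),
        ]
    )
    rng.shuffle(idx)
    trials = []
    for i in idx:
        t = ModelTrialInput.from_statistics(bank.image_diff[i], bank.object_diff[i])
        resp = sensory_response(t, params, t=0.0, seed=rng)
        if resp == RESPONSE_INVALID:
            continue
        t.human_response = resp
        trials.append(t)
    return trials


def parameter_recovery(
    w_true_values=(0.2, 0.5, 0.8),
    n_replicates: int = 20,
    n_trials: int = 3000,
    bank: TrialBank | None = None,
    bank_blocks: int = 12,
    responder_kwargs: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Median-absolute-error assessment of the cue-weight fit.

    Returns a tidy frame with one row per (w_true, replicate) holding the
    fitted ``w_best``.
    """
    if bank is None:
        bank = build_trial_bank(n_blocks=bank_blocks, seed=seed)
    responder_kwargs = responder_kwargs or {}
    rows = []
    for wi, w_true in enumerate(w_true_values):
        for rep in range(n_replicates):
            rng = np.random.default_rng(np.random.SeedSequence([seed, 0x2EC, wi, rep]))
            params = ResponderParams(w_true=w_true, invalid_rate=0.0, **responder_kwargs)
            trials = draw_recovery_trials(bank, n_trials, params, rng)
            est = fit_w(trials, n_bootstrap=1, seed=int(rng.integers(2**31)))
            rows.append({"w_true": w_true, "replicate": rep, "w_best": est.w_best})
    return pd.DataFrame(rows)


def two_cohort_study(
    n_observers: int = 11,
    blocks_per_mode: int = 2,
    w_stationary: float = 0.45,
    w_drift: tuple[float, float, float] = (0.45, 0.75, 0.0),
    seed: int = 0,
) -> SessionLog:
    """Simulate the reliable-vs-unreliable cohort comparison.

    Every observer contributes ``blocks_per_mode`` reliable-shadow blocks
    (stationary cue weight) and the same number of unreliable-shadow blocks
    (cue weight drifting toward image cues over the block).
    """
    observers = [f"obs{i:02d}" for i in range(n_observers)]
    responders = {
        obs: {
            "reliable": ResponderParams(w_true=w_stationary),
            "unreliable": ResponderParams(w_true=w_drift[0], w_drift=w_drift),
        }
        for obs in observers
    }
    config = SessionConfig(
        observers=observers,
        blocks_per_mode=blocks_per_mode,
        shadow_modes=("reliable", "unreliable"),
        seed=seed,
        responders=responders,
    )
    return run_session(config)
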