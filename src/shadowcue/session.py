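"""Block and session orchestration.

A block is 100 sensory trials (~5 min): probes separated by inter-trial
intervals uniform on [2.0, 3.6] s are inserted at image- or object-driven
points (50/50), with congruent/incongruent signal gratings (50/50), while
the simulated observer walks the room.  Four consecutive incorrect or
invalid responses scramble the room (fresh box configuration).  After trial
100, one box is displaced to the spare (11th) specification's location, the
memory question is answered, and the score is computed: one point per
correct sensory response, doubled on a correct memory answer, halved on an
incorrect one.  Sessions interleave blocks of the three shadow
configurations in per-observer pseudo-random (seeded, balanced) order.

Every trial record carries, alongside the behavioral fields, the model's
pooled image/object differential values for that trial, which are the
sufficient statistics the cue-weight fit consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .observer import ModelTrialInput, trial_statistics
from .probe import (
    DegenerateMapError,
    ProbeBoundsError,
    composite_probe,
    make_probe_spec,
    render_probe,
    select_insertion_point,
    sobel_edge_map,
)
from .responder import (
    MEMORY_CORRECT,
    RESPONSE_INVALID,
    ResponderParams,
    memory_response,
    sensory_response,
)
from .scene import (
    CameraWalk,
    RoomParams,
    RoomSpec,
    block_average,
    depth_capture,
    displace_box_to_spare,
    generate_room,
    light_schedule,
    render_snapshot,
    scramble_room,
)

PX_PER_DEGREE = 2.0  # 90 px / 45 deg
SUPERSAMPLE = 2  # capture emulation: render fine, downsample to analysis res


@dataclass
class TrialRecord:
    observer_id: str
    block_id: str
    trial_index: int  # 1-based, 1..100
    t_probe: float  # seconds from block start
    shadow_mode: str
    insertion_type: str
    insertion_col: int
    insertion_row: int
    local_orientation: float
    congruent: bool
    response: str  # congruent | incongruent | invalid
    correct: Optional[bool]  # None iff response invalid
    consecutive_errors_after: int
    model_image_diff: float  # pooled differential stats (NaN if excluded)
    model_object_diff: float
    model_excluded: bool


@dataclass
class BlockConfig:
    shadow_mode: str
    observer_id: str = "obs0"
    block_id: str = "block0"
    n_trials: int = 100
    iti_range: tuple[float, float] = (2.0, 3.6)
    scramble_threshold: int = 4
    room_params: RoomParams = field(default_factory=RoomParams)
    # noise calibrated so the synthetic observer sits at threshold (d' ~ 1),
    # mirroring the per-participant noise adjustment of the original task;
    # the 3:1 mean:SD ratio of the nominal 3%/1% values is preserved
    probe_noise_mean: float = 0.15
    probe_noise_sd: float = 0.05
    probe_signal_contrast: float = 0.40
    memory_only_duration: float = 30.0


@dataclass
class BlockLog:
    config: BlockConfig
    trials: list[TrialRecord]
    room_history: list[RoomSpec]
    memory_outcome: str
    score: float

    @property
    def n_correct(self) -> int:
        return sum(1 for t in self.trials if t.correct is True)


@dataclass
class SessionConfig:
    observers: list[str]
    blocks_per_mode: int = 2
    shadow_modes: tuple[str, ...] = ("reliable", "absent", "unreliable")
    seed: int = 0
    responders: dict = field(default_factory=dict)  # observer -> mode -> ResponderParams
    room_params: RoomParams = field(default_factory=RoomParams)


@dataclass
class SessionLog:
    config: SessionConfig
    blocks: list[BlockLog]

    @property
    def records(self) -> list[TrialRecord]:
        return [t for b in self.blocks for t in b.trials]


class BlockError(RuntimeError):
    """A block could not be completed; carries a diagnostic message."""


def _free_pose(room: RoomSpec, walk: CameraWalk, t: float):
    """Walker pose at time t, advanced in 0.1 s steps out of any box the
    path happens to cross (boxes may have moved under the walker after a
    scramble)."""
    for k in range(200):
        pose = walk.pose_at(t + 0.1 * k)
        x, y, z = pose.position
        if not room.point_inside_any_box(x, y, z):
            return pose
    raise BlockError("walker could not find a box-free pose")


def _insert_and_composite(snapshot, depth_img, insertion_type, config, rng):
    """Insertion + probe synthesis with retry on rare degenerate outcomes
    (undefined driver orientation at the argmax, or an argmax too close to
    the border for full probe support).

    The probe patch is rendered and composited at the capture resolution,
    then downsampled with the rest of the frame, mirroring how the inserted
    probe reaches the analysis maps through the capture pipeline.
    """
    image_edges = sobel_edge_map(snapshot.image_map)
    object_edges = sobel_edge_map(depth_img)
    ss = snapshot.supersample
    hi = snapshot.image_hi if ss > 1 else snapshot.image_map
    last_err = None
    for _ in range(10):
        try:
            ins = select_insertion_point(
                image_edges, object_edges, insertion_type, seed=rng, border_margin=6
            )
            congruent = bool(rng.random() < 0.5)
            spec = make_probe_spec(
                congruent,
                ins.local_orientation,
                noise_mean=config.probe_noise_mean,
                noise_sd=config.probe_noise_sd,
                signal_contrast=config.probe_signal_contrast,
                seed=rng,
            )
            patch, window = render_probe(spec, PX_PER_DEGREE * ss)
            col, row = ins.point
            hi_point = (col * ss + (ss - 1) // 2, row * ss + (ss - 1) // 2)
            m_probe = block_average(
                composite_probe(hi, patch, window, hi_point), ss
            )
            # the 3x3 pooling box must also have full support
            h, w = snapshot.image_map.shape
            if not (1 <= row < h - 1 and 1 <= col < w - 1):
                raise ProbeBoundsError("pooling box exits the grid")
            return ins, spec, m_probe
        except (DegenerateMapError, ProbeBoundsError) as err:
            last_err = err
    raise BlockError(f"probe insertion failed repeatedly: {last_err}")


def run_block(config: BlockConfig, responder: ResponderParams, seed: int) -> BlockLog:
    """Simulate one 100-trial block; fully deterministic for a fixed seed."""
    ss = np.random.SeedSequence([seed, 0xB10C])
    room_seed, walk_seed, light_seed, stream_seed = [
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)
    ]
    rng = np.random.default_rng(np.random.SeedSequence([stream_seed]))
    room = generate_room(room_seed, config.room_params)
    walk = CameraWalk(room, walk_seed)
    room_history = [room]
    block_duration = config.n_trials * sum(config.iti_range) / 2.0

    trials: list[TrialRecord] = []
    t = 0.0
    consecutive = 0
    scramble_count = 0
    for i in range(1, config.n_trials + 1):
        t += rng.uniform(*config.iti_range)
        light = light_schedule(config.shadow_mode, i, light_seed)
        insertion_type = "image_driven" if rng.random() < 0.5 else "object_driven"
        # a view hugging a single surface can be featureless; the walker
        # simply keeps moving until the scene supports an insertion
        for retry in range(40):
            pose = _free_pose(room, walk, t)
            snapshot = render_snapshot(
                room, pose, light, trial_index=i, supersample=SUPERSAMPLE
            )
            depth_img = depth_capture(snapshot.depth_map)
            try:
                ins, spec, m_probe = _insert_and_composite(
                    snapshot, depth_img, insertion_type, config, rng
                )
                break
            except BlockError:
                t += 0.5
        else:
            raise BlockError("no insertable view found along the walk")
        trial_input = ModelTrialInput(
            m_image=snapshot.image_map,
            m_depth=depth_img,
            m_probe=m_probe,
            probe_point=ins.point,
        )
        response = sensory_response(
            trial_input, responder, t=t, seed=rng, block_duration=block_duration
        )
        if response == RESPONSE_INVALID:
            correct = None
        else:
            expected = "congruent" if spec.congruent else "incongruent"
            correct = response == expected
        if correct:
            consecutive = 0
        else:
            consecutive += 1
        stats = trial_statistics(trial_input)
        trials.append(
            TrialRecord(
                observer_id=config.observer_id,
                block_id=config.block_id,
                trial_index=i,
                t_probe=t,
                shadow_mode=config.shadow_mode,
                insertion_type=insertion_type,
                insertion_col=ins.point[0],
                insertion_row=ins.point[1],
                local_orientation=ins.local_orientation,
                congruent=spec.congruent,
                response=response,
                correct=correct,
                consecutive_errors_after=consecutive,
                model_image_diff=stats.image_diff,
                model_object_diff=stats.object_diff,
                model_excluded=stats.excluded,
            )
        )
        if consecutive >= config.scramble_threshold and i < config.n_trials:
            scramble_count += 1
            room = scramble_room(
                room, int(np.random.SeedSequence([room_seed, scramble_count]).generate_state(1)[0] % (2**31))
            )
            room_history.append(room)
            consecutive = 0

    final_room, _ = displace_box_to_spare(room, rng)
    room_history.append(final_room)
    outcome = memory_response(responder, rng)
    n_correct = sum(1 for tr in trials if tr.correct is True)
    score = n_correct * 2.0 if outcome == MEMORY_CORRECT else n_correct / 2.0
    return BlockLog(
        config=config,
        trials=trials,
        room_history=room_history,
        memory_outcome=outcome,
        score=score,
    )


def run_memory_only_block(
    config: BlockConfig, responder: ResponderParams, seed: int
) -> BlockLog:
    """A 30-second block without probes: walk, displace one box, answer the
    memory question.  Score degenerates to the memory outcome alone."""
    ss = np.random.SeedSequence([seed, 0x3E30])
    room_seed, walk_seed, stream_seed = [
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)
    ]
    rng = np.random.default_rng(np.random.SeedSequence([stream_seed]))
    room = generate_room(room_seed, config.room_params)
    walk = CameraWalk(room, walk_seed, duration=config.memory_only_duration + 5.0)
    _ = walk.pose_at(config.memory_only_duration)  # end-of-block viewpoint
    final_room, _ = displace_box_to_spare(room, rng)
    outcome = memory_response(responder, rng)
    return BlockLog(
        config=config,
        trials=[],
        room_history=[room, final_room],
        memory_outcome=outcome,
        score=0.0,
    )


def block_order(modes: Sequence[str], blocks_per_mode: int, rng: np.random.Generator) -> list[str]:
    """Balanced pseudo-random order of block modes for one observer."""
    order = [m for m in modes for _ in range(blocks_per_mode)]
    rng.shuffle(order)
    return order


def run_session(config: SessionConfig) -> SessionLog:
    """Run every observer's blocks in balanced pseudo-random mode order."""
    blocks: list[BlockLog] = []
    for oi, obs in enumerate(config.observers):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5E5, oi]))
        order = block_order(config.shadow_modes, config.blocks_per_mode, rng)
        for bi, mode in enumerate(order):
            responder = config.responders.get(obs, {}).get(mode) if config.responders else None
            if responder is None:
                responder = ResponderParams()
            bcfg = BlockConfig(
                shadow_mode=mode,
                observer_id=obs,
                block_id=f"{obs}_b{bi:02d}_{mode}",
                room_params=config.room_params,
            )
            block_seed = int(
                np.random.SeedSequence([config.seed, 0xB5, oi, bi]).generate_state(1)[0]
                % (2**31)
            )
            blocks.append(run_block(bcfg, responder, block_seed))
    return SessionLog(config=config, blocks=blocks)
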