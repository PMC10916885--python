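"""Procedural virtual room and image/depth snapshot rendering.

The simulated world is a 6 x 6 x 3 m room whose interior surfaces carry a
high-contrast black/white zigzag wallpaper, furnished with 10 textured boxes
(an 11th box specification is kept uninstantiated as the target location for
the end-of-block memory probe).  Snapshots are rendered by a pinhole ray
caster directly at the analysis resolution of 90 x 100 pixels (width x
height), covering a 45 x 50 degree field of view, and consist of an aligned
luminance map and metric depth map.

Lighting follows three regimes: ``reliable`` (one directional light per
block, elevation 45 deg, random azimuth), ``unreliable`` (a fresh azimuth
before every probe) and ``absent`` (no directional term, ambient doubled to
compensate for the lost diffuse illumination).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

IMAGE_WIDTH = 90
IMAGE_HEIGHT = 100
FOV_WIDTH_DEG = 45.0
FOV_HEIGHT_DEG = 50.0

# Shading constants (dimensionless luminance factors; the original luminance
# calibration is explicitly approximate, so these are chosen to keep output
# in [0, 1] while letting ambient doubling roughly compensate for the mean
# diffuse contribution).
AMBIENT = 0.30
DIFFUSE = 0.60
ALBEDO_DARK = 0.10
ALBEDO_LIGHT = 0.90


class PlacementError(RuntimeError):
    """Raised when box placement constraints cannot be satisfied."""


class RenderError(RuntimeError):
    """Raised for degenerate viewpoints (e.g. camera inside a box)."""


@dataclass(frozen=True)
class BoxSpec:
    """One box: floor-plane center, footprint, height and yaw rotation."""

    center_xy: tuple[float, float]
    width: float
    length: float
    height: float
    rotation: float  # degrees about the vertical axis, in [0, 180)

    def validate(self, room_center: tuple[float, float], min_center_dist: float) -> None:
        if not (0.40 <= self.width <= 1.20 and 0.40 <= self.length <= 1.20):
            raise ValueError("box footprint outside 0.40-1.20 m range")
        if not (0.40 <= self.height <= 2.40):
            raise ValueError("box height outside 0.40-2.40 m range")
        if not (0.0 <= self.rotation < 180.0):
            raise ValueError("rotation must lie in [0, 180)")
        d = math.hypot(self.center_xy[0] - room_center[0], self.center_xy[1] - room_center[1])
        if d < min_center_dist - 1e-9:
            raise ValueError("box too close to room center")


@dataclass(frozen=True)
class RoomParams:
    """Generation constraints for the procedural room."""

    room_dims: tuple[float, float, float] = (6.0, 6.0, 3.0)
    n_specs: int = 11
    n_instantiated: int = 10
    min_center_dist: float = 0.80  # from room center
    min_separation: float = 0.80  # pairwise, center to center
    width_range: tuple[float, float] = (0.40, 1.20)
    length_range: tuple[float, float] = (0.40, 1.20)
    height_range: tuple[float, float] = (0.40, 2.40)
    wall_margin: float = 0.85  # keeps the largest rotated box inside the walls
    max_attempts: int = 10_000
    wall_stripe: float = 0.70  # m
    wall_turn: float = 1.50  # m between 90-degree direction changes


@dataclass
class RoomSpec:
    """Room geometry plus the 11 box specifications (10 instantiated)."""

    params: RoomParams
    boxes: list[BoxSpec]
    instantiated: list[bool]
    seed: int

    @property
    def room_dims(self) -> tuple[float, float, float]:
        return self.params.room_dims

    @property
    def instantiated_boxes(self) -> list[BoxSpec]:
        return [b for b, keep in zip(self.boxes, self.instantiated) if keep]

    @property
    def spare_box(self) -> BoxSpec:
        for b, keep in zip(self.boxes, self.instantiated):
            if not keep:
                return b
        raise ValueError("no spare box specification")

    def point_inside_any_box(self, x: float, y: float, z: float, margin: float = 0.0) -> bool:
        for b in self.instantiated_boxes:
            if z > b.height + margin:
                continue
            th = math.radians(b.rotation)
            dx, dy = x - b.center_xy[0], y - b.center_xy[1]
            lx = math.cos(th) * dx + math.sin(th) * dy
            ly = -math.sin(th) * dx + math.cos(th) * dy
            if abs(lx) <= b.width / 2 + margin and abs(ly) <= b.length / 2 + margin:
                return True
        return False

    def to_json(self) -> str:
        return json.dumps(
            {
                "params": asdict(self.params),
                "boxes": [asdict(b) for b in self.boxes],
                "instantiated": self.instantiated,
                "seed": self.seed,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "RoomSpec":
        d = json.loads(text)
        p = d["params"]
        for k in ("room_dims", "width_range", "length_range", "height_range"):
            p[k] = tuple(p[k])
        params = RoomParams(**p)
        boxes = [BoxSpec(center_xy=tuple(b.pop("center_xy")), **b) for b in d["boxes"]]
        return cls(params=params, boxes=boxes, instantiated=list(d["instantiated"]), seed=d["seed"])


@dataclass(frozen=True)
class LightState:
    """Directional light regime for one probe presentation."""

    mode: str  # reliable | unreliable | absent
    azimuth: Optional[float] = None  # degrees in [0, 360)
    elevation: Optional[float] = None  # degrees; 45 whenever directional
    ambient_gain: float = 1.0

    def __post_init__(self):
        if self.mode not in ("reliable", "unreliable", "absent"):
            raise ValueError(f"unknown light mode {self.mode!r}")
        if self.mode == "absent":
            if self.azimuth is not None or self.elevation is not None:
                raise ValueError("absent mode carries no directional term")
        else:
            if self.azimuth is None or self.elevation is None:
                raise ValueError("directional mode requires azimuth and elevation")

    def direction(self) -> np.ndarray:
        """Unit vector pointing from the scene toward the light."""
        az = math.radians(self.azimuth)
        el = math.radians(self.elevation)
        return np.array(
            [math.cos(el) * math.cos(az), math.cos(el) * math.sin(az), math.sin(el)]
        )


@dataclass(frozen=True)
class CameraPose:
    position: tuple[float, float, float]
    yaw: float  # degrees, 0 = +x, counterclockwise in the floor plane
    pitch: float  # degrees, positive = looking up


@dataclass
class SceneSnapshot:
    """Aligned luminance and metric depth maps with provenance.

    When rendered with ``supersample > 1`` the maps are block averages of a
    finer render (emulating the downsampling of a high-resolution capture to
    analysis resolution); ``image_hi`` then holds the full-resolution
    luminance so a probe can be composited before downsampling.
    """

    image_map: np.ndarray  # (100, 90) float in [0, 1]
    depth_map: np.ndarray  # (100, 90) float, meters, strictly positive
    pose: CameraPose
    light: LightState
    trial_index: int = 0
    supersample: int = 1
    image_hi: Optional[np.ndarray] = None


def block_average(arr: np.ndarray, factor: int) -> np.ndarray:
    """Average non-overlapping factor x factor blocks."""
    if factor == 1:
        return arr
    h, w = arr.shape
    return arr.reshape(h // factor, factor, w // factor, factor).mean(axis=(1, 3))


def depth_capture(depth_map: np.ndarray, levels: int = 256) -> np.ndarray:
    """Depth snapshot as an intensity image, the way a capture pipeline
    stores it: min-max normalized to [0, 1] and quantized to ``levels``
    gray levels (default 8-bit)."""
    lo, hi = float(depth_map.min()), float(depth_map.max())
    if hi - lo <= 0:
        return np.zeros_like(depth_map)
    n = (depth_map - lo) / (hi - lo)
    return np.round(n * (levels - 1)) / (levels - 1)


# ---------------------------------------------------------------------------
# Room generation


def generate_room(seed: int, params: RoomParams | None = None) -> RoomSpec:
    """Sequential rejection sampling of box placements.

    Boxes are placed one at a time; a candidate is rejected if its center is
    within 0.80 m of the room center or of a previously placed box.  Raises
    :class:`PlacementError` after ``max_attempts`` rejections for one box,
    which signals over-constrained parameters.
    """
    params = params or RoomParams()
    rng = np.random.default_rng(seed)
    W, L, _ = params.room_dims
    cx, cy = W / 2, L / 2
    lo_x, hi_x = params.wall_margin, W - params.wall_margin
    lo_y, hi_y = params.wall_margin, L - params.wall_margin
    centers: list[tuple[float, float]] = []
    boxes: list[BoxSpec] = []
    for _ in range(params.n_specs):
        for attempt in range(params.max_attempts):
            x = rng.uniform(lo_x, hi_x)
            y = rng.uniform(lo_y, hi_y)
            if math.hypot(x - cx, y - cy) < params.min_center_dist:
                continue
            if any(math.hypot(x - px, y - py) < params.min_separation for px, py in centers):
                continue
            break
        else:
            raise PlacementError(
                f"could not place box {len(boxes)} after {params.max_attempts} attempts"
            )
        box = BoxSpec(
            center_xy=(x, y),
            width=rng.uniform(*params.width_range),
            length=rng.uniform(*params.length_range),
            height=rng.uniform(*params.height_range),
            rotation=rng.uniform(0.0, 180.0),
        )
        box.validate((cx, cy), params.min_center_dist)
        centers.append((x, y))
        boxes.append(box)
    inst = [True] * params.n_instantiated + [False] * (params.n_specs - params.n_instantiated)
    return RoomSpec(params=params, boxes=boxes, instantiated=inst, seed=seed)


def scramble_room(room: RoomSpec, seed: int) -> RoomSpec:
    """Regenerate all box placements (room dims and textures unchanged)."""
    return generate_room(seed, room.params)


def displace_box_to_spare(room: RoomSpec, rng: np.random.Generator) -> tuple[RoomSpec, int]:
    """Move one randomly selected instantiated box to the spare (11th) spec's
    location, preserving its size and rotation.  Returns the new room and the
    index (within instantiated boxes) of the displaced box."""
    idx = int(rng.integers(room.params.n_instantiated))
    spare = room.spare_box
    moved = []
    k = 0
    for b, keep in zip(room.boxes, room.instantiated):
        if keep:
            if k == idx:
                b = BoxSpec(
                    center_xy=spare.center_xy,
                    width=b.width,
                    length=b.length,
                    height=b.height,
                    rotation=b.rotation,
                )
            moved.append(b)
            k += 1
    inst = [True] * len(moved)
    new = RoomSpec(params=room.params, boxes=moved, instantiated=inst, seed=room.seed)
    return new, idx


# ---------------------------------------------------------------------------
# Texture


def zigzag_texture(u, v, scale: float = 1.0, stripe: float = 0.70, turn: float = 1.50):
    """Binary zigzag wallpaper value at surface coordinates (u, v) in meters.

    Stripes of width ``stripe / scale`` run at +-45 degrees, reversing
    direction every ``turn / scale`` meters along v (a triangular-wave shear
    of the stripe coordinate with unit slope).  ``scale`` is 1 on room
    surfaces and 2 on box faces.  Returns 0/1 (int array or scalar).
    """
    s = stripe / scale
    T = turn / scale
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    offset = T - np.abs(np.mod(v, 2.0 * T) - T)  # triangle wave, slope +-1
    val = np.floor((u + offset) / s).astype(np.int64) % 2
    if val.ndim == 0:
        return int(val)
    return val


# ---------------------------------------------------------------------------
# Lighting schedule


def light_schedule(mode: str, trial_index: int, seed: int) -> LightState:
    """Light state for one probe.

    reliable: a single azimuth drawn once per (seed) block and held.
    unreliable: a fresh azimuth before every probe (seed x trial).
    absent: no directional term; ambient gain doubled.
    """
    if mode == "absent":
        return LightState(mode="absent", ambient_gain=2.0)
    if mode == "reliable":
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA21]))
        az = float(rng.uniform(0.0, 360.0))
    elif mode == "unreliable":
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA22, trial_index]))
        az = float(rng.uniform(0.0, 360.0))
    else:
        raise ValueError(f"unknown light mode {mode!r}")
    return LightState(mode=mode, azimuth=az, elevation=45.0, ambient_gain=1.0)


# ---------------------------------------------------------------------------
# Camera walk


class CameraWalk:
    """Smooth random-waypoint walk at fixed eye height.

    Way-points are drawn uniformly inside the room (with a wall margin),
    rejecting points inside instantiated boxes; the camera moves between them
    at constant speed, yaw follows the direction of travel and pitch follows
    a slow bounded oscillation.  Deterministic for a fixed seed.
    """

    def __init__(
        self,
        room: RoomSpec,
        seed: int,
        speed: float = 0.70,  # m/s
        eye_height: float = 1.60,
        pitch_max: float = 30.0,
        margin: float = 0.80,
        duration: float = 400.0,
    ):
        self.room = room
        self.speed = speed
        self.eye_height = eye_height
        self.pitch_max = pitch_max
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xCA3]))
        W, L, _ = room.room_dims
        pts = [np.array([W / 2, L / 2])]
        total = 0.0
        while total < speed * duration + 1.0:
            for _ in range(1000):
                cand = rng.uniform([margin, margin], [W - margin, L - margin])
                if not room.point_inside_any_box(cand[0], cand[1], eye_height, margin=0.25):
                    break
            total += float(np.linalg.norm(cand - pts[-1]))
            pts.append(cand)
        self.points = np.array(pts)
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        self.cum_t = np.concatenate([[0.0], np.cumsum(seg)]) / speed
        self.pitch_phase = float(rng.uniform(0, 2 * math.pi))
        self.pitch_rate = float(rng.uniform(0.05, 0.15))  # Hz

    def pose_at(self, t: float) -> CameraPose:
        t = float(np.clip(t, 0.0, self.cum_t[-1] - 1e-6))
        i = int(np.searchsorted(self.cum_t, t, side="right") - 1)
        i = min(i, len(self.points) - 2)
        seg_t = self.cum_t[i + 1] - self.cum_t[i]
        frac = 0.0 if seg_t <= 0 else (t - self.cum_t[i]) / seg_t
        p = self.points[i] + frac * (self.points[i + 1] - self.points[i])
        d = self.points[i + 1] - self.points[i]
        yaw = math.degrees(math.atan2(d[1], d[0]))
        pitch = self.pitch_max * 0.5 * math.sin(
            2 * math.pi * self.pitch_rate * t + self.pitch_phase
        )
        return CameraPose(position=(float(p[0]), float(p[1]), self.eye_height), yaw=yaw, pitch=pitch)


def sample_pose(room: RoomSpec, t: float, walk_state: CameraWalk | None = None,
                seed: int = 0) -> CameraPose:
    """Pose of the simulated walker at time ``t`` (seconds from block start)."""
    walk = walk_state if walk_state is not None else CameraWalk(room, seed)
    return walk.pose_at(t)


# ---------------------------------------------------------------------------
# Ray-cast renderer


def _camera_rays(pose: CameraPose, width: int = IMAGE_WIDTH, height: int = IMAGE_HEIGHT,
                 fov_w: float = FOV_WIDTH_DEG, fov_h: float = FOV_HEIGHT_DEG) -> np.ndarray:
    yaw = math.radians(pose.yaw)
    pitch = math.radians(pose.pitch)
    fwd = np.array(
        [math.cos(pitch) * math.cos(yaw), math.cos(pitch) * math.sin(yaw), math.sin(pitch)]
    )
    right = np.array([math.sin(yaw), -math.cos(yaw), 0.0])
    up = np.cross(right, fwd)
    tx = math.tan(math.radians(fov_w / 2))
    ty = math.tan(math.radians(fov_h / 2))
    jj = (np.arange(width) + 0.5) / width * 2 - 1  # -1..1 left to right
    ii = 1 - (np.arange(height) + 0.5) / height * 2  # +1..-1 top to bottom
    ndc_x, ndc_y = np.meshgrid(jj * tx, ii * ty)
    dirs = fwd[None, None, :] + ndc_x[..., None] * right[None, None, :] + ndc_y[..., None] * up
    dirs /= np.linalg.norm(dirs, axis=-1, keepdims=True)
    return dirs  # (H, W, 3)


def _intersect_walls(origin: np.ndarray, dirs: np.ndarray, dims) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exit distance of interior rays through the room box.

    Returns (t, axis, sign): distance, wall axis (0=x,1=y,2=z) and whether the
    high (+1) or low (-1) face was hit.
    """
    bounds = np.array(dims)
    t_best = np.full(dirs.shape[:2], np.inf)
    axis = np.zeros(dirs.shape[:2], dtype=np.int8)
    sign = np.zeros(dirs.shape[:2], dtype=np.int8)
    for k in range(3):
        d = dirs[..., k]
        with np.errstate(divide="ignore", invalid="ignore"):
            t_hi = (bounds[k] - origin[k]) / d
            t_lo = (0.0 - origin[k]) / d
        for t, s in ((t_hi, 1), (t_lo, -1)):
            valid = (t > 1e-9) & np.isfinite(t) & (t < t_best)
            t_best = np.where(valid, t, t_best)
            axis = np.where(valid, k, axis)
            sign = np.where(valid, s, sign)
    return t_best, axis, sign


def _intersect_box(origin: np.ndarray, dirs: np.ndarray, box: BoxSpec):
    """Slab test of rays against one oriented box.

    Returns (t_entry, normal_axis, normal_sign) in the box local frame, with
    t_entry = inf where there is no hit in front of the camera.
    """
    th = math.radians(box.rotation)
    c, s = math.cos(th), math.sin(th)
    R = np.array([[c, s, 0.0], [-s, c, 0.0], [0.0, 0.0, 1.0]])  # world -> local
    o = R @ (origin - np.array([box.center_xy[0], box.center_xy[1], 0.0]))
    d = dirs @ R.T
    half = np.array([box.width / 2, box.length / 2, box.height / 2])
    center = np.array([0.0, 0.0, box.height / 2])
    t_near = np.full(dirs.shape[:2], -np.inf)
    t_far = np.full(dirs.shape[:2], np.inf)
    n_axis = np.zeros(dirs.shape[:2], dtype=np.int8)
    for k in range(3):
        dk = d[..., k]
        ok = o[k] - center[k]
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = (-half[k] - ok) / dk
            t2 = (half[k] - ok) / dk
        lo = np.minimum(t1, t2)
        hi = np.maximum(t1, t2)
        parallel = np.abs(dk) < 1e-12
        outside = parallel & (np.abs(ok) > half[k])
        lo = np.where(parallel, -np.inf, lo)
        hi = np.where(parallel, np.inf, hi)
        upd = lo > t_near
        t_near = np.where(upd, lo, t_near)
        n_axis = np.where(upd, k, n_axis)
        t_far = np.minimum(t_far, hi)
        t_far = np.where(outside, -np.inf, t_far)
    hit = (t_near <= t_far) & (t_near > 1e-9)
    t_entry = np.where(hit, t_near, np.inf)
    # local hit coordinates relative to box center (for texture + normal sign)
    return t_entry, n_axis, (o, d, R, half, center)


def _box_occludes(points: np.ndarray, light_dir: np.ndarray, box: BoxSpec) -> np.ndarray:
    """Whether the shadow ray from each point toward a directional light hits
    the box.  ``points``: (N, 3)."""
    th = math.radians(box.rotation)
    c, s = math.cos(th), math.sin(th)
    R = np.array([[c, s, 0.0], [-s, c, 0.0], [0.0, 0.0, 1.0]])
    o = (points - np.array([box.center_xy[0], box.center_xy[1], 0.0])) @ R.T
    d = R @ light_dir
    half = np.array([box.width / 2, box.length / 2, box.height / 2])
    center = np.array([0.0, 0.0, box.height / 2])
    t_near = np.full(points.shape[0], -np.inf)
    t_far = np.full(points.shape[0], np.inf)
    for k in range(3):
        ok = o[:, k] - center[k]
        dk = d[k]
        if abs(dk) < 1e-12:
            t_far = np.where(np.abs(ok) > half[k], -np.inf, t_far)
            continue
        t1 = (-half[k] - ok) / dk
        t2 = (half[k] - ok) / dk
        t_near = np.maximum(t_near, np.minimum(t1, t2))
        t_far = np.minimum(t_far, np.maximum(t1, t2))
    return (t_near <= t_far) & (t_far > 1e-6) & (t_near < np.inf)


def render_snapshot(room: RoomSpec, pose: CameraPose, light: LightState,
                    trial_index: int = 0, supersample: int = 1) -> SceneSnapshot:
    """Render aligned luminance and depth maps at 90 x 100 over 45 x 50 deg.

    Nearest-hit depth per pixel; luminance = albedo x (ambient x gain +
    Lambertian diffuse x shadow visibility) for directional modes, and
    albedo x doubled ambient when the light is absent.  Shadow rays test
    occlusion by instantiated boxes only.  ``supersample`` renders at an
    integer multiple of the analysis resolution and block-averages down
    (anti-aliasing, as downsampled captures would be); 1 = exact per-pixel
    ray cast.
    """
    x, y, z = pose.position
    W, L, H = room.room_dims
    if not (0 < x < W and 0 < y < L and 0 < z < H):
        raise RenderError("camera outside the room")
    if room.point_inside_any_box(x, y, z):
        raise RenderError("camera inside a box (degenerate viewpoint)")

    origin = np.array(pose.position)
    dirs = _camera_rays(
        pose, width=IMAGE_WIDTH * supersample, height=IMAGE_HEIGHT * supersample
    )
    h, w = dirs.shape[:2]

    t_wall, wall_axis, wall_sign = _intersect_walls(origin, dirs, room.room_dims)
    t_hit = t_wall.copy()
    # -1 = wall, otherwise index into instantiated boxes
    hit_id = np.full((h, w), -1, dtype=np.int16)
    box_axes = np.zeros((h, w), dtype=np.int8)
    boxes = room.instantiated_boxes
    box_frames = []
    for bi, box in enumerate(boxes):
        t_entry, n_axis, frame = _intersect_box(origin, dirs, box)
        closer = t_entry < t_hit
        t_hit = np.where(closer, t_entry, t_hit)
        hit_id = np.where(closer, bi, hit_id)
        box_axes = np.where(closer, n_axis, box_axes)
        box_frames.append(frame)

    pts = origin[None, None, :] + dirs * t_hit[..., None]

    albedo = np.empty((h, w))
    normal = np.zeros((h, w, 3))
    stripe, turn = room.params.wall_stripe, room.params.wall_turn

    wall_mask = hit_id == -1
    if wall_mask.any():
        wa = wall_axis[wall_mask]
        ws = wall_sign[wall_mask]
        p = pts[wall_mask]
        u = np.where(wa == 0, p[:, 1], np.where(wa == 1, p[:, 0], p[:, 0]))
        v = np.where(wa == 2, p[:, 1], p[:, 2])
        tex = zigzag_texture(u, v, 1.0, stripe, turn)
        albedo[wall_mask] = np.where(tex == 1, ALBEDO_LIGHT, ALBEDO_DARK)
        n = np.zeros((len(p), 3))
        n[np.arange(len(p)), wa] = -ws  # interior-facing normal
        normal[wall_mask] = n

    for bi, box in enumerate(boxes):
        m = hit_id == bi
        if not m.any():
            continue
        o_l, d_l, R, half, center = box_frames[bi]
        p_local = o_l[None, None, :] + d_l * t_hit[..., None]
        pl = p_local[m] - center[None, :]
        ax = box_axes[m]
        sgn = np.sign(np.take_along_axis(pl, ax[:, None].astype(np.int64), axis=1)[:, 0])
        sgn = np.where(sgn == 0, 1.0, sgn)
        u = np.where(ax == 0, pl[:, 1], pl[:, 0])
        v = np.where(ax == 2, pl[:, 1], pl[:, 2] + box.height / 2)
        tex = zigzag_texture(u, v, 2.0, stripe, turn)
        albedo[m] = np.where(tex == 1, ALBEDO_LIGHT, ALBEDO_DARK)
        n_local = np.zeros((int(m.sum()), 3))
        n_local[np.arange(len(sgn)), ax] = sgn
        normal[m] = n_local @ R  # local -> world (R is world->local, orthonormal)

    if light.mode == "absent":
        image = albedo * (AMBIENT * light.ambient_gain)
    else:
        ldir = light.direction()
        lambert = np.clip(normal @ ldir, 0.0, None)
        flat = pts.reshape(-1, 3)
        lit = lambert.reshape(-1) > 0
        visible = np.ones(flat.shape[0], dtype=bool)
        if lit.any():
            shadow_pts = flat[lit] + 1e-4 * ldir[None, :]
            occ = np.zeros(shadow_pts.shape[0], dtype=bool)
            for box in boxes:
                rem = ~occ
                if not rem.any():
                    break
                occ[rem] |= _box_occludes(shadow_pts[rem], ldir, box)
            vis_lit = ~occ
            visible[lit] = vis_lit
        visibility = visible.reshape(h, w)
        image = albedo * (AMBIENT * light.ambient_gain + DIFFUSE * lambert * visibility)

    image = np.clip(image, 0.0, 1.0)
    return SceneSnapshot(
        image_map=block_average(image, supersample),
        depth_map=block_average(t_hit, supersample),
        pose=pose,
        light=light,
        trial_index=trial_index,
        supersample=supersample,
        image_hi=image if supersample > 1 else None,
    )
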