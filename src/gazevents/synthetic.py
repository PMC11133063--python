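"""Seeded synthetic natural-viewing recordings with ground-truth labels.

The simulator renders a scene camera looking at a textured background plane
(plus a few textured foreground objects at a nearer depth, giving mild
parallax) while scripting the four natural-viewing events:

* gaze fixation (label 1) — camera static, gaze locked on a stationary
  point, angular jitter only;
* gaze pursuit (label 2) — camera static, gaze tracks an object moving at
  a scripted angular speed;
* gaze shift (label 3) — rapid gaze jump with a minimum-jerk position
  profile (30-80 ms, peak velocity in the 200-500 deg/s band);
* gaze following (label 4) — gaze held on a stationary world point while
  the camera yaws and the body translates laterally.

World frame: x right, y down, z forward, aligned with the initial camera.
The background plane sits at ``BG_DEPTH``; foreground objects at
``OBJ_DEPTH``.  Rendering is homography-exact for the background, so the
recovered camera rotation can be checked against the scripted trajectory.
Gaze jitter is smoothed Gaussian angular noise (white noise at the gaze
rate would alias into implausibly large sample-to-sample velocities).

Everything is driven by one ``numpy`` generator seeded from the config, so
recordings are bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d
from skimage.transform import ProjectiveTransform, resize, warp

from .errors import ValidationError
from .io import CameraIntrinsics, GazeRecording, SceneVideo, write_gaze_csv, write_intrinsics

#: event-kind -> integer label
EVENT_LABELS = {"GFi": 1, "GP": 2, "GS": 3, "GFo": 4}

BG_DEPTH = 10.0       # background plane distance (world units)
OBJ_DEPTH = 6.0       # foreground object distance
TEX_SCALE = 28.0      # texture pixels per world unit
TEX_SHAPE = (960, 2560)


@dataclass
class EventSpec:
    """One scripted event: kind in {GFi, GFo, GP, GS}, duration in seconds.

    ``params`` may carry per-event kinematics: ``yaw_rate`` (deg/s) and
    ``trans_vel`` (units/s) for GFo, ``obj_speed`` (deg/s) for GP,
    ``amplitude_deg`` for GS.  Missing values are drawn from the default
    ranges at build time.
    """

    kind: str
    duration: float
    params: dict = field(default_factory=dict)


@dataclass
class SimulationConfig:
    """Study conditions of one synthetic recording."""

    event_script: list[EventSpec]
    gaze_rate: float = 120.0
    frame_rate: float = 30.0
    width: int = 320
    height: int = 240
    fx: float = 277.0
    fy: float = 277.0
    noise_deg: float = 0.1
    blink_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.gaze_rate <= 0 or self.frame_rate <= 0:
            raise ValidationError("rates must be positive")
        for ev in self.event_script:
            if ev.kind not in EVENT_LABELS:
                raise ValidationError(f"unknown event kind {ev.kind!r}")
            if ev.duration <= 0:
                raise ValidationError(f"non-positive duration for {ev.kind}")
            p = ev.params
            if ev.kind == "GFo" and not (0 <= abs(p.get("yaw_rate", 12.0)) <= 60):
                raise ValidationError(f"GFo yaw_rate {p['yaw_rate']} outside plausible 0-60 deg/s")
            if ev.kind == "GP" and not (0 < p.get("obj_speed", 8.0) <= 40):
                raise ValidationError(f"GP obj_speed {p['obj_speed']} outside plausible 0-40 deg/s")
            if ev.kind == "GS" and not (0.02 <= ev.duration <= 0.12):
                raise ValidationError(f"GS duration {ev.duration} outside plausible 20-120 ms")

    @property
    def duration(self) -> float:
        return float(sum(ev.duration for ev in self.event_script))

    @property
    def intrinsics(self) -> CameraIntrinsics:
        return CameraIntrinsics(self.fx, self.fy, (self.width - 1) / 2.0,
                                (self.height - 1) / 2.0, self.width, self.height)


@dataclass
class GroundTruthRecording:
    """A simulated recording plus everything the simulator knows about it."""

    gaze: GazeRecording
    video: SceneVideo
    camera_yaw_deg: np.ndarray    # per frame
    camera_pos: np.ndarray        # per frame, (n, 3)
    object_tracks: dict           # name -> (n_frames, 3) world centers
    config: SimulationConfig


def default_event_script(duration: float, rng: np.random.Generator) -> list[EventSpec]:
    """Cycle fixation / following / pursuit with a gaze shift between each.

    Durations and kinematics are drawn from ranges typical of natural
    viewing; the final event is truncated so the script sums to ``duration``.
    """
    kinds = ["GFi", "GFo", "GP"]
    script: list[EventSpec] = []
    t, i = 0.0, 0
    while t < duration - 0.25:
        kind = kinds[i % 3]
        if script:
            gs = EventSpec("GS", float(np.round(rng.uniform(0.035, 0.07), 4)))
            script.append(gs)
            t += gs.duration
        dur = float(min(rng.uniform(1.5, 2.2), duration - t))
        params = {}
        if kind == "GFo":
            params = {"yaw_rate": float(rng.uniform(10, 16) * rng.choice([-1, 1])),
                      "trans_vel": float(rng.uniform(0.3, 0.8) * rng.choice([-1, 1]))}
        elif kind == "GP":
            params = {"obj_speed": float(rng.uniform(5, 12)),
                      "obj_sign": float(rng.choice([-1, 1]))}
        script.append(EventSpec(kind, dur, params))
        t += dur
        i += 1
    return script


def build_scene_texture(seed: int, extent: tuple[int, int] = TEX_SHAPE,
                        frame_shape: tuple[int, int] = (240, 320)) -> np.ndarray:
    """Seeded multi-scale noise texture with per-region distinct statistics.

    The extent must be at least 4x the frame size in both dimensions so the
    camera can rotate without leaving the texture.  A fine high-frequency
    component keeps corners detectable everywhere.
    """
    h, w = extent
    if h < 4 * frame_shape[0] or w < 4 * frame_shape[1]:
        raise ValidationError(f"texture extent {extent} smaller than 4x frame {frame_shape}")
    rng = np.random.default_rng(seed)
    tex = np.zeros((h, w))
    cell = 160
    for r0 in range(0, h, cell):
        for c0 in range(0, w, cell):
            r1, c1 = min(r0 + cell, h), min(c0 + cell, w)
            sigma = rng.uniform(1.0, 2.6)
            contrast = rng.uniform(0.5, 1.0)
            offset = rng.uniform(0.0, 1.0 - contrast)
            block = gaussian_filter(rng.random((r1 - r0, c1 - c0)), sigma)
            lo, hi = block.min(), block.max()
            tex[r0:r1, c0:c1] = offset + contrast * (block - lo) / max(hi - lo, 1e-9)
    tex = 0.85 * tex + 0.15 * gaussian_filter(rng.random((h, w)), 0.8)
    return np.clip(tex, 0.0, 1.0)


def _camera_axes(yaw_deg: float) -> np.ndarray:
    """Camera-to-world rotation for a pure pan (columns: right, down, forward)."""
    a = np.radians(yaw_deg)
    fwd = np.array([np.sin(a), 0.0, np.cos(a)])
    right = np.array([np.cos(a), 0.0, -np.sin(a)])
    down = np.array([0.0, 1.0, 0.0])
    return np.column_stack([right, down, fwd])


def _project(K: np.ndarray, R_wc: np.ndarray, C: np.ndarray, P: np.ndarray) -> np.ndarray:
    p = K @ (R_wc.T @ (np.asarray(P) - C))
    return p[:2] / p[2]


def _ray_to_plane(C: np.ndarray, d_world: np.ndarray, depth: float) -> np.ndarray:
    lam = (depth - C[2]) / d_world[2]
    return C + lam * d_world


def _min_jerk(tau: np.ndarray) -> np.ndarray:
    return 10 * tau ** 3 - 15 * tau ** 4 + 6 * tau ** 5


@dataclass
class _Timeline:
    t_gaze: np.ndarray
    label: np.ndarray
    gaze_dir: np.ndarray   # head frame (x right, y up, z forward)
    gaze_px: np.ndarray
    t_frames: np.ndarray
    cam_yaw: np.ndarray    # per frame, degrees
    cam_pos: np.ndarray    # per frame
    cam_yaw_fn: object     # callable t -> yaw
    cam_pos_fn: object
    pursuit_tracks: list   # (t0, t1, start(3,), vel(3,), tex_key)


def script_event_timeline(config: SimulationConfig,
                          rng: np.random.Generator | None = None) -> _Timeline:
    """Turn the event script into per-sample gaze ground truth and camera poses."""
    rng = rng or np.random.default_rng(config.seed)
    K = config.intrinsics.K
    duration = config.duration
    n_g = int(round(duration * config.gaze_rate))
    n_f = int(round(duration * config.frame_rate))
    t_gaze = np.arange(n_g) / config.gaze_rate
    t_frames = np.arange(n_f) / config.frame_rate

    # pass A: camera trajectory (piecewise linear in yaw and position)
    events = []
    yaw, pos = 0.0, np.zeros(3)
    t0 = 0.0
    for ev in config.event_script:
        e = {"spec": ev, "t0": t0, "t1": t0 + ev.duration,
             "yaw0": yaw, "yaw_rate": 0.0, "pos0": pos.copy(), "vel": np.zeros(3)}
        if ev.kind == "GFo":
            rate = ev.params.get("yaw_rate")
            if rate is None:
                rate = float(rng.uniform(10, 16) * rng.choice([-1, 1]))
            # steer back toward center when a pan would leave the texture
            if (abs(yaw + rate * ev.duration) > 45.0
                    and abs(yaw - rate * ev.duration) < abs(yaw + rate * ev.duration)):
                rate = -rate
            tv = ev.params.get("trans_vel")
            if tv is None:
                tv = float(rng.uniform(0.3, 0.8) * rng.choice([-1, 1]))
            if (abs(pos[0] + tv * ev.duration) > 2.5
                    and abs(pos[0] - tv * ev.duration) < abs(pos[0] + tv * ev.duration)):
                tv = -tv
            e["yaw_rate"] = float(rate)
            e["vel"] = np.array([tv, 0.0, 0.0])
        events.append(e)
        yaw = e["yaw0"] + e["yaw_rate"] * ev.duration
        pos = e["pos0"] + e["vel"] * ev.duration
        t0 = e["t1"]

    def cam_yaw_fn(t):
        t = np.asarray(t, dtype=float)
        out = np.empty(t.shape)
        for e in events:
            m = (t >= e["t0"] - 1e-12) & (t <= e["t1"] + 1e-12)
            out[m] = e["yaw0"] + e["yaw_rate"] * (t[m] - e["t0"])
        return out

    def cam_pos_fn(t):
        t = np.asarray(t, dtype=float)
        out = np.empty(t.shape + (3,))
        for e in events:
            m = (t >= e["t0"] - 1e-12) & (t <= e["t1"] + 1e-12)
            out[m] = e["pos0"] + np.outer(t[m] - e["t0"], e["vel"])
        return out

    # pass B: gaze anchors.  Each non-GS event fixates/follows a world point;
    # each GS carries gaze from the previous anchor to the next event's one.
    def comfort_center(e):
        """Azimuth/elevation (deg) the next anchor should sit near."""
        if e["spec"].kind == "GFo":
            t_mid = 0.5 * (e["t0"] + e["t1"])
            return float(cam_yaw_fn(t_mid)), float(rng.uniform(-5, 5))
        return float(e["yaw0"] + rng.uniform(-6, 6)), float(rng.uniform(-5, 5))

    def anchor_point(az_deg, el_deg, C, depth=BG_DEPTH):
        el = np.radians(el_deg)
        az = np.radians(az_deg)
        d = np.array([np.cos(el) * np.sin(az), -np.sin(el), np.cos(el) * np.cos(az)])
        return _ray_to_plane(C, d, depth)

    first = events[0]
    C0 = first["pos0"]
    az0, el0 = comfort_center(first)
    gaze_anchor = anchor_point(az0, el0, C0)

    label = np.zeros(n_g, dtype=int)
    gaze_world = np.zeros((n_g, 3))
    pursuit_tracks = []
    for idx, e in enumerate(events):
        ev = e["spec"]
        m = (t_gaze >= e["t0"] - 1e-12) & (t_gaze < e["t1"] - 1e-12)
        if idx == len(events) - 1:
            m = (t_gaze >= e["t0"] - 1e-12)
        label[m] = EVENT_LABELS[ev.kind]
        tt = t_gaze[m]
        if ev.kind in ("GFi", "GFo"):
            gaze_world[m] = gaze_anchor
        elif ev.kind == "GP":
            C = e["pos0"]
            d = gaze_anchor - C
            start = _ray_to_plane(C, d, OBJ_DEPTH)
            speed = ev.params.get("obj_speed", float(rng.uniform(5, 12)))
            sign = ev.params.get("obj_sign", float(rng.choice([-1, 1])))
            # start upstream so the sweep stays inside the field of view
            sweep = np.radians(speed) * (OBJ_DEPTH - C[2]) * ev.duration
            start = start - np.array([sign * sweep / 2, 0.0, 0.0])
            vel = np.array([sign * np.radians(speed) * (OBJ_DEPTH - C[2]), 0.0, 0.0])
            gaze_world[m] = start + np.outer(tt - e["t0"], vel)
            pursuit_tracks.append((e["t0"], e["t1"], start, vel, f"pursuit_{idx}"))
            gaze_anchor = start + vel * ev.duration
        elif ev.kind == "GS":
            nxt = events[idx + 1] if idx + 1 < len(events) else None
            C = e["pos0"]
            d_cur = gaze_anchor - C
            d_cur /= np.linalg.norm(d_cur)
            az_cur = np.degrees(np.arctan2(d_cur[0], d_cur[2]))
            el_cur = np.degrees(np.arctan2(-d_cur[1], np.hypot(d_cur[0], d_cur[2])))
            amp = ev.params.get("amplitude_deg")
            if amp is None:
                amp = float(ev.duration * rng.uniform(250, 420) / 1.875)
            if nxt is not None:
                az_c, el_c = comfort_center(nxt)
            else:
                az_c, el_c = float(cam_yaw_fn(e["t1"])), 0.0
            step = np.array([az_c - az_cur, el_c - el_cur])
            norm = np.linalg.norm(step)
            step = step / norm * amp if norm > 1e-9 else np.array([amp, 0.0])
            target = anchor_point(az_cur + step[0], el_cur + step[1], C)
            start_pt = gaze_anchor
            tau = np.clip((tt - e["t0"]) / ev.duration, 0, 1)
            gaze_world[m] = start_pt + np.outer(_min_jerk(tau), target - start_pt)
            gaze_anchor = target

    # camera pose per gaze sample / frame
    yaw_g = cam_yaw_fn(t_gaze)
    pos_g = cam_pos_fn(t_gaze)
    cam_yaw_f = cam_yaw_fn(t_frames)
    cam_pos_f = cam_pos_fn(t_frames)

    # head-centered gaze direction with smoothed angular jitter
    gaze_dir = np.zeros((n_g, 3))
    gaze_px = np.zeros((n_g, 2))
    jit_az = gaussian_filter1d(rng.standard_normal(n_g), 3.0, mode="nearest")
    jit_el = gaussian_filter1d(rng.standard_normal(n_g), 3.0, mode="nearest")
    for arr in (jit_az, jit_el):
        s = arr.std()
        if s > 1e-12:
            arr *= config.noise_deg / s
    for i in range(n_g):
        R_wc = _camera_axes(yaw_g[i])
        d_cam = R_wc.T @ (gaze_world[i] - pos_g[i])
        d_cam /= np.linalg.norm(d_cam)
        az = np.arctan2(d_cam[0], d_cam[2]) + np.radians(jit_az[i])
        el = np.arctan2(-d_cam[1], np.hypot(d_cam[0], d_cam[2])) + np.radians(jit_el[i])
        d_cam = np.array([np.cos(el) * np.sin(az), -np.sin(el), np.cos(el) * np.cos(az)])
        p = K @ d_cam
        gaze_px[i] = p[:2] / p[2]
        gaze_dir[i] = [d_cam[0], -d_cam[1], d_cam[2]]  # head frame has y up

    return _Timeline(t_gaze, label, gaze_dir, gaze_px, t_frames,
                     cam_yaw_f, cam_pos_f, cam_yaw_fn, cam_pos_fn, pursuit_tracks)


def _render_background(texture: np.ndarray, K: np.ndarray, yaw_deg: float,
                       C: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    h_t, w_t = texture.shape
    S = np.array([[TEX_SCALE, 0.0, w_t / 2.0], [0.0, TEX_SCALE, h_t / 2.0], [0.0, 0.0, 1.0]])
    A = np.array([[BG_DEPTH - C[2], 0.0, C[0]], [0.0, BG_DEPTH - C[2], C[1]], [0.0, 0.0, 1.0]])
    M = S @ A @ _camera_axes(yaw_deg) @ np.linalg.inv(K)
    return warp(texture, ProjectiveTransform(matrix=M), output_shape=shape,
                order=1, mode="constant", cval=0.5)


def _paste_object(frame: np.ndarray, obj_tex: np.ndarray, K: np.ndarray,
                  yaw_deg: float, C: np.ndarray, center: np.ndarray,
                  half_size_world: float) -> None:
    R_wc = _camera_axes(yaw_deg)
    p_cam = R_wc.T @ (center - C)
    if p_cam[2] <= 0.1:
        return
    px = K @ p_cam
    cx, cy = px[0] / px[2], px[1] / px[2]
    half_px = int(round(K[0, 0] * half_size_world / p_cam[2]))
    if half_px < 2:
        return
    size = 2 * half_px
    patch = resize(obj_tex, (size, size), order=1, anti_aliasing=False)
    x0, y0 = int(round(cx)) - half_px, int(round(cy)) - half_px
    h, w = frame.shape
    sx0, sx1 = max(x0, 0), min(x0 + size, w)
    sy0, sy1 = max(y0, 0), min(y0 + size, h)
    if sx1 > sx0 and sy1 > sy0:
        frame[sy0:sy1, sx0:sx1] = patch[sy0 - y0:sy1 - y0, sx0 - x0:sx1 - x0]


def simulate_recording(config: SimulationConfig, out_dir=None,
                       recording_id: str | None = None) -> GroundTruthRecording:
    """Render a full synthetic recording; optionally write it in the package formats.

    Written files: ``gaze.csv``, ``frames/NNNNNN.png`` + ``frame_times.csv``,
    ``intrinsics.json`` and ``ground_truth.json``.  Byte-reproducible per seed.
    """
    rng = np.random.default_rng(config.seed)
    recording_id = recording_id or f"sim{config.seed}"
    texture = build_scene_texture(int(rng.integers(2 ** 31)),
                                  frame_shape=(config.height, config.width))
    tl = script_event_timeline(config, rng)
    K = config.intrinsics.K

    # static foreground distractors (parallax sources), plus pursuit objects
    obj_texs = {}
    static_objects = []
    for i, az in enumerate((-18.0, 0.0, 18.0)):
        center = _ray_to_plane(np.zeros(3), np.array(
            [np.sin(np.radians(az)), rng.uniform(-0.15, 0.15), np.cos(np.radians(az))]),
            OBJ_DEPTH)
        key = f"static_{i}"
        obj_texs[key] = rng.random((40, 40))
        static_objects.append((key, center))
    for t0, t1, start, vel, key in tl.pursuit_tracks:
        obj_texs[key] = rng.random((40, 40))

    n_f = len(tl.t_frames)
    frames = []
    tracks = {key: np.full((n_f, 3), np.nan) for key in obj_texs}
    for i in range(n_f):
        t = tl.t_frames[i]
        yaw, C = tl.cam_yaw[i], tl.cam_pos[i]
        frame = _render_background(texture, K, yaw, C, (config.height, config.width))
        for key, center in static_objects:
            _paste_object(frame, obj_texs[key], K, yaw, C, center, 0.35)
            tracks[key][i] = center
        for t0, t1, start, vel, key in tl.pursuit_tracks:
            if t0 - 0.5 <= t <= t1 + 0.5:  # keep target visible around its event
                center = start + vel * np.clip(t - t0, 0, t1 - t0)
                _paste_object(frame, obj_texs[key], K, yaw, C, center, 0.5)
                tracks[key][i] = center
        frames.append((np.clip(frame, 0, 1) * 255).astype(np.uint8))

    label = tl.label.copy()
    if config.blink_fraction > 0:
        n_blinks = max(1, int(config.blink_fraction * config.duration * 2))
        for _ in range(n_blinks):
            i0 = int(rng.integers(0, len(label) - 12))
            label[i0:i0 + int(0.1 * config.gaze_rate)] = 5

    gaze = GazeRecording(recording_id=recording_id, t=tl.t_gaze,
                         gaze_dir=tl.gaze_dir, gaze_px=tl.gaze_px,
                         label=label, nominal_rate=config.gaze_rate)
    video = SceneVideo(frames=frames, frame_times=tl.t_frames,
                       intrinsics=config.intrinsics)
    gt = GroundTruthRecording(gaze=gaze, video=video,
                              camera_yaw_deg=tl.cam_yaw, camera_pos=tl.cam_pos,
                              object_tracks=tracks, config=config)
    if out_dir is not None:
        _write_recording(gt, Path(out_dir))
    return gt


def _write_recording(gt: GroundTruthRecording, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    frames_dir = out_dir / "frames"
    frames_dir.mkdir(exist_ok=True)
    write_gaze_csv(gt.gaze, out_dir / "gaze.csv")
    write_intrinsics(gt.config.intrinsics, out_dir / "intrinsics.json")
    for i, frame in enumerate(gt.video.frames):
        iio.imwrite(frames_dir / f"{i:06d}.png", frame)
    with open(frames_dir / "frame_times.csv", "w", encoding="utf-8") as fh:
        fh.write("t\n")
        fh.writelines(f"{float(t)!r}\n" for t in gt.video.frame_times)
    manifest = {
        "recording_id": gt.gaze.recording_id,
        "seed": gt.config.seed,
        "event_script": [{"kind": ev.kind, "duration": ev.duration, "params": ev.params}
                         for ev in gt.config.event_script],
        "camera_yaw_deg": gt.camera_yaw_deg.tolist(),
        "camera_pos": gt.camera_pos.tolist(),
        "object_tracks": {k: v.tolist() for k, v in gt.object_tracks.items()},
    }
    with open(out_dir / "ground_truth.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh)
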