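"""Pinhole camera model of the simulator display.

The driver's eye sits ``eye_height_m`` above the ground plane and
``screen_distance_m`` from a flat display subtending ``fov_h_deg`` by
``fov_v_deg``.  Ground-plane points are projected through the eye onto
the screen plane and expressed in normalised screen coordinates in
[0, 1] x [0, 1], origin bottom-left, so that (0.5, ...) is straight
ahead and the horizon maps to y = 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class CameraModel:
    eye_height_m: float = 1.2
    screen_distance_m: float = 1.0
    fov_h_deg: float = 89.0
    fov_v_deg: float = 58.0

    def __post_init__(self) -> None:
        if not (0 < self.fov_h_deg < 180 and 0 < self.fov_v_deg < 180):
            raise ValueError("FOV angles must lie in (0, 180) degrees")
        if self.screen_distance_m <= 0:
            raise ValueError("screen_distance_m must be positive")

    @property
    def half_width(self) -> float:
        """Half screen width in metres at the screen plane."""
        return self.screen_distance_m * np.tan(np.radians(self.fov_h_deg / 2))

    @property
    def half_height(self) -> float:
        return self.screen_distance_m * np.tan(np.radians(self.fov_v_deg / 2))


def world_to_screen(cam: CameraModel, pos, yaw, points):
    """Project ground-plane point(s) to normalised screen coordinates.

    Parameters
    ----------
    pos : (2,) or (n, 2)
        Vehicle/eye ground position(s) ``(x, z)``.
    yaw : float or (n,)
        Heading angle(s), radians; the camera looks along
        ``(cos(yaw), sin(yaw))`` in the ground plane.
    points : (m, 2) or (n, m, 2)
        Ground-plane points to project.  A 2-d ``points`` array is
        broadcast against per-frame ``pos``/``yaw``.

    Returns
    -------
    screen : ndarray, shape points.shape
        Normalised (x, y); undefined where ``behind`` is True.
    behind : bool ndarray
        True where the point has non-positive forward depth.
    """
    pos = np.asarray(pos, dtype=float)
    yaw = np.asarray(yaw, dtype=float)
    pts = np.asarray(points, dtype=float)
    single = pos.ndim == 1
    if single:
        pos = pos[None, :]
        yaw = np.atleast_1d(yaw)
        if pts.ndim == 1:
            pts = pts[None, :]
        pts = pts[None, ...]         # (1, m, 2)
    elif pts.ndim == 2:
        pts = pts[None, ...]

    rel = pts - pos[:, None, :]                       # (n, m, 2)
    c, s = np.cos(yaw), np.sin(yaw)
    depth = rel[..., 0] * c[:, None] + rel[..., 1] * s[:, None]
    lateral = -rel[..., 0] * s[:, None] + rel[..., 1] * c[:, None]
    behind = depth <= 1e-9

    with np.errstate(divide="ignore", invalid="ignore"):
        # screen-plane offsets in metres, then normalised by half extents
        sx = 0.5 + 0.5 * (lateral * cam.screen_distance_m / depth) / cam.half_width
        sy = 0.5 + 0.5 * (-cam.eye_height_m * cam.screen_distance_m / depth) / cam.half_height
    screen = np.stack([sx, sy], axis=-1)
    if single:
        return screen[0], behind[0]
    return screen, behind


def screen_to_ray(cam: CameraModel, screen_xy):
    """Unit 3-d ray (forward, lateral, up) through screen coordinate(s)."""
    s = np.asarray(screen_xy, dtype=float)
    lat = (s[..., 0] - 0.5) * 2 * cam.half_width
    up = (s[..., 1] - 0.5) * 2 * cam.half_height
    fwd = np.full_like(lat, cam.screen_distance_m)
    ray = np.stack([fwd, lat, up], axis=-1)
    return ray / np.linalg.norm(ray, axis=-1, keepdims=True)


def screen_to_angles_deg(cam: CameraModel, screen_xy):
    """Horizontal/vertical visual angle (degrees) of screen point(s)
    relative to straight ahead — the signal the gaze segmenter runs on."""
    s = np.asarray(screen_xy, dtype=float)
    h = np.degrees(np.arctan((s[..., 0] - 0.5) * 2 * cam.half_width
                             / cam.screen_distance_m))
    v = np.degrees(np.arctan((s[..., 1] - 0.5) * 2 * cam.half_height
                             / cam.screen_distance_m))
    return np.stack([h, v], axis=-1)


def angular_separation_deg(cam: CameraModel, screen_a, screen_b):
    """Visual angle (degrees) between two screen points as seen from the
    eye — the angle metric used by the far-from-midline exclusion."""
    ra = screen_to_ray(cam, screen_a)
    rb = screen_to_ray(cam, screen_b)
    dot = np.clip(np.sum(ra * rb, axis=-1), -1.0, 1.0)
    return np.degrees(np.arccos(dot))
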