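"""Annotated top-view grayscale + depth rendering of the tissue.

Each cell is drawn as a sphere seen from an orthographic camera above the
scene.  The grayscale channel carries (x, y) position and size through the
projected disc and a per-role intensity; the depth channel carries z
through the normalized camera distance to the nearest sphere surface.  The
two 64x64 channels stacked channel-first form the 2x64x64 observation the
DRL agents consume.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image


@dataclass
class Camera:
    """Orthographic camera looking along -z ("top") or tilted ("oblique")."""

    target_position: tuple[float, float, float] = (0.0, 0.0, 0.0)
    distance: float = 100.0
    view: str = "top"  # "top" | "oblique"
    oblique_angle_deg: float = 30.0  # tilt about the x axis for oblique views
    image_size: int = 64
    extent: float | None = None  # world half-width of the field of view, µm
    projection: str = "orthographic"

    def __post_init__(self):
        if self.image_size < 8:
            raise ValueError("image_size must be >= 8")
        if self.distance <= 0:
            raise ValueError("camera distance must be > 0")


@dataclass
class Palette:
    """Per-role grayscale intensities and RGB inspection colors.

    The four roles map to pairwise distinct intensities so the roles stay
    separable after the RGB-to-gray collapse.
    """

    migrating: float = 1.0
    target: float = 0.8
    subgoal: float = 0.9  # subgoal cells are drawn white-ish
    environment: float = 0.5
    rgb: dict = field(default_factory=lambda: {
        "migrating": (255, 0, 0),      # red
        "environment": (0, 80, 255),   # blue
        "target": (0, 200, 0),         # green
        "subgoal": (255, 255, 255),    # white
    })

    def intensity(self, role: str) -> float:
        return getattr(self, role)


@dataclass
class Observation:
    """Stacked 2-channel observation: channel 0 gray, channel 1 depth."""

    gray: np.ndarray
    depth: np.ndarray

    @property
    def stack(self) -> np.ndarray:
        return np.stack([self.gray, self.depth], axis=0)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.stack.shape


def _camera_frame(camera: Camera):
    """Rotation taking world coords into camera coords (camera looks down -z)."""
    if camera.view == "top":
        return np.eye(3)
    if camera.view == "oblique":
        a = np.deg2rad(camera.oblique_angle_deg)
        # tilt about x: camera swings toward +y
        return np.array([
            [1, 0, 0],
            [0, np.cos(a), -np.sin(a)],
            [0, np.sin(a), np.cos(a)],
        ])
    raise ValueError(f"unknown view {camera.view!r}")


def rasterize(
    frame_table: pd.DataFrame,
    camera: Camera | None = None,
    palette: Palette | None = None,
    annotations: dict | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render one frame into (gray, depth) float images in [0, 1].

    Cells are filled discs of projected radius; at overlapping pixels the
    cell nearer the camera wins (painter's order by surface height).
    Background gray is 0 and background depth is 1.

    ``annotations`` maps cell name -> role ("migrating", "target",
    "subgoal", "environment"); unannotated cells are environment cells.
    """
    if frame_table is None or len(frame_table) == 0:
        raise ValueError("cannot rasterize an empty frame")
    camera = camera or Camera()
    palette = palette or Palette()
    annotations = annotations or {}

    R = _camera_frame(camera)
    pts = frame_table[["x", "y", "z"]].to_numpy(float)
    radii = frame_table["diameter"].to_numpy(float) / 2.0
    names = frame_table["name"].tolist()

    tgt = np.asarray(camera.target_position, float)
    cam_pts = (pts - tgt) @ R.T  # camera-frame coords, camera above at +distance

    size = camera.image_size
    if camera.extent is not None:
        extent = float(camera.extent)
    else:
        spread = np.abs(cam_pts[:, :2]).max() if len(cam_pts) else 1.0
        extent = float(spread + radii.max() + 1.0)
    pix = 2.0 * extent / size  # world µm per pixel

    gray = np.zeros((size, size), float)
    zbuf = np.full((size, size), -np.inf)  # surface height in camera frame

    # pixel-center world coordinates (camera frame)
    us = (np.arange(size) + 0.5) * pix - extent          # +x to the right
    vs = extent - (np.arange(size) + 0.5) * pix          # +y up the image

    for k in np.argsort(cam_pts[:, 2]):  # far to near; near overwrites
        x, y, z = cam_pts[k]
        r = radii[k]
        cols = np.where(np.abs(us - x) <= r)[0]
        rows = np.where(np.abs(vs - y) <= r)[0]
        if len(cols) == 0 or len(rows) == 0:
            continue
        du = us[cols] - x
        dv = vs[rows] - y
        rho2 = dv[:, None] ** 2 + du[None, :] ** 2
        inside = rho2 <= r * r
        if not inside.any():
            continue
        ztop = np.full(rho2.shape, -np.inf)
        ztop[inside] = z + np.sqrt(r * r - rho2[inside])
        sub = np.ix_(rows, cols)
        win = ztop > zbuf[sub]
        role = annotations.get(names[k], "environment")
        gray_sub = gray[sub]
        gray_sub[win] = palette.intensity(role)
        gray[sub] = gray_sub
        zb = zbuf[sub]
        zb[win] = ztop[win]
        zbuf[sub] = zb

    # depth: camera distance to nearest surface, normalized to scene z range
    cam_z = camera.distance
    znear = (cam_pts[:, 2] + radii).max()   # top of highest sphere
    zfar = (cam_pts[:, 2] - radii).min()    # bottom of lowest sphere
    depth = np.ones((size, size), float)
    covered = np.isfinite(zbuf)
    if znear > zfar:
        depth[covered] = (znear - zbuf[covered]) / (znear - zfar)
    else:  # single depth plane
        depth[covered] = 0.0
    np.clip(depth, 0.0, 1.0, out=depth)
    # keep the camera distance meaningful: surfaces behind the camera are clipped
    if cam_z < znear:
        depth[covered & (zbuf > cam_z)] = 0.0
    return gray, depth


def build_observation(gray: np.ndarray, depth: np.ndarray) -> Observation:
    """Stack gray and depth into the 2-channel observation."""
    gray = np.asarray(gray, float)
    depth = np.asarray(depth, float)
    if gray.shape != depth.shape:
        raise ValueError(f"channel size mismatch: {gray.shape} vs {depth.shape}")
    return Observation(gray=gray, depth=depth)


def _rgb_render(frame_table, camera, palette, annotations) -> np.ndarray:
    """RGB inspection view (same projection, per-role colors)."""
    annotations = annotations or {}
    gray, _ = rasterize(frame_table, camera, palette, annotations)
    # re-rasterize per role to recover role masks from intensities
    rgb = np.zeros((camera.image_size, camera.image_size, 3), np.uint8)
    roles = {"migrating", "target", "subgoal", "environment"}
    for role in roles:
        level = palette.intensity(role)
        mask = np.isclose(gray, level)
        rgb[mask] = palette.rgb[role]
    return rgb


def to_grayscale(rgb: np.ndarray) -> np.ndarray:
    """Standard luminance collapse of an RGB uint8 image to [0,1] floats."""
    w = np.array([0.299, 0.587, 0.114])
    return (rgb.astype(float) @ w) / 255.0


def render_views(env, cameras, out_dir: str, prefix: str = "frame") -> list[str]:
    """Write PNG files (gray + depth per camera, plus an oblique RGB view)."""
    os.makedirs(out_dir, exist_ok=True)
    state = env.get_state()
    annotations = env.annotations()
    palette = env.palette
    paths = []
    for ci, cam in enumerate(cameras):
        gray, depth = rasterize(state.cell_table, cam, palette, annotations)
        for channel, img in (("gray", gray), ("depth", depth)):
            p = os.path.join(out_dir, f"{prefix}_cam{ci}_{channel}.png")
            Image.fromarray((img * 255).astype(np.uint8), mode="L").save(p)
            paths.append(p)
    oblique = Camera(
        target_position=cameras[0].target_position if cameras else (0, 0, 0),
        distance=cameras[0].distance if cameras else 100.0,
        view="oblique", image_size=max((c.image_size for c in cameras), default=64),
        extent=cameras[0].extent if cameras else None,
    )
    rgb = _rgb_render(state.cell_table, oblique, palette, annotations)
    p = os.path.join(out_dir, f"{prefix}_oblique_rgb.png")
    Image.fromarray(rgb, mode="RGB").save(p)
    paths.append(p)
    return paths
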