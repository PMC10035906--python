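"""Assemble a renderer-agnostic 3D scene from a filtered network.

The scene is an ordered list of colored primitives — node spheres, link
polylines (*line* mode) or swept tube meshes (*volume* mode), optional
degree-bar cylinders and an optional support solid — plus a camera.
Nothing here knows about glTF or rasterization; exporters consume the
SceneModel.

Link colors encode weight: min-max normalized over the links actually
retained in the scene, then mapped through a matplotlib colormap.  A
constant-weight network maps every link to the colormap midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from matplotlib import colormaps

from .io_formats import SpatialNetwork
from . import link_geometry as lg


@dataclass
class StyleConfig:
    """Rendering style: draw mode, colors, radii and optional extras."""

    draw_mode: str = "volume"  # "line" or "volume"
    colormap: str = "viridis"
    node_radius: float = 0.03
    node_color: tuple[float, float, float] = (0.85, 0.85, 0.85)
    link_radius_scale: float = 0.01
    link_radius_min: float = 0.002
    link_radius_max: float = 0.05
    background_color: tuple[float, float, float] = (0.05, 0.05, 0.08)
    show_degree_bars: bool = False
    degree_bar_scale: float = 0.02
    degree_bar_radius: float = 0.01
    degree_bar_color: tuple[float, float, float] = (1.0, 0.8, 0.2)
    support: str = "none"  # "none", "sphere", "cube", or a mesh file path
    support_color: tuple[float, float, float] = (0.9, 0.8, 0.1)
    support_translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    support_rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)  # XYZ Euler, radians
    support_scale: float = 1.0
    tube_sides: int = 8
    sphere_subdivisions: int = 2

    def __post_init__(self) -> None:
        if self.draw_mode not in ("line", "volume"):
            raise ValueError(f"draw_mode must be 'line' or 'volume', got {self.draw_mode!r}")
        if self.tube_sides < 3:
            raise ValueError(f"tube_sides must be >= 3, got {self.tube_sides}")
        for name in ("node_radius", "link_radius_scale", "link_radius_min",
                     "link_radius_max", "degree_bar_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.colormap not in colormaps:
            raise ValueError(
                f"unknown colormap {self.colormap!r}; valid names include: "
                f"{', '.join(sorted(colormaps)[:12])}, ..."
            )


@dataclass
class Primitive:
    """One scene element: geometry plus flat color and a tag."""

    kind: str  # sphere | tube | polyline | cylinder | support-mesh
    vertices: np.ndarray
    faces: np.ndarray | None
    color: tuple[float, float, float]
    tag: str

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.faces is not None:
            self.faces = np.asarray(self.faces, dtype=np.int64)
            if self.faces.size and self.faces.max() >= len(self.vertices):
                raise ValueError(f"primitive {self.tag}: face index out of range")


@dataclass
class Camera:
    position: np.ndarray
    look_at: np.ndarray
    up: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))


@dataclass
class SceneModel:
    primitives: list[Primitive]
    camera: Camera
    background: tuple[float, float, float]

    def by_kind(self, kind: str) -> list[Primitive]:
        return [p for p in self.primitives if p.kind == kind]


def normalize_weights(weights: np.ndarray) -> np.ndarray:
    """Min-max normalize to [0, 1]; constant input maps to 0.5."""
    weights = np.asarray(weights, dtype=float)
    lo, hi = weights.min(), weights.max()
    if hi == lo:
        return np.full_like(weights, 0.5)
    return (weights - lo) / (hi - lo)


def tube_mesh(polyline: np.ndarray, radius: float, sides: int) -> tuple[np.ndarray, np.ndarray]:
    """Sweep a circular cross-section along a polyline.

    One ring of ``sides`` vertices is placed at every polyline point, rings
    joined by quads split into triangles, ends closed by fan caps around a
    center vertex.  The ring frame is parallel-transported along the curve
    so the tube does not twist at inflection points.  Consecutive duplicate
    points are merged before meshing.

    Returns (vertices, faces).
    """
    pts = np.asarray(polyline, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"polyline must be P x 3, got {pts.shape}")
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-12
    pts = pts[keep]
    if len(pts) < 2:
        raise ValueError("polyline needs at least 2 distinct points")
    if radius <= 0:
        raise ValueError(f"tube radius must be positive, got {radius}")

    tangents = np.empty_like(pts)
    tangents[0] = pts[1] - pts[0]
    tangents[-1] = pts[-1] - pts[-2]
    tangents[1:-1] = pts[2:] - pts[:-2]
    tangents /= np.linalg.norm(tangents, axis=1)[:, None]

    # parallel transport of an initial normal along the tangent field
    t0 = tangents[0]
    ref = np.array([0.0, 1.0, 0.0])
    if abs(np.dot(ref, t0)) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    n = ref - np.dot(ref, t0) * t0
    n /= np.linalg.norm(n)
    normals = [n]
    for k in range(1, len(pts)):
        t_prev, t_cur = tangents[k - 1], tangents[k]
        axis = np.cross(t_prev, t_cur)
        s = np.linalg.norm(axis)
        c = float(np.clip(np.dot(t_prev, t_cur), -1.0, 1.0))
        if s < 1e-12:
            n_new = normals[-1] if c > 0 else -normals[-1]
        else:
            axis = axis / s
            ang = np.arctan2(s, c)
            n_prev = normals[-1]
            n_new = (
                n_prev * np.cos(ang)
                + np.cross(axis, n_prev) * np.sin(ang)
                + axis * np.dot(axis, n_prev) * (1 - np.cos(ang))
            )
        n_new = n_new - np.dot(n_new, t_cur) * t_cur
        n_new /= np.linalg.norm(n_new)
        normals.append(n_new)

    theta = 2.0 * np.pi * np.arange(sides) / sides
    verts = []
    for p, t, nrm in zip(pts, tangents, normals):
        b = np.cross(t, nrm)
        ring = p + radius * (np.outer(np.cos(theta), nrm) + np.outer(np.sin(theta), b))
        verts.append(ring)
    vertices = np.vstack(verts)

    faces = []
    for k in range(len(pts) - 1):
        o0, o1 = k * sides, (k + 1) * sides
        for s_ in range(sides):
            s1 = (s_ + 1) % sides
            faces.append([o0 + s_, o1 + s_, o1 + s1])
            faces.append([o0 + s_, o1 + s1, o0 + s1])
    # end caps: fan around a center vertex at each end
    c0 = len(vertices)
    c1 = c0 + 1
    vertices = np.vstack([vertices, pts[0], pts[-1]])
    last = (len(pts) - 1) * sides
    for s_ in range(sides):
        s1 = (s_ + 1) % sides
        faces.append([c0, s1, s_])
        faces.append([c1, last + s_, last + s1])
    return vertices, np.asarray(faces, dtype=np.int64)


def support_primitive(
    kind: str,
    translation=(0.0, 0.0, 0.0),
    rotation=(0.0, 0.0, 0.0),
    scale: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """A support solid: unit sphere, unit cube, or a user OBJ/PLY mesh.

    The unit primitive is scaled, then rotated (XYZ Euler angles in
    radians), then translated.  Returns (vertices, faces).
    """
    if kind == "sphere":
        mesh = trimesh.creation.icosphere(subdivisions=2, radius=1.0)
    elif kind == "cube":
        mesh = trimesh.creation.box(extents=(2.0, 2.0, 2.0))
    else:
        path = Path(kind)
        if not path.exists():
            raise ValueError(f"support mesh file not found: {kind}")
        mesh = trimesh.load(str(path), force="mesh")
    verts = np.asarray(mesh.vertices, dtype=float) * float(scale)
    rx, ry, rz = rotation
    for axis, ang in (((1, 0, 0), rx), ((0, 1, 0), ry), ((0, 0, 1), rz)):
        if ang:
            rot = trimesh.transformations.rotation_matrix(ang, axis)[:3, :3]
            verts = verts @ rot.T
    verts = verts + np.asarray(translation, dtype=float)
    return verts, np.asarray(mesh.faces, dtype=np.int64)


def default_camera(coords: np.ndarray) -> Camera:
    """Look at the barycenter from 2.5x the bounding-sphere radius along +x."""
    center = lg.barycenter(coords)
    r = float(np.max(np.linalg.norm(coords - center, axis=1)))
    r = max(r, 1e-6)
    return Camera(
        position=center + np.array([2.5 * r, 0.0, 0.0]),
        look_at=center,
        up=np.array([0.0, 1.0, 0.0]),
    )


def build_scene(
    net: SpatialNetwork,
    geom: lg.GeometryConfig | None = None,
    shape: lg.ShapeParams | None = None,
    style: StyleConfig | None = None,
) -> SceneModel:
    """Build the full scene: node spheres, link curves, bars, support.

    One sphere per node; one link primitive per retained link (polyline in
    line mode, tube in volume mode), colored by normalized weight; degree
    bars and support solid appended when enabled.  Deterministic: identical
    inputs give a bit-identical scene.
    """
    if net.n_nodes < 1:
        raise ValueError("cannot build a scene from an empty network")
    geom = geom or lg.GeometryConfig()
    shape = shape or lg.ShapeParams.preset("Default")
    style = style or StyleConfig()
    C = geom.resolve_reference(net.coords)
    cmap = colormaps[style.colormap]

    primitives: list[Primitive] = []
    unit_sphere = trimesh.creation.icosphere(
        subdivisions=style.sphere_subdivisions, radius=1.0
    )
    sphere_v = np.asarray(unit_sphere.vertices)
    sphere_f = np.asarray(unit_sphere.faces, dtype=np.int64)
    for i, p in enumerate(net.coords):
        primitives.append(
            Primitive(
                kind="sphere",
                vertices=sphere_v * style.node_radius + p,
                faces=sphere_f.copy(),
                color=style.node_color,
                tag=f"node_{i}",
            )
        )

    pairs = net.link_pairs()
    weights = net.link_weights()
    norm = normalize_weights(weights) if len(weights) else weights
    for (i, j), wgt, t in zip(pairs, weights, norm):
        curve = lg.link_path(
            net.coords[i], net.coords[j], C, shape, geom.samples_per_half
        )
        radius = lg.link_radius(
            curve.frame.d_ij,
            style.link_radius_scale,
            style.link_radius_min,
            style.link_radius_max,
        )
        color = tuple(float(c) for c in cmap(float(t))[:3])
        tag = f"link_{i}_{j}"
        if style.draw_mode == "line":
            primitives.append(
                Primitive("polyline", curve.polyline, None, color, tag)
            )
        else:
            v, f = tube_mesh(curve.polyline, radius, style.tube_sides)
            primitives.append(Primitive("tube", v, f, color, tag))

    if style.show_degree_bars:
        for i, (p, deg) in enumerate(zip(net.coords, net.degrees())):
            if deg == 0:
                continue
            base, tip = lg.degree_bar(p, C, int(deg), style.degree_bar_scale)
            v, f = tube_mesh(
                np.vstack([base, tip]), style.degree_bar_radius, style.tube_sides
            )
            primitives.append(
                Primitive("cylinder", v, f, style.degree_bar_color, f"bar_{i}")
            )

    if style.support != "none":
        v, f = support_primitive(
            style.support,
            translation=style.support_translation,
            rotation=style.support_rotation,
            scale=style.support_scale,
        )
        primitives.append(
            Primitive("support-mesh", v, f, style.support_color, "support")
        )

    return SceneModel(
        primitives=primitives,
        camera=default_camera(net.coords),
        background=style.background_color,
    )
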