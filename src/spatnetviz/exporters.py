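"""Scene serialization: glTF 2.0 files and high-resolution raster images.

glTF export writes a single self-contained ``.gltf`` (JSON with an
embedded base64 buffer): one mesh node per scene primitive, named after
its tag (``node_12``, ``link_3_7``, ``bar_4``, ``support``), triangle
meshes as mode TRIANGLES and line-mode polylines as mode LINE_STRIP, each
with a flat base-color material.  The generator string is fixed and no
timestamp is written, so identical scenes produce byte-identical files.

Raster export renders the scene offscreen with a painter's-algorithm
software projector on the matplotlib Agg backend: orthographic projection
from the scene camera, primitives depth-sorted far-to-near.  The default
output matches the canonical export spec: 6000 x 3500 pixels at 96 DPI in
TIFF.  The camera and projection window are serialized to a JSON sidecar
so a render can be reproduced exactly.
"""

from __future__ import annotations

import base64
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
from matplotlib.collections import LineCollection, PolyCollection
from matplotlib.patches import Circle
from PIL import Image

from .scene_builder import Camera, SceneModel

_GLTF_TRIANGLES = 4
_GLTF_LINE_STRIP = 3
_COMP_FLOAT = 5126
_COMP_UINT32 = 5125


@dataclass
class RasterSpec:
    """Raster output geometry: pixel dimensions, DPI metadata, format."""

    width: int = 6000
    height: int = 3500
    dpi: float = 96.0
    format: str = "tiff"

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("raster dimensions must be >= 1 pixel")
        if self.dpi <= 0:
            raise ValueError("dpi must be positive")
        if self.format not in ("tiff", "png"):
            raise ValueError(f"format must be 'tiff' or 'png', got {self.format!r}")


# ---------------------------------------------------------------------------
# glTF 2.0


def export_gltf(scene: SceneModel, path: str | Path) -> None:
    """Write the scene as a single embedded-buffer glTF 2.0 file."""
    if not scene.primitives:
        raise ValueError("cannot export an empty scene")
    path = Path(path)

    buffer = bytearray()
    accessors: list[dict] = []
    buffer_views: list[dict] = []
    meshes: list[dict] = []
    nodes: list[dict] = []
    materials: list[dict] = []

    def add_view(data: bytes, target: int | None) -> int:
        offset = len(buffer)
        buffer.extend(data)
        while len(buffer) % 4:
            buffer.append(0)
        view = {"buffer": 0, "byteOffset": offset, "byteLength": len(data)}
        if target is not None:
            view["target"] = target
        buffer_views.append(view)
        return len(buffer_views) - 1

    for prim in scene.primitives:
        verts = np.ascontiguousarray(prim.vertices, dtype=np.float32)
        pos_view = add_view(verts.tobytes(), 34962)
        accessors.append(
            {
                "bufferView": pos_view,
                "componentType": _COMP_FLOAT,
                "count": len(verts),
                "type": "VEC3",
                "min": verts.min(axis=0).tolist(),
                "max": verts.max(axis=0).tolist(),
            }
        )
        pos_acc = len(accessors) - 1

        materials.append(
            {
                "name": f"{prim.tag}_mat",
                "pbrMetallicRoughness": {
                    "baseColorFactor": [*(float(c) for c in prim.color), 1.0],
                    "metallicFactor": 0.0,
                    "roughnessFactor": 0.9,
                },
            }
        )
        mat = len(materials) - 1

        gltf_prim: dict = {"attributes": {"POSITION": pos_acc}, "material": mat}
        if prim.faces is None:
            gltf_prim["mode"] = _GLTF_LINE_STRIP
        else:
            idx = np.ascontiguousarray(prim.faces.ravel(), dtype=np.uint32)
            idx_view = add_view(idx.tobytes(), 34963)
            accessors.append(
                {
                    "bufferView": idx_view,
                    "componentType": _COMP_UINT32,
                    "count": int(idx.size),
                    "type": "SCALAR",
                }
            )
            gltf_prim["indices"] = len(accessors) - 1
            gltf_prim["mode"] = _GLTF_TRIANGLES

        meshes.append({"name": prim.tag, "primitives": [gltf_prim]})
        nodes.append({"name": prim.tag, "mesh": len(meshes) - 1})

    uri = "data:application/octet-stream;base64," + base64.b64encode(bytes(buffer)).decode()
    doc = {
        "asset": {"version": "2.0", "generator": "spatnetviz"},
        "scene": 0,
        "scenes": [{"nodes": list(range(len(nodes)))}],
        "nodes": nodes,
        "meshes": meshes,
        "materials": materials,
        "accessors": accessors,
        "bufferViews": buffer_views,
        "buffers": [{"byteLength": len(buffer), "uri": uri}],
        "extras": {
            "camera": {
                "position": scene.camera.position.tolist(),
                "look_at": scene.camera.look_at.tolist(),
                "up": scene.camera.up.tolist(),
            },
            "background": list(scene.background),
        },
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, separators=(",", ":"), sort_keys=True)


def load_gltf(path: str | Path) -> list[dict]:
    """Read back a glTF file written by :func:`export_gltf`.

    Returns one record per mesh node: ``{"name", "mode", "vertices",
    "faces" (None for line strips), "color"}``.
    """
    with open(path) as fh:
        doc = json.load(fh)
    uri = doc["buffers"][0]["uri"]
    prefix = "data:application/octet-stream;base64,"
    if not uri.startswith(prefix):
        raise ValueError("expected an embedded base64 buffer")
    buffer = base64.b64decode(uri[len(prefix):])

    def read_accessor(idx: int) -> np.ndarray:
        acc = doc["accessors"][idx]
        view = doc["bufferViews"][acc["bufferView"]]
        start = view.get("byteOffset", 0) + acc.get("byteOffset", 0)
        n_comp = {"VEC3": 3, "SCALAR": 1}[acc["type"]]
        dtype = {_COMP_FLOAT: np.float32, _COMP_UINT32: np.uint32}[acc["componentType"]]
        count = acc["count"] * n_comp
        arr = np.frombuffer(buffer, dtype=dtype, count=count, offset=start)
        return arr.reshape(acc["count"], n_comp) if n_comp > 1 else arr

    out = []
    for node in doc["nodes"]:
        mesh = doc["meshes"][node["mesh"]]
        prim = mesh["primitives"][0]
        verts = read_accessor(prim["attributes"]["POSITION"]).astype(float)
        faces = None
        if "indices" in prim:
            faces = read_accessor(prim["indices"]).astype(np.int64).reshape(-1, 3)
        color = None
        if "material" in prim:
            mat = doc["materials"][prim["material"]]
            color = tuple(mat["pbrMetallicRoughness"]["baseColorFactor"][:3])
        out.append(
            {
                "name": node["name"],
                "mode": prim.get("mode", _GLTF_TRIANGLES),
                "vertices": verts,
                "faces": faces,
                "color": color,
            }
        )
    return out


# ---------------------------------------------------------------------------
# raster


def _camera_basis(camera: Camera) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    forward = camera.look_at - camera.position
    fn = np.linalg.norm(forward)
    forward = forward / fn if fn > 0 else np.array([1.0, 0.0, 0.0])
    right = np.cross(forward, camera.up)
    rn = np.linalg.norm(right)
    if rn < 1e-12:  # camera looking along up: pick any perpendicular
        right = np.cross(forward, np.array([1.0, 0.0, 0.0]))
        rn = np.linalg.norm(right)
        if rn < 1e-12:
            right = np.cross(forward, np.array([0.0, 0.0, 1.0]))
            rn = np.linalg.norm(right)
    right /= rn
    up = np.cross(right, forward)
    return right, up, forward


def _project(points: np.ndarray, camera: Camera, basis) -> tuple[np.ndarray, np.ndarray]:
    right, up, forward = basis
    rel = points - camera.position
    xy = np.column_stack([rel @ right, rel @ up])
    depth = rel @ forward
    return xy, depth


def export_raster(
    scene: SceneModel,
    spec: RasterSpec | None = None,
    path: str | Path = "render.tiff",
    write_sidecar: bool = True,
) -> None:
    """Render the scene to a raster image of exactly the requested size.

    Orthographic projection from the scene camera; primitives painted
    far-to-near (and faces depth-sorted within each mesh).  Node labels
    are never rasterized.  DPI metadata is written into the image file
    (TIFF resolution tags / PNG pHYs).  A JSON sidecar records the camera
    and projection window.
    """
    spec = spec or RasterSpec()
    path = Path(path)
    if not scene.primitives:
        raise ValueError("cannot render an empty scene")
    basis = _camera_basis(scene.camera)

    # projection window: bounding box of all projected vertices, padded,
    # then expanded to the image aspect ratio so scale is isotropic
    all_xy = np.vstack(
        [_project(p.vertices, scene.camera, basis)[0] for p in scene.primitives]
    )
    lo, hi = all_xy.min(axis=0), all_xy.max(axis=0)
    pad = 0.05 * max(float(np.max(hi - lo)), 1e-6)
    lo, hi = lo - pad, hi + pad
    cx, cy = (lo + hi) / 2.0
    half_w, half_h = (hi[0] - lo[0]) / 2.0, (hi[1] - lo[1]) / 2.0
    aspect = spec.width / spec.height
    if half_w / half_h < aspect:
        half_w = half_h * aspect
    else:
        half_h = half_w / aspect

    fig = plt.figure(
        figsize=(spec.width / spec.dpi, spec.height / spec.dpi), dpi=spec.dpi
    )
    try:
        ax = fig.add_axes([0.0, 0.0, 1.0, 1.0])
        ax.set_axis_off()
        ax.set_xlim(cx - half_w, cx + half_w)
        ax.set_ylim(cy - half_h, cy + half_h)
        fig.patch.set_facecolor(scene.background)
        ax.set_facecolor(scene.background)

        order = []
        for k, prim in enumerate(scene.primitives):
            _, depth = _project(prim.vertices, scene.camera, basis)
            order.append((float(np.mean(depth)), k))
        order.sort(reverse=True)  # far first

        px_per_unit = spec.width / (2 * half_w)
        for _, k in order:
            prim = scene.primitives[k]
            xy, depth = _project(prim.vertices, scene.camera, basis)
            if prim.kind == "sphere":
                center = xy.mean(axis=0)
                radius = float(np.max(np.linalg.norm(xy - center, axis=1)))
                ax.add_patch(Circle(center, radius, facecolor=prim.color, edgecolor="none"))
            elif prim.faces is None:
                segs = np.stack([xy[:-1], xy[1:]], axis=1)
                ax.add_collection(
                    LineCollection(
                        segs, colors=[prim.color], linewidths=72.0 / spec.dpi
                    )
                )
            else:
                tris = xy[prim.faces]
                face_depth = depth[prim.faces].mean(axis=1)
                far_to_near = np.argsort(-face_depth)
                ax.add_collection(
                    PolyCollection(
                        tris[far_to_near], facecolors=[prim.color], edgecolors="none"
                    )
                )
        _ = px_per_unit  # isotropic by construction; kept for sidecar readers

        if spec.format == "tiff":
            fig.savefig(path, dpi=spec.dpi, format="tiff",
                        facecolor=scene.background)
        else:
            fig.savefig(path, dpi=spec.dpi, format="png",
                        facecolor=scene.background)
    finally:
        plt.close(fig)

    if write_sidecar:
        sidecar = {
            "camera": {
                "position": scene.camera.position.tolist(),
                "look_at": scene.camera.look_at.tolist(),
                "up": scene.camera.up.tolist(),
            },
            "projection": "orthographic",
            "window": {
                "center": [float(cx), float(cy)],
                "half_width": float(half_w),
                "half_height": float(half_h),
            },
            "width": spec.width,
            "height": spec.height,
            "dpi": spec.dpi,
        }
        with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
            json.dump(sidecar, fh, indent=1)


def read_raster_info(path: str | Path) -> dict:
    """Reload an exported image and report its pixel size and DPI tags."""
    with Image.open(path) as im:
        return {"width": im.width, "height": im.height, "dpi": im.info.get("dpi")}
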