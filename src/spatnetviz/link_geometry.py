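"""Per-link curve geometry: the two-piece Bezier path and its companions.

Every link between nodes ``S_i`` and ``S_j`` is drawn in the plane spanned
by the two nodes and a virtual reference point ``C`` (by default the
barycenter of all node positions, optionally shifted along the vertical
axis).  With ``M`` the chord midpoint and ``d_ij`` the internode Euclidean
distance, the curve climbs to a summit ``U`` on the line through ``C`` and
``M``, placed on the side of ``M`` opposite ``C`` so links bow away from
the reference point.  Four dimensionless coefficients control the shape:

* ``a1`` — summit height:      ``h   = a1 * d_ij``, distance from M to U;
* ``a2`` — summit handles:     ``d_U = a2 * d_ij / 2``, distance from U to
  the inner control points, laid perpendicular to the U-M reference line;
* ``a3`` — node angle:         ``alpha = a3 * pi``, departure angle of the
  curve at each node, measured in the link plane from the chord direction;
* ``a4`` — node handles:       ``d_S = a4 * d_ij / 2``, distance from each
  node to its adjacent control point.

The path consists of two cubic Bezier pieces with control polygons
``(S_i, B1, B2, U)`` and ``(U, B2', B1', S_j)``: each piece has two
interior control points, which a quadratic cannot represent.  Eight named
presets cover the canonical silhouettes (Default, Bell, Triangle, Circle,
Circle2, Square, Peak, Straight).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import logging

import numpy as np

logger = logging.getLogger(__name__)

_PLANE_TOL = 1e-9  # relative to d_ij


@dataclass(frozen=True)
class ShapeParams:
    """The four link-shape coefficients (a1, a2, a3, a4)."""

    a1: float = 0.75
    a2: float = 0.5
    a3: float = 0.38
    a4: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.a1, self.a2, self.a3, self.a4)
        if not all(np.isfinite(vals)):
            raise ValueError(f"shape coefficients must be finite, got {vals}")
        if self.a1 < 0 or self.a2 < 0 or self.a4 < 0:
            raise ValueError("a1, a2, a4 must be >= 0")
        if not 0.0 <= self.a3 <= 1.0:
            raise ValueError(f"a3 must lie in [0, 1], got {self.a3}")

    @classmethod
    def preset(cls, name: str) -> "ShapeParams":
        """Resolve a named preset; raises ValueError listing valid names."""
        try:
            return cls(*PRESETS[name])
        except KeyError:
            raise ValueError(
                f"unknown preset {name!r}; valid presets: {', '.join(PRESETS)}"
            ) from None


#: Named coefficient quadruples (a1, a2, a3, a4).
PRESETS: dict[str, tuple[float, float, float, float]] = {
    "Default": (0.75, 0.5, 0.38, 0.0),
    "Bell": (0.75, 0.5, 0.0, 0.5),
    "Triangle": (0.75, 0.0, 0.0, 0.0),
    "Circle": (0.5, 0.5, 0.5, 0.5),
    "Circle2": (0.9, 1.0, 0.8, 1.0),
    "Square": (0.5, 1.0, 0.5, 1.0),
    "Peak": (0.75, 0.0, 0.0, 1.0),
    "Straight": (0.0, 0.0, 0.0, 0.0),
}


@dataclass
class GeometryConfig:
    """Reference point and sampling resolution for link construction.

    ``reference_point`` defaults to the barycenter of all node coordinates
    when left as None; ``altitude_offset`` shifts it along the vertical (y)
    axis.  ``samples_per_half`` is the number of parameter steps per Bezier
    piece, so a link polyline has ``2 * samples_per_half + 1`` points.
    """

    reference_point: np.ndarray | None = None
    altitude_offset: float = 0.0
    samples_per_half: int = 32

    def __post_init__(self) -> None:
        if self.samples_per_half < 2:
            raise ValueError("samples_per_half must be >= 2")
        if self.reference_point is not None:
            rp = np.asarray(self.reference_point, dtype=float)
            if rp.shape != (3,) or not np.all(np.isfinite(rp)):
                raise ValueError("reference_point must be a finite 3-vector")
            self.reference_point = rp

    def resolve_reference(self, coords: np.ndarray) -> np.ndarray:
        c = barycenter(coords) if self.reference_point is None else self.reference_point
        return c + np.array([0.0, self.altitude_offset, 0.0])


@dataclass
class ChordFrame:
    """Orthonormal in-plane frame of a single link.

    ``u`` points along the chord from S_i to S_j; ``w`` is the elevation
    direction: the component of (M - C) orthogonal to the chord, pointing
    from the reference point C toward and beyond the midpoint M.
    """

    M: np.ndarray
    u: np.ndarray
    w: np.ndarray
    d_ij: float


@dataclass
class LinkCurve:
    """Fully resolved geometry of one link."""

    S_i: np.ndarray
    S_j: np.ndarray
    U: np.ndarray
    B1: np.ndarray
    B2: np.ndarray
    B2p: np.ndarray
    B1p: np.ndarray
    h: float
    d_U: float
    d_S: float
    alpha: float
    polyline: np.ndarray
    radius: float = 1.0
    color_scalar: float = 0.0
    frame: ChordFrame = field(repr=False, default=None)  # type: ignore[assignment]


def barycenter(coords: np.ndarray) -> np.ndarray:
    """Arithmetic mean of the node coordinates (the default C)."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 1:
        raise ValueError(f"expected a non-empty N x 3 array, got shape {coords.shape}")
    return coords.mean(axis=0)


def _orthonormal_elevation(v: np.ndarray, u: np.ndarray, d_ij: float) -> np.ndarray | None:
    """Component of v orthogonal to u, normalized; None if degenerate."""
    w_raw = v - np.dot(v, u) * u
    norm = np.linalg.norm(w_raw)
    if norm < _PLANE_TOL * d_ij:
        return None
    return w_raw / norm


def chord_frame(S_i: np.ndarray, S_j: np.ndarray, C: np.ndarray) -> ChordFrame:
    """Build the in-plane orthonormal frame (M, u, w) of a link.

    Degenerate case: if C lies on the chord line the plane is undefined;
    fall back to the global vertical for w, then to the lateral x-axis
    when the chord itself is vertical.
    """
    S_i = np.asarray(S_i, dtype=float)
    S_j = np.asarray(S_j, dtype=float)
    C = np.asarray(C, dtype=float)
    chord = S_j - S_i
    d_ij = float(np.linalg.norm(chord))
    if d_ij == 0.0:
        raise ValueError(
            f"coincident nodes at {S_i.tolist()}: zero-length links are not drawable"
        )
    u = chord / d_ij
    M = (S_i + S_j) / 2.0
    w = _orthonormal_elevation(M - C, u, d_ij)
    if w is None:
        logger.debug("degenerate frame (C on chord line) at M=%s; vertical fallback", M)
        w = _orthonormal_elevation(np.array([0.0, 1.0, 0.0]), u, 1.0)
        if w is None:  # vertical chord: use the lateral axis
            w = _orthonormal_elevation(np.array([1.0, 0.0, 0.0]), u, 1.0)
    return ChordFrame(M=M, u=u, w=w, d_ij=d_ij)


def summit(frame: ChordFrame, a1: float) -> np.ndarray:
    """Summit U = M + a1 * d_ij * w; |U - M| = h = a1 * d_ij exactly."""
    return frame.M + a1 * frame.d_ij * frame.w


def control_points(
    frame: ChordFrame,
    U: np.ndarray,
    params: ShapeParams,
    S_i: np.ndarray | None = None,
    S_j: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """The four interior control points (B1, B2, B2p, B1p).

    B1/B1p sit at distance d_S from their node, at angle alpha from the
    chord direction rotated toward the summit side (mirrored at S_j).
    B2/B2p sit at distance d_U from U along -u/+u: perpendicular to the
    U-M reference line, the fixed square-angle constraint.  Endpoints are
    reconstructed from the frame when not given explicitly.
    """
    alpha = params.a3 * np.pi
    d_S = params.a4 * frame.d_ij / 2.0
    d_U = params.a2 * frame.d_ij / 2.0
    if S_i is None:
        S_i = frame.M - frame.u * frame.d_ij / 2.0
    if S_j is None:
        S_j = frame.M + frame.u * frame.d_ij / 2.0
    dep = np.cos(alpha) * frame.u + np.sin(alpha) * frame.w
    dep_m = -np.cos(alpha) * frame.u + np.sin(alpha) * frame.w
    B1 = S_i + d_S * dep
    B1p = S_j + d_S * dep_m
    B2 = U - d_U * frame.u
    B2p = U + d_U * frame.u
    return B1, B2, B2p, B1p


def _cubic_bezier(p0, p1, p2, p3, t: np.ndarray) -> np.ndarray:
    t = t[:, None]
    s = 1.0 - t
    return s**3 * p0 + 3 * s**2 * t * p1 + 3 * s * t**2 * p2 + t**3 * p3


def link_path(
    S_i: np.ndarray,
    S_j: np.ndarray,
    C: np.ndarray,
    params: ShapeParams,
    samples_per_half: int = 32,
) -> LinkCurve:
    """Construct the full two-piece cubic Bezier path of one link.

    Each half is sampled at ``samples_per_half + 1`` uniformly spaced
    parameter values; the halves share the summit U, which is not
    duplicated, giving ``2 * samples_per_half + 1`` polyline points.  The
    polyline starts exactly at S_i and ends exactly at S_j.
    """
    S_i = np.asarray(S_i, dtype=float)
    S_j = np.asarray(S_j, dtype=float)
    frame = chord_frame(S_i, S_j, C)
    U = summit(frame, params.a1)
    B1, B2, B2p, B1p = control_points(frame, U, params, S_i=S_i, S_j=S_j)
    t = np.linspace(0.0, 1.0, samples_per_half + 1)
    first = _cubic_bezier(S_i, B1, B2, U, t)
    second = _cubic_bezier(U, B2p, B1p, S_j, t)
    polyline = np.vstack([first, second[1:]])
    polyline[0] = S_i  # exact endpoint interpolation, no float residue
    polyline[-1] = S_j
    polyline[samples_per_half] = U
    return LinkCurve(
        S_i=S_i,
        S_j=S_j,
        U=U,
        B1=B1,
        B2=B2,
        B2p=B2p,
        B1p=B1p,
        h=params.a1 * frame.d_ij,
        d_U=params.a2 * frame.d_ij / 2.0,
        d_S=params.a4 * frame.d_ij / 2.0,
        alpha=params.a3 * np.pi,
        polyline=polyline,
        frame=frame,
    )


def link_radius(d_ij: float, scale: float, r_min: float, r_max: float) -> float:
    """Link tube radius: scale / d_ij clamped to [r_min, r_max].

    The radius decreases with internode distance so that the highest
    (longest) links are also the thinnest.
    """
    if d_ij <= 0:
        raise ValueError(f"internode distance must be positive, got {d_ij}")
    if not (0 < r_min <= r_max):
        raise ValueError(f"need 0 < r_min <= r_max, got ({r_min}, {r_max})")
    return float(np.clip(scale / d_ij, r_min, r_max))


def link_color_scalar(weight: float) -> float:
    """Color scalar of a link: its weight, passed through unchanged.

    Normalization to [0, 1] over the retained link set happens when the
    scene is assembled.
    """
    return float(weight)


def degree_bar(
    node: np.ndarray, C: np.ndarray, degree: int, bar_scale: float
) -> tuple[np.ndarray, np.ndarray]:
    """Degree glyph: a segment from the node pointing radially away from C.

    Height is exactly ``bar_scale * degree``.  For nodes lying on a sphere
    centered at C the bars are perpendicular to the spherical surface.
    A node coinciding with C falls back to the vertical direction.
    """
    node = np.asarray(node, dtype=float)
    C = np.asarray(C, dtype=float)
    v = node - C
    norm = np.linalg.norm(v)
    direction = v / norm if norm > 0 else np.array([0.0, 1.0, 0.0])
    return node, node + bar_scale * degree * direction


def with_style(curve: LinkCurve, weight: float, radius: float) -> LinkCurve:
    """Attach rendering scalars to a geometric curve."""
    return replace(curve, color_scalar=link_color_scalar(weight), radius=radius)
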