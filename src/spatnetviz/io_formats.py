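"""Reading and writing spatial-network inputs.

A spatial network is a graph whose nodes occupy fixed positions in physical
space.  Inputs are plain CSV files (coordinates, adjacency matrix, optional
labels) or a single JSON bundle carrying all three.  Coordinate files are,
by default, interpreted in ``xzy`` axis order — the second column is the
*depth* axis and the third the vertical (altitude) axis — and permuted into
the internal y-up, right-handed ``x, y, z`` convention that every other
module assumes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Tolerance under which an adjacency matrix counts as symmetric.
SYMMETRY_TOL = 1e-9

_AXIS_ORDERS = {
    # input column -> internal (x, y, z) column
    "xyz": (0, 1, 2),
    "xzy": (0, 2, 1),
}


class NetworkFormatError(ValueError):
    """Raised for malformed coordinate/adjacency/label input."""


@dataclass
class SpatialNetwork:
    """Node coordinates plus a symmetric non-negative weight matrix.

    Attributes
    ----------
    coords
        ``(N, 3)`` float array in internal ``x, y, z`` order with ``y`` the
        vertical (altitude) axis.
    weights
        ``(N, N)`` symmetric float array; ``weights[i, j] == 0`` means no
        link, the diagonal is zero (self-loops are never drawn).
    labels
        Optional list of ``N`` node labels.
    """

    coords: np.ndarray
    weights: np.ndarray
    labels: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        validate_network(self)

    @property
    def n_nodes(self) -> int:
        return self.coords.shape[0]

    @property
    def n_links(self) -> int:
        iu = np.triu_indices(self.n_nodes, k=1)
        return int(np.count_nonzero(self.weights[iu]))

    def link_pairs(self) -> np.ndarray:
        """Return the ``(L, 2)`` array of linked node index pairs, i < j,
        in ascending lexicographic order."""
        i, j = np.nonzero(np.triu(self.weights, k=1))
        return np.column_stack([i, j])

    def link_weights(self) -> np.ndarray:
        pairs = self.link_pairs()
        return self.weights[pairs[:, 0], pairs[:, 1]]

    def degrees(self) -> np.ndarray:
        """Unweighted node degrees (count of incident nonzero weights)."""
        return np.count_nonzero(self.weights, axis=1)

    def __eq__(self, other: object) -> bool:  # value equality for round-trips
        if not isinstance(other, SpatialNetwork):
            return NotImplemented
        return (
            self.coords.shape == other.coords.shape
            and np.array_equal(self.coords, other.coords)
            and np.array_equal(self.weights, other.weights)
            and self.labels == other.labels
        )


def validate_network(net: SpatialNetwork) -> None:
    """Check every SpatialNetwork invariant; raise NetworkFormatError."""
    c, w = net.coords, net.weights
    if c.ndim != 2 or c.shape[1] != 3:
        raise NetworkFormatError(f"coordinates must be N x 3, got {c.shape}")
    n = c.shape[0]
    if n < 1:
        raise NetworkFormatError("network must contain at least one node")
    if not np.all(np.isfinite(c)):
        raise NetworkFormatError("coordinates contain non-finite values")
    if w.shape != (n, n):
        raise NetworkFormatError(
            f"weight matrix shape {w.shape} does not match {n} coordinate rows"
        )
    if not np.all(np.isfinite(w)):
        raise NetworkFormatError("weights contain non-finite values")
    if np.any(w < 0):
        raise NetworkFormatError("weights must be non-negative")
    if np.any(np.abs(w - w.T) > SYMMETRY_TOL):
        raise NetworkFormatError(
            "weight matrix is not symmetric (directed networks are not supported)"
        )
    if np.any(np.diag(w) != 0):
        raise NetworkFormatError("weight matrix diagonal must be zero (no self-loops)")
    if net.labels is not None and len(net.labels) != n:
        raise NetworkFormatError(
            f"{len(net.labels)} labels provided for {n} nodes"
        )


def _read_numeric_csv(path: str | Path) -> list[list[float]]:
    """Parse a headerless comma-separated numeric file, reporting the first
    offending line.  A non-numeric first row is rejected as a header."""
    path = Path(path)
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split(",")
            try:
                rows.append([float(f) for f in fields])
            except ValueError:
                kind = "header row (non-numeric)" if lineno == 1 else "non-numeric field"
                raise NetworkFormatError(
                    f"{path}: line {lineno}: {kind}: {line!r}"
                ) from None
    if not rows:
        raise NetworkFormatError(f"{path}: file is empty")
    return rows


def read_coordinates(path: str | Path, axis_order: str = "xzy") -> np.ndarray:
    """Read node coordinates from a headerless 3-column CSV.

    With the default ``axis_order="xzy"`` the file's second column becomes
    the internal depth (z) coordinate and the third column the vertical (y)
    coordinate.
    """
    if axis_order not in _AXIS_ORDERS:
        raise NetworkFormatError(
            f"unknown axis_order {axis_order!r}; expected one of {sorted(_AXIS_ORDERS)}"
        )
    rows = _read_numeric_csv(path)
    for lineno, row in enumerate(rows, start=1):
        if len(row) != 3:
            raise NetworkFormatError(
                f"{path}: line {lineno}: expected 3 coordinate fields, got {len(row)}"
            )
    raw = np.asarray(rows, dtype=float)
    perm = _AXIS_ORDERS[axis_order]
    coords = np.empty_like(raw)
    coords[:, perm] = raw  # input column k lands on internal axis perm[k]
    if not np.all(np.isfinite(coords)):
        raise NetworkFormatError(f"{path}: non-finite coordinate")
    return coords


def read_adjacency(path: str | Path, symmetrize: bool = False) -> np.ndarray:
    """Read an N x N adjacency matrix from a headerless CSV.

    Strict by default: asymmetry beyond ``SYMMETRY_TOL`` or a nonzero
    diagonal is an error.  With ``symmetrize=True`` the matrix is replaced
    by ``(A + A.T) / 2`` and the diagonal zeroed, with a logged warning.
    """
    rows = _read_numeric_csv(path)
    n = len(rows)
    for lineno, row in enumerate(rows, start=1):
        if len(row) != n:
            raise NetworkFormatError(
                f"{path}: non-square matrix: line {lineno} has {len(row)} "
                f"fields for {n} rows"
            )
    a = np.asarray(rows, dtype=float)
    if np.any(a < 0):
        raise NetworkFormatError(f"{path}: negative weight")
    if symmetrize:
        if np.any(np.abs(a - a.T) > SYMMETRY_TOL):
            logger.warning("%s: asymmetric matrix symmetrized as (A + A.T)/2", path)
        a = (a + a.T) / 2.0
        if np.any(np.diag(a) != 0):
            logger.warning("%s: nonzero diagonal zeroed", path)
            np.fill_diagonal(a, 0.0)
    else:
        if np.any(np.abs(a - a.T) > SYMMETRY_TOL):
            raise NetworkFormatError(
                f"{path}: matrix is asymmetric; pass symmetrize=True to coerce"
            )
        if np.any(np.diag(a) != 0):
            raise NetworkFormatError(f"{path}: nonzero diagonal (self-loops)")
    return a


def read_labels(path: str | Path) -> list[str]:
    """Read one node label per line; length is checked at assembly."""
    with open(path) as fh:
        labels = [line.rstrip("\n") for line in fh]
    while labels and labels[-1] == "":
        labels.pop()
    return labels


def assemble_network(
    coords: np.ndarray,
    weights: np.ndarray,
    labels: Sequence[str] | None = None,
) -> SpatialNetwork:
    """Build and validate a SpatialNetwork from parsed parts."""
    return SpatialNetwork(coords, weights, list(labels) if labels else None)


def read_network_csv(
    coords_path: str | Path,
    adjacency_path: str | Path,
    labels_path: str | Path | None = None,
    axis_order: str = "xzy",
    symmetrize: bool = False,
) -> SpatialNetwork:
    """Read a full network from its CSV parts."""
    coords = read_coordinates(coords_path, axis_order=axis_order)
    weights = read_adjacency(adjacency_path, symmetrize=symmetrize)
    labels = read_labels(labels_path) if labels_path is not None else None
    return assemble_network(coords, weights, labels)


def read_network_bundle(path: str | Path) -> SpatialNetwork:
    """Read a network from a single JSON bundle.

    Schema: an object with keys ``"coordinates"`` (N x 3 array, in
    ``axis_order``), ``"matrix"`` (N x N array), optional ``"labels"``
    (N strings) and optional ``"axis_order"`` (default ``"xzy"``).
    """
    path = Path(path)
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise NetworkFormatError(f"{path}: invalid JSON: {exc}") from None
    if not isinstance(data, dict):
        raise NetworkFormatError(f"{path}: bundle must be a JSON object")
    for key in ("coordinates", "matrix"):
        if key not in data:
            raise NetworkFormatError(f"{path}: bundle missing key {key!r}")
    axis_order = data.get("axis_order", "xzy")
    if axis_order not in _AXIS_ORDERS:
        raise NetworkFormatError(
            f"{path}: unknown axis_order {axis_order!r} in bundle"
        )
    raw = np.asarray(data["coordinates"], dtype=float)
    if raw.ndim != 2 or raw.shape[1] != 3:
        raise NetworkFormatError(
            f"{path}: 'coordinates' must be N x 3, got shape {raw.shape}"
        )
    perm = _AXIS_ORDERS[axis_order]
    coords = np.empty_like(raw)
    coords[:, perm] = raw
    weights = np.asarray(data["matrix"], dtype=float)
    if weights.ndim != 2 or weights.shape[0] != weights.shape[1]:
        raise NetworkFormatError(f"{path}: 'matrix' must be square")
    labels = data.get("labels")
    if labels is not None:
        labels = [str(s) for s in labels]
    return assemble_network(coords, weights, labels)


def write_network_bundle(net: SpatialNetwork, path: str | Path) -> None:
    """Write a JSON bundle; inverse of :func:`read_network_bundle`.

    Coordinates are written in ``xzy`` order with an explicit
    ``"axis_order"`` key so read(write(net)) == net.
    """
    perm = _AXIS_ORDERS["xzy"]
    out_coords = net.coords[:, perm]  # internal axis perm[k] -> output column k
    bundle: dict = {
        "axis_order": "xzy",
        "coordinates": out_coords.tolist(),
        "matrix": net.weights.tolist(),
    }
    if net.labels:
        bundle["labels"] = net.labels
    with open(path, "w") as fh:
        json.dump(bundle, fh, indent=1)
        fh.write("\n")
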