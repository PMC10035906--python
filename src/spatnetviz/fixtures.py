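"""Synthetic spatial networks for demos and tests.

Four generators cover the demo families: scale-free topology on a sphere
(preferential attachment), a 3D lattice with mostly nearest-neighbour
links, the complete graph on a sphere, and a random geometric graph in
the unit cube.  All randomness flows through ``numpy.random.Generator``
seeded with the caller's integer seed (PCG64), so a fixed seed gives a
bit-identical network on every platform.
"""

from __future__ import annotations

import numpy as np

from .io_formats import SpatialNetwork


def _sphere_points(n: int, rng: np.random.Generator) -> np.ndarray:
    """n points area-uniform on the unit sphere.

    Uniform azimuth plus uniform cosine of the polar angle; avoids the
    polar clustering of naive angle-uniform sampling.
    """
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n)
    cos_theta = rng.uniform(-1.0, 1.0, size=n)
    sin_theta = np.sqrt(1.0 - cos_theta**2)
    return np.column_stack(
        [sin_theta * np.cos(phi), cos_theta, sin_theta * np.sin(phi)]
    )


def sphere_ba_network(n: int, m: int, seed: int) -> SpatialNetwork:
    """Nodes uniform on the unit sphere, links by preferential attachment.

    The urn variant used here: the first ``m`` nodes start isolated; each
    arriving node draws ``m`` distinct targets from an urn holding every
    previous link endpoint (plus each seed node once), then its links'
    endpoints join the urn.  Total link count is exactly ``m * (n - m)``.
    Weights are 1.
    """
    if not (n > m >= 1):
        raise ValueError(f"need n > m >= 1, got n={n}, m={m}")
    rng = np.random.default_rng(seed)
    coords = _sphere_points(n, rng)
    urn: list[int] = list(range(m))  # seed nodes, once each
    w = np.zeros((n, n))
    for new in range(m, n):
        targets: set[int] = set()
        while len(targets) < m:
            targets.add(urn[rng.integers(len(urn))])
        for t in sorted(targets):
            w[new, t] = w[t, new] = 1.0
            urn.extend([new, t])
    return SpatialNetwork(coords, w)


def lattice_network(
    nx: int, ny: int, nz: int, p_extra: float = 0.0, seed: int = 0
) -> SpatialNetwork:
    """Integer-grid lattice with 6-neighbourhood links plus random shortcuts.

    Nodes sit at integer grid coordinates (``y`` vertical).  Every pair of
    6-neighbourhood grid points is linked; additionally
    ``round(p_extra * L_neighbour)`` random non-neighbour pairs are linked.
    The link weight is ``1 + mean elevation of its endpoints`` so colour
    maps can encode connection altitude (the offset keeps ground-level
    links from vanishing, since weight 0 means "no link").
    """
    if min(nx, ny, nz) < 1:
        raise ValueError(f"grid dims must be >= 1, got ({nx}, {ny}, {nz})")
    if p_extra < 0:
        raise ValueError("p_extra must be >= 0")
    idx = np.arange(nx * ny * nz).reshape(nx, ny, nz)
    gx, gy, gz = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    coords = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()]).astype(float)
    n = len(coords)
    w = np.zeros((n, n))

    def elevation_weight(a: int, b: int) -> float:
        return 1.0 + (coords[a, 1] + coords[b, 1]) / 2.0

    pairs = []
    for axis in range(3):
        a = np.moveaxis(idx, axis, 0)
        pairs.append(np.column_stack([a[:-1].ravel(), a[1:].ravel()]))
    neighbour_pairs = np.vstack(pairs)
    for a, b in neighbour_pairs:
        w[a, b] = w[b, a] = elevation_weight(a, b)

    n_extra = int(round(p_extra * len(neighbour_pairs)))
    if n_extra > 0:
        rng = np.random.default_rng(seed)
        added = 0
        while added < n_extra:
            a, b = rng.integers(n, size=2)
            if a == b or w[a, b] != 0:
                continue
            w[a, b] = w[b, a] = elevation_weight(a, b)
            added += 1
    return SpatialNetwork(coords, w)


def complete_network(n: int, seed: int = 0) -> SpatialNetwork:
    """Complete graph on n sphere points; weight = 1 / distance.

    Link count is n * (n - 1) / 2 (31125 for n = 250).  The inverse-
    distance weights make both weight-based and distance-based filters
    non-trivial on this fixture.
    """
    if n < 2:
        raise ValueError(f"complete network needs n >= 2, got {n}")
    rng = np.random.default_rng(seed)
    coords = _sphere_points(n, rng)
    diff = coords[:, None, :] - coords[None, :, :]
    d = np.linalg.norm(diff, axis=-1)
    with np.errstate(divide="ignore"):
        w = np.where(d > 0, 1.0 / np.where(d > 0, d, 1.0), 0.0)
    np.fill_diagonal(w, 0.0)
    return SpatialNetwork(coords, w)


def random_geometric_network(n: int, radius: float, seed: int) -> SpatialNetwork:
    """Uniform points in the unit cube; link iff distance < radius.

    Weight = 1 - d_ij / radius, so close pairs are strong and weights stay
    strictly positive on every link.
    """
    if n < 1:
        raise ValueError(f"need n >= 1, got {n}")
    if radius <= 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0.0, 1.0, size=(n, 3))
    diff = coords[:, None, :] - coords[None, :, :]
    d = np.linalg.norm(diff, axis=-1)
    w = np.where((d < radius) & (d > 0), 1.0 - d / radius, 0.0)
    np.fill_diagonal(w, 0.0)
    return SpatialNetwork(coords, w)
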