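"""Link and node filters applied before any geometry is built.

Dense spatial networks are unreadable when every link is drawn; the
filters here reduce either the link set (ECO density criterion, explicit
density or count, minimum physical distance) or the node set (top-degree
subnetwork).  All filters are pure: they return a new network plus a
FilterReport, never mutate their input, and preserve symmetry, the zero
diagonal and the retained weights and coordinates.

Tie handling is deterministic everywhere: links of equal weight are ranked
by ascending (i, j) index pair, nodes of equal degree by ascending index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_formats import SpatialNetwork

logger = logging.getLogger(__name__)

#: ECO average-degree constant: the filter keeps about DEGREE * N / 2 links.
ECO_DEGREE = 3.0


@dataclass(frozen=True)
class FilterReport:
    """What a filter did: counts before/after and the rule applied."""

    rule: str
    parameter: object
    links_before: int
    links_after: int
    nodes_before: int
    nodes_after: int

    def __post_init__(self) -> None:
        assert self.links_after <= self.links_before
        assert self.nodes_after <= self.nodes_before

    def to_dict(self) -> dict:
        return {
            "rule": self.rule,
            "parameter": self.parameter,
            "links_before": self.links_before,
            "links_after": self.links_after,
            "nodes_before": self.nodes_before,
            "nodes_after": self.nodes_after,
        }


def _report(rule: str, parameter, before: SpatialNetwork, after: SpatialNetwork) -> FilterReport:
    rep = FilterReport(
        rule=rule,
        parameter=parameter,
        links_before=before.n_links,
        links_after=after.n_links,
        nodes_before=before.n_nodes,
        nodes_after=after.n_nodes,
    )
    logger.info(
        "filter %s(%s): links %d -> %d, nodes %d -> %d",
        rep.rule, rep.parameter, rep.links_before, rep.links_after,
        rep.nodes_before, rep.nodes_after,
    )
    return rep


def _keep_strongest(net: SpatialNetwork, k: int, rule: str, parameter) -> tuple[SpatialNetwork, FilterReport]:
    """Retain the k largest-weight links; ties broken by ascending (i, j)."""
    pairs = net.link_pairs()
    weights = net.link_weights()
    # link_pairs is already in ascending (i, j) order; a stable sort on
    # descending weight therefore resolves ties toward the smaller pair.
    order = np.argsort(-weights, kind="stable")
    kept = pairs[order[: min(k, len(order))]]
    new_w = np.zeros_like(net.weights)
    new_w[kept[:, 0], kept[:, 1]] = net.weights[kept[:, 0], kept[:, 1]]
    new_w[kept[:, 1], kept[:, 0]] = net.weights[kept[:, 1], kept[:, 0]]
    out = SpatialNetwork(net.coords.copy(), new_w, list(net.labels) if net.labels else None)
    return out, _report(rule, parameter, net, out)


def eco_count(n_nodes: int) -> int:
    """Number of links the ECO criterion retains: round(ECO_DEGREE * N / 2),
    rounding halves up."""
    return int(np.floor(ECO_DEGREE * n_nodes / 2.0 + 0.5))


def eco_filter(
    net: SpatialNetwork, degree: float = ECO_DEGREE
) -> tuple[SpatialNetwork, FilterReport]:
    """Keep the strongest links so the average node degree is ~``degree``.

    Retains the K = round(degree * N / 2) largest-weight links (all links
    when fewer exist).  The node set is unchanged.  Connectedness is not
    enforced; a warning is logged if the filtered graph is disconnected.
    """
    if net.n_links < 1:
        raise ValueError("eco_filter requires at least one link")
    k = int(np.floor(degree * net.n_nodes / 2.0 + 0.5))
    out, rep = _keep_strongest(net, k, "eco", degree)
    if _n_components(out) > _n_components(net):
        logger.warning("ECO filtering disconnected the network")
    return out, rep


def _n_components(net: SpatialNetwork) -> int:
    from scipy.sparse.csgraph import connected_components

    n, _ = connected_components((net.weights > 0), directed=False)
    return n


def density_filter(
    net: SpatialNetwork, keep: float | int
) -> tuple[SpatialNetwork, FilterReport]:
    """Keep the strongest links: a proportion in (0, 1] or an absolute count.

    An integral ``keep`` is an absolute link count (must be <= L); a float
    in (0, 1] keeps ceil(keep * L) links.
    """
    L = net.n_links
    if isinstance(keep, (int, np.integer)) and not isinstance(keep, bool):
        k = int(keep)
        if k <= 0 or k > L:
            raise ValueError(f"link count {k} out of range (1..{L})")
    else:
        keep = float(keep)
        if not 0.0 < keep <= 1.0:
            raise ValueError(f"density proportion must lie in (0, 1], got {keep}")
        k = int(np.ceil(keep * L))
    return _keep_strongest(net, k, "density", keep)


def min_distance_filter(
    net: SpatialNetwork, d_min: float
) -> tuple[SpatialNetwork, FilterReport]:
    """Keep only links spanning a Euclidean distance strictly above d_min."""
    if d_min < 0:
        raise ValueError(f"d_min must be >= 0, got {d_min}")
    pairs = net.link_pairs()
    new_w = np.zeros_like(net.weights)
    if len(pairs):
        d = np.linalg.norm(net.coords[pairs[:, 0]] - net.coords[pairs[:, 1]], axis=1)
        kept = pairs[d > d_min]
        new_w[kept[:, 0], kept[:, 1]] = net.weights[kept[:, 0], kept[:, 1]]
        new_w[kept[:, 1], kept[:, 0]] = net.weights[kept[:, 1], kept[:, 0]]
    out = SpatialNetwork(net.coords.copy(), new_w, list(net.labels) if net.labels else None)
    return out, _report("min_distance", d_min, net, out)


def top_degree_subnetwork(
    net: SpatialNetwork, k: int
) -> tuple[SpatialNetwork, FilterReport]:
    """Induced subnetwork on the k most-connected nodes.

    Degree is the unweighted incident-link count, computed before removal;
    ties are broken by ascending node index.  Coordinates and labels are
    re-indexed consistently.
    """
    n = net.n_nodes
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in 1..{n}, got {k}")
    deg = net.degrees()
    order = np.lexsort((np.arange(n), -deg))  # primary: -degree, secondary: index
    kept = np.sort(order[:k])
    coords = net.coords[kept].copy()
    weights = net.weights[np.ix_(kept, kept)].copy()
    labels = [net.labels[i] for i in kept] if net.labels else None
    out = SpatialNetwork(coords, weights, labels)
    return out, _report("top_degree", k, net, out)
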