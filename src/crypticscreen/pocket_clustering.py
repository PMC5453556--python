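"""Greedy largest-first clustering of pockets across an ensemble.

Pockets detected independently in many conformations of the same protein
are grouped by center-of-mass proximity so that "the same pocket" can be
tracked across states.  The algorithm is greedy:

1. the largest unclustered pocket founds a new cluster center;
2. every pocket is assigned to the closest existing center within the
   distance cutoff (by default pockets may be re-assigned when a closer
   center is founded later);
3. repeat until every pocket is assigned.

Ties in "largest" are broken by size and then lexicographically smallest
center of mass, so the result is independent of input order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np

from .errors import ConfigError, ContractError


class PocketLike(Protocol):
    """What clustering needs from a pocket: size, location, provenance."""

    source_state: str

    @property
    def n_elements(self) -> int: ...

    @property
    def center_of_mass(self) -> tuple[float, float, float]: ...


@dataclass(frozen=True)
class PocketSummary:
    """Lightweight stand-in for a Pocket, e.g. loaded from a JSON report."""

    source_state: str
    n_elements: int
    center_of_mass: tuple[float, float, float]


@dataclass(frozen=True)
class ClusteringParams:
    #: Maximum center-of-mass distance (Å) from a member to its cluster center.
    distance_cutoff: float = 5.0
    #: Re-assign already-clustered pockets when a closer center appears later.
    reassign: bool = True

    def __post_init__(self) -> None:
        if self.distance_cutoff <= 0:
            raise ConfigError("distance_cutoff must be positive")


@dataclass
class ClusterMember:
    state_id: str
    pocket: PocketLike
    distance: float


@dataclass
class PocketCluster:
    cluster_id: int
    center: PocketLike
    members: list[ClusterMember]

    @property
    def state_ids(self) -> set[str]:
        return {m.state_id for m in self.members}


def _sort_key(p: PocketLike) -> tuple:
    return (-p.n_elements, tuple(p.center_of_mass))


def cluster_pockets(
    pockets: Sequence[PocketLike], params: ClusteringParams | None = None
) -> list[PocketCluster]:
    """Partition pockets into clusters around greedily chosen centers.

    Every pocket ends up in exactly one cluster, at distance ≤ cutoff from
    its center (a founding pocket sits at distance 0 in its own cluster).
    Clusters are returned in founding order (largest founder first).
    """
    params = params or ClusteringParams()
    if not pockets:
        raise ContractError("cannot cluster an empty pocket list")

    order = sorted(range(len(pockets)), key=lambda i: _sort_key(pockets[i]))
    coms = np.array([pockets[i].center_of_mass for i in order], dtype=float)

    n = len(order)
    assignment = np.full(n, -1, dtype=int)  # index into centers, -1 = unassigned
    center_rows: list[int] = []

    while np.any(assignment < 0):
        # largest unclustered pocket founds the next center
        founder = int(np.nonzero(assignment < 0)[0][0])
        center_rows.append(founder)
        centers_xyz = coms[center_rows]
        d = np.linalg.norm(coms[:, None, :] - centers_xyz[None, :, :], axis=2)
        nearest = d.argmin(axis=1)
        within = d[np.arange(n), nearest] <= params.distance_cutoff
        if params.reassign:
            assignment = np.where(within, nearest, -1)
        else:
            newly = (assignment < 0) & within
            assignment[newly] = nearest[newly]
        # the founder always belongs to its own cluster
        assignment[founder] = len(center_rows) - 1

    clusters: list[PocketCluster] = []
    for cid, row in enumerate(center_rows):
        members = []
        for j in np.nonzero(assignment == cid)[0]:
            p = pockets[order[int(j)]]
            dist = float(np.linalg.norm(coms[int(j)] - coms[row]))
            members.append(ClusterMember(state_id=p.source_state, pocket=p, distance=dist))
        members.sort(key=lambda m: (m.distance, _sort_key(m.pocket)))
        clusters.append(
            PocketCluster(cluster_id=cid, center=pockets[order[row]], members=members)
        )
    return clusters


def map_pocket_presence(clusters: Sequence[PocketCluster], target: int) -> set[str]:
    """The distinct states whose structures contain the target pocket cluster."""
    for c in clusters:
        if c.cluster_id == target:
            return c.state_ids
    raise KeyError(f"no cluster with id {target}")


def nearest_cluster(
    clusters: Sequence[PocketCluster], reference_xyz: Sequence[float]
) -> PocketCluster:
    """Pick the cluster whose center COM is closest to a reference point.

    Convenience selector for targeting a known site (e.g. the ligand
    position in a holo crystal structure).
    """
    if not clusters:
        raise ContractError("no clusters to select from")
    ref = np.asarray(reference_xyz, dtype=float)
    return min(
        clusters,
        key=lambda c: float(np.linalg.norm(np.asarray(c.center.center_of_mass) - ref)),
    )


def clusters_to_records(clusters: Sequence[PocketCluster]) -> list[dict]:
    """JSON-ready cluster report."""
    return [
        {
            "cluster_id": c.cluster_id,
            "center_state": c.center.source_state,
            "center_com": [round(x, 4) for x in c.center.center_of_mass],
            "members": [
                {"state_id": m.state_id, "distance": round(m.distance, 4)}
                for m in c.members
            ],
        }
        for c in clusters
    ]
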