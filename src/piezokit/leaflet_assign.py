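"""Branching-network leaflet assignment for phosphate marker particles.

A bilayer's two leaflets are recovered from phosphate-bead coordinates alone:
starting from a seed particle, the network grows by repeatedly absorbing every
particle within a cutoff distance (default 2 nm, chosen smaller than the
leaflet separation) of any particle already in the group, until no more can
be added.  The grown group is one leaflet; the remainder is assumed to be the
other.  A validation pass then re-grows from the putative other leaflet and
checks it reproduces exactly — guarding against flip-flopped lipids or a
cutoff large enough to bridge the leaflets.

Growth is breadth-first over the cutoff graph, i.e. the grown set is the
connected component of the seed.  Distances are 3D Euclidean with
minimum-image convention in x and y only (never z, which would short-circuit
the leaflet gap through the periodic image).  The deterministic seed is the
particle with maximum z; its component is labelled "upper".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .coords_io import ParticleFrame

__all__ = ["LeafletPartition", "assign_leaflets", "validate_partition", "grow_network"]


@dataclass
class LeafletPartition:
    """Two disjoint particle-id sets covering the phosphate set.

    ``validated`` is True when the cross-leaflet re-growth pass reproduced the
    complementary leaflet exactly; a degenerate outcome (the cutoff graph does
    not split into exactly two components) is flagged via
    ``degenerate_reason`` rather than returned silently.
    """

    upper: frozenset[int]
    lower: frozenset[int]
    cutoff: float
    seed_particle: int
    validated: bool
    degenerate_reason: str | None = None
    mismatched_ids: tuple[int, ...] = ()

    @property
    def is_degenerate(self) -> bool:
        return self.degenerate_reason is not None


def _wrapped_tree(frame: ParticleFrame) -> tuple[cKDTree, np.ndarray]:
    """KD-tree over positions, periodic in x/y when a box is present."""
    pos = frame.positions.copy()
    if frame.box is not None:
        lx, ly = frame.box[0], frame.box[1]
        pos[:, 0] = np.mod(pos[:, 0], lx)
        pos[:, 1] = np.mod(pos[:, 1], ly)
        # z made non-negative for the KD-tree's coordinate requirement; a
        # rigid shift leaves all pair distances unchanged.
        pos[:, 2] -= pos[:, 2].min()
        return cKDTree(pos, boxsize=[lx, ly, 0.0]), pos
    return cKDTree(pos), pos


def grow_network(frame: ParticleFrame, seed_index: int, cutoff: float) -> np.ndarray:
    """Grow a leaflet network from one particle: BFS over the cutoff graph.

    Returns the boolean membership mask (generator order) of the connected
    component containing ``seed_index`` in the graph joining particle pairs
    at distance <= cutoff.
    """
    tree, pos = _wrapped_tree(frame)
    n = frame.n_particles
    member = np.zeros(n, dtype=bool)
    member[seed_index] = True
    frontier = [seed_index]
    while frontier:
        neighbours = tree.query_ball_point(pos[frontier], cutoff)
        new: set[int] = set()
        for nbrs in neighbours:
            new.update(nbrs)
        fresh = [i for i in new if not member[i]]
        member[list(new)] = True
        frontier = fresh
    return member


def assign_leaflets(frame: ParticleFrame, cutoff: float = 2.0) -> LeafletPartition:
    """Split phosphate particles into two leaflets by branching-network growth.

    The seed is the particle with maximum z; its grown component is the upper
    leaflet and the remainder the lower.  The complementary pass
    (:func:`validate_partition`) is run automatically and its verdict stored.

    Raises
    ------
    ValueError
        On fewer than 2 particles or a non-positive cutoff.
    """
    if frame.n_particles < 2:
        raise ValueError("leaflet assignment needs at least 2 particles")
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")

    seed_index = int(np.argmax(frame.positions[:, 2]))
    upper_mask = grow_network(frame, seed_index, cutoff)
    ids = frame.particle_ids
    upper = frozenset(int(i) for i in ids[upper_mask])
    lower = frozenset(int(i) for i in ids[~upper_mask])

    if not lower:
        return LeafletPartition(
            upper=upper,
            lower=lower,
            cutoff=cutoff,
            seed_particle=int(ids[seed_index]),
            validated=False,
            degenerate_reason=(
                "all particles fall in one connected component; the cutoff "
                "bridges the leaflets or the bilayer is merged"
            ),
        )

    partition = LeafletPartition(
        upper=upper,
        lower=lower,
        cutoff=cutoff,
        seed_particle=int(ids[seed_index]),
        validated=False,
    )
    ok, mismatched = validate_partition(frame, partition)
    if ok:
        return LeafletPartition(
            upper=upper, lower=lower, cutoff=cutoff,
            seed_particle=partition.seed_particle, validated=True,
        )
    return LeafletPartition(
        upper=upper, lower=lower, cutoff=cutoff,
        seed_particle=partition.seed_particle, validated=False,
        degenerate_reason=(
            "re-growth from the other leaflet did not reproduce it; the "
            "remainder is not a single isolated component"
        ),
        mismatched_ids=tuple(sorted(mismatched)),
    )


def validate_partition(
    frame: ParticleFrame, partition: LeafletPartition
) -> tuple[bool, list[int]]:
    """Cross-leaflet validation: re-grow from the putative other leaflet.

    Grows a network from one particle of ``partition.lower`` and returns
    ``(True, [])`` iff the grown set equals that leaflet exactly; otherwise
    ``(False, mismatched_ids)`` where the ids are the symmetric difference
    between the grown set and the claimed leaflet.
    """
    ids = frame.particle_ids
    id_to_index = {int(p): i for i, p in enumerate(ids)}
    lower_indices = [id_to_index[p] for p in partition.lower if p in id_to_index]
    if not lower_indices:
        return False, sorted(partition.upper ^ frozenset(int(i) for i in ids))
    # deterministic re-growth seed: lowest-z particle of the claimed leaflet
    seed = min(lower_indices, key=lambda i: frame.positions[i, 2])
    grown_mask = grow_network(frame, seed, partition.cutoff)
    grown = frozenset(int(i) for i in ids[grown_mask])
    mismatched = sorted(grown ^ partition.lower)
    return not mismatched, mismatched
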