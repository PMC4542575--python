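"""Shared fixtures: random SWC trees and the reference morphometry table."""

from __future__ import annotations

import math

import numpy as np
import pytest

from synaptome.morphometry import (
    STRUCT_APICAL,
    STRUCT_BASAL,
    STRUCT_SOMA,
    SwcMorphology,
    SwcNode,
)


def make_random_tree(
    rng: np.random.Generator,
    n_nodes: int = 60,
    step_mean: float = 8.0,
) -> SwcMorphology:
    """Grow a random dendritic tree rooted at a soma node.

    Children of the soma start a basal or apical branch; deeper nodes
    inherit their parent's structure. Step lengths are exponential with
    the given mean, directions uniform on the sphere.
    """
    nodes = [SwcNode(1, STRUCT_SOMA, 0.0, 0.0, 0.0, 5.0, -1)]
    for i in range(2, n_nodes + 1):
        parent = nodes[int(rng.integers(len(nodes)))]
        if parent.structure == STRUCT_SOMA:
            structure = STRUCT_BASAL if rng.random() < 0.5 else STRUCT_APICAL
        else:
            structure = parent.structure
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        step = rng.exponential(step_mean)
        x, y, z = (
            parent.x + step * direction[0],
            parent.y + step * direction[1],
            parent.z + step * direction[2],
        )
        nodes.append(SwcNode(i, structure, x, y, z, 1.0, parent.id))
    return SwcMorphology(tuple(nodes))


def brute_force_dendrite_lengths(
    morphology: SwcMorphology, exclusion: float, n_steps: int = 4000
) -> tuple[float, float]:
    """Independent oracle: numerical path integration of dendritic length.

    Walks each node's ancestry to the root to get path distances, then
    integrates every dendritic segment in small steps, keeping the steps
    whose midpoint path distance exceeds the exclusion.
    """
    by_id = {n.id: n for n in morphology.nodes}

    def root_distance(node: SwcNode) -> float:
        d = 0.0
        cur = node
        while cur.parent != -1:
            parent = by_id[cur.parent]
            d += math.dist((cur.x, cur.y, cur.z), (parent.x, parent.y, parent.z))
            cur = parent
        return d

    totals = {STRUCT_BASAL: 0.0, STRUCT_APICAL: 0.0}
    for child in morphology.nodes:
        if child.structure not in totals or child.parent == -1:
            continue
        parent = by_id[child.parent]
        seg = math.dist(
            (child.x, child.y, child.z), (parent.x, parent.y, parent.z)
        )
        d_parent = root_distance(parent)
        h = seg / n_steps
        for i in range(n_steps):
            if d_parent + (i + 0.5) * h > exclusion:
                totals[child.structure] += h
    return totals[STRUCT_APICAL], totals[STRUCT_BASAL]


@pytest.fixture
def worked_example_table(tmp_path):
    """One-cell morphometry table reducing to the 100 um reference segment."""
    path = tmp_path / "cells.csv"
    path.write_text(
        "cell_id,L_ap_um,L_ba_um,spine_density_per_um,soma_area_um2,"
        "soma_syn_density_per_um2,ais_length_um,ais_syn_density_per_um\n"
        "c1,65,50,1.5,0,0,0,0\n"
    )
    return path
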