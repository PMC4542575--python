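"""Light-microscopy inputs: SWC reconstructions and morphometry tables.

SWC is the standard 7-column plain-text format for neuronal
reconstructions: node id, structure type, x, y, z (um), radius (um),
parent id (-1 for roots). Structure codes follow the community
convention: 1 = soma, 2 = axon, 3 = basal dendrite, 4 = apical dendrite.

From a reconstruction this module computes the apical and basal dendritic
lengths that feed the synapse estimators, excluding the proximal
spine-free zone: the portion of every dendritic path whose path distance
from the soma (measured along the tree, not as the crow flies) is within
the exclusion radius. Segments straddling the cutoff are split
proportionally.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple

import pandas as pd

__all__ = [
    "NeuronMorphometry",
    "SwcNode",
    "SwcMorphology",
    "SwcParseError",
    "STRUCT_SOMA",
    "STRUCT_AXON",
    "STRUCT_BASAL",
    "STRUCT_APICAL",
    "parse_swc",
    "write_swc",
    "dendrite_lengths",
    "read_morphometry_table",
    "MORPHOMETRY_COLUMNS",
]

STRUCT_SOMA = 1
STRUCT_AXON = 2
STRUCT_BASAL = 3
STRUCT_APICAL = 4

_KNOWN_STRUCTURES = {STRUCT_SOMA, STRUCT_AXON, STRUCT_BASAL, STRUCT_APICAL}


@dataclass(frozen=True)
class NeuronMorphometry:
    """Per-cell light-microscopy measurements.

    Lengths in um, areas in um^2; densities per um (spines, AIS synapses)
    or per um^2 (soma synapses).
    """

    cell_id: str
    l_ap: float
    l_ba: float
    spine_density: float
    soma_area: float = 0.0
    soma_syn_density: float = 0.0
    ais_length: float = 0.0
    ais_syn_density: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "l_ap",
            "l_ba",
            "spine_density",
            "soma_area",
            "soma_syn_density",
            "ais_length",
            "ais_syn_density",
        ):
            value = getattr(self, name)
            if value < 0:
                raise ValueError(
                    f"cell {self.cell_id!r}: {name} must be >= 0, got {value}"
                )


class SwcNode(NamedTuple):
    id: int
    structure: int
    x: float
    y: float
    z: float
    radius: float
    parent: int


class SwcParseError(ValueError):
    """Malformed SWC input; the message names the offending line."""


@dataclass(frozen=True)
class SwcMorphology:
    """A validated SWC reconstruction (one or more trees)."""

    nodes: tuple[SwcNode, ...]

    def __post_init__(self) -> None:
        _validate_topology(self.nodes)

    @property
    def by_id(self) -> dict[int, SwcNode]:
        return {n.id: n for n in self.nodes}

    @property
    def roots(self) -> tuple[SwcNode, ...]:
        return tuple(n for n in self.nodes if n.parent == -1)

    def soma_node(self) -> SwcNode | None:
        """The soma origin: the root soma node if any, else the first
        node labelled soma, else None."""
        soma_nodes = [n for n in self.nodes if n.structure == STRUCT_SOMA]
        if not soma_nodes:
            return None
        for n in soma_nodes:
            if n.parent == -1:
                return n
        return soma_nodes[0]


def _validate_topology(nodes: tuple[SwcNode, ...]) -> None:
    ids = [n.id for n in nodes]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise SwcParseError(f"duplicate node ids: {dupes}")
    id_set = set(ids)
    for n in nodes:
        if n.parent != -1 and n.parent not in id_set:
            raise SwcParseError(
                f"node {n.id} references undefined parent {n.parent}"
            )
        if not all(math.isfinite(v) for v in (n.x, n.y, n.z, n.radius)):
            raise SwcParseError(f"node {n.id} has non-finite coordinates")
    # cycle check by walking each node to a root
    parent = {n.id: n.parent for n in nodes}
    state: dict[int, int] = {}  # 0 visiting, 1 done
    for start in ids:
        path = []
        cur = start
        while cur != -1 and state.get(cur) != 1:
            if state.get(cur) == 0:
                raise SwcParseError(f"cycle detected involving node {cur}")
            state[cur] = 0
            path.append(cur)
            cur = parent[cur]
        for node_id in path:
            state[node_id] = 1


def parse_swc(path: str | Path) -> SwcMorphology:
    """Parse an SWC file, reporting malformed rows with line numbers."""
    nodes: list[SwcNode] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            fields = stripped.split()
            if len(fields) != 7:
                raise SwcParseError(
                    f"{path}:{lineno}: expected 7 columns, got {len(fields)}"
                )
            try:
                node = SwcNode(
                    id=int(fields[0]),
                    structure=int(fields[1]),
                    x=float(fields[2]),
                    y=float(fields[3]),
                    z=float(fields[4]),
                    radius=float(fields[5]),
                    parent=int(fields[6]),
                )
            except ValueError as exc:
                raise SwcParseError(f"{path}:{lineno}: {exc}") from None
            nodes.append(node)
    return SwcMorphology(tuple(nodes))


def write_swc(morphology: SwcMorphology, path: str | Path) -> None:
    """Write a reconstruction back to SWC (round-trips with parse_swc)."""
    with open(path, "w") as fh:
        fh.write("# id structure x y z radius parent\n")
        for n in morphology.nodes:
            fh.write(
                f"{n.id} {n.structure} {n.x:.6g} {n.y:.6g} {n.z:.6g} "
                f"{n.radius:.6g} {n.parent}\n"
            )


def _segment_length(a: SwcNode, b: SwcNode) -> float:
    return math.dist((a.x, a.y, a.z), (b.x, b.y, b.z))


def dendrite_lengths(
    morphology: SwcMorphology, exclusion: float = 15.0
) -> tuple[float, float]:
    """Apical and basal dendritic length beyond the proximal exclusion.

    Returns ``(L_ap, L_ba)`` in um. Each parent-child segment belongs to
    the structure of the child node; the part of the segment whose path
    distance from the soma origin lies within ``exclusion`` is dropped,
    splitting straddling segments proportionally. Path distances are
    measured along the tree from the soma node; nodes not connected to the
    soma measure distance from their own root.
    """
    if exclusion < 0:
        raise ValueError(f"exclusion must be >= 0, got {exclusion}")
    soma = morphology.soma_node()
    if soma is None and exclusion > 0:
        raise ValueError(
            "morphology has no soma node; cannot apply a proximal exclusion"
        )

    by_id = morphology.by_id
    unknown = sorted(
        {n.structure for n in morphology.nodes} - _KNOWN_STRUCTURES
    )
    if unknown:
        warnings.warn(
            f"ignoring nodes with unknown SWC structure codes {unknown}",
            stacklevel=2,
        )

    # path distance of every node from its tree root (soma sits at a root
    # in well-formed files; distance is 0 at the root regardless)
    dist: dict[int, float] = {}

    def path_distance(node: SwcNode) -> float:
        chain = []
        cur = node
        while cur.id not in dist:
            if cur.parent == -1:
                dist[cur.id] = 0.0
                break
            chain.append(cur)
            cur = by_id[cur.parent]
        for n in reversed(chain):
            parent = by_id[n.parent]
            dist[n.id] = dist[parent.id] + _segment_length(parent, n)
        return dist[node.id]

    totals = {STRUCT_BASAL: 0.0, STRUCT_APICAL: 0.0}
    for child in morphology.nodes:
        if child.structure not in totals or child.parent == -1:
            continue
        parent = by_id[child.parent]
        seg = _segment_length(parent, child)
        if seg == 0:
            continue
        d_child = path_distance(child)
        d_parent = d_child - seg
        if d_parent >= exclusion:
            kept = seg
        elif d_child <= exclusion:
            kept = 0.0
        else:
            kept = d_child - exclusion
        totals[child.structure] += kept
    return totals[STRUCT_APICAL], totals[STRUCT_BASAL]


MORPHOMETRY_COLUMNS = (
    "cell_id",
    "L_ap_um",
    "L_ba_um",
    "spine_density_per_um",
    "soma_area_um2",
    "soma_syn_density_per_um2",
    "ais_length_um",
    "ais_syn_density_per_um",
)

# above this value a spine density almost certainly means the wrong units
_SPINE_DENSITY_SANITY = 10.0


def read_morphometry_table(path: str | Path) -> list[NeuronMorphometry]:
    """Read and validate a delimited morphometry table.

    Expects the documented header (comma, tab or semicolon separated):
    ``cell_id, L_ap_um, L_ba_um, spine_density_per_um, soma_area_um2,
    soma_syn_density_per_um2, ais_length_um, ais_syn_density_per_um``.
    Negative values or missing columns raise; implausible spine densities
    (> 10/um) only warn.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in MORPHOMETRY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"morphometry table {path} is missing columns {missing}")
    records: list[NeuronMorphometry] = []
    offenders: list[str] = []
    for _, row in df.iterrows():
        try:
            rec = NeuronMorphometry(
                cell_id=str(row["cell_id"]),
                l_ap=float(row["L_ap_um"]),
                l_ba=float(row["L_ba_um"]),
                spine_density=float(row["spine_density_per_um"]),
                soma_area=float(row["soma_area_um2"]),
                soma_syn_density=float(row["soma_syn_density_per_um2"]),
                ais_length=float(row["ais_length_um"]),
                ais_syn_density=float(row["ais_syn_density_per_um"]),
            )
        except ValueError as exc:
            offenders.append(str(exc))
            continue
        if rec.spine_density > _SPINE_DENSITY_SANITY:
            warnings.warn(
                f"cell {rec.cell_id!r}: spine density "
                f"{rec.spine_density}/um exceeds {_SPINE_DENSITY_SANITY}/um; "
                "check units",
                stacklevel=2,
            )
        records.append(rec)
    if offenders:
        raise ValueError(
            "invalid morphometry rows:\n  " + "\n  ".join(offenders)
        )
    return records


def write_morphometry_table(
    records: Iterable[NeuronMorphometry], path: str | Path
) -> None:
    """Write records in the standard delimited format (CSV)."""
    rows = [
        {
            "cell_id": r.cell_id,
            "L_ap_um": r.l_ap,
            "L_ba_um": r.l_ba,
            "spine_density_per_um": r.spine_density,
            "soma_area_um2": r.soma_area,
            "soma_syn_density_per_um2": r.soma_syn_density,
            "ais_length_um": r.ais_length,
            "ais_syn_density_per_um": r.ais_syn_density,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(MORPHOMETRY_COLUMNS)).to_csv(path, index=False)
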