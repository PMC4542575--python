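"""Tissue-scale arithmetic: sectioning budgets and per-volume synapse counts.

A cortical minicolumn is idealised as a cylinder (about 50 um diameter,
2000 um from pia to white matter). Full ultrastructural reconstruction of
such a cylinder with serial sections of a given area and thickness
requires cylinder volume / section volume sections — the arithmetic that
motivates statistical sampling instead of exhaustive reconstruction.

Tissue composition numbers (neurons per mm^3, synapses per mm^3, the
pyramidal fraction, a mean dendritic length per cell) combine into the
dendritic length packed into a cubic millimetre and the average synapse
count per neuron. Internally every density is stored per um^3; the
mm-scale values accepted at the interface are converted once on input,
which keeps silent 1e9 unit errors out of the arithmetic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable

from .morphometry import NeuronMorphometry
from .rules import SynapticRuleSet, DEFAULT_RULES

__all__ = [
    "CylinderSpec",
    "TissueComposition",
    "IntrinsicExtrinsicReport",
    "sections_for_cylinder",
    "length_per_volume",
    "synapses_per_neuron",
    "minicolumn_origin_split",
    "MM3_TO_UM3",
]

MM3_TO_UM3 = 1e9


@dataclass(frozen=True)
class CylinderSpec:
    """Minicolumn geometry: diameter and height in um."""

    diameter: float = 50.0
    height: float = 2000.0

    def __post_init__(self) -> None:
        if self.diameter <= 0 or self.height <= 0:
            raise ValueError("cylinder dimensions must be > 0")

    def volume(self, pi_value: float = math.pi) -> float:
        """Volume in um^3; pi is explicit so printed-precision
        conventions can be reproduced."""
        return pi_value * (self.diameter / 2.0) ** 2 * self.height


@dataclass(frozen=True)
class TissueComposition:
    """Bulk composition of cortical gray matter.

    ``neuron_density`` and ``synapse_density`` are per mm^3;
    ``mean_dendritic_length`` is mm per cell; ``pyramidal_fraction`` is
    the share of neurons that are pyramidal cells.
    """

    neuron_density: float = 27_000.0
    pyramidal_fraction: float = 0.8
    mean_dendritic_length: float = 10.0
    synapse_density: float = 1e9

    def __post_init__(self) -> None:
        if self.neuron_density < 0 or self.synapse_density < 0:
            raise ValueError("densities must be >= 0")
        if not 0.0 <= self.pyramidal_fraction <= 1.0:
            raise ValueError("pyramidal_fraction must lie in [0, 1]")
        if self.mean_dendritic_length < 0:
            raise ValueError("mean_dendritic_length must be >= 0")


def sections_for_cylinder(
    cyl: CylinderSpec,
    section_area: float,
    thickness: float,
    pi_value: float = math.pi,
) -> float:
    """Number of sections needed to exhaust a cylinder.

    ``section_area`` in um^2, ``thickness`` in um. With the reference
    minicolumn (50 x 2000 um), 100 um^2 sections at 20 nm and two-digit
    pi the count is 1,962,500.
    """
    if section_area <= 0 or thickness <= 0:
        raise ValueError("section_area and thickness must be > 0")
    return cyl.volume(pi_value) / (section_area * thickness)


def length_per_volume(t: TissueComposition) -> float:
    """Pyramidal dendritic length per mm^3 of tissue, in metres.

    neuron density x pyramidal fraction x mean dendritic length (mm),
    converted to m. The reference composition gives 216 m/mm^3.
    """
    length_mm = (
        t.neuron_density * t.pyramidal_fraction * t.mean_dendritic_length
    )
    return length_mm / 1000.0


def synapses_per_neuron(t: TissueComposition) -> float:
    """Average synapses per neuron: synapse density / neuron density."""
    if t.neuron_density <= 0:
        raise ValueError("neuron_density must be > 0")
    return t.synapse_density / t.neuron_density


@dataclass(frozen=True)
class IntrinsicExtrinsicReport:
    """Split of axospinous synapses in a minicolumn by origin.

    ``intrinsic`` synapses sit on spines of neurons whose somata lie
    within the column; ``extrinsic`` ones belong to dendrites entering
    from outside. ``clamped`` flags the degenerate case where the
    intrinsic estimate exceeded the total and extrinsic was floored at 0.
    """

    intrinsic: float
    extrinsic: float
    total: float
    clamped: bool = False

    @property
    def intrinsic_fraction(self) -> float | None:
        return self.intrinsic / self.total if self.total > 0 else None


def minicolumn_origin_split(
    cells_within: Iterable[NeuronMorphometry],
    rules: SynapticRuleSet = DEFAULT_RULES,
    cyl: CylinderSpec = CylinderSpec(),
    neuropil_asym_spinous_density: float = 0.67,
) -> IntrinsicExtrinsicReport:
    """Apportion a minicolumn's axospinous synapses by neuron origin.

    The spine count of the resident cells — spine density times included
    dendritic length, plus the second synapses on double-synapse spines —
    counts as intrinsic, using the equivalence between dendritic spines
    and axospinous asymmetric synapses in a volume. The total axospinous
    count is ``neuropil_asym_spinous_density`` (per um^3) times the
    cylinder volume; the remainder is extrinsic, floored at zero with a
    warning when the resident cells alone exceed the neuropil total.
    """
    if neuropil_asym_spinous_density < 0:
        raise ValueError("neuropil_asym_spinous_density must be >= 0")
    volume = cyl.volume()
    if volume <= 0:
        raise ValueError("cylinder volume must be > 0")

    intrinsic = 0.0
    for cell in cells_within:
        included = cell.l_ap + cell.l_ba - rules.proximal_exclusion
        if included < 0:
            raise ValueError(
                f"cell {cell.cell_id!r}: dendritic length shorter than the "
                f"proximal exclusion {rules.proximal_exclusion} um"
            )
        n_spines = included * cell.spine_density
        intrinsic += n_spines * (1.0 + rules.p_double)

    total = neuropil_asym_spinous_density * volume
    extrinsic = total - intrinsic
    clamped = False
    if extrinsic < 0:
        warnings.warn(
            "intrinsic axospinous estimate exceeds the neuropil total; "
            "extrinsic floored at 0",
            stacklevel=2,
        )
        extrinsic = 0.0
        clamped = True
    return IntrinsicExtrinsicReport(intrinsic, extrinsic, total, clamped)
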