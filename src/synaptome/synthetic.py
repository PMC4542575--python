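"""Seeded generators for synthetic neuropil fields and virtual neurons.

The estimators in this package assume particular statistical structure in
their inputs: synapses scattered through the neuropil as a homogeneous
Poisson field with a strongly asymmetric type mix, and neuron
morphometries drawn from unimodal positive distributions. These
generators produce exactly that structure so every estimator can be
exercised, and its parameter recovery checked, without external data.

All generators are driven by a single integer seed; independent
substreams are derived with ``numpy.random.SeedSequence.spawn`` so that
multi-part simulations stay reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .morphometry import NeuronMorphometry
from .stereology import ASYMMETRIC, SYMMETRIC, SynapticProfile3D

__all__ = [
    "FieldSpec",
    "PopulationSpec",
    "simulate_synapse_field",
    "simulate_virtual_neurons",
    "simulate_axon_varicosities",
]

Vec3 = tuple[float, float, float]


@dataclass(frozen=True)
class FieldSpec:
    """A homogeneous Poisson synapse field in a box.

    ``intensity`` is synapses per um^3 (cortical neuropil is about
    1/um^3); ``asym_fraction`` the probability each synapse is asymmetric
    (neuropil values span 0.80-0.95); ``profile_size`` the per-axis extent
    of each profile's bounding box (um), fixed at the stated size and
    centred on the synapse position.
    """

    region_min: Vec3
    region_max: Vec3
    intensity: float = 1.0
    asym_fraction: float = 0.85
    profile_size: Vec3 = (0.3, 0.3, 0.3)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError("intensity must be >= 0")
        if not 0.0 <= self.asym_fraction <= 1.0:
            raise ValueError("asym_fraction must lie in [0, 1]")
        for a, b in zip(self.region_min, self.region_max):
            if a >= b:
                raise ValueError("region_min must be < region_max per axis")
        if any(s < 0 for s in self.profile_size):
            raise ValueError("profile_size must be >= 0")

    @property
    def volume(self) -> float:
        return float(
            np.prod([b - a for a, b in zip(self.region_min, self.region_max)])
        )


def simulate_synapse_field(spec: FieldSpec) -> list[SynapticProfile3D]:
    """Draw a Poisson synapse field.

    The object count is Poisson(intensity x region volume), centres are
    uniform in the region, and each object is independently asymmetric
    with probability ``asym_fraction``. Output is deterministic for a
    fixed spec.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_count, rng_pos, rng_type = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )
    n = int(rng_count.poisson(spec.intensity * spec.volume))
    lo = np.asarray(spec.region_min)
    hi = np.asarray(spec.region_max)
    centers = rng_pos.uniform(lo, hi, size=(n, 3))
    is_asym = rng_type.random(n) < spec.asym_fraction
    half = np.asarray(spec.profile_size) / 2.0
    profiles = []
    for i in range(n):
        c = centers[i]
        profiles.append(
            SynapticProfile3D(
                id=f"syn{i:06d}",
                type=ASYMMETRIC if is_asym[i] else SYMMETRIC,
                min_corner=tuple(c - half),
                max_corner=tuple(c + half),
            )
        )
    return profiles


@dataclass(frozen=True)
class Distribution:
    """Mean/sd pair for a truncated-normal morphometric quantity."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


# Defaults sketch a medium-sized cortical pyramidal cell: about 10 mm of
# dendrite in total (apical-heavy), 1.5 spines/um, a soma of ~1200 um^2
# receiving ~0.11 symmetric synapses/um^2, and a ~40 um AIS at ~0.6
# synapses/um.
@dataclass(frozen=True)
class PopulationSpec:
    """A virtual-neuron population: per-quantity truncated normals."""

    n_cells: int = 100
    l_ap: Distribution = Distribution(6000.0, 1500.0)
    l_ba: Distribution = Distribution(4000.0, 1000.0)
    spine_density: Distribution = Distribution(1.5, 0.3)
    soma_area: Distribution = Distribution(1200.0, 250.0)
    soma_syn_density: Distribution = Distribution(0.11, 0.02)
    ais_length: Distribution = Distribution(40.0, 8.0)
    ais_syn_density: Distribution = Distribution(0.6, 0.1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells <= 0:
            raise ValueError("n_cells must be > 0")


def _draw_truncated(
    dist: Distribution, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Normal(mean, sd) truncated at 0 from below; degenerate sd gives
    the mean exactly."""
    if dist.sd == 0:
        return np.full(n, float(dist.mean))
    a = (0.0 - dist.mean) / dist.sd
    return stats.truncnorm.rvs(
        a, np.inf, loc=dist.mean, scale=dist.sd, size=n, random_state=rng
    )


def simulate_virtual_neurons(spec: PopulationSpec) -> list[NeuronMorphometry]:
    """Draw a reproducible virtual-neuron morphometry table.

    Each quantity is drawn independently from its truncated normal;
    quantities are uncorrelated across and within cells.
    """
    ss = np.random.SeedSequence(spec.seed)
    fields = (
        ("l_ap", spec.l_ap),
        ("l_ba", spec.l_ba),
        ("spine_density", spec.spine_density),
        ("soma_area", spec.soma_area),
        ("soma_syn_density", spec.soma_syn_density),
        ("ais_length", spec.ais_length),
        ("ais_syn_density", spec.ais_syn_density),
    )
    draws = {}
    for (name, dist), child in zip(fields, ss.spawn(len(fields))):
        draws[name] = _draw_truncated(dist, spec.n_cells, np.random.default_rng(child))
    return [
        NeuronMorphometry(
            cell_id=f"vcell{i:04d}",
            l_ap=float(draws["l_ap"][i]),
            l_ba=float(draws["l_ba"][i]),
            spine_density=float(draws["spine_density"][i]),
            soma_area=float(draws["soma_area"][i]),
            soma_syn_density=float(draws["soma_syn_density"][i]),
            ais_length=float(draws["ais_length"][i]),
            ais_syn_density=float(draws["ais_syn_density"][i]),
        )
        for i in range(spec.n_cells)
    ]


def simulate_axon_varicosities(
    n_synapses: int, p_bouton: float = 0.88, seed: int = 0
) -> np.ndarray:
    """Label each synapse as made by a bouton or an inter-varicose segment.

    Along cortical axons most synapses are established at varicosities
    (boutons), but a minority (about 12%) sit on the thin inter-varicose
    shaft. The labels quantify the error of equating putative contacts
    (one per varicosity seen at the light microscope) with true synapses.

    Returns a boolean array: True = bouton synapse.
    """
    if not 0.0 <= p_bouton <= 1.0:
        raise ValueError("p_bouton must lie in [0, 1]")
    if n_synapses < 0:
        raise ValueError("n_synapses must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    return rng.random(n_synapses) < p_bouton
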