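"""Tissue-scale arithmetic for a cortical minicolumn.

Three quick calculations: how many serial EM sections exhausting one
minicolumn would take, how much pyramidal dendrite is packed into a
cubic millimetre of cortex, and the average synapse count per neuron.
"""

from synaptome import (
    CylinderSpec,
    TissueComposition,
    length_per_volume,
    sections_for_cylinder,
    synapses_per_neuron,
)

cyl = CylinderSpec(diameter=50.0, height=2000.0)
n_sections = sections_for_cylinder(cyl, section_area=100.0, thickness=0.02,
                                   pi_value=3.14)
print(f"sections to exhaust one minicolumn: {n_sections:,.0f}")

tissue = TissueComposition(neuron_density=27_000, pyramidal_fraction=0.8,
                           mean_dendritic_length=10.0, synapse_density=1e9)
print(f"pyramidal dendrite per mm^3:        {length_per_volume(tissue):.0f} m")
print(f"synapses per neuron:                {synapses_per_neuron(tissue):,.0f}")
# Nearly two million 20-nm sections for a single 50-um column is why
# exhaustive reconstruction gives way to statistical sampling.
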