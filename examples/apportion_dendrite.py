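"""Apportion synapses on a single stretch of spiny dendrite.

Takes the reference segment — 100 um of pyramidal-cell dendrite carrying
15 spines per 10 um — and applies the three placement rules to get the
expected number of synapses in each compartment (asymmetric/symmetric x
spine/shaft).
"""

from synaptome import DendriticSegmentStats, estimate_dendritic_synapses

segment = DendriticSegmentStats(length=100.0, spine_density=1.5)
bd = estimate_dendritic_synapses(segment)

print(f"spines:                {segment.length * segment.spine_density:.0f}")
print(f"synapses on spines:    {bd.spine_synapses:.2f}")
print(f"  asymmetric on spine: {bd.asym_spine:.2f}")
print(f"  symmetric on spine:  {bd.sym_spine:.2f}")
print(f"  asymmetric on shaft: {bd.asym_shaft:.2f}")
print(f"  symmetric on shaft:  {bd.sym_shaft:.2f}")
print(f"total:                 {bd.total:.2f}")
# The total (~218 synapses per 100 um) exceeds the spine count because
# shaft synapses are inferred from the neuropil-wide type proportions.
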