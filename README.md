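# synaptome

Statistical estimation of the number, type and compartmental placement of
synapses on cortical neurons and within tissue volumes.

Full ultrastructural reconstruction of even a single cortical minicolumn
is out of reach (a 50 μm × 2000 μm column sliced into 100 μm² × 20 nm
sections is nearly two million sections), so synapse maps must be built
statistically: light-microscopy morphometry of neurons, combined with
proportion rules measured by electron microscopy in small, unbiasedly
sampled volumes of neuropil. This package implements that pipeline for
quantitative neuroanatomists and modellers who need per-cell or
per-volume synapse budgets.

## The model

Cortical synapses fall into two ultrastructural classes: **asymmetric**
(excitatory) and **symmetric** (inhibitory). Their placement on
pyramidal-cell dendrites follows three empirical rules:

1. every dendritic spine bears at least one asymmetric synapse, and a
   fraction *p*<sub>double</sub> = 0.10 of spines bears a second synapse;
2. a fraction *f*<sub>sym,spine</sub> = 0.31 of symmetric synapses sit on
   spines (0.69 on shafts);
3. a fraction *f*<sub>asym,spine</sub> = 0.79 of asymmetric synapses sit
   on spines (0.21 on shafts).

For a dendritic segment of length *L* (after removing the proximal
spine-free 10–15 μm next to the soma) with spine density *D*<sub>sp</sub>:

```
n_spines   = L · D_sp                 n_double  = p_double · n_spines
sym_spine  = f_sym,spine · n_double   asym_spine = n_spines + n_double − sym_spine
sym_shaft  = sym_spine · (1 − f_sym,spine) / f_sym,spine
asym_shaft = asym_spine · (1 − f_asym,spine) / f_asym,spine
```

Soma and axon-initial-segment synapses (both exclusively symmetric on
pyramidal cells) are areal and linear products: *N*<sub>soma</sub> =
*S*<sub>a</sub> · *Sy*<sub>so</sub> and *N*<sub>AIS</sub> =
*L*<sub>ax</sub> · *Sy*<sub>ax</sub>.

The rule constants themselves come from counting segmented synaptic
profiles in serial-section EM stacks with an **unbiased counting brick**:
a 3D counting frame bound by three acceptance planes (top, left, front)
and three exclusion planes (right, bottom, back). An object is counted
iff it lies inside the brick or touches only acceptance planes — a rule
this package realizes exactly with a half-open box, which makes tiling a
volume with bricks count every object exactly once.

## Worked example

```python
from synaptome import DendriticSegmentStats, estimate_dendritic_synapses

bd = estimate_dendritic_synapses(DendriticSegmentStats(length=100, spine_density=1.5))
print(f"{bd.asym_spine:.2f} {bd.asym_shaft:.2f} {bd.sym_spine:.2f} "
      f"{bd.sym_shaft:.2f}  total {bd.total:.2f}")
```

prints

```
160.35 42.62 4.65 10.35  total 217.97
```

100 μm of spiny dendrite carries 150 spines; 10% bear a second synapse,
so 165 synapses sit on spines, of which 4.65 are symmetric (rule 2
applied to the 15 second synapses) and 160.35 asymmetric. Rules 2 and 3
then imply 10.35 symmetric and 42.62 asymmetric synapses on the shaft —
217.97 expected synapses in total, about 93% of them excitatory.

The same machinery scales to whole cells and populations
(`estimate_whole_cell`, `apportion_population`), reads SWC
reconstructions and morphometry tables (`parse_swc`, `dendrite_lengths`,
`read_morphometry_table`), counts simulated or segmented profile lists
(`count_brick`, `estimate_density`), and generates seeded synthetic
inputs (`simulate_synapse_field`, `simulate_virtual_neurons`). The
`examples/` directory holds one short script per capability; a thin CLI
mirrors them:

```sh
synaptome apportion cells.csv --out report.csv
synaptome brick-count profiles.json --frame-w 6.86 --frame-h 5.28
synaptome volumetrics sections --pi-digits 3
synaptome simulate field --intensity 1.0 --seed 7 --out field.json
```

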