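# Methods

## Estimation model

The package treats synapse counts as expectations of a simple
compositional model. For a spiny dendritic segment of length *L* (μm)
and spine density *D*<sub>sp</sub> (μm⁻¹):

- spines: *n* = *L·D*<sub>sp</sub>; double-synapse spines:
  *n*₂ = *p*<sub>double</sub>·*n*; synapses on spines: *n* + *n*₂.
- The split of the *second* synapses into symmetric/asymmetric uses the
  symmetric-on-spine proportion directly: sym<sub>spine</sub> =
  *f*<sub>sym,spine</sub>·*n*₂. This is the printed procedure of the
  source arithmetic, implemented verbatim rather than re-derived from
  neuropil-wide proportions; with the defaults it reproduces the
  reference breakdown (160.35 / 42.62 / 4.65 / 10.35, total 217.97)
  bit-for-bit. An alternative reading — 31% as a neuropil-wide share of
  all symmetric synapses — would give a different spine/shaft partition;
  we deliberately follow the procedure that the reference arithmetic
  uses.
- Shaft synapses of each type follow from requiring the on-spine
  fraction of each type to equal its rule constant, e.g.
  sym<sub>shaft</sub> = sym<sub>spine</sub>·(1−*f*)/*f*. When a numerator
  is zero the corresponding shaft count is defined as zero; a zero rule
  fraction combined with a populated spine compartment is rejected as an
  inconsistent rule set (it would demand division by zero).

Counts are kept real-valued everywhere; rounding to 2 decimals happens
only in report formatting. Conservation (four compartments sum to the
total), linearity in segment length, and the fraction round-trips are
enforced as property tests.

### Parameters and defaults

| parameter | default | units | meaning |
|---|---|---|---|
| `p_double` | 0.10 | – | spines bearing a second synapse |
| `f_sym_spine` | 0.31 | – | symmetric synapses on spines |
| `f_asym_spine` | 0.79 | – | asymmetric synapses on spines |
| `proximal_exclusion` | 15 | μm | spine-free initial dendrite |

The proximal exclusion is reported as a 10–15 μm range; the conservative
(largest) value is the default and the parameter is configurable. Spines
occasionally present inside the exclusion zone are treated as absent.
Spine density is treated as uniform over the included dendrite; regional
density profiles can be expressed by apportioning multiple
`DendriticSegmentStats` rows per cell.

`validate_ruleset` evaluates a candidate rule set on a reference segment
(100 μm, 1.5 μm⁻¹) and flags it when the implied asymmetric share falls
outside 0.80–0.95, the band observed across cortical layers, areas and
species.

## Counting brick

Coordinates are right-handed: x right, y down, z into the stack. The
brick's counting domain is the half-open box [min, max) per axis, which
realizes the three acceptance planes (minimum faces: top, left, front)
and three exclusion planes (maximum faces: right, bottom, back). For
axis-aligned object extents the counting rule reduces to: *count the
object iff its maximum corner lies in the half-open box*. This is
equivalent to "inside or touching only acceptance planes, touching no
exclusion plane", makes exclusion dominate on conflict, and gives exact
tiling exclusivity — every object in a tiled region is counted by
exactly one brick, the property that makes the estimator unbiased with
respect to object size and position.

Profiles are axis-aligned bounding boxes, not voxel masks: the counting
rule only needs interval overlap, and segmentation of raw EM images is
out of scope. Zero-extent (point) profiles degrade gracefully to
point-in-box membership. Shrinkage correction multiplies the stored
linear dimensions by per-axis factors before classification and volume
computation; the default factors of 1 mean dimensions are entered
already corrected (whether a given frame size was corrected by
multiplication or division is a property of the upstream measurement,
so the factors are exposed rather than fixed).

## Morphometry

SWC files use the community structure codes (1 soma, 2 axon, 3 basal,
4 apical); unknown codes are ignored with a warning. The proximal
exclusion is a *path-distance* cutoff measured along the tree from the
soma origin (the root soma node, or the first soma node when the root is
elsewhere): "15 μm from the soma" along a branched dendrite is naturally
a path measure. Segments straddling the cutoff are split proportionally;
each segment belongs to the structure of its child node. Length
measurement is invariant under node renumbering and row order, and a
numerical path-integration oracle checks it on random trees.

## Tissue-scale arithmetic

Sectioning budgets use an explicit `pi_value` parameter: the reference
figure of 1.9625 × 10⁶ sections for a 50 μm × 2000 μm cylinder arises
with two-digit π (3.14), while full precision (the default) gives
≈ 1.9635 × 10⁶. Tissue densities are stored per μm³ internally; the
mm-scale quantities accepted at the interface (neurons/mm³, mm of
dendrite) are converted once on input to keep 10⁹-scale unit errors out
of the arithmetic. The 10 mm mean dendritic length and derived 216 m/mm³
are illustrative defaults, not measurements.

The minicolumn origin split uses the equivalence between the number of
dendritic spines in a volume and the number of axospinous asymmetric
synapses there: resident cells' spine synapses (including rule-1 second
synapses) count as intrinsic; the neuropil total is an axospinous
density × cylinder volume; the remainder is extrinsic, floored at zero
with a warning when resident cells alone exceed the total. The default
axospinous density of 0.67 μm⁻³ is the product of a 1 μm⁻³ overall
synapse density, an 0.85 asymmetric fraction and the 0.79 on-spine
proportion.

## Synthetic data

The generators produce inputs with exactly the statistical structure the
estimators assume, no more:

- **Synapse fields** are homogeneous Poisson: count ~ Poisson(λ·V),
  centres uniform, types i.i.d. Bernoulli. Defaults are λ = 1 synapse/μm³
  (the density of cortical neuropil) and asymmetric fraction 0.85 (the
  centre of the 0.80–0.95 band, and the value used in the recovery
  tests). Profile extents are fixed centred boxes of 0.3 μm per axis —
  the scale of a synaptic junction — with no extent variability and no
  hard-core repulsion between objects; the counting rule is insensitive
  to overlap.
- **Virtual neurons** draw each morphometric quantity independently from
  a normal truncated at zero. Defaults sketch a medium-sized cortical
  pyramidal cell: L_ap 6000 ± 1500 μm, L_ba 4000 ± 1000 μm (≈10 mm total
  dendrite), spine density 1.5 ± 0.3 μm⁻¹, soma 1200 ± 250 μm² at
  0.11 ± 0.02 symmetric synapses/μm², AIS 40 ± 8 μm at 0.6 ± 0.1
  synapses/μm. Covariances between quantities (e.g. apical length vs.
  soma size) are unknown and assumed zero.
- **Varicosity labels** are i.i.d. Bernoulli with bouton probability
  0.88 by default — the typical share of axonal synapses made at
  varicosities — for quantifying the error of the
  one-varicosity-one-synapse putative-contact assumption.

What passing tests show, and what they do not: the synthetic fields are
spatially homogeneous and type-independent, so the recovery tests verify
the counting and estimation machinery, not robustness to clustering,
anisotropy or type-correlated placement found in real neuropil. The
virtual neurons have independent, unimodal morphometries; real
populations are layer-structured and correlated.

Randomness: one integer seed per generator spec; independent substreams
derived via `numpy.random.SeedSequence.spawn`, giving bit-reproducible
output for a fixed seed and NumPy generation algorithm.

## Numerical conventions and test scales

- Conservation and linearity are asserted at 1e-9 relative tolerance;
  unit round-trips at 1e-12.
- Stochastic assertions use 3-standard-error bands: density and
  asymmetric-fraction recovery averages 200 seeded bricks of the
  reference stack geometry (6.86 × 5.28 μm × 115 × 20 nm, ≈83 objects
  per brick); the Poisson count check uses the 99.9% central interval of
  Poisson(1000); population checks use 100–1000 virtual cells. These
  sizes give comfortably narrow bands while keeping the full suite
  around two seconds.
- The tiling-conservation check enumerates 1000 random boxes over a
  3×3×3 brick grid against a brute-force assignment oracle; it is exact,
  not statistical.

## Known limitations

- Rule constants are global: no layer-, area-, age- or species-specific
  values beyond configurability, no spine-morphology subtypes, no
  synaptic weights.
- The counting brick consumes already-segmented profiles; no image
  processing, synapse detection or physical-disector pairing.
- Interneurons are not modelled (their AIS lacks synapses and their
  somata receive both types); the soma/AIS symmetric-only accounting
  applies to pyramidal cells.
- The origin-split clamp (extrinsic floored at 0) signals inconsistent
  inputs rather than modelling them.
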