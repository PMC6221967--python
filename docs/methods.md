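# Methods

## Problem and model

A ribosome is a roughly globular ribonucleoprotein particle: an rRNA core
decorated by ~80 small proteins, some buried between rRNA helices, others
contributing solvent-facing area. `ribosurf` decides, for each protein chain
of a deposited structure, which of the two it is, using two independent
geometric signals and a nomenclature layer that ties the structure's chains
back to gene symbols.

**Radial burial score.** Let μ be the assembly core and `R95` the 95th
percentile of representative-atom distances to μ over all polymer chains.
For a protein chain with residue representative atoms `x_1..x_n` (Cα;
falling back to the residue's first heavy atom when missing):

    s = median_i ‖x_i − μ‖ / R95

The median (not the mean) aggregates residues because ribosomal proteins
often carry long extensions that snake toward the surface from a buried
globular body; the median tracks where the bulk of the chain sits. The
`R95` normalisation makes scores comparable across structures of different
size: ~1 at the particle's effective radius, >1 for protruding chains.

**Core definitions.** Three modes, because "the core" of a ribosome is
genuinely ambiguous:

* `assembly` (default): centroid of all polymer heavy atoms. Simplest
  single reference point; appropriate when the particle is one body.
* `rna_only`: centroid of the rRNA heavy atoms — the chemically natural
  core of a ribosome, useful when heavy protein decoration skews the
  all-atom centroid.
* `per_subunit`: two centers from 2-means over polymer-chain centroids
  (deterministic farthest-pair initialisation), one per ribosomal subunit;
  each chain is assigned to its nearest center before scoring. This serves
  the stricter reading in which a protein at the 40S/60S interface is
  "internal" even though it is far from the whole-particle centroid.

**Thresholding.** `surface` iff `s ≥ t` (ties surface, a documented
convention). `t` may be fixed, or chosen automatically as the midpoint of
the two cluster centers of a 1-D 2-means over the protein-chain scores
(initialised at the min and max score — deterministic, no RNG). If all
scores coincide the auto rule raises a degenerate-separation error rather
than inventing a split; the caller is advised to fix a threshold.

**Accessibility confirmation.** Shrake–Rupley SASA: each atom's sphere is
inflated by the probe radius (1.4 Å, water) and sampled at `n_points`
deterministic golden-spiral directions; a point is accessible when outside
every other atom's inflated sphere; the atom's area is the accessible
fraction × the inflated-sphere area. The per-chain *exposure ratio* is

    SASA(chain atoms, in full assembly) / SASA(chain atoms, isolated)

clamped to [0, 1]. It is reported alongside the radial label as an
independent confirmation rather than folded into the classifier: the radial
score is the decision variable, the SASA ratio the sanity check (a chain
labelled surface should not have a near-zero ratio). Neighbor search uses a
k-d tree with cutoff `r_i + r_max + 2·probe`; atoms outside the cutoff
cannot occlude, so the pruned computation is exactly equal to the all-pairs
one (the test suite asserts bitwise equality against a naive
reimplementation sharing the same point set).

**Canonical frame.** A lab-frame golden spiral makes SASA orientation
dependent at the ~1/n_points level. All SASA input coordinates are first
moved to a canonical frame: centroid at the origin, axes = principal axes
ordered by variance, signs fixed by the third moment of the projections
(largest-|projection| sign as fallback when the skewness vanishes),
right-handedness enforced. Proper rigid motions of the input then change the
canonical coordinates only at floating-point level, making scores, ratios
and labels rigid-body invariant to ~1e-9 relative, which the invariance
suite asserts. Near-spherically-symmetric inputs (degenerate principal
axes) are the known weak spot; for single atoms or isolated spheres the
result is orientation independent anyway.

**Nomenclature cascade.** Gene → chain resolution tries, in order:
(1) the universal name (uL4, eS6, RACK1) as a standalone token of the entity
description; (2) a legacy name ("60S ribosomal protein L4") as a contiguous
token run of the normalised description — token-wise matching, so "protein
L4" can never match "protein L40"; (3) the `L<n>`/`S<n>` token derived from
the gene symbol against "ribosomal protein" descriptions (exact token
equality, flagged `fuzzy`). The first stage that hits wins and its route is
recorded. Unmatched genes (mitochondrial Mrpl/Mrps symbols on a cytoplasmic
structure, paralogs absent from the model) yield an empty map — reported,
never an error. Multi-copy entities aggregate as "any modelled copy on the
surface ⇒ surface". The bundled table covers the 80 mouse cytoplasmic RPs
(including Rack1, Fau/eS30 and Uba52/eL40); an override TSV can extend it,
with duplicate symbols rejected.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| probe_radius | 1.4 | Å | water probe |
| n_points | 100 | — | 2% isolated-sphere accuracy; 960 gives 0.5% |
| vdW radii | C 1.7, N 1.55, O 1.52, S 1.8, P 1.8, generic 1.7 | Å | Bondi-style single-element radii |
| core mode | assembly | — | simplest single reference point |
| threshold | auto | — | midpoint of 1-D 2-means centers |
| representative atoms | Cα / P | — | order-of-magnitude speedup; `all` mode available |
| power threshold | 0.02 | reads/gene/cell | minimum useful droplet depth |

## Synthetic data

The generator emulates the one property the classifier keys on: radially
separable chain placement. Internal chains are Gaussian Cα blobs with
centroids uniform in a ball of `core_radius`; surface chains sit on a shell
of `shell_radius`, their directions taken from a randomly rotated
golden-spiral set so the surface coat surrounds the core and the assembly
centroid stays near the true origin (as in a real particle) even at small
chain counts. Default geometry (core 10–15 Å, shell 45–60 Å, 20–25 Cα per
chain, 1.5 Å jitter) keeps the shell/core separation ratio ≥ 2, the regime
in which auto-thresholding provably recovers the generator's labels; the
suite checks 100% recovery across 20 seeds. A burial fixture (a tiny chain
inside a carbon cage at covering density, spacing < the probe diameter)
exercises the SASA limit `exposure_ratio → 0`; Poisson gene×cell matrices
feed the power metric.

What the fixtures do **not** emulate: real protein folds, rRNA, packing
contacts between chains, partial burial, or the continuous score spectrum of
a real ribosome. Passing tests therefore demonstrate correctness of the
geometry, the arithmetic and the plumbing — not that any particular
threshold is biologically right for a given deposition; for real structures
the exposure ratio and the PyMOL visual check remain the confirmation step.
The 13-gene demo assembly mirrors the composition of a differential RP list
(9 surface, 4 internal products) with real entity names; it is a synthetic
stand-in for a deposition, clearly labelled as such in code.

## Numerical and I/O choices

* First model only; hydrogens and waters dropped; altlocs collapsed to the
  highest-occupancy conformer (ties: altloc letter order). Elements are
  inferred from atom names when the element column is blank.
* Author chain ids are the primary key (they are what PyMOL selections
  address); entity descriptions come from `_entity.pdbx_description`
  (mmCIF) or COMPND records (PDB), and the PDB writer emits COMPND so
  fixture descriptions survive the round trip. Chain ids longer than one
  character are remapped deterministically on writing.
* Coordinates are Å in the deposited frame; the writer enforces the 8.3
  fixed-column range and is lossless to 3 decimals (hence the 1e-3 Å
  round-trip tolerance).
* Chain polymer class is the plurality residue class, `other` below 3
  polymer residues; the core computation uses residue-level classes so that
  degenerate few-residue inputs still define a centroid.
* `surface_fraction` excludes unmapped genes from the denominator and
  reports them separately; an all-unmapped list is an error, not a 0/0.
* Exposure ratios are clamped to [0, 1]; point sampling can otherwise
  exceed 1 by one sample's worth.

## Limitations

* The surface/internal dichotomy compresses a continuum; chains near the
  threshold are flagged by their small `margin` and deserve visual review.
* SASA uses single-element radii, not atom-type (ProtOr) radii; adequate
  for a ratio of the same atoms in two contexts.
* rRNA chains are never classified (proteins only); nucleic acids
  contribute context (core position, occlusion) only.
* Gene→chain linking is name-based; depositions with uninformative entity
  descriptions need an override table or manual mapping, and sequence-based
  identification is out of scope.
* The canonical SASA frame can be unstable for inputs with exactly
  degenerate principal axes; no realistic assembly is in that regime.
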