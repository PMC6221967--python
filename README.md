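# ribosurf

Classify ribosomal proteins as **surface-exposed** or **internal** on a
ribosome 3D structure, and connect that classification to gene-level
expression results.

Single-cell transcriptomics frequently turns up differential lists of
ribosomal-protein (RP) transcripts. Whether those proteins sit on the
ribosome's solvent-facing surface — where they can engage mRNAs, factors and
regulators — or are buried against the rRNA core changes how such a list is
interpreted: surface subunits are far more likely to play selective,
regulatory roles in translation. `ribosurf` answers that question
programmatically for any deposited ribosome structure (e.g. an 80S cryo-EM
model) and any RP gene list, and computes the summary statistic of interest:
the fraction of a gene list's products on the ribosome surface.

## Method

For a structure with chains *c* and assembly core **μ** (centroid of all
polymer heavy atoms; alternatives: rRNA-only centroid, or one centroid per
40S/60S subunit from 2-means over chain centroids):

* **Radial burial score** — for each protein chain,
  `s(c) = median_i ‖x_i − μ‖ / R95`, where `x_i` are the chain's
  representative atoms (Cα; P for nucleic acids) and `R95` is the 95th
  percentile of representative-atom distances to the core over the whole
  assembly. Scores near 0 are deeply buried, near 1 at the particle surface.
* **Classification** — `surface` iff `s(c) ≥ t`; the threshold `t` is either
  fixed or found automatically as the midpoint of the two cluster centers of
  a deterministic 1-D 2-means over all chain scores.
* **Accessibility confirmation** — a Shrake–Rupley solvent-accessible
  surface area (golden-spiral point sampling, probe 1.4 Å) computed twice per
  chain: in the full assembly and in isolation. The exposure ratio
  `SASA_assembly / SASA_isolated ∈ [0, 1]` independently confirms the radial
  call (≈0 = fully occluded by the rest of the particle).
* **Nomenclature linking** — gene symbols (Rpl4, Rps6, …) are resolved to
  structure chains through a bundled three-way table (gene symbol ↔
  universal name uL4/eS6 ↔ legacy names like "60S ribosomal protein L4")
  and a strict matching cascade against the file's entity descriptions, with
  exact-number matching so L4 never matches L40.
* **Summary statistics** — `surface_fraction` (fraction of classified genes
  labelled surface) and the droplet-sequencing `power_metric`
  (mean reads per gene per cell = total reads / (genes × cells), compared to
  the 0.02 minimum useful depth).

All scoring is deterministic and rigid-body invariant; SASA is sampled in a
canonical molecule frame so results do not depend on how the deposition is
oriented.

## Worked example

`ribosurf` ships a seeded synthetic-assembly generator, so the full pipeline
runs without any download. Build a 13-chain demo particle whose entities
carry real RP names (9 chains on the surface shell, 4 in the core), then run
the gene pipeline:

```sh
ribosurf fixture --out-dir .            # or build the demo via the library:
python -c "from ribosurf import make_synthetic_ribosome_demo, write_pdb
st, genes, _ = make_synthetic_ribosome_demo(seed=0)
write_pdb(st, 'demo.pdb')
open('genes.txt','w').write('\n'.join(genes))"

ribosurf classify demo.pdb --out-dir out
ribosurf genes demo.pdb --genes genes.txt --out-dir out
```

which prints

```
9/13 classified genes on the surface (fraction 0.692); 0 unmapped
```

and writes `out/chains.tsv`:

```
chain_id  entity_description        n_residues  radial_score  exposure_ratio  label     margin
A         60S ribosomal protein L8  25          0.183062      0.9270          internal  0.362741
B         40S ribosomal protein S3  25          0.167555      0.5505          internal  0.378248
...
```

`radial_score` is the normalised median core distance, `exposure_ratio` the
assembly/isolated SASA ratio, `margin` the distance to the decision
threshold. `out/genes.tsv` records, per gene, the matched chains and the
route the nomenclature cascade took (`legacy_name` here). The companion
`surface_fraction.json` carries the counts (9 surface / 13 classified,
fraction 0.692) plus provenance (tool version, config hash, input
checksums).

The sequencing-depth check takes totals or a matrix:

```sh
ribosurf power --total-reads 42180000 --n-genes 1000 --n-cells 7264
# -> mean_reads_per_gene_per_cell 5.81, passes (threshold 0.02)
```

A PyMOL coloring script (surface chains red, internal gray) for visual
confirmation:

```sh
ribosurf pymol demo.pdb --out color_chains.pml
```

For a real deposition, point the same commands at the mmCIF/PDB file (e.g.
an 80S ribosome) and your differential gene list; with Cα representatives a
full 80S classifies in minutes on one CPU.

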