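# pocketpharm

Receptor-only (ligand-independent) pharmacophore generation from protein
binding pockets, with a triangle-hash pharmacophore matcher and virtual-
screening evaluation (ROC AUC, enrichment factors).

Structure-based pharmacophore tools usually need a bound ligand to decide
which interaction hotspots matter. `pocketpharm` builds a six-type
pharmacophore model — hydrogen-bond acceptor (HBA) and donor (HBD),
positive (POS) and negative (NEG) charge, hydrophobic and aromatic — from
the receptor alone (apo structures included), so it can be used on targets
for which no ligand-bound crystal structure exists. It is aimed at
computational chemists prototyping receptor-based virtual-screening
workflows and at method developers who want a small, fully transparent and
deterministic reference pipeline.

## Method

Inputs are a PDB structure plus a pocket definition (a grid of lattice
points in Å and the list of pocket-lining residues, as produced by a
cavity-detection program). The pipeline has four stages:

1. **Probe maps.** Five chemical probes (HBD, HBA, POS, NEG, hydrophobic)
   are scored at every grid point against complementary receptor atoms
   using a transparent Gaussian-well surrogate for GRID-style interaction
   energies, normalized to [0, 1].
2. **Filtering → pt1.** Scores below per-probe thresholds are zeroed
   (0.15 for HBD/HBA, 0.2 for hydrophobic, 0.5 for charges); points
   without enough same-type neighbors are removed (more than 30/30/40/5/5
   required within 2 Å); the survivors are reduced to representative
   points by greedy non-maximum suppression at 2.5 Å.
3. **Hybridization projection → pt2.** Every H-bond-capable or charged
   pocket-residue atom projects complementary interaction sites along the
   ideal directions implied by its SP2/SP3 hybridization. The site sits
   (d + e) Å from the atom, where d is the covalent X–H length (1.0 Å)
   and e the H···X contact gap (2.0 Å); its lateral tolerance is the cone
   base radius c = 1.5 Å. The cone obeys

       a² = (d + e)² + c²,   tan A = c / (d + e),   tan C = c / e,

   so max C = 37° and the D–H···A angle B = 180° − C may not drop below
   143°.
4. **Assembly → pt3, pt4.** Polar pt1 points survive only if a same-type
   pt2 site lies within 3 Å (they keep the grid position and score, and
   gain the pt2 direction); the final model is these merged points plus
   the hydrophobic pt1 points and the aromatic upgrades — a hydrophobic
   point with ≥ 6 aromatic atoms within 4.5 Å whose nearby ring normal
   faces the pocket interior becomes an aromatic feature.

For screening, ligand feature sets are aligned to a model by triangle
hashing: all model feature triples are indexed by type and binned side
lengths, each compatible ligand triple seeds a rigid least-squares
superposition, and the best greedy extension wins. The fit score is the
matched fraction of model features. Screens are summarized by the exact
Mann–Whitney AUC and enrichment factors

    EF = (Hits_sampled / N_sampled) × (N_total / Hits_total)

at 1 %, 2 % and 5 % of the ranked library.

## Worked example

The package ships a deterministic synthetic-pocket generator used
throughout the tests: residue fragments (an Asp carboxylate, a backbone
carbonyl, a Lys ammonium, a Phe ring, a Leu side chain) ring a spherical
cavity with their functional groups facing inward.

```bash
pocketpharm fixtures --seed 1 --out fx
pocketpharm generate --pdb fx/receptor.pdb --grid fx/grid.txt \
    --residues fx/residues.txt --out model.json --pml model.pml
pocketpharm screen --model fx/query_model.json --ligands fx/ligands.sdf \
    --out scores.csv
pocketpharm eval --scores scores.csv --labels fx/labels.csv --out report.json
```

prints

```
fixture written to fx (query model: {'HBA': 1, 'HBD': 1, 'POS': 1, 'NEG': 1, 'HYDROPHOBIC': 1, 'AROMATIC': 1})
model with 69 features: {'HBA': 9, 'HBD': 14, 'POS': 8, 'NEG': 8, 'HYDROPHOBIC': 28, 'AROMATIC': 2}
screened 120 ligands -> scores.csv
{
  "auc": 1.0,
  "ef": {"0.01": 6.0, "0.02": 6.0, "0.05": 6.0},
  "hits_total": 20,
  "n_total": 120
}
```

The generated model recovers at least one feature of each of the six
types planted in the pocket. The screen ranks all 20 jittered actives
above the 100 shuffled decoys (AUC 1.0); the enrichment factor saturates
at its ceiling N_total / Hits_total = 6 because every sampled molecule in
the top fractions is active. `fx/query_model.json` is the compact
one-feature-per-type query distilled from the full model — the practical
screening reference, since a handful of anchor features is a far more
selective 3-D query than every representative point.

Library use mirrors the CLI:

```python
from pocketpharm import make_toy_pocket, generate_pharmacophore
from pocketpharm.pocket import ToyPocketSpec

structure, grid, truth = make_toy_pocket(ToyPocketSpec(seed=1))
model = generate_pharmacophore(structure, grid)
print(model.type_counts())
# {'HBA': 9, 'HBD': 15, 'POS': 7, 'NEG': 8, 'HYDROPHOBIC': 30, 'AROMATIC': 2}
```

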