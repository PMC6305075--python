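# Methods

This note records the modeling assumptions, parameter choices and
numerical conventions behind `pocketpharm`, and what the synthetic
fixtures do and do not demonstrate.

## Receptor model

Structures are read from fixed-column PDB text, heavy atoms only. Apo
crystal structures usually lack hydrogens, so the pipeline never reads
hydrogen positions; wherever hydrogen geometry matters (H-bond cones),
ideal directions are generated analytically from the heavy-atom skeleton.
Water (HOH/WAT) is excluded: the method deliberately ignores
crystallographic water. Alternate locations other than blank/'A' are
skipped; insertion codes are folded into the residue key.

Chemical roles come from a residue-template table
(`structure._SIDECHAIN_TABLE` plus backbone rules): acceptors are backbone
O, carboxylate O (Asp/Glu), amide O (Asn/Gln), hydroxyl O (Ser/Thr/Tyr)
and His ring N; donor heavy atoms are backbone N (except Pro), side-chain
N of Arg/Lys/His/Trp/Asn/Gln and the hydroxyls; charges are Lys NZ and the
Arg guanidinium (cationic) and carboxylate O (anionic); hydrophobic atoms
are the side-chain carbons of Ala/Val/Leu/Ile/Met/Phe/Trp/Pro and Cys S;
aromatic members are the Phe/Tyr 6-rings, His 5-ring and the 9 atoms of
Trp's fused system. Histidine is treated as a neutral donor/acceptor by
default (`his_cationic=True` adds a charge). The table is a documented,
editable default — no protonation-state or pKa prediction is attempted.
Van der Waals radii are Bondi-style constants; they only enter through
clash checks and the hydrophobic contact distance, since the H-bond reach
is fixed empirically by e = 2.0 Å.

## Probe scoring

The five probes are scored with a deliberately transparent surrogate for
GRID-style interaction energies: each complementary receptor atom within
5 Å contributes exp(−(r − r_ideal)² / 2σ²) with σ = 0.8 Å, the sum is
clamped to [0, 1], and a grid point closer than 0.7 × (r_vdw + 1.5 Å) to
any heavy atom scores zero for every probe. Ideal contact distances:
2.9 Å heavy-to-heavy for H bonds, 3.5 Å for charge pairs, vdW contact
(atom radius + 1.7 Å) for hydrophobic. The functional form was chosen to
be unimodal in distance, unit-free and normalized, so that the literature
filter thresholds (0.15 / 0.2 / 0.5) are directly meaningful on a [0, 1]
scale; it sits behind a single interface (`probes.build_probe_map`) and
can be swapped for a calibrated energy model without touching the
filters. No angular weighting is applied at this stage — directionality
is enforced downstream by the hybridization cones, which keeps the two
stages independently testable.

## Filtering (pt1)

Three stages per probe type, with the literature thresholds as defaults:
score threshold (strictly-below-zeroed, so a score exactly at the
threshold survives), same-type neighbor count (strictly greater than
30/30/40/5/5 required), and greedy non-maximum suppression at 2.5 Å run
to exhaustion. The neighbor-count radius is not stated alongside the
count thresholds; the default is 2.0 Å — four lattice cells at the 0.5 Å
default pitch, which makes counts of 30–40 geometrically attainable
inside a genuine hotspot while still pruning thin shells. It is exposed
in `FilterConfig` like every other threshold.

Numerical conventions: inclusive distance boundaries carry a 1e-9 metric
slack and score thresholds a 1e-12 slack, because lattice points sit
exactly at radii like 2.0/2.5/3.0 Å and a rigid motion perturbs those
comparisons by an ulp. NMS ties — frequent on the clamped score plateau —
are broken by each point's summed distance to all same-type nonzero
points (a rigid-motion invariant, generically unique), then by
coordinates and grid index. These choices make the whole generator
deterministic and equivariant under rigid motions, which the test suite
asserts to 1e-6.

## Hybridization projection (pt2)

Interaction sites are projected (d + e) Å along ideal directions, with
d = 1.0 Å (typical N–H/O–H covalent length; the reference construction
fixes only c = 1.5 Å and e = 2.0 Å) and lateral tolerance c. Direction
sets per hybridization: SP2 with two heavy neighbors → the in-plane
exterior bisector; SP2 with one neighbor (carbonyl O) → two in-plane
directions at 120° from the bond, the trigonal lone pairs, with the plane
fixed by the neighbor's neighbor; SP3 with one neighbor (hydroxyl O,
ammonium N) → three directions on the tetrahedral cone (109.5° from the
bond vector) at azimuths 0°/120°/240°, the azimuth anchored to the
second-shell atom so the construction is frame-covariant; SP3 with two
neighbors → the two remaining tetrahedral directions. Three samples on
the SP3 cone cover the rotational degree of freedom without exploding
point counts.

Emitted feature types follow the ligand-side convention: a receptor donor
creates an acceptor region for the ligand (HBA), a receptor acceptor an
HBD region, anionic → POS, cationic → NEG. A site survives only if it
lies inside the pocket (within one lattice spacing of a grid point — the
simplest testable containment), passes the D–H···A angle bound, and does
not clash with receptor atoms. The angle bound is enforced at the exact
derived value 180° − C = 143.13° (printed as 143°), boundary inclusive;
the looser physical statement that hydrogen bonds break toward 90° is
subsumed by it.

## Aromatic features

A hydrophobic representative is upgraded when at least 6 aromatic atoms
lie within 4.5 Å (His alone, with 5 ring atoms, can never qualify — a
faithful consequence of the printed rule) and the nearest ring within
4.5 Å has its normal within 60° (either sign) of the direction from ring
centroid to pocket-grid centroid. The 60° half-cone is the package's
quantification of "normal faces the pocket interior": permissive, yet it
rejects the edge-on ring whose normal runs along the pocket wall. The
centroid-direction definition is the simplest ligand-free notion of
"inward". The source hydrophobic point is retained next to the aromatic
feature — an aromatic site is still a hydrophobic one.

## Model assembly and serialization

Polar pt1 points are validated by pt2 within 3.0 Å (inclusive): pt1
carries the energetic evidence (position, score), pt2 the directional
evidence (the merged feature inherits the nearest site's direction). No
NMS re-run is needed after merging since pt3 ⊆ pt1. Models serialize to
versioned JSON (lossless, byte-stable across runs) and to a
LigandScout-style PML export (write-only). The source-atom identity of
each directed feature is kept in metadata rather than emitted as a
separate "H-bond root" feature.

## Screening

The matcher is a documented reconstruction of triangle-hash pharmacophore
alignment: unordered model triples keyed by sorted (type, binned opposite
side) vertices at 0.5 Å bin width, ±1 bin lookup slack; collinear triples
(area < 0.1 Å²) are indexed but never seed transforms; each
type-consistent correspondence seeds a three-point Kabsch fit, extended
greedily (nearest pairs first, one-to-one, same type, within 1.5 Å) and
refined by one rigid re-fit on the matched pairs. fit = n_matched /
n_model, so partial ligands cannot reach 1.0; ties go to lower RMSD, then
enumeration order. Ligands are rigid single conformers; multi-conformer
input is scored per conformer keeping the best. Matching cost grows as
the cube of feature count on both sides, so screening should use the
distilled one-feature-per-type query model (`distill_model`), not the
full representative set.

EF uses N_sampled = ceil(fraction × N) with ties in the ranking broken by
ligand id (both unspecified conventions, fixed for determinism); AUC is
the exact Mann–Whitney statistic with ties counted half, computed by the
rank formula and cross-checked against brute-force pair counting in the
tests.

## Synthetic fixtures

`make_toy_pocket` plants residue fragments (Asp carboxylate, Gly
carbonyl, Lys ammonium, Phe ring — face-on or edge-on — and a Leu side
chain) on the wall of a spherical cavity of radius 6 Å, functional groups
facing the center, with a 0.5 Å lattice filling the cavity; the whole
assembly is rigidly rotated by a seed-derived rotation so fixtures are
congruent but generically oriented (axis-aligned placement would create
exactly tied probe scores on lattice symmetry planes). The ground truth
lists, for every planted role-bearing atom, the ligand-side feature type
it should produce and its interaction envelope — source position plus the
outer radius of the probe's scoring shell — against which recovered
features are checked.

`make_screening_fixture` emulates an active/decoy benchmark at desk
scale: actives are the query model's feature set under Gaussian jitter
(default 0.3 Å) and a random rigid motion per ligand; decoys have the
same feature count with permuted types and positions resampled in the
model bounding box. All randomness flows through one seeded generator;
fixtures reproduce byte-for-byte. Ligand sets serialize as pseudo-ligand
SDF (one carbon atom per feature point, types in a `FEATURE_TYPES`
property) plus a labels CSV.

What passing these tests shows: the geometry, filters, merge logic,
matcher and metrics behave as specified on inputs with known answers.
What they do not show: performance on real proteins and real chemistry —
the probe surrogate is not a calibrated force field, decoys are
count-matched rather than property-matched, ligand conformers are rigid,
and pocket quality is taken as given (cavity detection is an input, not
part of the package).

## Problem sizes

Default test problem sizes were chosen to keep the whole suite fast on a
laptop: toy pockets of radius 6 Å (~7,000 grid points, ~30 atoms), filter
oracles on 100 maps of ≤ 200 points, screening over 20 seeds of 120
pseudo-ligands against a 6-feature query. The pipeline itself is
vectorized (cdist/cKDTree) and handles pockets of tens of thousands of
grid points; note the known caveat that feature counts grow sharply
once pocket volume exceeds roughly three times a typical ligand volume.

## Known limitations

- The probe energy is a surrogate; absolute scores align with the literature
  thresholds only through its [0, 1] normalization, which is this
  package's interpretation.
- No excluded-volume spheres, feature weighting, flexible alignment or
  conformer generation.
- PML export is one-way and schematic; round-tripping uses the JSON
  format.
- Residue→role templates cover the 20 standard amino acids only; modified
  residues get no roles (with a warning).
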