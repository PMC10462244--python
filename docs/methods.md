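# Methods

This note records the model underlying `frasebot`, the parameters that
matter, the design choices made where the design was genuinely open, and
what the synthetic fixtures do and do not establish.

## Model and assumptions

The pipeline rests on three assumptions:

1. **Local environments transfer.** If three residues of the target form
   the same geometric/physicochemical triangle as three residues around a
   known ligand fragment, the fragment's pose is worth transplanting into
   the target by superposing the triangles. Proteins are treated as rigid;
   only the first model and first alternate location of a structure are
   used, and hydrogens are ignored throughout (distances, counts, typing) —
   crystal structures are typically hydrogen-free and no protonation model
   is attempted.
2. **Coarse matching, precise scoring.** Triplet fingerprints deliberately
   discard most geometric detail (only the 8–12 Å edge window constrains
   shape), so matching over-generates; the neural scorer and the geometric
   filters carry the discriminative burden.
3. **Decoys define non-nativeness.** Without per-fragment affinity data,
   "native" is operationalized as *distinguishable from fragment-shuffled
   decoys*: the classifier learns the joint distribution of type-pairs ×
   distances found in real complexes.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| triplet edge window | 8–12 | Å | near-equilateral Cα triangles; no extra aspect test (the window itself bounds edge ratios to 1.5) |
| environment radius | 4.5 | Å | residue inclusion around a fragment |
| fragment weight window | 50–300 | Da | fragment retention |
| max cuts per fragmentation | 3 | bonds | bounds the cut-subset enumeration; configurable |
| edge-compatibility gate | 2.0 | Å | corresponding triplet edges must agree before alignment; on by default |
| pose dedup distance | 0.5 | Å | merge seeded poses of the same FRASE |
| distance weight | exp(−(d−3)²), cutoff 10 | Å | interaction optimum at 3 Å; a hard 5 Å contact count is available behind `hard_count` |
| network | 377→32→16→1, ReLU/sigmoid | — | Adam, batch 50, 500 epochs, lr 1e-3 (optimizer default) |
| decoy multiplicity | 2 | — | decoys per true FRASE |
| collision clearance | ≥ 1.0 | Å | inclusive |
| buriedness | mean ≥ 5 atoms in 5 Å | — | average over ligand atoms, not per-atom minimum |
| score threshold | 0.4 | — | nativeness cutoff |
| cluster diameter bound | 3.0 | Å | max pairwise member distance; k grows until met |
| query tolerance radius | 1.5 | Å | half the diameter bound; configurable |

## Design choices

- **Residue bit table.** The 11-bit layout is: positions 1–3 size, 4–6
  hydrophobicity (3-bit thermometers), then HBA, HBD, positive ionizable,
  negative ionizable, aromatic. Size thermometers come from side-chain
  heavy-atom counts; hydrophobicity from the Fauchère–Pliška side-chain π
  scale, chosen because it places tryptophan at the maximum (all-ones) and
  glycine at zero, the two anchor encodings of the scheme. Kyte–Doolittle
  was rejected for this table because it ranks tryptophan low. Histidine is
  encoded neutral aromatic donor/acceptor (dominant state at pH 7.4). The
  table ships as `data/residue_bits.yaml` and can be replaced wholesale.
- **Atom typing.** Ligand types are assigned by SMARTS rules
  (`data/ligand_type_smarts.yaml`); protein types by per-residue atom-name
  templates with element-level defaults (`data/protein_atom_types.yaml`).
  Multi-typing is deliberate: the Kronecker-delta double sum accommodates
  atoms carrying several labels. "Hetero" is read as any N/O/S/P atom.
- **Fragment enumeration.** All connected pieces obtainable by deleting any
  subset of ≤ `max_cuts` acyclic single bonds, deduplicated by parent atom
  set. When a cut removes a substituent from a ring atom, the substituent's
  first atom stays as a carbon-like marker that contributes to weight and
  geometry but never to typing or pharmacophore features.
- **Matching.** Exact 33-bit fingerprint equality via a hash index keyed on
  the lexicographically smallest of the six permutations; lookups try the
  query's canonical key, which guarantees order invariance without double
  counting. The optional edge gate discards geometrically incompatible hits
  before alignment, since the fingerprint itself carries no geometry beyond
  the window.
- **Alignment.** Kabsch superposition on the 3 matched Cα atoms with the
  determinant-corrected SVD, so reflections are never produced; degenerate
  (collinear) triangles cannot satisfy the edge window.
- **Decoys.** A foreign fragment is recentered at the native fragment's
  centroid without rotation (a random-rotation flag exists). This preserves
  pocket occupancy while scrambling chemistry — exactly the signal the
  classifier must learn. Decoys are not clash-filtered.
- **Classifier.** scikit-learn's MLP implements the 32/16 ReLU + sigmoid
  architecture with log-loss (equivalent to sigmoid + binary
  cross-entropy). Features are z-scaled with statistics fit on the training
  split and stored inside the model; the train/validation split is 90/10 by
  FRASE under the run seed. The featurizer uses the Gaussian-weighted sum
  with a 10 Å cutoff as canonical; the 5 Å hard-count variant is available
  behind a flag.
- **Clustering.** Features are clustered independently per type; a single
  mixed k-means over type and coordinates would need an arbitrary type/
  distance weighting. k is emergent: the smallest k (10 restarts per k,
  seeded) whose clusters all satisfy the 3 Å diameter bound, read as max
  pairwise member distance. Ranking is by size, ties by compactness.
  Selecting which cluster centroids form the query is an explicit user
  choice — in practice guided by pocket adjacency — not an automated step.

## Synthetic fixtures: what they show and what they do not

The fixture module plants ground truth at every stage: proteins whose only
qualifying triplets are the planted ones (fillers sit ≥ 13 Å apart),
complexes whose fragment and environment are known by construction,
class-separable FRASE sets (donor–acceptor and aromatic-stack contacts at
2.8–3.9 Å in the true class, fragment-shuffled decoys), Gaussian feature
blobs, and a filter set with planted collision/exposure/score violations.
Residue side chains are minimal proxies — a few signature atoms, enough for
the typing and distance logic the algorithms consume, with no claim to
rotameric realism.

Passing tests on these fixtures establishes algorithmic correctness
(oracle equivalence, invariances, exact funnels, determinism) and that the
classifier can learn a planted distance/type signal. They do not establish
performance on crystallographic data: real environments are denser, noisier
and chemically richer, and a classifier trained on the synthetic set
transfers only to data drawn from the same construction. Problem sizes used
by the default suite — 500 true + 1000 decoy FRASEs at 50 training epochs,
≤ 100 triplets per oracle comparison, 60 features per clustering test —
keep each stage's check at desk scale; the 500-epoch default remains the
production configuration value.

## Numerical notes

- All distance thresholds are inclusive (≥ / ≤); distances use heavy atoms
  only.
- The diameter bound check allows 1e-9 slack for floating-point noise;
  cluster centroids are member means, not k-means centers.
- Fingerprint packing uses big-endian bit order, which preserves
  lexicographic order between bit strings and packed bytes.
- All randomness flows through `numpy.random.default_rng(seed)` or
  scikit-learn `random_state`; identical seeds reproduce identical decoys,
  weights, clusters and pipeline reports byte for byte.
- Degenerate inputs: featureless fragments yield empty feature lists;
  fragments with no heavy atoms are a filter error; an empty complex list
  builds an empty database; a seeded fragment with no environment is
  excluded from scoring.

## Known limitations

- Exact fingerprint matching cannot tolerate near-miss encodings (a
  Tanimoto relaxation flag exists but defaults off); borderline triangles
  just outside 8–12 Å are invisible.
- PDB-derived ligands without an accompanying SDF get connectivity from
  distance-based bond perception, which can mistype unusual chemistry.
- The decoy construction ignores steric clashes, so some decoys are
  physically impossible poses; the classifier may exploit that.
- Affinity- or drug-likeness-based curation of input complexes is out of
  scope: the database builder fragments whatever it is given (an optional
  whole-ligand weight gate exists).
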