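# frasebot

Fragment-based ligand discovery for proteins without known binders. Given
only an apo 3D structure of a target protein, `frasebot` seeds ligand
fragments from a database of *fragments in structural environments*
(FRASEs) into the target, scores how "native" each seeded pose looks with a
small neural classifier, filters the poses geometrically, and condenses the
survivors into a 3D pharmacophore query ready for virtual screening.

## Method

**FRASE database.** Every ligand of a set of protein–ligand complexes is
fragmented by breaking acyclic single bonds (ring systems are never cut;
the first atom of a substituent cut off a ring is retained as an α-atom
marker). Fragments of 50–300 Da are kept, and each is stored together with
its structural environment — all residues with a heavy atom within 4.5 Å of
the fragment.

**Triplet screening.** Both database environments and the target protein
are encoded as residue triplets: triples of residues whose Cα atoms form an
approximately equilateral triangle with all edges in 8–12 Å. Each residue
contributes an 11-bit many-hot property string (size and hydrophobicity as
3-bit thermometers, plus H-bond donor/acceptor, ±ionizable, and aromatic
flags), concatenated into 33-bit triplet fingerprints under all 6 residue
orderings so that matching is order-invariant. Exact fingerprint equality
through a hash index finds candidate matches; each hit FRASE is rigidly
aligned into the target by least-squares superposition of the three Cα
atoms (proper rotations only), transplanting its fragment into the target.

**Nativeness scoring.** Each (fragment, environment) pair is featurized
into a 377-element interaction fingerprint over the 29 ligand × 13 protein
atom-type vocabulary:

    f_mn = Σ_i Σ_j δ_mi δ_nj w(d_ij),   w(d) = exp(−(d−3)²) for d ≤ 10 Å, else 0,

where δ_mi = 1 iff ligand atom *i* carries type *m* (atoms may carry
several types). A dense network (377 → 32 ReLU → 16 ReLU → 1 sigmoid,
binary cross-entropy, Adam, batch 50, 500 epochs) is trained to separate
true FRASEs from decoys made by shuffling fragments between environments;
its sigmoid output is the nativeness score in (0, 1).

**Filtering and pharmacophore assembly.** Seeded fragments survive when
they do not collide with the protein (every atom ≥ 1 Å from protein atoms),
are buried (on average ≥ 5 protein atoms within 5 Å of each ligand atom),
and score ≥ 0.4. Survivors are converted to pharmacophoric features (HBD,
HBA, Pos, Neg, Ar at ring centroids, Hyd at aliphatic-group centroids) and
clustered per type with k-means, growing k until every cluster's diameter
is ≤ 3 Å; the largest cluster centroids compose the exported query.

## Worked example

The package ships a synthetic-fixture generator, so the full pipeline runs
without any external data. Build a toy bundle (three planted complexes and
a target carrying the matching triplets) and run the pipeline:

```sh
frasebot fixtures --out demo --seed 3
cd demo
frasebot run --target target.pdb --complexes complexes --seed 11 \
    --report report.json --set epochs=50 --set score_threshold=0.0
```

The report's funnel (`report.json`) reads:

```json
"stages": {
  "db_frases": 4, "seeded": 4, "input": 4,
  "collision": 4, "buriedness": 4, "score": 4,
  "features": 6, "clusters": 5
}
```

The three ligands yield 4 database FRASEs; each planted triplet is found in
the target, so 4 fragments are seeded exactly at their planted pockets; all
pass the collision and buriedness filters because the fixture pockets are
lined with an atom cage; 6 pharmacophoric features condense into 5 clusters
(two aromatic features merge into the top-ranked cluster of size 2). The
score threshold is zeroed here because a 4-record toy database cannot train
a meaningful classifier — with a real database the default `0.4` threshold
applies and typically removes most poses. Repeating the command with the
same seed reproduces the report byte for byte.

The per-module functions (`frasebot.triplet_screen.screen`,
`frasebot.nativeness.train_model`, `frasebot.pharmacophore.cluster_features`,
…) expose the same pipeline as a library.

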