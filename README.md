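# pksmith

Prediction of mature **type I cis-AT polyketide** structures from biosynthetic
gene clusters (BGCs), validated against tandem mass spectra.

Modular type I cis-AT polyketide synthases build a polyketide chain one
two-carbon extender unit at a time: each module's acyltransferase (AT) domain
selects the extender (malonyl-CoA `mal`, methylmalonyl-CoA `mmal`, ...), its
ketoreductase/dehydratase/enoylreductase (KR/DH/ER) domains set the unit's
oxidation state, a thioesterase (TE) releases the chain as a linear acid or
macrolactone, and tailoring enzymes decorate the released core.  Genome
mining finds tens of thousands of such clusters, but connecting a cluster to
the structure of its product requires predicting every one of those steps —
and then deciding, among the many structures consistent with the genes, which
one the organism actually makes.  `pksmith` is for natural-product genome
miners and metabolomics researchers who want that whole chain of inference in
one auditable toolkit.

## What it computes

1. **AT substrate specificity.** A 24-residue active-site signature is
   extracted from each AT domain by pairwise global alignment (BLOSUM62,
   affine gaps 10/1, free end gaps) to a packaged reference profile with
   marked columns, one-hot encoded (24 × 20 = 480 bits), and classified with
   extremely randomized trees (150 trees, depth 10).  Evaluation helpers bin
   test signatures by minimum Hamming distance to the training set
   (bin *Bk+* = distance ≥ *k*) and run shuffled five-fold cross-validation.
2. **Module substrate maturation.** The standard reduction ladder: no active
   KR → β-ketone; KR → hydroxyl; KR+DH → enoyl; KR+DH+ER → saturated.
   Inactive domains (catalytic motif absent) are skipped.
3. **Assembly-line order.** Per-gene docking regions (head = first 100
   residues, tail = last 50) are compared by Smith–Waterman bit-score
   *(λS − ln K)/ln 2*; a pair's pairwise-nearest-neighbor (PNN) features —
   its similarity to the *n* = 3 most similar interacting and non-interacting
   training pairs — feed a logistic interaction model.  A gene permutation is
   scored as

   S_pathway = Σ_{p∈Non-adj} S_p + Σ_{p∈Forward} S_p·W_forward + Σ_{p∈Backward} S_p·W_backward

   over its consecutive pairs *p* (classes by genomic adjacency; both weights
   default to 1).  All *g*! permutations are ranked for *g* ≤ 9; beyond that
   an admissible best-first branch-and-bound returns the top orders.
4. **Core assembly and tailoring.** Units are chained by Claisen
   condensation (downstream α-carbon to upstream carbonyl), released as the
   linear acid and, with a TE, as one macrolactone per eligible hydroxyl.
   Tailoring modifications are declarative rules — a substructure motif plus
   a graph-edit script — matched by subgraph isomorphism; with *k* cores and
   enzymes matching *m₁…mₙ* sites, enumeration yields
   *k* × (*m₁*+1) × … × (*mₙ*+1) candidate mature compounds.  A packaged
   database of 78 curated rules covers the common tailoring families
   (glycosylation, methylation, hydroxylation, acylation, halogenation,
   redox, cyclization).
5. **Spectral validation.** Candidates are fragmented in silico (one or two
   rounds of cutting one acyclic single bond or two bonds of one ring) and
   scored against spectra by shared-peak count over [M+H]⁺ fragment m/z.
   Exact search gates on precursor mass; variable search tolerates one
   unknown offset Δ (an unpredictable starter unit), matching fragments at
   *f* or *f*+Δ.  False discovery rates use edge-switching decoys (25 swaps
   preserving composition, valence totals, and connectivity, filtered
   against targets by InChIKey) with FDR = N_decoy / N_target.

## Worked example

Everything below runs offline on synthetic fixtures with planted ground
truth (`pksmith fixtures` writes a BGC whose true assembly order, substrate
labels, and docking motifs are known):

```bash
pksmith fixtures -o demo/fix --seed 11 --n-genes 3 --shuffle
pksmith order demo/fix/bgc.json --training demo/fix/docking_training.tsv \
    -o demo/order --seed 11
pksmith structures demo/fix/bgc.json \
    --at-training demo/fix/at_training.tsv \
    --docking-training demo/fix/docking_training.tsv -o demo/run --seed 11
```

`demo/order/orders.tsv` starts:

```
rank  order     score     probability
1     g1-g0-g2  1.809970  0.426976
2     g0-g2-g1  1.009551  0.191772
3     g2-g1-g0  0.867559  0.166387
```

The top-ranked order `g1-g0-g2` is the planted (non-colinear) assembly order
recorded in `demo/fix/ground_truth.json`; its score 1.81 is the sum of the
two consecutive-pair interaction probabilities, and the probability column is
the softmax-normalized pathway score.  `demo/run/cores.tsv` then contains the
assembled core in that order:

```
smiles                                        cyclization  pathway_rank
CC(=O)C(C)C(O)CC(=O)C(C)C(O)CC(=O)C(C)C(=O)O  linear       1
```

— six alternating `mal`/`mmal` units, the KR-carrying modules reduced to
hydroxyls, released as the free acid (monoisotopic mass 316.1522 Da in
`candidates.tsv`).  With tailoring enzymes on the BGC the candidate list
grows to the *k*×∏(*mᵢ*+1) combinations; `pksmith search` and `pksmith fdr`
match candidates against an MGF/mzML corpus and estimate the FDR.

## BGC JSON schema

```json
{
  "genes": [{
    "id": "g0", "genomic_rank": 0, "strand": "+",
    "protein": "MKT...",
    "modules": [{"domains": [
      {"kind": "KS", "start": 0, "end": 80, "active": true, "sequence": "..."},
      {"kind": "AT", "start": 80, "end": 380, "sequence": "..."}
    ]}]
  }],
  "tailoring_enzymes": [{"kind": "GT-glucose", "sequence": "..."}]
}
```

Coordinates are 0-based half-open residue intervals within the gene's
protein.  antiSMASH-style annotated GenBank regions are read via
`parse_genbank_region` (CDS features with `translation` and `pks_domains`
qualifiers); domain detection itself (HMM search) is consumed from such
annotations, not re-implemented.
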