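# Methods

This note records the models, parameter choices, numerical conventions, and
known limitations behind `pksmith`.  The pipeline has five stages; each is a
pure function of its inputs, configuration, and seed.

## 1. BGC data model

A BGC is a list of genes sorted by genomic rank; each gene carries ordered
modules of catalytic domains (AT, KS, ACP, KR, DH, ER, TE) plus a list of
tailoring-enzyme tags.  Coordinates are 0-based half-open everywhere;
GenBank's 1-based inclusive locations are converted at the parser boundary.
Domain detection (HMM profile search) is deliberately out of scope: the
parsers accept pre-annotated inputs (declarative JSON or antiSMASH-style
GenBank qualifiers), and minus-strand genes always use the annotated
translation — re-translating would introduce codon-table ambiguity.
Windowing a genomic region around anchor enzymes uses a 10 kb default flank
on each side, the conventional span for delimiting a polyketide cluster.
Unknown tailoring tags are carried through and skipped by the modification
engine with a warning rather than an error, so a cluster annotated with an
enzyme family the rule database lacks still produces its other candidates.

## 2. AT substrate specificity

**Signature extraction.** The 24 active-site residues that determine AT
substrate choice are read off a pairwise global alignment of the query
against a single packaged reference profile with 24 marked columns
(BLOSUM62, gap open 10 / extend 1, free end gaps so a domain embedded in a
longer protein aligns cleanly).  A multiple-sequence alignment would also
work; the pairwise form was chosen because it is deterministic and
dependency-free, and the aligner is pluggable.  Reference columns with no
aligned query residue yield `-`.

The packaged reference is a **synthetic stand-in**: a deterministic
300-residue sequence with 24 deterministically chosen marked columns
(`data/at_reference_synthetic.fasta`).  It exercises the extraction
machinery and supports the fixture-driven tests; analyses of real AT domains
should substitute a structurally derived profile via `load_reference`.

**Encoding and classifier.** Signatures are one-hot encoded: 24 positions ×
20 amino acids = 480 bits, one set bit per non-gap position; gaps and the
ambiguous residue X give all-zero blocks so the length is fixed.  The
classifier is `ExtraTreesClassifier` with 150 trees and maximum depth 10 —
the operating point for this task — seeded for determinism.  Argmax ties
break lexicographically by label.  The label vocabulary is open-ended (read
from training data); the packaged fixture set guarantees `mal` and `mmal`.

**Evaluation.** `hamming_bins` measures generalization: bin *Bk+* holds test
points whose minimum Hamming distance to every training point is at least
*k*, so accuracy as a function of *k* exposes how performance decays away
from the training distribution.  Cross-validation uses five folds and five
shuffles by default, with near-equal disjoint folds per shuffle and the
confusion matrix averaged across shuffles and rounded for display.

Self-training on large unlabeled domain collections is exposed as a hook but
off by default; no refinement procedure is prescribed here.

## 3. Module substrate maturation

Each extender unit is a two-carbon fragment: carbonyl carbon C1 and α-carbon
C2 (branch on C2: H for `mal`, methyl for `mmal`, ethyl for `emal`, methoxy
for `mxmal` — the packaged monomer library is a JSON file and extensible).
The module's own reductive domains set C1's state:

| active domains | state | C1 group |
|---|---|---|
| none | ketone | C=O |
| KR | hydroxyl | CH–OH |
| KR+DH | enoyl | C=C (dehydrated) |
| KR+DH+ER | saturated | CH₂ |

Inconsistent content (DH without KR, ER without DH) warns and falls back to
the deepest consistent state.  Inactive domains are skipped.  The
inactive-domain heuristic is catalytic-motif presence (e.g. a Rossmann-like
NADPH-binding pattern for KR), packaged as an editable JSON table, because
no algorithm for inactivity detection is prescribed; pre-set flags from the
input are never overridden.  Stereochemistry is not modelled anywhere —
structures are compared at the constitutional level.

**Chemical conventions.** During assembly the downstream unit's α-carbon
bonds to the upstream unit's C1, so C1 is the β-position of the next
condensation.  An enoyl unit's olefin is placed on that condensation bond
(the chemically correct α,β-unsaturation; e.g. two `mal` units with the
first enoyl give crotonic acid), while the standalone serialized unit draws
the olefin intra-unit so the per-unit formula ladder holds exactly
(hydroxyl = ketone + H₂; enoyl = hydroxyl − H₂O; saturated = enoyl + H₂).
The final unit's C1 becomes the free-acid carboxyl on release; a reduced
state on the final unit would act on a β-position outside the chain and is
ignored with a warning.  When the first module lacks an AT, the chain is
assembled from the remaining units and its first α-carbon is marked as the
attachment point of an unknown starter acyl group, to be resolved by the
variable spectral search (starter units are treated as unpredictable).

## 4. Assembly order

**Docking regions.** Head = first 100 N-terminal residues, tail = last 50
C-terminal residues of each gene product.  (The docking literature describes
the N-terminal docking region as the larger, three-helix element, which is
why the longer window is assigned to the head; both lengths are
configurable.)  The pathway-start gene's head and pathway-end gene's tail
dock nothing and are marked excluded; start/end are detected by domain
content — a TE-bearing gene anchors the end, a gene whose first module lacks
KS anchors the start — and anchored genes are pinned during ranking.

**Similarity.** Smith–Waterman local alignment (BLOSUM62, gap open 11 /
extend 1) converted to bits with the standard gapped Karlin–Altschul
constants λ = 0.267, K = 0.041.  The scorer is cached and pluggable (an
external BLAST adapter can replace it).  The similarity of two (tail, head)
pairs is the head–head plus tail–tail bit-score.

**PNN features and interaction model.**  For a query pair, the *n* = 3 most
similar interacting and *n* most similar non-interacting training pairs are
selected (ties broken by id).  The default `per_score` mode emits the head
and tail bit-scores to each neighbor (4*n* features); a `summed` mode emits
one summed similarity per neighbor (2*n* features) for a more compact
variant.  Negatives are subsampled (seeded) to the positive count; each
training pair's features are computed against the training set excluding
itself; features are standardized and fed to logistic regression.  The
interaction score S_p is the predicted interaction probability, which makes
pathway scores interpretable and avoids tied ranks.

**Pathway score and ranking.**  A candidate order is scored as the sum of
its consecutive-pair scores, with pairs that are genomically adjacent in
forward or backward orientation multiplied by W_forward / W_backward (both 1
by default; raising W_forward rewards colinearity, reflecting that gene
order is usually mostly preserved in the assembly line).  Up to 9 free genes
(362,880 orders, about a second vectorized) every permutation is scored;
beyond that a best-first branch-and-bound with the admissible bound
"partial score + remaining-edge count × maximum edge weight" returns the top
orders, and it provably agrees with exhaustive enumeration (tested for all
sizes ≤ 7).  Ties break lexicographically by gene-id sequence.  A
softmax-normalized probability per order is also emitted.

## 5. Core release, tailoring rules, enumeration

Release always yields the linear free acid; with a TE present, each hydroxyl
oxygen whose ester ring would have ≥ 5 atoms yields one macrolactone
(chemical-plausibility floor; configurable).  Cyclization is additionally
expressible as an ordinary database rule for clusters where a dedicated
cyclase acts post-release; using one or the other per core avoids double
counting.

A modification rule is: an `enzyme_tag`, a substructure `motif` (SMARTS), a
valid-SMILES `example` embedding the motif, and an ordered edit script
(`add_atom`, `remove_atom`, `add_bond`, `remove_bond`, `set_bond`,
`set_charge`, `attach` for fragment condensations such as sugars) addressed
by motif-match atom indices (`"n<j>"` addresses the j-th atom the script
itself introduced).  Loading validates every rule by applying its script to
its own example and sanitizing the product; each rule also carries its net
`formula_delta`, re-checked in the tests.  Motif matching uses RDKit
substructure search with embeddings collapsed to unique atom sets
(automorphic re-mappings removed) in deterministic order.

The packaged database (`data/tailoring_rules_synthetic.json`) holds **78
rules** spanning glycosylation (a 17-sugar library plus C- and N-glycosyl
variants), O-/N-/C-methylation, hydroxylation, epoxidation, acyl transfer,
halogenation, phosphorylation/sulfation and their removal, redox
interconversions, transamination, decarboxylation, prenylation, and
ring-forming reactions.  It is labelled *synthetic*: the per-family reaction
chemistry is standard, but the entries were authored for this package and do
not capture the site- and substrate-specificity of particular characterized
enzymes.  Users can supply their own database in the same schema.

**Enumeration semantics.**  Each enzyme is applied at most once, at one
chosen site, or skipped — the `(mᵢ + 1)` choice set; this is the only
reading consistent with the product formula *k*×∏(*mᵢ*+1) (independent
per-site application would give 2^m).  Multi-copy enzymes are expressed as
repeated database entries.  Site counts are taken on the pristine core;
sites are re-located after each applied edit, and a combination whose chosen
site no longer exists (or whose edit fails valence checks) is dropped with a
log entry while still counting toward the raw total.  Streams are lazy with
a default cap of 10⁶ candidates and report both raw and deduplicated
(canonical-SMILES) counts, since mature-compound collections can reach
millions per cluster.

## 6. Spectral search and FDR

Fragmentation: round 1 removes one acyclic **single** bond, or any two bonds
of one ring (enumerated as unordered pairs of ring bonds whose joint removal
disconnects the graph); round 2 applies the operator to every round-1
fragment.  The operator sits behind one function so alternative bond-type
restrictions are a one-line change.  Fragment masses are the sum of
heavy-atom + attached-hydrogen monoisotopic masses (no hydrogen
rearrangement), deduplicated at 1 µDa; the parent mass is always present.

Scoring is the shared-peak count: the number of (intensity-filtered, default
1% relative floor) peaks within `frag_tol` of any singly-protonated fragment
m/z, each peak counted once.  Adducts are [M+H]⁺ only (positive mode);
proton mass 1.007276 Da.  Exact search additionally gates on
|precursor neutral mass − molecule mass| ≤ `prec_tol`.  Variable search
accepts one offset Δ ≤ `max_shift`, matching each fragment at *f* or *f*+Δ;
when the candidate declares an attachment atom, Δ applies only to fragments
containing it.  Offsets within `prec_tol` are treated as Δ = 0, so
`max_shift = 0` reproduces exact search identically.  Defaults
(`frag_tol` = `prec_tol` = 0.02 Da, `max_shift` = 400 Da) are practical
high-resolution values, configurable everywhere.  The score is a peak count,
not a p-value; no statistical significance model is attached to individual
matches — discovery control is delegated to the target-decoy estimate.

Decoys: 25 edge-switching steps on the kekulized heavy-atom bond graph; a
step swaps the endpoints of two bonds (each bond keeping its order, hence
every atom's bond-order total is preserved), and is rejected unless the
result stays singly connected and sanitizes; 100 retries per step, and a
whole-decoy regeneration loop (fresh seed stream) rejects decoys whose
InChIKey appears in the target set.  FDR at a score threshold is
N_decoy / N_target, undefined (NaN, flagged) when no target passes.

## 7. Synthetic fixtures — what they do and do not show

`make_bgc` plants three signals: label-determining residues at three fixed
signature positions; complementary 12-residue docking motifs at cognate gene
junctions, drawn from a pool of connector families chosen without
replacement (terminal head/tail get dedicated never-pairing families so
every docking region is in-distribution); and catalytic motifs present or
ablated in reductive domains.  Everything else is uniform random protein
sequence.  `make_spectrum` emits the molecule's own depth-2 [M+H]⁺ fragment
ladder with configurable peak dropout, Gaussian m/z jitter, and uniform
decoy peaks.  The docking training set contributes four positive and four
mixed-family negative pairs per connector family: with *n* = 3 neighbors and
leave-self-out feature computation a positive query must still find three
same-family interacting neighbors, so four per family is the minimum
adequately powered size.

Passing tests on these fixtures demonstrates that the machinery is correct:
signals that are present by construction are recovered end to end.  They do
not demonstrate accuracy on real sequences, where signature/label
relationships are noisy, docking compatibility is not a clean block motif,
and spectra contain co-eluting species — benchmarking those requires the
external labelled datasets (hundreds of labelled AT domains, docking pairs
from characterized clusters, reference spectra), which this package accepts
in the documented TSV/MGF formats but does not ship.  Problem sizes in the
test and acceptance runs (3–9 genes, 1–2 modules per gene, tens of training
pairs, 50-spectrum corpora, 100 decoys) were chosen as the smallest scales
at which every contract is exercised, including the 9-gene factorial
enumeration.

## 8. Known limitations

- Trans-AT systems, non-elongating modules beyond the inactive-domain flag,
  and in-module methyltransferases are not modelled.
- Starter units are never predicted structurally; they are handled as a mass
  offset by the variable search.
- No stereochemistry, no isotope envelopes, no retention-time modelling.
- The rule database's 78 entries are family-level chemistry, not
  enzyme-level specificity; site preference is combinatorial, delegated to
  spectral ranking.
- The interaction model's accuracy depends on docking training data; the
  shipped fixture generator is a planted-signal surrogate, not a biological
  training set.
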