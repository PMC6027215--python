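# Methods

## Scope and model

`hat_annotator` annotates consensus sequences of *hAT*-superfamily DNA
transposons (Class II, cut-and-paste; prototypes *hobo*, Activator, *Tam3*).
A consensus element is treated as autonomous when it satisfies both parts of
the family's functional definition:

1. it is flanked by terminal inverted repeats (TIRs) of at least 8 bp, the
   5′ arm reappearing near the 3′ end as its reverse complement; and
2. it encodes a transposase that retains the five diagnostic catalytic
   residues — in maize Activator (AC) numbering D301, D367, R463, the
   aromatic W/F at 464, and E719; in Hermes numbering D180, D248, R318,
   W319, E572.

Elements failing either test are nonautonomous, with the failed criteria
recorded (`no_tir`, `truncated_transposase`, `no_transposase`). Deletion
derivatives named by the N-suffix convention (`Os_TEMPINDAS-N1`,
`hAT-14N1`) are linked back to their parent element when the parent is in
the dataset.

## TIR detection

Detection is anchored on a degenerate consensus motif, by default the
5-nt plant *hAT* anchor `(T/C)A(A/G)NG`, matched against the 5′ arm prefix
with a budget of `max_anchor_mismatches` (default 1). Arm-vs-arm
complementarity gets its own budget, `max_arm_mismatches` (default 4),
counting Hamming mismatches between the 5′ arm and the reverse complement
of the 3′ arm; `N` never matches anything. Both budgets are separate and
configurable because either reading of "up to 4 mismatches" (against the
anchor, or between arms) is one flag away.

Arms must start (5′) or end (3′) within `terminal_window` (default 200 bp)
of the sequence ends, may not overlap, and range from `min_len` 8 bp to
`max_len` 30 bp — typical *hAT* TIR lengths; the cap prevents degenerate
whole-sequence "repeats". `find_tirs` enumerates **every** qualifying
(5′ window, 3′ window, length) combination rather than only maximal
extensions, so its output is directly comparable against an exhaustive
all-substring-pairs scan; `best_tir` ranks by (length desc, mismatches asc,
position asc). The scan is numpy-vectorized per arm length; sequences of a
few kb scan in ~0.1 s.

Arm deduplication is exact string identity on the 5′ arm, first occurrence
kept — the simplest reproducible reading of "nonidentical" TIRs.

The TIR consensus over the first `n_columns` (default 8) arm positions uses
two thresholds: a column prints a single letter when the top base reaches
`single_threshold` (0.6), a bracket pair `[X/Y]` when the top two bases
together reach `pair_threshold` (0.8) and each holds at least
`1 − pair_threshold` (0.2), and `N` otherwise. These values are chosen so a
50/50 column yields a pair and a uniform column yields `N`; both are
configurable. Bracket alternatives print in descending frequency (exact
ties reverse-alphabetically, so a perfect T/C tie prints `[T/C]`); two
renderings of the same allowed sets compare equal via
`DegenerateMotif.same_pattern`.

## Transposase analysis

Elements are translated in all six frames under the standard genetic code
(codons containing `N` translate to `X`); candidate ORFs are maximal
stop-free runs of at least `min_aa` residues (default 100 — *hAT*
transposases run ~600–800 aa, and 100 excludes noise ORFs while keeping
deletion fragments visible). No ATG start is required, since consensus
transposases are often frame fragments. Each candidate is aligned globally
(Needleman–Wunsch, BLOSUM62, gap open 10, extend 0.5 — standard defaults,
configurable) to the reference transposase; the best-scoring ORF is read at
the five reference-numbered positions. A mismatching residue or an aligned
gap at any site fails that site ("lacking" the residue); all five must pass
for an `active` call, otherwise `truncated`; with no qualifying ORF the
call is `absent`.

The two numbering presets (AC, Hermes) are independent: each needs a
reference protein that itself carries the residues. No real transposase
sequence ships with the package; the synthetic module provides invented
reference proteins (below), and real analyses supply their own reference
FASTA.

Conserved-block extraction takes a protein MSA and returns maximal runs of
columns that are gap-free in every row and whose top residue reaches
`min_column_conservation` (default 0.5), with run length ≥ `min_block_len`
(default 3); per-block column count matrices are the text-mode stand-in
for a sequence logo.

## Phylogeny

Distances: p-distance with pairwise deletion (columns with a gap or `N` in
either sequence are skipped — TE consensus alignments are gappy, and
complete deletion could empty them) and the Jukes–Cantor correction
d = −(3/4)·ln(1 − 4p/3), the default for tree building; saturated pairs
(p ≥ 0.75) inside bootstrap replicates fall back to p-distance and are
logged rather than aborting the replicate.

Neighbor joining follows Saitou–Nei exactly: join the pair minimizing
Q(i,j) = (n−2)d(i,j) − Σ_k d(i,k) − Σ_k d(j,k), ties broken by the smallest
node-index pair; branch lengths b(i,u) = d(i,j)/2 + [Σd(i,·) − Σd(j,·)] /
(2(n−2)); update d(u,k) = (d(i,k)+d(j,k)−d(i,j))/2. A negative branch is
clamped to zero with the deficit shifted to its sibling so the joined pair's
path length is preserved. The tree ends in a trifurcating root (unrooted
convention). NJ is exact on additive matrices, which the tests exploit:
path-length matrices from random trees must be reproduced to 1e−9.

Bootstrap: 100 pseudo-replicates by default; replicate r resamples
alignment columns with replacement using a generator seeded `seed + r`
(a documented derivation, so one integer reproduces the whole analysis).
Supports are attached to the internal edges of the full-data tree by
bipartition matching — no majority-rule consensus tree is built. Trees are
dendropy objects; Newick serialization puts supports on internal-node
labels and branch lengths at six decimals.

## Synthetic data generator

The generator emulates Repbase-style consensus *hAT* elements with known
truth. Layout per element:
`[TSD][5′ TIR][filler][ORF][filler][revcomp TIR][TSD]` with the TIR sampled
from `[T/C]AGNGNNG` (default arm length 12 bp), a fixed-length TSD
(default 6 bp, valid range 4–8) repeated verbatim on both flanks, and
element length 3000 bp. A fraction of elements (default 0.5) carry an ORF
encoding an invented 750-aa transposase whose five signature residues sit
at the AC-numbered positions; of those, 20% get one signature codon mutated
to alanine (`knocked_out`) and 30% spawn an `-N1` internal-deletion
derivative that removes 40–70% of the ORF, always spanning the third
catalytic site, while keeping both TIRs.

Two deliberate non-uniformities keep planted truth exact:

* **Stop cassettes in filler.** Filler is uniform over {A,C,G,T} except
  that the self-reverse-complementary 12-mer `TTAATTAATTAA` (stop codons in
  all six frames) is spliced in every ~250 bp, and the planted ORF is
  bracketed by in-frame stops. Plain uniform filler of this length would
  contain, in expectation, about two spurious stop-free runs above 100 aa
  per element, which would blur the `absent`/`truncated` distinction for
  elements that truly carry no transposase.
* **Purifying selection on intact ORFs.** Divergence applies independent
  per-site substitutions at `per_site_mutation_rate`, but inside the ORF of
  an element whose signature is intact only synonymous changes are kept.
  At a 5% per-site rate an unconstrained 2250-nt ORF would accumulate ~5
  premature stops and lose catalytic residues — the element would genuinely
  no longer encode an active transposase and its frozen "autonomous" label
  would be wrong. The constraint mirrors the biology (families observed
  with intact transposases are those whose active copies were conserved)
  and keeps truth labels meaningful; knocked-out, deleted, and
  transposase-free elements evolve neutrally everywhere.

Tree-structured radiation (`radiate_family`, `mutate_and_radiate`) diverges
a root sequence along a random unrooted binary topology with per-branch
substitution probabilities, returning leaves plus the generating tree;
`three_clade_alignment` builds the three-group, long-internal-branch
radiation used as a scaled stand-in for deep (between-kingdom) splits.

What the generator does **not** emulate: host-genome flanks and real
insertion landscapes, indels outside the single deletion operator (so TIR
truth coordinates stay exact), base-composition bias, horizontal transfer,
and real transposase sequence diversity (the reference is invented). A
perfect score on synthetic data therefore demonstrates the pipeline's
internal logic, not recall on real Repbase holdings.

## Numerical and procedural choices

* Coordinates are 0-based, half-open, forward strand throughout.
* The autonomous percentage is floored (not rounded) to one decimal:
  35/276 → 12.6%.
* TIR-pair ordering, NJ tie-breaks, bootstrap sub-seeding, and dataset
  generation are all deterministic given one integer seed; `run_all` dumps
  its effective configuration and a MANIFEST with content hashes.
* Alignment traceback ties are resolved by the aligner's deterministic
  first-reported path; scores are optimal regardless.
* Problem sizes in the shipped study: ~200-element families, 10-kb
  three-clade alignments with 100 bootstrap replicates, 100 additive
  matrices of 4–12 leaves — sizes at which every oracle comparison runs
  exhaustively while the whole suite stays interactive.

## Known limitations

* `find_tirs` reports all qualifying pairs; on long inputs with permissive
  budgets the pair list (not the best pair) can be large.
* The TIR consensus bracket orientation follows observed frequency, so a
  near-50/50 column's printed order depends on the sample.
* Six-frame ORF calling cannot recover transposases split by frameshifts
  into fragments below `min_aa`.
* The Hermes/AC numbering presets are independent; the package does not
  derive one from the other via structural alignment.
* NJ is quadratic per join (cubic total) in pure Python — adequate for
  hundreds of taxa, not thousands.
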