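# Methods

This note documents the models, rules and numerical choices behind
`stressnet`, and what its synthetic validation does and does not show.

## Homology model

The search emulates a protein-query versus translated-nucleotide
(TBLASTN-style) scan. Each unigene is translated in all six frames
(standard genetic code; codons containing `N` become `X`, stops become
`*`, trailing partial codons are dropped). The query is aligned to every
frame with a local affine-gap Smith–Waterman aligner (Biopython's
`PairwiseAligner` in local mode) and only the best-scoring frame per
query–subject pair is retained: hits are single-interval by design, no
multi-HSP stitching, which keeps the coverage definition unambiguous.
Ties between frames go to the first in the order +1, +2, +3, −1, −2, −3.

Scoring defaults are BLOSUM62 with gap open 11 and extend 1 (a gap of
length L costs 11 + L). Stop codons in a translated frame are given a
score of −10⁴ against every residue, so no local alignment extends
through a stop — mirroring how a translated search treats interrupted
reading frames. Statistical significance uses the Karlin–Altschul form
E = K·m·n·e^(−λS) with the standard gapped-BLOSUM62 constants λ = 0.267,
K = 0.041; m is the query length in residues and n the total nucleotide
length of the subject database. These constants are configuration, not
physics: the upstream tool is emulated, not re-derived, and no
composition-based score adjustment is attempted.

A hit qualifies only if all three criteria hold as strict inequalities:
E-value < 1.0×10⁻⁶, identity > 50%, query coverage > 80%. Identity is
exact matches over alignment columns (gaps included); coverage is the
aligned query span over the query length, computed on the protein side.
Equality at any threshold rejects. Precomputed hits in BLAST outfmt 6
can replace the built-in aligner; since outfmt 6 carries no frame
column, the frame is recomputed from subject coordinates when subject
lengths are available, otherwise only the strand sign is recorded
(nothing downstream consumes the frame).

## Interolog transfer

Every qualifying hit contributes: if reference interaction (p, q) exists
in any species and p, q have homologous unigenes u ≠ v, the edge (u, v)
is created. All qualifying hits per unigene are used — the union
reading of the transfer rule — because restricting to best hits silently
drops support; a `best_hit_per_species` mode exists for sensitivity
analysis. Self-loops are discarded (an interaction needs two distinct
unigenes). Evidence records (species, protein_a, protein_b) are
deduplicated, merged across species and stored per edge. Hits whose
query is in no reference network are skipped with a logged warning
rather than an error, since partial id mismatches are routine with real
database inputs.

## Topology

Components are ordered by size descending, ties by smallest node id, so
output is reproducible. The degree distribution P(k) = N(k)/N is
computed within the induced subgraph of the node set under study
(typically the giant component); isolated unigenes are not part of the
network and never enter N. The scale-free fit is unweighted ordinary
least squares on (log₁₀ k, log₁₀ P(k)) over entries with k ≥ 1 and
P(k) > 0 — one point per distinct degree — matching how a quoted
"P(k) = a·k^(−γ)" fit is conventionally read off a log-log plot. r² is
reported from the same regression; a perfectly flat distribution is
defined to have r² = 1 (zero residual, zero variance). A discrete
maximum-likelihood alternative (Clauset-style continuous approximation,
coefficient from the Hurwitz-zeta normalisation) is available as
`method="mle"` but is not the default, because the OLS fit is the
quantity the package's outputs are compared against.

## Prediction rule

"More than four known genes, with no homology among them" is
operationalised as:

* **Support**: for unigene u and category c, a known gene g supports u
  when at least one unigene homologous to g is a direct neighbour of u.
  Direct neighbours only — no second-degree expansion.
* **Redundancy**: supporting genes are collapsed into single-linkage
  clusters under pairwise protein–protein homology (same E-value and
  identity thresholds as elsewhere; coverage is not required for
  redundancy detection, since a shared domain already makes two
  supporters non-independent). Default mode counts distinct clusters
  and flags u when the count is strictly greater than `min_support`
  (default 4). A `strict-disqualify` mode instead rejects any candidate
  whose supports contain a homologous pair, since the phrasing of the
  rule admits both readings.
* **Novelty**: u is never flagged for a category whose known genes map
  onto u itself; cross-category exclusion is deliberately not applied —
  a drought candidate may well be a known cold gene's homolog.

`min_support` is exposed because "over four" is a chosen operating
point, not a law; raising it can only shrink the prediction set
(anti-monotonicity, property-tested).

## Synthetic data: what it emulates

The generator stands in for three real inputs: reference PPI networks
with proteomes (a curated interaction database), a unigene library (a
de-novo assembly), and categorised known stress genes (a curated stress
transcription-factor list).

* **Networks** grow by seeded preferential attachment: seed graph = one
  edge; each new node attaches `edges_per_new_node` (default 3 in the
  pipeline) distinct degree-weighted targets, giving 1 + m(n − 2) edges,
  connectedness by construction and a power-law degree tail. Any
  scale-free growth model would do; this one is fixed and seeded for
  reproducibility.
* **Proteomes** are i.i.d. uniform sequences over the 20 residues,
  lengths uniform on [120, 240] by default — long enough that implanted
  homologies are unambiguous and random pairs score far below the
  E-value threshold. An optional "ortholog species" clones the first
  network's topology and point-mutates each protein to 90% identity, so
  transferred edges genuinely accumulate two-species evidence.
* **Unigenes** are back-translations (uniform synonymous codon choice,
  seeded) of point-mutated source proteins. Substitutions only — no
  indels — so coverage stays 100% and identity is the single controlled
  variable; the first and last two residues are never mutated so local
  alignments keep full span. The realised identity is exact, recorded in
  the truth, and within ±3 percentage points of the target for any
  protein longer than ~34 residues. Frames, including reverse-complement
  placements, vary across records via small random pads. Decoys are
  uniform random nucleotide sequences.
* **Known-gene sets** designate network nodes' proteins as known genes
  so that chosen candidate nodes have `support_size` (default 5) known
  neighbours, negative controls exactly `support_size − 1`, and a
  redundant-pair control `min_support` distinct supports plus one extra
  known gene homologous to an existing support (raw gene count above
  threshold, cluster count at it). Independent random known genes are
  pairwise non-homologous with overwhelming probability, so the
  homologous pair is implanted explicitly. Controls are placed before
  candidates, while the category has no known genes yet, which makes
  their counts exact; later designations are constrained to stay clear
  of control neighbourhoods. Categories are independent: a node may be
  a candidate in one category and a control in another, exactly as real
  multi-stress genes behave.

The recorded ground truth for "which unigenes should be flagged" is not
the list of deliberately implanted nodes: it is recomputed by exhaustive
evaluation of the rule on the reference graph restricted to nodes that
received unigenes. Overlapping known-gene neighbourhoods can create
legitimate extra satisfiers, and those belong in the truth; end-to-end
precision/recall is therefore a real statement about the pipeline, not
about the construction.

**What passing does not show.** The generator has no paralogy, no domain
shuffling, no indels, no assembly artifacts (chimeras, fragmentation),
no expression-dependent coverage, and its random proteomes lack the
compositional biases real sequences have. Perfect synthetic recovery
therefore validates the machinery — thresholds applied as specified,
transfer and rule logic exact, determinism — not the biological error
rate of interolog transfer on real data, which is known to be dominated
by homology-detection noise and database quality.

## Problem sizes and runtime

Default pipeline runs use 50-node reference networks (two species after
the ortholog clone), ~100 unigenes + 10 decoys and 12 known genes per
category: a few tens of thousands of alignment scores, well under a
minute end to end on one CPU, which is ample to exercise every code
path with non-trivial structure. The topology demonstration uses a
2000-node, m = 2 preferential-attachment network. Oracle-equivalence
checks run on 100 random instances each (≤ 30 reference nodes, ≤ 40
unigenes for transfer; ≤ 40-node networks for the rule), and the
alignment oracle on 200 random pairs of length ≤ 12, where exhaustive
dynamic programming is cheap.

## Numerical and edge-case choices

* Thresholds are strict inequalities exactly as written; boundary values
  (identity 50.0, coverage 80.0, E-value 1.0×10⁻⁶) are rejected and
  pinned by tests.
* Alignment tie-breaking is the aligner's deterministic traceback; frame
  ties prefer forward frames in order. Scores, not identities, are the
  oracle-checked quantity: co-optimal alignments may differ in identity
  by a column, which the ±3-point synthetic tolerance absorbs.
* Local alignments with no positive-scoring cell return "no alignment"
  rather than a zero-score empty interval.
* All randomness flows from one config seed through named substreams
  (network / proteome / unigenes / stress genes / orthologs), so adding
  a stage never perturbs another stage's draws. Identical config + seed
  gives byte-identical outputs; files are written with sorted keys and
  sorted records, and no timestamps.
* Empty degree distributions, components of size < 2, fits with fewer
  than two usable points, categories with zero implanted candidates and
  all-decoy unigene sets are all defined (error or empty result, never
  silence).

## Known limitations

* The aligner is a faithful Smith–Waterman, not a seeded heuristic: it
  is exact but O(mn) per pair, so it is sized for validation and small
  studies; production-scale searches should feed outfmt 6 files from a
  dedicated search tool through `--hits-file`.
* E-values use fixed Karlin–Altschul constants; they are not re-estimated
  per scoring system or composition-adjusted.
* Single-interval hits underestimate coverage for genuinely split
  alignments (long introns would need multi-HSP logic; transcriptome
  subjects rarely do).
* The redundancy clustering is single-linkage: one promiscuous domain
  can chain otherwise unrelated supporters into one cluster, which is
  conservative for prediction (fewer clusters, fewer flags).
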