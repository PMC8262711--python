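# Methods

## Coordinate and data model

All positional annotations use 1-based coordinates, inclusive on both
ends (the UniProt convention used by every upstream resource the formats
are modelled on). A protein record carries the sequence that defines the
coordinate frame; every loader validates spans against that frame at the
boundary, and reference-residue mismatches (variant `ref` letter, PTM
residue) are hard errors rather than warnings — a silently shifted
coordinate would corrupt every downstream overlap computation. PPI pairs
are stored in canonical lexicographic order, so (A,B) and (B,A) evidence
rows merge; evidence identity for deduplication is the
(source id, method) tuple, with the throughput class treated as display
metadata. Homodimeric interactions (A,A) are permitted.

## Domain ingestion

Pfam-style hit tables are filtered at expectation value ≤ 0.001; the
boundary is inclusive, since the upstream convention states a cut-off
without boundary semantics and excluding exact-boundary hits would be
arbitrary. Overlapping domain hits are kept as-is: no clan-level or
overlap resolution is applied before storage.

## Motif scanning

Motif classes are regular expressions over the amino-acid alphabet,
matched case-insensitively against the upper-cased sequence. Scanning
restarts at every residue, so mutually overlapping occurrences are all
reported — motif occurrences are positional features, and adjacent or
overlapping sites occur in real substrates (e.g. tandem kinase
recognition sites). Where a pattern admits several match lengths at one
start, the leftmost-longest match is recorded: Python's regex engine is
leftmost-*preferred*, so the implementation probes longer end positions
explicitly, guaranteeing deterministic output independent of alternation
order inside the pattern. `^` and `$` anchor to the full sequence; they
are honoured when they appear as the outermost first/last characters of
the pattern (anchors buried inside alternations are out of scope).
Zero-length matches are discarded — they carry no positional feature.
Patterns from different catalog sources with the same shape are kept as
distinct classes.

The display toggles are subtractive only: `confirmed_only` keeps curated
(annotated) instances, and `exclude_in_domains` drops instances *fully
contained* within a same-protein domain hit. Containment rather than
overlap is the criterion because a motif straddling a domain boundary
still lies partly in disordered sequence.

## Domain–motif admissibility rules

A candidate (motif instance, domain hit) pair is admissible iff a curated
rule exists for the (motif class, domain family) pair and every populated
restriction passes; the decision decomposes over the individual checks,
so relaxing any failing restriction can only move a pair toward
admissibility. Taxon matching uses a flat lineage-tag set per supported
organism (e.g. human → {Eukaryota, …, Mammalia}); a rule's allowed-taxa
set passes if it intersects the organism's tags. Gene restrictions are
exact, case-insensitive symbol matches. Required co-motifs are satisfied
by instances of either status in the motif-side protein (a stricter
annotated-only mode is available); only motif-side co-motifs are
supported. The phosphosite requirement counts only
`ptm_type = phosphorylation` sites, at positions within the motif span
inclusive of both endpoints. Structure-derived (3did-style) DMIs bypass
the rule table entirely — they are evidence-based, and the curation
effort behind the table is specific to the regex-derived catalog.

## Domain–domain association scoring

Scoring follows the classical over-representation idea for sequence
signatures in interacting proteins. Given the non-redundant interaction
set (unique unordered pairs with ≥ 2 distinct evidence records), with I
pairs over a universe of N distinct proteins:

* I_ab counts interacting pairs exhibiting (a, b) — presence on opposite
  sides, counted at most once per interaction regardless of copy number;
  a homodimer (P,P) exhibits (a,b) when P contains both.
* E_ab = I · (2 − δ_ab) · (n_a/N) · (n_b/N). The (2 − δ_ab) factor
  counts the two orientations in which a heterotypic pair can decorate an
  unordered interaction; n_x counts proteins *within the interaction
  universe* containing x (the universe, not a whole proteome, is the
  population actually sampled by the interaction set).
* score = ln(I_ab / E_ab); the logarithm base is configurable and
  defaults to natural, as no published base is fixed for this statistic.
* Unobserved pairs get the sentinel −5, chosen to sit below any computed
  log-odds of interest; they are scored only on demand (the full
  cross-product of an interactome-scale domain vocabulary is never
  materialized).

Enrichment — the condition for drawing an inferred-DDI edge — is the
conjunction score ≥ 2 ∧ I_ab ≥ 4 ∧ n_a ≥ 4 ∧ n_b ≥ 4; the count minima
screen out high ratios built on a handful of proteins. The observed
frequency I_ab / I is reported as an empirical P-value (0 for unobserved
pairs, which carry no edge). No multiple-testing correction is applied
across pairs, and scoring is done per organism. For network edges, the
DMI analogue of this P-value is computed over the PPI set supplied to the
builder: the fraction of its pairs in which one partner carries the motif
class and the other the domain family.

## Network assembly

One node per retained protein; one node per retained feature (domain,
motif, PTM, curated feature, variant), each carrying its span and
attributes. Edge identity is (etype, endpoint pair): evidence for the
same pair within a layer merges rather than creating parallel edges.
Layer toggles are strictly subtractive, and the union of all layers
equals the full build. Exports (Cytoscape element JSON and GraphML via
networkx) use stable node and edge ordering, so identical inputs yield
byte-identical documents; floats in the interaction table are written in
round-trip precision, making write → read lossless for all edge
attributes.

Display rules: cancer variants require a recurrence of ≥ 5 samples
(other variant categories pass untouched); protein sets above the
20-protein cap are truncated *in input order* — the query order is the
only ordering the user controls — with a warning, and the interaction
table can be built uncapped. Inferred-DDI edges are drawn only for
enriched pairs at or above the configurable minimum score (default 2);
non-enriched scored pairs remain available in the score table. Predicted
3D-interface edges carry unit weight with the Z-score as an attribute,
keeping edge weights non-negative.

## Synthetic data generator

The generator emulates the integrated inputs of a mechanistic-network
study at desk scale: uniform-random sequences over the 20-letter
alphabet, non-overlapping domain placements (one domain per sequence
block), interaction sets with exact planted domain-pair co-occurrence
over a uniform background, and variants whose reference letters always
match the sequence, with heavy-tailed (Zipf, exponent 1.7) cancer
recurrence counts populating both sides of the 5-sample display filter.
All randomness flows from one integer seed per spec; derived streams use
fixed offsets so proteome, interactions and variants are independently
reproducible.

Planted enrichment is exact by construction: target co-occurrence pairs
are chosen among carrier proteins (covering every carrier before random
extras, which pins the per-domain universe counts), and the background
sample excludes any pair that would exhibit a planted domain pair. Two
reference regimes are provided: `recovery_spec` (80 proteins, 70
interactions, 5 carriers per planted domain, target co-occurrence 14)
places the planted log-odds near 2.9 — comfortably above the enrichment
threshold for any realistic interaction-universe size — and
`sentinel_spec` (20 proteins, 30 interactions, zero target) produces a
carrier-bearing pair that never co-occurs. The permuted-label null
reassigns whole per-protein domain architectures to shuffled proteins,
preserving the domain-count spectrum while destroying any association
with the interaction structure.

What the generator does *not* emulate: realistic interactome degree
distributions, domain-family abundance spectra, sequence composition
biases, disordered-region structure, or correlated evidence between
databases. Passing tests on this data therefore demonstrate correctness
of the counting, scoring, filtering and assembly logic under known ground
truth — not calibration of the enrichment procedure on real
interactomes, where degree heterogeneity and annotation bias matter.

## Numerical and degenerate-input choices

Empty inputs yield empty outputs throughout (empty FASTA → empty record
list, empty PPI set → empty score list, empty network → header-only
table and valid empty export documents). A zero-size interaction
universe makes the empirical P-value undefined and raises. Protein-count
lookups for domains absent from the universe raise a KeyError rather
than returning a fabricated zero frequency. Sorting keys (class id,
start, end for motifs; canonical pairs for scores; node/edge ids for
exports) break all ties deterministically.

## Known limitations

* Regex anchors inside groups or alternations are not given
  full-sequence anchor semantics.
* The 3D-prediction layer consumes a precomputed table; no structure
  scoring is performed.
* Restriction rules cannot demand a co-motif in the domain-side protein.
* The interactor-expansion step only ranks partners present in the
  supplied PPI table; partners without sequence records are reported but
  not added to the network.
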