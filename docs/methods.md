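# Methods

## The benchmarking model

The package treats read-classification benchmarking as a four-stage
pipeline over a shared taxonomy: (1) simulate a community whose per-read
taxonomy is known by construction; (2) obtain a classification of those
reads; (3) compare assignment and truth rank by rank; (4) compare
aggregate abundance profiles. The taxonomy is a rooted tree in the NCBI
taxdump dialect with an *open* rank vocabulary: nodes may carry any rank
string, and rank-aware queries (`rank_ancestor`, `lineage`) simply report
absence when no node of the queried rank lies on a taxon's root path.
That absence is the modelling core, not an edge case: reference
collections built from metagenome-assembled genomes routinely contain
species with no genus or family node, and every headline artefact of such
collections (depressed per-rank classification rates, "truth unknown"
reads, spuriously disjoint collection overlaps) follows mechanically from
it.

Canonical ranks default to phylum/class/order/family/genus/species.
Kingdom and superkingdom are excluded because all per-rank outputs run
phylum→species; the list is a constructor argument for users who want
otherwise. The root is the unique node that is its own parent.

## Synthetic communities

`generate_taxonomy` builds strata whose sizes scale as powers of the
species count (for 100 species: 4 phyla, 7 classes, 13 orders, 25
families, 50 genera), each node parented uniformly at random into the
stratum above, plus one below-species "strain" child per species so that
over-resolved assignments have a real node to land on. Per species,
independently, the genus node is dropped with probability
`missing_genus_frac` (the species is re-parented to its family, or order
if the family is also dropped) and the family with
`missing_family_frac`; a species that keeps its genus but loses its
family gets a fresh genus node hanging directly off the order, as
deposited MAG lineages sometimes do. Independence makes both fractions
separately recoverable from a completeness report. `informal_species_frac`
of species receive placeholder names ("uncultured X bacterium RUG…",
"X bacterium", "uncultured Y sp.") that the configurable
informal-name predicate recognises; the predicate flags whole-word
occurrences of uncultured/candidate/candidatus, trailing
"bacterium"/"archaeon" with optional strain tag, and "sp." placeholders.
Two presets encode the lineage-completeness profiles of a cultured
isolate collection (≈2% missing family, ≈16% missing genus, formal names)
and a rumen MAG collection (≈35% / ≈78% missing, ≈87% informal names).

Genomes are i.i.d. uniform A/C/G/T with lengths uniform in ±20% of
`mean_genome_length`. Reads are paired-end: abundances are drawn per
genome (`exponential` = i.i.d. Exp(1) normalised to sum 1 — the
conventional reading of an "exponential abundance distribution", since
simulators differ in parameterisation; also `lognormal` and `uniform`),
pair counts are multinomial, fragments are uniform along the genome with
Gaussian insert sizes clipped to [read length, genome length], mate 2 is
the reverse-complement end of the fragment, and substitution errors are
applied per base at `substitution_rate` (default 0.001, the order of
Illumina substitution error). The error model is substitution-only — no
indels, no chimeras, no quality-dependent profiles; qualities are written
as constant 'I' and never consumed. This is sufficient to stress an exact
k-mer classifier (any substitution kills k overlapping k-mers) but it
does **not** emulate a real sequencer: passing tests demonstrate the
bookkeeping and the lineage mechanics, not robustness to realistic error
spectra, GC bias, or shared sequence between related genomes (genomes
here are unrelated random strings, so inter-genome k-mer collisions are
vanishingly rare at k = 21).

`simulate_classifier_output` bypasses the classifier entirely and
produces a classification table with known error structure, for
calibrating the evaluator: per read, mutually exclusive outcomes —
unclassified; misassignment at rank *r* (a uniform random other species
whose ancestor at *r* exists and differs from the truth's — chosen so the
injected rate returns as exactly the incorrect-at-*r* percentage);
under-resolution (a uniform random strict ancestor, root excluded, which
returns as unclassified-at-this-level at species); over-resolution (a
below-species child). All generators are pure functions of (config,
seed).

## The classifier

`build_index` stores every canonical k-mer (lexicographic minimum of the
k-mer and its reverse complement; k odd to exclude palindromes, default
21) of every genome, mapping each to the LCA of all genomes containing
it. `classify_read` pools hit counts over both mates and scores
Kraken-style: score(t) = Σ hits over t's root path, candidates are the
taxa with at least one *direct* hit, the winner is the candidate with
maximal score, and ties — which can only occur between taxa on different
branches, since a deeper taxon on the same path strictly dominates —
resolve to the LCA of the tied taxa. The candidate rule (direct hits
only) and the tie-break are a documented dialect of the k-mer/LCA family,
not a claim of bit-compatibility with any external tool; the test suite
pins them against an independent all-nodes enumeration oracle. Exact
k-mers rather than minimizers keep that oracle tractable and make the
self-classification soundness property provable: with an index built from
exactly the source genomes and error-free reads, every k-mer hit lies on
the truth taxon's root path, so every assignment does too, and no read
can score "incorrect" at any rank.

## Evaluation semantics

The five-way status cascade is evaluated in a fixed order: truth lineage
lacks the rank ⇒ `truth_unknown`; no assignment ⇒
`unclassified_at_any_level`; assigned lineage lacks the rank ⇒
`unclassified_at_this_level`; ancestors equal ⇒ `correct`; else
`incorrect`. Two deliberate decisions: the truth side takes precedence
over unclassified (a read without a truth label cannot be scored
regardless of the classifier, so correctness is undefined first), and a
below-species assignment projects up through `rank_ancestor` (a strain
assignment is correct at species if the species ancestors agree). All
status percentages use the total simulated read count as denominator, so
the five categories sum to 100 exactly at every rank. Per-rank
*classification rate* uses different semantics on purpose: a read counts
as classified at rank *r* iff its assigned lineage has a label at *r*,
regardless of truth — a genus-level assignment is therefore *unclassified
at species level*. Reads present in the truth but absent from the
classification (or vice versa) are a hard error, not silent
unclassifieds: with simulated data the truth is total by construction,
so a mismatch is a harness bug.

## Abundance and concordance

Truth profiles are normalised by all simulated reads, classified profiles
by reads with any classification (a per-rank denominator is available as
an option); reads whose taxon lacks the rank label contribute to the
denominator but to no entry. Concordance pairs taxa with nonzero percent
in both profiles on log10 scale — zero-valued taxa are excluded because
they have no position on a log scatter (an optional pseudo-count offset
is available, default off) — and reports two statistics side by side,
because "deviation from ground truth" and "fit to a regression" are
different questions: R²(fit), the OLS coefficient of determination, and
R²(y=x) = 1 − Σ(y−x)²/Σ(y−ȳ)². A classified profile that under-calls
every taxon by the same factor keeps R²(fit) = 1 while R²(y=x) falls;
both equal 1 iff the shared profiles coincide. R²(fit) is the headline
value. Fewer than 3 shared taxa, or zero truth variance, yields an
explicit insufficient-data flag rather than numbers.

## Numerical and format choices

Percentages are plain double-precision ratios ×100; the sum-to-100
invariant holds to 1e-9 (tested) because the five counts partition the
read set exactly. The taxdump writer emits the NCBI field layout
("\t|\t" separators, "\t|" terminator, first 3/4 columns significant);
nodes without a scientific name load with the placeholder `taxid:<id>`.
Kraken output column 5 is a run-length "taxid:count" encoding with a
"|:|" mate separator, preserved opaquely; readers accept 3-column files.
Report rank codes follow the usual single letters with `<code><n>` for
uncoded ranks below a coded ancestor. Degenerate classifier inputs
(reads shorter than k, non-ACGT symbols) yield unclassified / skipped
k-mers rather than errors.

## Problem sizes

The positive-control configuration used by the acceptance script and the
heavier tests is 100 species × ~20 kb genomes × 50,000 read pairs at
k = 21 (~2 M distinct k-mers). Genome length is the package's scaling
choice: classification behaviour under a fully representative index is
length-independent (every read k-mer is indexed regardless), while index
size and runtime scale linearly, so 20 kb keeps a full run in minutes on
one CPU. Calibration experiments use 20,000 reads × 10 seeds; oracle
equivalence runs ≥500 random reads against 5-genome indices and ≥1000
rank queries on random 100-node trees.

## Known limitations

Random unrelated genomes cannot exhibit the database-driven confusion
(conserved regions, contamination, shared ancestry) that produces false
positives against real references; here false positives arise only from
injected misassignment. The classifier has no minimizer down-sampling,
no hash capping, and no confidence scoring, so database-size effects are
out of reach. Merged/deleted taxid remapping is not supported. The
informal-name predicate is a heuristic tuned to MAG-style deposit names;
it will misclassify exotic formal names containing its trigger tokens.
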