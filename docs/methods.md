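# Methods

This note documents the models and procedures implemented in
`viromekit`, the defaults and why they were chosen, the numerical
conventions that pin down otherwise ambiguous behavior, and what the
synthetic fixtures do and do not demonstrate about real data.

## Coordinates and formats

Internally every interval is 0-based half-open. The two surfaces that
use 1-based inclusive conventions — 12-column tabular hit files and
GenBank flat files — are converted in `viromekit.io` and nowhere else,
so off-by-one risk is concentrated in one module. A subject interval
with `s_start > s_end` encodes a minus-strand alignment, as search
tools emit it; it is normalized internally to (min, max, strand).
Gzip-compressed inputs are detected by magic bytes and accepted
transparently. Hit tables with more than 12 columns are read with a
warning (extra columns ignored); fewer than 12 is an error with the
line number.

## Circular contigs

A contig is called circular when a suffix of the sequence equals a
prefix, with overlap length at least `k` (default 10) and at most half
the sequence; the longest qualifying overlap is removed, so
`trimmed_length = original − overlap`. k = 10 was chosen because a
random 10-mer coincidence between two ends has probability ≈ 4⁻¹⁰ ≈
10⁻⁶ per contig, a negligible false-positive rate at desk scale, while
real assembler-produced terminal repeats are at least that long. The
whole detection step can be disabled (`--no-detect-circular`) for
assemblers that already collapse end redundancy, in which case every
contig is treated as linear. Sequences shorter than 2k + 1 are returned
linear with a warning rather than an error.

Detection is idempotent: re-running it on a trimmed circular contig
finds no further overlap at the same k. (A pathological periodic
sequence — e.g. a perfect tandem repeat — can trigger a second
trimming round; real and simulated genomes do not.)

## Gene calling

The built-in ORF finder is intentionally naive: it scans all six frames
for spans start-codon…stop-codon (starts ATG/GTG/TTG, stops
TAA/TAG/TGA, bacterial translation table, alternative starts rendered
as M), reporting for each stop the ORF beginning at the first start
codon after the previous in-frame stop, with a default minimum span of
120 nt (stop codon included). It is a stand-in adequate for synthetic
fixtures and quick looks; for production data `import_orfs` adapts an
external predictor's 1-based coordinate table (with partial-gene
flags) and derives the translations.

Genes spanning the origin of a circular contig are recovered by
scanning the trimmed sequence with its first min(1000, L) nucleotides
appended, then reducing coordinates modulo L; ORFs whose reduced start
and strand coincide with one already reported are duplicates from the
appended copy and are dropped. A wrapping ORF has `start > end` and its
nucleotides are `residues[start:] + residues[:end]`. The 1000-nt
duplication bounds the length of a junction gene that can be recovered;
genes longer than 1 kb across the origin are missed, matching the
behavior of the duplication trick itself.

Truncation flags (`truncated_start` / `truncated_end`) mark ORFs that
touch a linear contig's edge without the codon that should anchor that
side (start codon at the 5′ end, stop codon at the 3′ end). Circular
contigs have no edges and are never flagged; the absence of any
truncated gene on a linear contig is the signal that it may be a
complete genome.

## Affiliation

Best hit = highest bit-score among hits passing the e-value screen,
with ties broken by lower e-value, then higher percent identity, then
lexicographic subject id — a total order, so results are deterministic.
The e-value threshold (default 10⁻³) is applied *inclusively* (≤)
everywhere; one convention avoids boundary drift between modules.

Read-level compositions: raw mode weights each reference by its share
of best hits; length-normalized mode reweights by 1/genome-length
(w_g ∝ n_g / L_g) and renormalizes over references, the standard
correction for longer genomes recruiting more reads at equal
abundance. The full e-value-weighted multi-hit normalization of
dedicated abundance estimators is out of scope. Weights plus the
unassigned fraction always sum to 1 (tolerance 10⁻⁹, enforced by the
type).

Contig LCA: among the contig's affiliated genes, the five with the
highest best-hit bit-scores are selected (strongest evidence first —
the selection rule is otherwise unconstrained, so this deterministic
choice is pinned) and the call is the longest common prefix of their
lineages. Contig best-hit mode is defined as the affiliation of the
single maximum-bit-score gene hit. A contig with no affiliated gene
gets no call and counts as unassigned.

## k-mer comparison

Counts are pooled over all of a virome's sequences (not averaged per
sequence), overlapping windows, forward strand only, windows containing
N skipped. "Bias" is the observed/expected ratio under a zero-order
Markov (mononucleotide product) null — the standard word-usage
deviation; 1 means no bias, and a zero expectation defines bias 0. A
strand-collapsed option exists but is off by default: forward-only is
reproducible and stated. Distances are plain euclidean between profile
vectors. Hierarchical clustering uses average linkage; NMDS embeds in
two dimensions with 20 random restarts (seed-controlled), keeping the
best solution and reporting normalized stress.

At 1 Mb of uniform random sequence the 256 tetranucleotide bias entries
concentrate near 1 with a relative spread of ~1.6 % each, so the
maximum |bias − 1| over all words is typically ≈ 0.05 — profiles from
megabase-scale datasets are statistically tight, but individual-word
deviations of a few percent are sampling noise, not signal.

## Recruitment

A read is recruited by the genome holding its *best* hit only; a weaker
hit to the plotted genome does not recruit. Position is the floor
midpoint of the strand-normalized subject interval — the plotted
quantity is "where on the genome", and a midpoint puts each read in
exactly one 500-nt bin. Bin i covers positions [500i + 1, 500(i+1)];
the last bin covers the remainder; counts are conserved per virome. A
convenience filter keeps viromes with more than 200 recruited reads
(strictly greater), the conventional cutoff for a readable stacked
plot; it is a parameter, not hard-coded.

## Protein clustering

"Similarity" for the 75/90/98 % tiers is pinned as global-alignment
identity = identities / alignment columns (gaps in the denominator),
computed with a fixed scoring scheme (match 2, mismatch −1, gap open
−2, extend −0.5) and the first optimal alignment, so identity is a
deterministic function of the pair. Because identity can never exceed
min(len)/max(len), pairs whose length ratio is below the threshold are
skipped without aligning. Greedy centroid clustering processes proteins
longest-first (ties by id) and joins the first centroid at or above
threshold — order-dependent, like the tools it mirrors, but
deterministic given the input. Note the membership criterion
(member-to-centroid identity ≥ t) is the guarantee; greedy clusters
need not equal transitive-closure clusters.

Domain-seeded clustering takes the longest remaining protein as seed,
absorbs everything the injected `recruiter` returns, removes them, and
repeats — always a partition, singletons allowed. In production the
recruiter wraps an external iterative profile search; re-implementing
profile HMMs is out of scope, so tests use a pure alignment-identity
recruiter (≥ 0.5). Cluster domain labels aggregate member hits with
score ≥ 30 bits, ordered by total member score.

Rarefaction draws seeded subsamples without replacement and counts
distinct clusters touched; means are monotone in sample size and reach
the total cluster count at full depth (sd 0 there, since the subsample
is the whole set).

## Networks

The margin rule is multiplicative and inclusive: keep hits with
bit-score ≥ (1 − margin) × best, margin 0.10, after the e-value screen.
The multiplicative reading is the natural one for a relative margin;
inclusivity is pinned to avoid float-boundary flakiness. The best hit
is always retained. Aggregated edges count *distinct query ORFs* with
retained hits between a node pair; an ORF hitting its own contig is
dropped. Reference proteins resolve to their genome through an explicit
protein-to-genome table; an unresolvable subject raises rather than
being silently dropped. Reference nodes carry their family-level taxon
as the `taxonomy` attribute for display coloring. Shared-gene filtering
applies only to aggregated networks (aggregate first); a no-op filter
returns the network unchanged, and any real filtering removes orphaned
nodes.

## Synthetic fixtures

The generators exist to give every downstream rule a closed-form
oracle:

* substitutions only (no indels), so percent identity is exactly
  100 × (1 − mutations/length);
* bit-score surrogate 2 × matched bases — arbitrary but monotone in
  match count, which is all that ordering, tie-breaking and the margin
  rule depend on; e-value 10^(−bit/10) capped to [10⁻¹⁸⁰, 10];
* abundance profiles are exact counts, not multinomial draws;
* decoy hits, when enabled, are drawn strictly below the true hit's
  bit-score, so best-hit recovery of the planted source is guaranteed
  at any decoy rate;
* gene-bearing genomes are cassettes of planted genes separated by
  stop-codon spacers (leading spacer TGA-run, internal/trailing
  TAA-runs, everything in frame 0), so the naive ORF finder recovers
  each planted gene with exact protein equality — including junction
  genes when a circular contig is rotated into a gene;
* the longitudinal study fixture gives each subject an independent
  random community sequence and each timepoint a lightly mutated copy
  (default 3 × 3, 100 kb, μ_within = 0.01), planting within-subject
  k-mer similarity for ordination to recover.

Everything is driven by explicit seeds; equal parameters give
byte-identical output, which is what makes the end-to-end determinism
check meaningful.

What passing on fixtures does **not** show: robustness to indels,
chimeric contigs, uneven coverage, contaminating cellular sequence, or
real search-tool score statistics. The fixtures validate the *rules*
(thresholds, tie-breaks, coordinate arithmetic, conservation laws), not
the biology of any particular dataset.

## Problem sizes

Default verification sizes — 50 + 50 contigs of 5 kb for circular
detection, 1,000 random cases for the LCA and margin oracles, 500
proteins for partition checks, 10 viromes of 20 kb for distance
oracles, 1 Mb for bias calibration, 3 × 3 × 100 kb for the ordination
study — were chosen as the smallest scales at which every rule is
exercised with comfortable statistical margins.

## Known limitations

* The naive ORF finder ignores ribosome-binding context and codon usage
  and will over-call ORFs on real sequence; it is a testing device.
* Circular detection trusts exact end equality; a single sequencing
  error in the terminal repeat defeats it (as it does the trick it
  models).
* NMDS stress depends on restarts; with 20 seeded restarts the planted
  3-subject structure is recovered reliably, but stress values are not
  comparable across different seeds.
* XGMML export targets the common reader subset (nodes, edges, typed
  `att` elements), not the full schema.
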