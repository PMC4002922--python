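# viromekit

Offline toolkit for analyzing viral metagenomes (**viromes**), both as
raw sequencing reads and as assembled contigs. It provides, as a plain
Python library plus a `viromekit` command-line interface, the
computations a virome annotation server performs behind the scenes —
with no web service, no live reference database, and a synthetic-fixture
generator so every stage is testable offline with planted ground truth.

## Who this is for

Viral communities are dominated by unknowns: most virome reads match
nothing in reference databases, and no single marker gene spans all
viruses. Practitioners therefore combine several complementary views of
a dataset, and `viromekit` implements the computational core of each:

* **Circular contig handling.** A contig whose two ends carry the same
  k-mer likely represents a complete circular genome. `viromekit`
  detects the terminal repeat (default k = 10, longest qualifying
  overlap), trims the redundant copy, and — by scanning a temporary
  sequence with the first min(1000, L) nt duplicated at the end —
  predicts genes that span the origin, reported as wrapping ORFs with
  `join` locations in GenBank output.
* **Taxonomic affiliation.** From a 12-column tabular similarity table
  (e-value screen ≤ 10⁻³): per-sequence best hits (highest bit-score;
  ties by e-value, identity, subject id), virome compositions as raw
  best-hit counts or genome-length-normalized weights
  (w_g ∝ n_g / L_g), and per-contig calls — best hit, or the lowest
  common ancestor (LCA) of the best hits of the ≤ 5 highest-scoring
  genes (longest common lineage prefix).
* **k-mer frequency bias.** Alignment-free whole-dataset comparison:
  per-virome di/tri/tetranucleotide profiles, either raw frequencies or
  observed/expected bias under a zero-order (mononucleotide) null,
  compared by euclidean distance and summarized by average-linkage
  hierarchical clustering or non-metric multidimensional scaling
  (NMDS, 2-d, 20 seeded restarts, reporting stress).
* **Recruitment plots.** Reads whose best hit lands on a chosen
  reference genome become (position, % identity) points (position =
  alignment midpoint) and per-500-nt histogram counts, kept per virome
  for stacked plots.
* **Protein clustering & rarefaction.** Greedy centroid clustering of
  predicted proteins at 75/90/98 % global-alignment identity, and
  seeded domain clustering (longest protein seeds a cluster of
  everything an injected recruiter gathers), with per-cluster domain
  labels (score ≥ 30) and rarefaction curves of cluster richness.
* **Gene-sharing networks.** Contigs and reference genomes as nodes;
  for each ORF every hit with e-value ≤ 10⁻³ and bit-score ≥ 0.9 × that
  ORF's best is kept, giving per-ORF or aggregated (shared-gene-count)
  edges, with the classic "≥ 2 shared genes" display filter and
  GraphML/XGMML/CSV export.

External search tools (BLAST-style protein search, profile HMM scans,
gene predictors) are deliberately abstracted as their tabular outputs;
a naive six-frame ORF finder is built in for testing and desk-scale
work, and `import_orfs` adapts real predictor coordinates.

## Worked example

Generate a synthetic assembled virome with planted truth (12 contigs
from 6 gene-bearing reference genomes, half of them circularized with a
10-nt terminal repeat), then run the full contig workflow:

```bash
viromekit fixtures --mode contigs --seed 7 --out bundle
viromekit contigs --bundle bundle --out run --seed 7
```

`run/contig_affiliations.csv` then begins

```
id,best_hit_subject,subject_id,lineage,level,support
virome_s00001,ref001,,Viruses;Order_1;Family_Order_1.1;Species_ref001,3,5
virome_s00002,ref001,,Viruses;Order_1;Family_Order_1.1;Species_ref001,3,5
```

— each contig's LCA call reaches species level (`level` 3 with
`support` 5 genes agreeing) and its best-hit affiliation names the true
source genome. `run/compositions.csv` holds the hierarchical
taxa-by-mode table (parents are sums of children; per-column totals are
1 − unassigned), `run/network.graphml` the contig–reference
gene-sharing network (here 18 nodes, 18 edges: each contig tied to its
source genome and to its sibling contig), `run/rarefaction.csv` the
cluster-richness curve, and one GenBank flat file per contig, e.g.

```
LOCUS       virome_s00001           2064 bp    DNA     circular ENV 01-JAN-1980
```

with one CDS per predicted ORF (origin-wrapping genes as
`join(...)` locations) and the contig's LCA in the source feature.

For unassembled data, `viromekit reads` produces raw and
length-normalized compositions plus recruitment-plot CSVs, and
`viromekit compare virome1.fasta virome2.fasta ...` writes
tetranucleotide-bias distance matrices, a dendrogram and NMDS
coordinates (stress in the header comment).

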