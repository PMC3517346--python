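# Methods

`paofam` re-implements, as a self-contained and fully testable pipeline,
the comparative workflow used to characterise the metazoan polyamine
oxidase family: detect homologs of the spermine oxidase (SMO),
acetylpolyamine oxidase (APAO) and invertebrate polyamine oxidase (PAO)
subfamilies, group them into gene families, analyse alignment
conservation, build a phylogeny, and classify SMO/APAO as paralogs born
from one ancient duplication.  Because the original analysis depends on
remote databases and external ML/Bayesian software, every stage here runs
against a synthetic molecular-evolution test bed whose ground truth is
known exactly; the package's claims are therefore about the correctness
of the machinery under controlled conditions, not about re-deriving the
biological result from the original accessions.

## Homology search

The search is an exact Smith–Waterman local alignment with affine gaps
(Gotoh three-state recursion, anti-diagonal vectorisation), BLOSUM62
scores, gap open 11 / extend 1, where a gap of length L costs
`open + (L-1)*extend`.  After the optimal alignment of a pair is
reported, its aligned residues are masked (score −∞) in both sequences
and the search repeats, so multiple hits per pair are non-overlapping by
construction.  Raw scores map to bitscores and E-values through the
Karlin–Altschul transform with the standard gapped BLOSUM62-11-1
constants λ = 0.267, K = 0.041 (configurable); the search keeps hits with
E ≤ 1e-10.  This replaces a heuristic BLASTP search; a reader for
12-column BLAST tabular output allows injecting externally computed hits
instead.  Exactness was chosen deliberately: every reported score is
reproducible by an independent naive dynamic-programming oracle, which
the test suite exploits.

## Hit chaining

Multiple hits for one ordered pair are combined into the subset
maximising total aligned length (query residues + subject residues)
subject to pairwise non-overlap in *both* coordinate systems, found by
exact branch-and-bound (cap: 64 hits/pair).  Ties break by higher summed
raw score, then by the lexicographically smallest index set, so the
output is deterministic.  "Overlap" means sharing ≥ 1 residue position;
abutting half-open intervals are compatible.  Collinearity between
chained hits is *not* required (`require_collinear` switches it on); the
chained pair is thereafter treated as a single hit with pooled identity
`Σ identities / Σ aligned_columns` and summed bitscore.

## Families

A chained pair passes the homology filter when pooled identity ≥ 0.30,
summed bitscore ≥ 50, and aligned length ≥ 50% of *both* sequence
lengths; self pairs are excluded.  All thresholds are inclusive (≥).  A
pair of sequences is a two-way hit when both directions pass; gene
families are the connected components of the two-way-hit graph
(single-linkage clustering), computed with union–find and emitted in a
deterministic order.  Coverage is computed from the chained totals —
chaining exists precisely to accumulate alignable regions before the 50%
test.

## Alignment and conservation

The built-in aligner is progressive: UPGMA guide tree on pairwise
global-alignment identity distances, then profile–profile merges under
affine-gap sum-of-pairs scoring (gap symbols score 0).  It is a surrogate
for a production MSA tool, so importing aligned FASTA or Clustal `.aln`
files is first-class.  Column conservation is the fraction of rows
carrying the single most frequent residue, with gaps in the denominator
(a flag switches to gap-free denominators; whether the original 90%
statistic counted gaps is not documented, so both behaviours are
exposed).  A column is conserved at the classical threshold when the
score is ≥ 0.90; a strict-inequality flag exists because the source
material is ambiguous between "at least" and "more than" 90%.  Consensus
sequences take the majority non-gap residue per column, drop columns
where gap is the majority state, and break ties alphabetically.
Active-site panels (e.g. the mouse SMO Trp80/His82/…/Thr528 set and the
mouse APAO counterpart, shipped as constants) are resolved through the
reference sequence's own numbering; a disagreement between the panel's
expected residue and the reference row is a hard error, which guards
against numbering drift.

## Phylogeny

Distances are mismatch fractions over mutually ungapped columns, with
Poisson (−ln(1−p)) or Kimura (−ln(1−p−p²/5)) correction.  Trees are
built with neighbor joining (Saitou–Nei); on additive matrices the
algorithm recovers the generating tree exactly (topology and branch
lengths), which the tests verify over random trees with branches in
[0.01, 1].  Q-matrix ties break to the smallest index pair; negative
branch-length estimates are clamped to zero with the deficit moved to
the sibling edge.  Support comes from column bootstrap: resample
columns with replacement, rebuild, and report per-internal-edge
bipartition frequencies on the full-data tree (stored as internal node
labels in Newick).  The study-scale default is 500 replicates; the
simulation experiments use 100, which is ample at the divergences
simulated.  Maximum-likelihood and Bayesian inference are intentionally
out of scope; externally computed trees can be imported as Newick and
used everywhere a tree is expected.  Rooting places the root at the
midpoint of the outgroup leaf's edge.

## Reconciliation

Standard LCA reconciliation with no loss or transfer costs: each
gene-tree node maps to the species-tree LCA of its taxa; a node mapping
to the same species node as one of its children is a duplication,
otherwise a speciation.  Two genes are paralogs iff their gene-tree LCA
is a duplication.  This is the minimal formalisation of reading a gene
tree as "duplication on the vertebrate stem, speciations elsewhere".
Monophyly of a named leaf subset is leaf-set equality with some clade of
the rooted tree, reported with the subtending edge's bootstrap support.

## Isoform analysis

The packaged 25-row survey of mammalian SMO loci (verbatim transcription,
including the ambiguous "isoform 1" label of the Sumatran orangutan
entry) is censused by the rule `has_long_isoform ⇔ label ≠ "no isoform"`,
giving 22 carriers and 3 non-carriers (wallaby, opossum, platypus).
Presence/absence characters are placed on a species tree with Fitch small
parsimony; ambiguous internal states resolve to the parent's state and an
ambiguous root to "absent" (the trait is treated as ancestrally absent),
after which the changed edges are reported as gains/losses.  Domain-block
conservation (the nuclear-domain NDA/NDB analogs) is the mean column
conservation of a block within a clade.

## The synthetic test bed

Families evolve along a rooted binary species tree under a reversible
amino-acid process with invariant sites and gamma rate heterogeneity
(I+G): a site is invariant with probability `p_invariant`, otherwise its
rate multiplier is Gamma(α, mean 1) (α = `gamma_shape`; `None` collapses
to a single rate).  Substitutions are realised site-by-site with
exponential waiting times (Gillespie), so per-site substitution counts
are exact and the I+G emulation is itself testable (binomial test on the
invariant fraction; dispersion test against Poisson in the single-rate
limit).  The default exchangeability matrix is derived from BLOSUM62
log-odds (s_ij = 2^(S_ij/2), uniform frequencies) — an empirical-flavour
reversible model that ships with the package as code, not data; any
empirical matrix in PAML `.dat` layout (JTT, WAG, …) can be loaded
instead, and the rate matrix is normalised to one expected substitution
per site per unit branch length either way.

One duplication can be placed on any species-tree edge: at the top of
that edge the proto-locus P splits into paralogs A and B, which then
evolve independently (the SMO/APAO analog).  Copies can be lost per
(taxon, locus).  Constrained "active-site" columns have rate 0, globally
or restricted to one paralog's subtree (the SMO-specific Glu216/Ser218
pocket analog: constrained in A, free in B).  Indels are single-residue
events at `indel_rate` per site per unit branch length, applied after
the substitution pass of each branch; inserted sites draw a fresh rate
and evolve for the residual branch time, and constrained columns are
never deleted.  A fixed-length extra block (default 40 residues, the
alternatively spliced exon analog) is appended at a configurable anchor
on the stem of a chosen clade and evolves under the same process within
that clade only.  A global column registry gives the true alignment, the
true (duplication-aware) gene tree is emitted as Newick, and one seeded
generator consumed in fixed traversal order makes all outputs
byte-reproducible.  The default alignment length (500 sites; the
experiments below use 240–300) is a free design choice, as is the demo
species-tree shape: the designated outgroup is attached as the basal
lineage so that outgroup rooting is consistent with the species tree.

What the simulator does *not* emulate — composition heterogeneity,
domain shuffling, codon-level effects, selection (dN/dS), alignment
over long indels, heterotachy — bounds what green tests mean: they
demonstrate the pipeline's correctness against known truth under an
I+G-style model, not robustness to every property of real proteomes.

## Benchmark experiments (`paofam.evaluation`)

* **Oracle agreement.**  Local alignment (500 random pairs ≤ 60 aa) vs a
  plain-python full-matrix DP; hit chaining (1000 random instances, ≤ 10
  hits) vs explicit subset enumeration; single-linkage families (500
  random 30-node graphs) vs BFS components; all must agree exactly.
* **NJ consistency.**  200 random 8–16-taxon trees, additive matrices
  from explicit path sums: exact recovery of topology and lengths.
* **Duplication recovery.**  200 random single-duplication scenarios
  reconciled with their *true* gene trees: the inferred duplication must
  map to the planted species branch (isolates reconciliation from tree
  estimation error).
* **End-to-end family recovery.**  Two independently rooted families on
  one shallow 8-taxon species tree (within-family identity well above
  40%, between-family pairs unrelated); the default filters must
  reproduce the true partition (adjusted Rand index 1.0), and each
  family must be a monophyletic clade with bootstrap support ≥ 0.95 at
  100 replicates.
* **Conservation closed loop.**  12 planted rate-0 columns in a deeply
  diverged 24-taxon family (homogeneous rates, no invariant sites, total
  tree length tens of substitutions per site) must be exactly the
  columns flagged at the 90% threshold on the true alignment; the
  divergence is chosen so that the chance a free column stays ≥ 90%
  conserved is below 1e-5 per family.
* **Threshold monotonicity.**  On a fixed dataset, raising any filter
  threshold never decreases the family count.

Problem sizes were picked so the whole suite runs in well under a minute
per experiment on one core.

## Known limitations

* The progressive aligner is basic (no iterative refinement, no
  position-specific gap penalties); deep or indel-rich families should
  be aligned externally and imported.
* The masking strategy for secondary Smith–Waterman hits is greedy; a
  suboptimal first hit can in principle split a longer alternative
  alignment.
* Reconciliation assumes a correctly rooted gene tree and does not
  penalise losses; with noisy estimated trees it will report spurious
  duplications, which is why the recovery benchmark feeds it true trees
  and the pipeline reports supports alongside.
* Fitch parsimony here treats gains and losses as equally costly;
  asymmetric-cost (Dollo-style) placements are out of scope.
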