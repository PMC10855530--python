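# Methods

This note documents the models, conventions and numerical choices behind
mitocompare, in the spirit of a package methods appendix: what each
statistic is, which defaults matter, what the simulator does and does not
emulate, and where the known limitations are.

## Coordinates and input conventions

All public coordinates are 1-based and fully inclusive on both ends, the
convention of printed mitogenome gene tables; conversion to Python slices
happens only inside `mito_io`. Gene names are canonicalized through a
synonym map (`COX1 → COI`, `CYTB → Cytb`, `ATPase6 → atp6`,
`tRNA-Phe (F) → trnF`, `D-loop → CR`, …); serine/leucine isoacceptors are
resolved from an explicit `(S1)`/`(L2)` qualifier or, failing that, from the
annotated anticodon. Features that would span the circular origin are
rejected outright rather than normalized — they do not occur in the genomes
this package targets, and silent wrap-around handling is a classic source
of off-by-one errors. Ambiguity codes other than N are mapped to N with a
warning. Anticodon strings are stored verbatim as annotated: published
tables mix codon-side and anticodon-side conventions, so reorienting them
automatically would corrupt half of the inputs.

## Architecture accounting

For adjacent features the gap is `downstream.start − upstream.stop − 1`
(positive = intergenic spacer, negative = overlap, 0 = abutting); the
circular wrap pair lifts the first feature's start by the genome length.
Each boundary is attributed to its upstream gene, matching printed-table
row association. The conservation law
`Σ feature sizes + spacers − overlaps = genome length`
holds exactly for a fully tiled circle and is exposed as
`tiling_residual()`; duplicated features (e.g. a second control region)
enter the sum like any other feature, which keeps the law exact under
rearrangements. Partition percentages are rounded to two decimals, half-up,
to match printed values. Gene-order comparison reports duplications (name
counts > 1), missing reference genes, and order-breaking genes — the
complement of a longest common subsequence between the first-occurrence
order and the ancestral teleost order packaged as a constant.

## Composition

AT-skew = (A−T)/(A+T), GC-skew = (G−C)/(G+C), computed on exact counts with
N excluded from every denominator. A zero denominator yields skew 0 with an
explicit degenerate flag, keeping tabular output rectangular. Partition
rows (PCG/rRNA/tRNA/CR) are computed on sense-strand concatenations in
genome order — the convention of gene-by-gene analyses — while the
whole-genome row uses the heavy strand as deposited.

## Codon usage

The vertebrate mitochondrial code (translation table 2) is taken from
Biopython: AGA/AGG join TAA/TAG as stops, ATA is Met, TGA is Trp. Gene
length mod 3 of 1 or 2 is interpreted as an incomplete stop (`T--` or
`TA-`) completed to TAA by polyadenylation; a remnant that cannot be
completed to TAA triggers a warning, not an error, since real annotations
contain such oddities. RSCU(c) = count(c) / mean count of c's synonymous
family, with leucine and serine split into 2-fold and 4-fold sub-families
(Leu2 = TTA/TTG, Leu4 = CTN, Ser2 = AGT/AGC, Ser4 = TCN) as per-codon usage
panels conventionally do. Stop codons and incomplete remnants never enter
counts; start codons do by default (they are genuine codons), with a
documented switch to exclude them. Unobserved families get RSCU 0 plus an
`rscu_undefined` flag rather than NaN.

## Divergence statistics

**Counting.** Transitions are A↔G and C↔T; sites with a gap or ambiguous
base in either sequence are excluded pairwise (pairwise deletion) for
distances.

**K2P.** d = −½ ln[(1−2P−Q)·√(1−2Q)] on transition/transversion
proportions P and Q. A non-positive log argument raises a saturated-pair
error; distance matrices refuse to impute. The correction never shrinks:
d ≥ p-distance, with equality only at p = 0.

**NG86 Ka/Ks.** Synonymous site fractions per codon are precomputed for
all 60 sense codons (changes to stop codons count as nonsynonymous sites),
averaged over both sequences; differences for multi-hit codons are averaged
over all minimal mutational pathways with equal weights, excluding pathways
through stop codons (if every pathway passes through a stop, all are used so
the statistic stays defined). The 64×64 pathway table is precomputed, so
pairwise scans are lookups. Jukes–Cantor correction K = −¾ ln(1 − 4p/3);
p ≥ ¾ leaves the corrected rate undefined with a flag, and Ks = 0 leaves
the ratio undefined with a flag. The implementation agrees with Biopython's
`calculate_dn_ds(method="NG86")` to machine precision on random codon pairs
(cross-checked in the test suite).

Two documented properties of this classical estimator matter for
interpretation. First, equal pathway weighting can assign fractional
nonsynonymous differences to purely synonymous histories: a double hit such
as TTA → CTA → CTT presents the endpoint pair TTA/CTT, whose two minimal
pathways are (syn, syn) and (nonsyn, nonsyn); the average contributes
Nd = 1 even though no nonsynonymous substitution occurred. Consequently
"Ka = 0 under synonymous-only evolution" holds only up to this artifact;
the tests assert the sharp version (realized nonsynonymous count exactly
zero, and every codon pair contributing Nd admits a fully synonymous
minimal pathway). Second, equal-rate site counting understates dN/dS under
transition bias, because transitions are enriched for synonymous changes;
the understatement grows with the transition/transversion rate ratio κ
(roughly ×0.8 at κ = 1.5, ×0.75 at κ = 2, ×0.65 at κ = 3 in the recovery
experiments shipped with the suite). This is inherent to NG86 and is why
likelihood codon models exist; those are outside this package's scope.

**Nucleotide diversity.** π in a window is the mean over all n(n−1)/2
sequence pairs of pairwise differences per comparable site, with
complete-column deletion (a column containing any gap/N is ignored
everywhere) and no multiple-hit correction. Windows are anchored at
position 1 on a 200 bp / 25 bp grid by default; the trailing partial window
is dropped; the reported midpoint of the first window is position 100.
Segregating sites are complete columns with more than one base.

**Saturation.** Per-pair tables of K2P distance against transition and
transversion proportions; saturated pairs are flagged with NaN distance but
kept, since their s/v values are exactly the interesting ones.

## Neighbor joining and bootstrap

Saitou–Nei agglomeration on the Q-criterion. Ties in Q are broken by the
lexicographically smallest pair of cluster labels (a cluster is labelled by
its smallest leaf name), making the algorithm fully deterministic. Negative
branch-length estimates are clamped to zero with the deficit transferred to
the sister branch. Trees are unrooted, represented with a trifurcating
root; for three remaining clusters the closed-form three-point formulas
apply. On exactly additive matrices NJ reproduces the generating tree —
topology and branch lengths — which the suite verifies on 100 random
additive trees and against scikit-bio's independent implementation.

Bootstrap resamples alignment columns with replacement; the support of an
internal edge is the percentage of completed replicate trees containing the
same leaf bipartition. Replicates hitting a saturated pair are skipped and
counted. An alignment with zero variable columns would trivially "support"
the arbitrary tie-broken topology at 100%, so that case is flagged
(`no_variation`) with supports reported as 0. Newick output is canonical
(children sorted by smallest leaf name) so serialization round-trips are
byte-stable; supports appear as internal node labels.

## tRNA cloverleaf heuristic

A bounded exhaustive enumeration over arm placements — acceptor stem 7 bp,
DHU stem absent or 2–4 bp with a 4–9 nt loop, anticodon stem 5 bp with a
7 nt loop, TψC stem 4–5 bp with a 3–8 nt loop, small spacers and a variable
region up to 9 nt — scored by paired stem positions (Watson–Crick 2,
G·U/G·T wobble 1), deterministic tie-break preferring canonical loop sizes.
This is deliberately not a thermodynamic folder: the purpose is a
reproducible, testable detector of the biological signals of interest —
DHU-arm presence/absence (mitochondrial trnS1 lacks the arm) and wobble
pair counts — not minimum free energy. Fewer than five paired acceptor
positions sets a `non_canonical` flag; an anticodon hint adds a scoring
bonus to layouts whose loop centre matches it.

## Control region tools

Conserved blocks are located per species by the best gapless (Hamming)
match of each library motif against the degapped CR, kept at ≥ 70% identity
by default; a species below threshold is reported absent (real CRs with
unprecedented length variation can be excluded via a skip list, and the
default report config exposes that option). Variable columns are counted
across the matched block sequences of the species that carry the block.
The packaged motif library (`cr_motifs_synthetic.yaml`, versioned) holds
constructed teleost-style consensus strings at the conventional block
lengths — CSB-D the longest central conserved domain at 33 bp; CSB-A/B/C/E/F
at 18/18/28/19/20 bp; CSB-1/2/3 at 23/18/20 bp. The strings are synthetic
stand-ins, not transcriptions of any published figure, and users with a
curated library can pass their own.

Tandem repeats are detected from the rotated self-match profile
(`seq[i] == seq[i−p]`) per candidate period p ∈ [10, 60]: maximal segments
with running identity ≥ 80% spanning at least two full copies become
candidates; overlaps are resolved by highest identity, then smallest
period. Copy number is region length / period to one decimal (so 46 bp at
period 17 reports 2.7 copies); the consensus is the column majority over
the aligned copies. The greedy maximal extension can absorb flanking
sequence that happens to stay above the identity threshold, which slightly
inflates copy numbers on noisy flanks; at identity 1.0 the detected region
is the exact maximal run and is mirror-symmetric under reverse complement.

## The simulator

`simulate_family` generates what the analysis stages consume: ~10
congeneric circular mitogenomes in the ancestral teleost gene order with
abutting features (the tiling law holds by construction), AT content
targeted at 56%, evolved gene-by-gene along a random ultrametric tree
(default height 0.2 expected neutral proposals/site; child node heights are
35–65% of the parent's so no internal branch is vanishingly short).
Mutation proposals follow an HKY-like scheme — target base weighted by its
stationary frequency times κ for transitions — which keeps composition
stationary at the target; κ defaults to 2.0, a modest transition bias under
which the NG86 recovery experiments return planted ω within ±30% (see the
bias discussion above). In protein-coding genes, proposals creating stops
are rejected, nonsynonymous proposals are accepted with probability
ω (per-gene map spanning 0.011–0.199 by default, strongest constraint on
ND5 and weakest on COIII), and every accepted event is tallied in the truth
record, so realized synonymous/nonsynonymous counts are exact. tRNAs are
built as perfect cloverleafs (trnS1 without the DHU arm) and, like rRNAs,
evolve at 0.2× the PCG proposal rate; the control region evolves at full
rate except inside its conserved blocks (0.1×), so block conservation
against a variable background — the signature of real central conserved
domains — emerges in the output. One taxon (default `taxon03`) receives a
planted ETAS tandem repeat (17 bp motif, 2.7 copies) prepended to its CR;
one taxon (default `taxon10`) receives a trnD + CR duplication via
`inject_rearrangement`, which splices the duplicate immediately downstream
and re-lays all coordinates, preserving the tiling law.

Everything is driven by a single seeded generator: identical spec + seed
gives byte-identical output.

What the simulator does **not** emulate — and what passing tests therefore
do not show about real data: indels and alignment uncertainty (genes are
born aligned; real comparative work needs an aligner, and π/distance values
are alignment-sensitive), among-site rate heterogeneity within genes,
strand-asymmetric mutation pressure, base-composition drift between
lineages, recombination, heteroplasmy, and realistic ETAS repeat-number
polymorphism. PCG stop codons are complete (TAA) and frozen; real genes
often end on incomplete stops, which the codon module handles but the
simulator does not produce.

## Pipeline conventions and problem sizes

`run_report` matches genes across genomes by canonical name (first copy
used when duplicated, with a log message), drops genes missing in any taxon
or of unequal length from concatenations (no aligner is run) with a
warning, and runs independent stages to completion even when one fails
(failures land in `report.errors` under the stage name). The supermatrix is
concatenated in canonical gene order with a charset coordinate map; the
dataset choice (13 PCGs vs 13 PCGs + 2 rRNAs) is a config switch. All
thresholds live in `ReportConfig` (YAML-loadable), and every run embeds a
provenance block (package version, config, taxa, Python version).

Default problem sizes used by the tests and the acceptance script — a
10-taxon, ~16.5 kb family with 1000 bootstrap replicates, and 20-replicate
recovery experiments on 500-codon genes — were chosen so the full suite
runs in well under a minute while keeping Monte-Carlo error comfortably
inside the asserted tolerances.

## Known limitations

- NG86 only; no maximum-likelihood dN/dS, no codon models, no model
  selection. NJ only; ML/Bayesian inference is delegated to external tools
  via the exported supermatrices.
- The cloverleaf finder reports the best layout on a fixed grid; unusual
  mitochondrial tRNA geometries (long variable arms of serine tRNAs beyond
  9 nt, severely truncated arms) may fold suboptimally.
- Block scanning is gapless; a block interrupted by an indel in a real CR
  will score below threshold rather than align around the gap.
- The CR motif library is synthetic (see above); block identities against
  real control regions depend on supplying a curated library.
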