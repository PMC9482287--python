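# Methods

## Scope and model

`organellekit` implements the comparative analysis applied to organelle
genomes of holoparasitic plants: gene-content degradation profiling and
staging of a plastome, quadripartite structure metrics, detection and
phylogenetic classification of plastid-derived fragments in a
mitochondrial genome, a single-site fragility audit of donor calls, and
pathway-completeness reporting from expression evidence. All stages are
pure functions of their inputs plus a seed; the package ships a synthetic
fixture generator so the whole pipeline runs and is tested end to end
without external data.

## Gene-status classification

A gene copy is classified against its reference CDS as:

- **lost** — no homologous segment at expect value < 10⁻¹⁰ (the same
  significance gate as the transfer scan);
- **pseudogene** — homologous but (a) shorter than τ_len = 0.5 of the
  reference length, or (b) carrying an in-frame stop strictly before the
  last codon of the aligned reference span ("translation terminated in
  advance"), or (c) below τ_id = 0.6 global nucleotide identity;
- **intact** otherwise.

Structural RNAs (trn/rrn) skip the stop-codon test. The thresholds are
deliberately conservative and configurable; published analyses in this
area rarely state numeric cutoffs, and "significant difference from the
reference" is operationalized here as the identity threshold. Identity is
computed on the optimal global alignment (biopython's PairwiseAligner),
normalized by the longer sequence, so both divergence and large
truncations reduce it. Homology detection uses the package's seeded
ungapped local aligner (below); a gene so diverged that no 13-mer seed
survives is reported lost rather than divergent, which is the same
resolution limit a BLAST-based annotation pass has.

Duplicated plastome genes (the two inverted-repeat copies) are reported
once per symbol; if the copies differ in status the less degraded one
wins. Mitochondrial gene counts are per annotation row, since duplicated
mito loci are genuinely separate genes.

## Degradation staging

The stage rule table operates on per-category (intact, total) counts:

- **Absent** — no plastome at all.
- **Degradation II** — any housekeeping category in {atp, rps, rpl} with
  intact fraction < 0.5.
- **Stationary** — not Degradation II; ndh and rpo fully non-intact; and
  at most one intact gene across psa/psb/pet (the characteristic psbA
  holdout).
- **Degradation I** — not the above; any of psa/psb/pet/rpo degraded.
- **Photosynthetic** — otherwise; loss of ndh alone does not advance the
  stage (ndh loss is common in fully photosynthetic relatives).

The table is monotone: degrading one more gene never moves a profile to
an earlier stage (property-tested). A design point worth recording: rbcL
is *not* a sufficient Degradation II trigger. It is a single-gene
category that holoparasites frequently lose while still otherwise in the
Stationary stage, so treating its loss as a late-stage marker would
misclassify exactly the genomes this model is meant to describe; the atp/
rps/rpl criterion carries the late-stage signal instead.

## Quadripartite structure

Inverted repeats are found by exact 21-mer anchoring of the sequence
against its own reverse complement, X-drop extension (match +1, mismatch
−3, drop 20), and selection of the longest disjoint segment pair at
≥ 99% identity and ≥ 1 kb (defaults; both configurable). The scan runs on
the doubled sequence so repeats spanning the linearization origin are
found, making region lengths rotation-invariant. The two arcs between the
repeats are labeled LSC (longer) and SSC (shorter); output coordinates
are normalized to start at the LSC, the common plastome convention. With
no qualifying repeat the partition degenerates to a single LSC. The test
oracle is an exhaustive exact-match scan over every alignment offset at
toy scale.

Region-size change between two partitions is the signed percentage
100·(|R_b| − |R_a|)/|R_a|, reported to one decimal; a zero-length
baseline region yields an undefined (None) result rather than an error.
`REFERENCE_PARTITIONS` ships region lengths for the comparison species;
they are fixture values chosen to embody the published percentage
changes, since the primary sources do not print all four region lengths
per species (their printed totals and percentages are not mutually
consistent to the base pair).

## Transfer detection

Mitochondrial chromosomes are scanned against the plastid reference gene
panel with a seeded (k = 13) ungapped extension aligner scored +1/−2,
with Karlin–Altschul significance E = K·m·n·e^(−λS) (λ = 1.33, K = 0.621,
the standard values for this scoring) and cutoff E < 10⁻¹⁰. Same-gene
hits on one replicon and strand within join_gap = 50 bp are chained into
one fragment, a convention for insertions split by post-insertion decay;
copy indices are assigned in (replicon, coordinate) order. Precomputed
12-column tabular hits can be ingested instead of scanning — both routes
produce the same hit type. Ungapped extension is appropriate because the
fragments of interest are recent, near-identical insertions; the package
does not attempt gapped alignment statistics.

A fragment is ORF-complete only if it contains the reference's full CDS
span with intact start codon, terminal stop, and no internal in-frame
stop — the claim "these fragments are unable to be translated" is made
checkable per fragment.

## Phylogenetic classification and the fragility audit

Trees are rooted on a designated outgroup; bootstrap supports are read
from internal-node labels and stored per bipartition, which makes every
query invariant to how the input newick happened to be rooted or to tip
order. Missing supports are treated as below threshold (published figures
hide values ≤ 50%).

With min_support = 70 (the BS > 70% convention):

- **IGT** — the smallest supported clade containing the query consists
  otherwise only of the parasite's own lineage (Lamiales/Orobanchaceae),
  and that lineage plus the query is monophyletic at ≥ min_support.
- **HGT** — the native lineage *without* the query is monophyletic at
  ≥ min_support (trivially so if it is represented by a single tip), and
  the query's smallest supported enclosing clade lies within one other
  non-outgroup group, reported as the donor.
- **undetermined** — anything else, including fragments with fewer than
  min_sites = 3 parsimony-informative sites ("too short to determine the
  donor").

"Nested within" is operationalized as the smallest enclosing clade with
support ≥ min_support whose other tips all belong to one group; the
monophyly requirement on the native lineage is enforced at ≥ min_support
even in the ambiguous monotypic phrasing of the field's usual rule — we
require the support when more than one native tip is present.

The site audit counts parsimony-informative columns (≥ 2 states each in
≥ 2 sequences) where the query shares its base exclusively with candidate
donor group A vs group B, then flips the query base at each decisive
column and recomputes the tally: a call is **fragile** if any single flip
changes the winning group. Fragile calls keep their topology-based
verdict but carry reason `fragile_single_site`; demotion to undetermined
is an explicit option (`--demote-fragile`), because a single-site pivot
argues for caution, not for automatically discarding the call.

The NJ + bootstrap builder exists so fixture trees can be built from
alignments end to end: neighbor joining on p-distances with deterministic
lowest-index tie-breaking (an earlier draft delegated to dendropy's NJ,
whose tie-breaks follow set iteration order and are not reproducible
across processes), and clade support as the percentage of
column-resampled replicates containing the same unrooted split. It is
fixture plumbing, not a substitute for likelihood-based inference on real
data.

## Pathway completeness

Pathway definitions are JSON documents freezing one gene roster per
pathway: ko00195 with 63 genes (30 plastid + 33 nuclear) across five
components, and ko00860 as a 14-step enzymatic chain from glutamyl-tRNA
to chlorophyll a plus two component sets. The ko00195 roster follows the
source analysis' component assignment (petB/petD counted under
photosynthetic electron transport) rather than the current KEGG layout,
so its printed component split is reproducible; exact membership beyond
the explicitly named genes is version-dependent and fixture-frozen. An
alias table maps subunit names (alpha/beta/…) to gene symbols.
"Detected" is a caller-supplied boolean — the package does not quantify
expression. The chain-break finder returns the earliest step with no
detected gene and the product of the preceding step; detected genes that
are not pathway members are reported, never silently dropped.

## Synthetic fixtures: what they emulate, and what they do not

The default `FixtureSpec` encodes the study conditions of a Buchnereae
holoparasite: plastome regions 30,072 / 480 / 2 × 32,761 bp; 68 intact,
11 pseudogene (the named eleven), 40 lost genes against a 119-gene
photosynthetic reference; a mitogenome of three circular chromosomes
(87,933 / 303,254 / 241,909 bp) with 75 local genes split 9/28/38 and
nine planted plastid fragments of eight genes (ycf2 twice); donor-tree
scenarios whose classifier outcomes tally IGT 4 / HGT 3 / undetermined 2
with Orchidaceae (85% BS) and Gentianaceae (100% BS) donors; an rpl20
alignment whose donor signal rests on a single A/G column at position
187; and expression tables giving the 11-gene photosynthesis pattern and
the nine-hem-gene chlorophyll chain ending at EC 1.3.1.75.

Generator conventions:

- Reference genes default to 300 bp random CDSs (80 bp tRNAs, 120 bp
  rRNAs, 900 bp ycf1/ycf2); real lengths are irrelevant to the logic
  under test. Filler is i.i.d. uniform nucleotide at ~35% GC (plastome) /
  44% GC (mitogenome), approximating the published GC contents and, more
  importantly, guaranteeing no spurious homology at the scan's
  significance gate.
- Pseudogene defects are seeded draws between an internal stop at a
  uniform position in [10%, 60%) of the CDS and truncation to 40% of
  reference length; structural RNAs always truncate. Both satisfy the
  classifier's criteria by construction.
- The duplicated rRNA operon is represented as eight distinct symbols
  (rrn16/rrn16b, …), each carried by both IRs, so per-symbol reporting
  matches the conventional per-copy rRNA count of plastome annotation.
- Region and fragment boundaries are pinned: the four bases flanking each
  IR boundary and each planted fragment are set to guaranteed mismatches,
  so repeat extension and homology extension stop exactly at the planted
  edges. This is what makes exact-coordinate recovery a meaningful
  invariant rather than a probabilistic one.
- Identical spec + seed give byte-identical outputs (all randomness flows
  from numpy SeedSequence streams keyed by purpose).

What passing on these fixtures does **not** show: performance on real,
repeat-rich mitogenomes (chimeric insertions, nested repeats, diverged
paralogs), annotation noise, RNA editing, codon-usage or
substitution-model realism, or likelihood-based tree uncertainty. The
fixtures exercise the decision logic at realistic scales, not the
messiness of real assemblies.

## Numerical choices and degenerate inputs

- Alignment scoring: seeds k = 13 (pairwise) / k = 21 (IR detection);
  X-drop 20; mismatch −2 (homology) / −3 (IR). E-values use ungapped
  Karlin–Altschul constants for the +1/−2 system.
- Ties: arc-label tie (|LSC| = |SSC|) broken by smaller start coordinate;
  NJ Q-criterion ties by lowest index; equal-status IR gene copies
  collapse to copy 1.
- Degenerate inputs: plastomes without detectable repeats partition as a
  single LSC; empty gene catalogs count zero everywhere; zero-baseline
  region changes and zero-denominator content ratios return None;
  ragged alignments, overlapping audit groups, empty references and
  invalid supports raise ValueError.
- Problem sizes in the test suite: the full 96 kb plastome and 633 kb
  mitogenome fixtures run once per session; property suites use 0.8–9 kb
  molecules (500 partition fixtures, 100 transfer-recovery seeds, 1,000
  monophyly cases), sizes at which the exhaustive oracles are exact and
  the whole suite stays well under half a minute.

## Known limitations

- The ungapped scanner under-reports homology interrupted by indels;
  real MIPT surveys chain gapped BLAST hits.
- `classify_gene` trusts the caller's annotation to delimit gene copies;
  there is no ab initio gene finding or lift-over.
- The stage model is a rule table over category fractions — adequate for
  the three stages it must distinguish, but not a probabilistic model of
  gene-loss order.
- The IGT/HGT classifier consumes one tree per fragment; it does not
  test alternative topologies or integrate over bootstrap replicates
  beyond the per-clade support values.
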