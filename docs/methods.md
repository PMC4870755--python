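# Methods

This note documents the models implemented in `mthap`, the defaults they
ship with, what the synthetic-data generator does and does not emulate, and
the numerical choices made where the design was genuinely open.

## Coordinate and annotation model

All coordinates are 1-based inclusive against a linearized circular genome
(position 1 fixed at the reference origin). Features that wrap the origin
carry `wraps=True` and are handled by unrolling. The annotation is a minimal
TSV dialect (name, kind, start, end, strand, complex, codon_start_offset)
rather than GFF: the pipeline needs typed CDS/tRNA/rRNA/control/motif spans
and ETC-complex membership, nothing more. A position overlapping two
features (e.g. the 10 bp ATPase8/ATPase6 overlap) counts once per feature in
susceptibility tallies; there is no tie-break rule because none is defensible
without transcript-level evidence.

Amino-acid consequences use the vertebrate mitochondrial code (ATA=Met,
TGA=Trp, AGA/AGG=stop) and are reported in three-letter p.Xaa#Xaa style.
Two historically reported changes at 8116 (ATPase6 codon 58) and 13898
(NADH6 codon 64) are synonymous Met→Met under this code; they are
Ile→Met substitutions only under the standard nuclear code, an artifact of
commercial-workbench annotation. The package reports the mitochondrial-code
result. Similarly the 13529 T>C change at NADH5 codon 591 is Phe→Ser in the
substitution's actual direction; the conventional "Ser591Phe" label has the
direction inverted, and `translate_codon_change` reports what the alleles
imply.

## Synthetic reference and haplotypes

The reference backbone is a seeded random sequence (GC 40 ± 5%) with a
pig-like gene order over 16,679 bp, constrained so that every documented
polymorphic site carries its documented reference allele and every annotated
codon carries its documented amino acid. It is synthetic: no accession is
downloaded and the sequence matches no real genome outside the constrained
positions.

The five haplotype profiles carry 28 haplotype-unique polymorphisms
(4/3/13/5/3 for A–E, including one insertion) plus 30 shared D-loop sites,
each carried by four of the five haplotypes. The shared sites emulate the
hypervariable-segment divergence that real maternal lineages show: they
separate every haplotype pair by ≥ 12 D-loop sites — enough that a column
bootstrap essentially never erases a pair's signal (the probability that a
replicate drops all k separating columns is ≈ e^−k) — while never counting
as distinguishing, since a distinguishing site requires exactly one
haplotype to differ from the reference.

## Read simulation

Reads are single-end, drawn uniformly along the individual's genome with
normally distributed lengths (default 100 ± 12 bp; lengths vary because real
amplicon reads do, and fixed-length reads would collide in the duplicate
filter at high depth). Each read comes from the consensus molecule or from
one variant molecule per the target frequencies; a molecule carries exactly
one variant, so summed target frequencies must stay below 1 (per-site
frequencies are all the study design measures; no phasing). A configurable
fraction of reads (default 10%) are exact duplicates of earlier reads, and
strand balance, per-base substitution errors, and an optional single-strand
restriction per variant are supported. Reads never span the circular origin;
the amplicon design this emulates makes junction coverage irrelevant.

The truth table is the downstream evaluation oracle. Its `frequency` column
is the realized variant fraction among the unique reads overlapping the
site; `target_frequency` is the requested population level. Recovery is
judged against the realized value because the caller can only measure what
the read set contains — the binomial gap between target and realized levels
is the generator's sampling noise, not pipeline error.

The default simulated depth is 500× (the pipeline's calling thresholds are
unchanged); deep-coverage checks run at 1000×. These are scaled-down
stand-ins for production depths in the few-thousand× range and keep a full
two-pass run over the 16.7 kb genome in the tens of seconds.

## Alignment and variant calling

Alignment is semi-global (read global, reference local) under per-base costs
match 0 / mismatch 2 / insertion-deletion 3, with reads accepted at ≥ 80%
identity (matches / alignment columns) and both orientations tried. The
implementation seeds candidate loci with exact 13-mers (four spread offsets;
disjoint for reads ≥ 52 bp, so a single mismatch never hides all seeds;
shorter reads fall back to a full scan), scores candidates gaplessly, and
accepts a gapless placement outright when it has ≤ 1 mismatch — provably
optimal, since any indel pair costs ≥ 6 — otherwise refines the best locus
with a banded dynamic program (Needleman–Wunsch with free reference end
gaps, via Biopython's pairwise aligner configured to these costs). Reads
placing at two distinct loci at equal cost are flagged multi-mapping and
excluded for reproducibility.

QC order is trim (1 nt per end) → length (≥ 15 bp) → mean-read Phred
(≥ 15); the quality rule is applied to the read mean, not per base, because
the acceptance rule this implements is a read filter. Duplicates share
(start, end, strand) — single-end data carry no mate cue — and collapse to
the first-seen read.

The two-pass design mirrors deep amplicon practice: pass 1 aligns against
the reference and builds a representative (consensus) sequence per
individual — majority allele at > 50% frequency and depth ≥ 10, reference
base retained otherwise, indels folded in with a projection map back to
reference numbering. Pass 2 remaps the reads against the representative and
calls, at each projected reference coordinate, every allele that differs
from the *reference* allele and meets all of: ≥ 50 supporting reads, ≥ 3%
frequency, ≥ 1 forward and ≥ 1 reverse read. Haplotype-defining alleles
therefore surface at ≈ 100% frequency and heteroplasmies at their molecular
level. Indel frequencies use depth at the anchor position. Positions created
by consensus insertions, which have no reference coordinate, are reported
with a `+k` suffix on the anchor. The 3% threshold applies to the
deduplicated pileup.

Classification: an allele is a haplotype SNP iff it exceeds 90% frequency in
every replicate of exactly one haplotype and in no individual of any other;
3–49% is a heteroplasmic variant; anything else (including the 49–90% band,
for which the study design defines no class) is surfaced as unclassified
rather than dropped. Susceptibility tables divide per-feature and
per-complex variant counts by region length in bp; complexes aggregate their
member CDSs (NADH1–6/4L → I, CYTB → III, COI–III → IV, ATPase6/8 → V).

Known limitation: a 1 bp indel whose position falls within ~2 bp of a read
end is absorbed into the cheaper mismatch/soft-end interpretation, biasing
indel frequencies low by roughly (4/read-length); at 150 bp reads this is
under 1 percentage point at 30% frequency. Deletions inside homopolymer
runs (such as 16383delC in the CSBII G-tract) lose additionally, because a
run-adjacent deletion is unresolvable near read ends — the same ambiguity
that makes this motif hard for flow-space sequencers.

## Distance, tree and assignment model

K2P distances exclude, per pair, sites where either sequence has a gap or N;
saturation (log argument ≤ 0) raises rather than returning infinity.
Neighbor joining is the standard Saitou–Nei agglomeration with Q-criterion
ties broken by first index. Taxa at distance exactly zero are agglomerated
first into a zero-length multifurcation: their arrangement carries no
signal, and canonicalizing it keeps clades of identical sequences intact
(without this, tie ordering can interleave groups along zero-length edges).
Negative branch lengths are clamped to zero with the deficit moved to the
sibling edge. Bootstrap resamples alignment columns with a seeded generator
and scores each original internal split by the percentage of replicate trees
containing it; saturated replicates are skipped and counted.

Assignment is single-linkage clustering at a K2P threshold: connected
components of the graph d < t, labelled A, B, … by descending size then
first-seen order (the label-to-lineage mapping is arbitrary). A singleton
individual sitting at exactly t from two or more clusters is reported
`unassigned`. The default threshold, 4 × 10⁻⁴, is half the minimum
between-haplotype D-loop distance of the built-in unique-site profiles
(≈ 8 × 10⁻⁴ for a single distinguishing site over the 1,249 bp D-loop); with
zero within-haplotype divergence any value strictly between 0 and that
minimum recovers the generating grouping exactly.

## Phenotype generator and statistics

Per-haplotype defaults are taken from the documented group statistics:
litter and stillborn means/SEMs with the documented sow and litter counts
(per-litter SD recovered as SEM·√n); BCB⁺:BCB⁻ ratio means; stage
probabilities recovered as efficiency-index × litter mean (maturation
78/76/66/72/76%, fertilization 81/83/71/81/85%, blastocyst 20/18/17/14/20%
for A–E); oocyte copy-number means 295,671 (B), 699,867 (D), 410,301 (E)
with documented SEMs, and mid-range defaults of 450,000 (A) and 500,000 (C)
where no value is printed; MII→blastocyst fold changes 6.4 (B), 2.5 (C),
2.2 (D), with 3.0 as the default where unstated. Oocyte cohort sizes
default to 20 MII and 10 blastocysts per haplotype, and 12 ovaries and 150
COCs per haplotype. Litter sizes are rounded normals (litter data in this
design are normally distributed), stillborn counts are clipped to the litter
size, and embryo outcomes are hierarchical Bernoulli draws
(matured → fertilized → blastocyst), so stage rates are conditional as in
the laboratory workflow.

The 16383delC level is linearly coupled to copy number at a configurable R²
(default 0.82). The noise term is standardized against the realized spread
of the cohort's copy numbers, so the configured signal fraction describes
the generated cohort rather than an asymptotic population — at n = 6 group
means the recovered R² then concentrates tightly around the configured
value instead of swinging with the noise draw.

qPCR: Ct = intercept + slope·log₁₀(ng template) + noise over a 9-point
10-fold series from 1 ng/µL; the default slope −3.3219 (= −log₂10) is a
perfectly efficient assay. Quantification inverts the fitted curve and
converts at 660 g/mol/bp; per-sample copies multiply by the
dilution factor, default 25 (2 µL assayed of a 50 µL single-oocyte lysate).
The conversion constant and factor are both configurable since only the
dilution is dictated by the protocol.

Group comparisons follow the study's routing: Shapiro–Wilk at α = 0.05
gates parametric designs (one-way ANOVA with Dunnett-style comparison
against a reference haplotype, or Tukey HSD) versus Kruskal–Wallis with
Dunn's rank post-hoc; each parity is an independent observation, and
reference-group comparisons run against haplotype A. No multiple-testing
correction is added beyond the named post-hoc procedures. Fisher's exact
test is computed by exact hypergeometric enumeration in rational arithmetic
(the two-sided p sums the probabilities of all tables with the observed
margins that are no more probable than the observed table); scipy's
implementation serves as an independent cross-check in the tests, never as
the implementation. Pearson correlations report r, R² and the two-tailed p
from the t transform with n − 2 df.

## Efficiency indices

The developmental-efficiency index is a stage mean divided by the mean
litter size of the haplotype, rounded to 4 decimals for reporting; lower is
more efficient. Computed from printed-precision inputs, haplotype B's BCB
index lands at 0.2788 against a published 0.2779 — the published table was
computed from unrounded inputs — so B is checked at a documented 0.001
tolerance while A, C, D, E reproduce exactly.

## What the generator does not emulate

Flow-space (homopolymer-calibrated) error profiles, PCR chimeras, mapping
reference bias, within-haplotype D-loop micro-variation, nuclear
mitochondrial insertions (numts), and linkage between heteroplasmies.
Passing tests therefore demonstrate the correctness of the filtering and
quantification machinery under clean, known-truth conditions, not robustness
to every artifact of real flow-space data.

## Problem sizes used in the test suite

Caller truth recovery runs at 1000× over the full 16.7 kb genome with
150 bp reads; the end-to-end pipeline test runs at 120× with one individual
per haplotype and 20 bootstrap replicates; haplotype recovery uses 50
D-loop sequences and 100 replicates; the NJ oracle enumerates all 3 + 15
unrooted 4- and 5-taxon topologies; the Fisher oracle covers all 2×2 tables
with margins ≤ 20; correlation recovery uses 200 seeded replicates at
n = 6. All randomness flows from explicit seeds and every generator is
bit-reproducible given (parameters, seed).
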