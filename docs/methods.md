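# Methods

This note documents the models, estimators and numerical choices behind
`equimhc`, and what the synthetic study conditions do and do not emulate.

## Scope and data model

All statistics operate on a `CodonAlignment`: equal-length, frame-trimmed
nucleotide sequences with species/locus tags parsed from record IDs
(`Species|Locus|Allele` by default, configurable regex).  DQB loci carry
the complete 269-bp exon 2; DRB amplicons lack the nine 3'-terminal exon
nucleotides (260 bp), because the locus-specific nested reverse primer
sits on the exon–intron boundary.  Sequences with an internal in-frame
stop codon are flagged on input: they remain in diversity counts
(pseudogene-like variants are still observed variation) but are excluded
from all selection statistics.  Coordinates are 0-based half-open
internally and 1-based in every human-readable report.

## Presence/absence from coverage

The statistic is the non-zero-coverage fraction: the share of a gene's
positions covered by at least one read.  A gene is called absent iff the
fraction is strictly below the threshold (default 0.10, i.e. ≥ 90%
zero-covered bases); the strict inequality follows the "lower than 10%"
reading of the rule.  Depth ≥ 1 counts as covered regardless of mapping
quality — any MQ filtering belongs upstream, in whatever produced the
depth table.  Duplicate depth rows are resolved by maximum (deterministic
and conservative for presence calling).  Reports print integer percents,
rounded half-up.

The statistic cannot distinguish "absent from the genome" from "present
but not captured by the protocol"; calls should be read as absence of
evidence of the region in the sequencing data.

## Allele calling

Amplicon processing mirrors a standard tagged-amplicon workflow:

1. **Demultiplexing** — exact MID prefix match (tags must be mutually
   non-prefix); the tag is clipped; mismatched reads go to an unmatched bin.
2. **Primer sorting** — reads are assigned to the locus whose primer pair
   they match best at ≥ 90% identity (matches/alignment-length, ungapped,
   end-to-end); ties resolve to the first locus in configuration order and
   are logged.
3. **Primer trimming** — leading forward and trailing reverse-complemented
   reverse primer removed, tolerating ≤ 2 mismatches each; untrimmable
   reads are dropped and counted.
4. **Clustering** — greedy centroid clustering at 0.99 identity in
   canonical order (length descending, then lexicographic), followed by
   per-column majority consensus.  Consensus ties resolve by base order
   A < C < G < T with a logged warning, so downstream codon analysis never
   sees ambiguity codes.
5. **Validation** — a candidate becomes an allelic haplotype only with
   ≥ 2 independent sources: two distinct PCR runs, or one PCR run plus one
   of {Sanger trace, clone, genome-derived haplotype}.  No minimum cluster
   size is imposed beyond this rule.  Survivors get Klein-style names
   (species tag + locus + `*` + zero-padded serial, assigned in first-seen
   order, with the mapping emitted).

## Diversity indices

VNP counts alignment columns with ≥ 2 distinct bases; PIP additionally
requires ≥ 2 of those bases in ≥ 2 sequences.  Under the default
complete-deletion policy, columns containing a gap or N in any row are
excluded; pairwise-deletion instead restricts each column to its gap-free
rows.  Published per-locus tables do not state which policy produced them,
so both are first-class and reproduction checks accept either.  Pooled
sub-region rows concatenate the per-locus alignments row-wise (all DRB at
260 bp, all DQB at 269 bp).  Allele sharing reports identical nucleotide
sequences observed in ≥ 2 species/sub-species per locus; identical
sequences at two loci within one species are reported separately as
inter-locus identities (concerted-evolution candidates), never as
trans-species sharing.

## Pairwise dN/dS (NG86) and the global Z-test

Synonymous site counts follow Nei–Gojobori (1986): at each codon position
the synonymous fraction is taken among the single-nucleotide changes that
do not create a stop codon, so every sense codon contributes exactly
3 sites split between S and N.  Differences between codons are averaged
over all orderings of the differing positions, excluding pathways through
stop codons (with an include-all fallback if every ordering were blocked,
which does not occur under the universal code).  Proportions pS = Sd/S and
pN = Nd/N get the Jukes–Cantor correction d = −(3/4)·ln(1 − 4p/3);
proportions at or beyond saturation (p ≥ 0.75) are capped at d = 5.0 and
flagged.  Codons containing gaps, N or a stop in either sequence are
excluded pairwise.

The global test averages dN and dS over all sequence pairs and tests
H0: dN = dS against H1: dN > dS.  The variance of d̄N − d̄S comes from
1000 seeded bootstrap resamplings of codon sites (multinomial column
weights applied to per-pair, per-site count contributions), Z is the
ratio of the difference to its bootstrap SE, and the one-tailed p-value is
the upper normal tail — reported as 1.0 whenever dN ≤ dS or the statistic
is degenerate (no variation, SE = 0).  The per-locus report prints both
the Z statistic and the raw mean difference; the Z statistic is the
column to compare across loci, since the one-tailed normal tail of Z
reproduces the test's p-value exactly.

## Site-wise selection and the consensus rule

Two in-repo methods feed the consensus:

- **Counting (SLAC-style).**  Ancestral codons per site by Fitch parsimony
  on the fixed NJ tree (ties resolved to the lowest codon in lexicographic
  order, logged).  Each branch change is decomposed into synonymous and
  nonsynonymous fractions by NG86 pathway averaging.  The expected
  nonsynonymous fraction per site derives from the NG86 site counts of the
  node states, and observed Nd is tested against it with a binomial tail
  extended to fractional counts through the regularized incomplete beta
  function.  Positive (resp. negative) at one-tailed p ≤ 0.1 with an
  excess (deficit) of nonsynonymous change; the threshold is configurable.
- **Per-site likelihood (FEL-style).**  For each codon site, an MG94×JC
  likelihood on the fixed tree with synonymous rate α and nonsynonymous
  rate β = ωα is profiled over a log-spaced (ω, α) grid
  (ω ∈ [0.05, 20], 13 points + ω = 1; α ∈ [0.02, 15], 12 points); the
  null profiles α at ω = 1.  The likelihood-ratio statistic is referred
  to χ²(1 df).  The grid-profile approximation makes the test mildly
  conservative, which is the right direction for a screen.  Sites with at
  most one distinct observed codon report α = β = 0, p = 1.

A site is a selected amino acid site (SAAS) only when ≥ 2 methods call it
in the same direction.  Externally computed method tables (e.g. from
FUBAR/MEME/CodeML runs) can be ingested into the same consensus; those
methods are not re-implemented.  Reports cross-tabulate observed amino
acid substitutions (majority residue as reference) with ABS membership and
SAAS status, and — when an external predictor table is supplied —
intersect the substitutions flagged deleterious by every tool.

ABS codon positions are a configuration input; `examples/loci.yaml` ships
an example list derived from the human/murine class II structure, not a
definitive annotation.

## Phylogenetics engine

Distances are JC69 on nucleotide columns passing the gap policy, capped at
5.0 substitutions/site at saturation (keeps NJ defined; logged).  Neighbor
joining comes from scikit-bio; negative branch lengths are clamped to zero
with the deficit moved to the adjacent (sibling) branch.  Bootstrap
supports are the percentage of replicate NJ trees (column resampling,
seeded) containing each bipartition of the point-estimate tree.

The likelihood engine is Felsenstein pruning under JC69 with uniform base
frequencies.  Branch lengths are optimized coordinate-wise: under JC the
edge likelihood is linear per site in x = exp(−4t/3), so each edge's
1-D problem is concave in x and solved exactly by safeguarded Newton
iteration.  Partials are refreshed per sweep; a sweep that would decrease
the total log-likelihood (possible because of within-sweep staleness) is
rolled back, so sweeps are monotone.  Convergence is declared below 1e-6
log-units (20 sweeps maximum).  JC69 is deliberately the only likelihood
model: the screens need a likelihood, not a fitted substitution model;
per-alignment model selection is out of scope and a κ extension is noted
as future work.

## Single-breakpoint recombination screen

Candidates are interior codon boundaries keeping ≥ 10 codons per side
(codon boundaries only, so partitions never break the reading frame; the
minimum partition is configurable).  The baseline is an NJ topology with
ML branch lengths on the full alignment; each candidate fits the two
partitions independently (topology re-estimated per partition — a
desk-scale surrogate for genetic-algorithm breakpoint searches).  Model
size is k = number of branch lengths + 1 per tree (topology bookkeeping),
n = alignment sites, and the criterion is
cAIC = −2 lnL + 2k + 2k(k+1)/(n−k−1).  Recombination is declared iff the
best two-partition cAIC is below the single-tree cAIC (ΔcAIC < 0); there
is no secondary significance test.  Within the screen, branch-length
optimization uses a looser convergence threshold (1e-3 log-units, 10
sweeps) than the library default, because the cAIC differences being
compared are orders of magnitude larger.  When a breakpoint is declared,
downstream site-wise selection runs per partition with per-partition
trees.

## Synthetic study conditions

The simulator is an MG94×HKY-style codon process on the 61 sense codons:
single-nucleotide codon exchanges at rate proportional to the target
codon's frequency, ×κ for transitions, ×ω(class) for nonsynonymous
changes.  The mixture over site classes is normalized with one shared
factor (the usual site-class convention), so branch lengths are expected
substitutions per codon averaged over classes and high-ω classes evolve
proportionally faster.  Defaults are κ = 1 and uniform codon frequencies:
NG86 counting assumes no transition/transversion or compositional bias,
so these defaults make ω = 1 simulations exactly neutral for the tested
statistic; κ > 1 is supported and documented as making the Z-test
conservative.

Tree shapes: a fixed 12-tip "equid-like" topology (caballine, ass and
zebra clades) with a deliberately conflicting variant for recombination
experiments, random binary trees, and `allele_genealogy` — a near-star
genealogy with short internal and long terminal branches (terminal mean
0.4, internal mean 0.1 substitutions/codon).  The last is the default
condition for selection-test experiments because long-term balancing
selection keeps MHC allelic lineages segregating far beyond neutral
coalescence, producing exactly such deep comb-like genealogies.
Calibration and power experiments use 20 tips and 90 codons (the scale of
an exon-2 allele panel), with 30% of sites in the elevated-ω class.

Read simulation decorates each allele copy as
MID + forward primer + allele + reverse-complemented reverse primer with
i.i.d. substitution errors on the allele only.  Depth tracks are
Poisson(mean depth) per base with optional dropout for present genes and
< 10% sparse low-depth noise for absent genes.

What the generators do **not** emulate: indels and alignment error,
PCR chimeras, quality-score structure, ancient-DNA damage, codon usage and
GC bias, rate variation within a class, and allelic dropout.  Green tests
therefore certify the estimators and decision rules under their stated
assumptions — not robustness of the laboratory workflow to those artifacts.

## Numerical choices

- JC saturation cap 5.0 substitutions/site; likelihood clamped at 1e-300
  before logs.
- Branch-length optimization: exact per-edge Newton in x = exp(−4t/3),
  t ∈ [0, 8]; lengths below 1e-8 snapped to 0; monotone sweeps with
  rollback.
- Bootstrap and simulation randomness all flow through seeded
  `numpy.random.default_rng`; identical seeds give byte-identical reports.
- Fractional binomial tails via `scipy.special.betainc`; χ² and normal
  tails via scipy.stats.
- Degenerate inputs: invariant alignments give Z = 0, p = 1; invariant
  sites give class "none"; empty depth files give all-zero vectors; N < 2
  diversity cells render as NA (never 0).

## Known limitations

- The likelihood engine is JC69-only; strong base-composition or ts/tv
  bias in real data is absorbed into branch lengths rather than modeled.
- The FEL-style grid bounds ω̂ at 20 and rates at the grid range; extreme
  sites saturate at the bounds.
- The SBP screen fits NJ topologies per partition; with very short
  partitions the topology estimate, not the cAIC rule, limits accuracy.
- Reproduction of published per-locus tables requires the deposited
  sequence data, which the package does not download; the acceptance
  checks for those tables report exactly what is missing.
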