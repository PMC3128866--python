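# Methods

## The study design the package models

The pipeline is built around a four-genotype floral-transcriptome
comparison: an outcrossing genotype (heterozygous at many loci), two
independently derived selfing genotypes of the same species
(near-homozygous), and a selfing outgroup species. Because no genome
reference exists, each genotype's reads are assembled separately and a
consensus reference transcriptome is constructed from the per-sample
contig sets; reads are then mapped back to that consensus for genotype
calling, paralog screening, population-genetic summaries and
expression analysis.

## Synthetic-data generator

`floratx.simulate` draws an ancestral transcriptome (log-normal locus
lengths, mean ≈ 900 bp, minimum 200 bp) and evolves it down the study
phylogeny under a Jukes–Cantor-like substitution model (uniform random
base changes, no indels — the downstream grouping criteria are all
identity-based, and keeping the process ungapped makes alignment
oracles exact).

Key parameters (defaults in parentheses):

- **intraspecific divergence** (0.010/site): each ingroup genotype is
  mutated from the ingroup ancestor at *half* this rate so realized
  *pairwise* ingroup divergence matches the setting. An optional
  topology flag makes selfer2 sister to the outcrosser to model a more
  recent split.
- **interspecific divergence** (0.048/site): outgroup branch rate.
- **heterozygosity rates** (0.20 of loci for the outcrosser, 0.05 for
  selfers; 1 + Poisson(2) het sites per heterozygous locus). No
  quantitative per-mating-system rates are established for this system;
  these defaults are chosen to reproduce the qualitative ordering
  outcrosser ≫ selfers, which is the property the pipeline tests.
- **paralogy** (5% of loci duplicated at 97% family identity):
  duplication precedes speciation, so both copies are present in every
  genotype. Paralogs drive the mis-mapping signal the SUSPECT flag
  detects.
- **reads** (40 bp paired ends, fragment length N(200, 20), 20× mean
  coverage): fragments are sampled per locus proportional to expression
  weight × length; base qualities follow a deterministic Q38→Q15 decay
  with ±2 noise, and sequencing errors are drawn consistent with the
  emitted qualities, rescaled so the overall error rate equals the
  configured value (0.01). A zero error rate yields error-free reads.
- **expression** (log-normal, meanlog 3.0, sdlog 1.2 on the FPKM
  scale): per-genotype weights share a locus effect plus genotype noise
  (σ = 0.3 for ingroup, 0.8 for the outgroup), so ingroup expression
  correlations exceed outgroup ones by construction.
- **assembler artifacts**: 5% of loci fragmented into two overlapping
  contigs, 5% emitting a second >99%-identical allelic contig, plus
  short (<100 bp) junk contigs.

What the generator does *not* emulate: indels and structural variation,
alternative splicing, platform-specific error motifs, coverage biases
(GC, positional), and assembly errors beyond fragmentation/duplication.
Passing tests therefore demonstrate correctness of the analysis logic
under the stated model, not robustness to every artifact of real data.

## Consensus construction

Local similarity search is an internal seed-and-extend aligner: exact
16-mer seeds on both strands, per-diagonal ungapped extension taking
the maximal-scoring contiguous segment under match +1 / mismatch −2
(found exactly by a maximum-subarray scan). Because extension is
ungapped, identity agrees with a full dynamic-programming aligner on
indel-free instances — which the generator guarantees — and any pair
sharing a ≥95%-identity region of ≥32 bp contains an exact seed.
Best-hit ranking uses the segment score; ties break to the
lexicographically smallest subject. BLAST outfmt-6 tables can be
ingested in place of the internal aligner.

Design choices where the procedure was genuinely open:

- Redundancy collapse keeps the **longer** contig of a qualifying pair
  (ties by id) and is applied transitively per connected component,
  making it idempotent and input-order independent.
- "Found in more than two samples" is implemented as *at least two
  samples* (`min_samples=2`, configurable to 3): pairwise RBH
  naturally produces two-member groups and the grouping criteria
  already guard specificity.
- Groups keep ≤1 member per sample; transitive-closure conflicts keep
  the member with the highest total RBH score, returning losers to the
  leftover pool.
- Group consensus stacks members at their anchor diagonal offsets
  (valid because members are ≥90% identical and ungapped), takes
  per-column majority, breaks ties toward the longest member, and
  keeps every member's overhang.
- "No unalignable segments" for extensions is operationalised as: the
  aligned block must reach within 5 bp of both ends of the mutual
  overlap; mismatch-only interruptions are absorbed by the scoring,
  whereas a ≥30 bp unalignable insert truncates the block and fails
  the check.
- Fragment joining translates consensuses in six frames, screens
  against an amino-acid 5-mer index of the guide proteins, aligns the
  top candidates with a local protein aligner, and joins fragments
  whose guide intervals overlap by ≤15 residues, inserting an N spacer
  of 3× the residue gap.
- The singleton criterion — a guide hit of ≥50 aligned residues at
  ≥60% identity for contigs ≥1000 bp — is a deliberate stand-in for an
  E-value threshold; it selects contigs with credible protein homology
  without E-value machinery.

## Genotype calling

The mapper places each read at its minimal-mismatch ungapped position
(both strands) within a budget of ⌊0.05·len⌋ + 1 mismatches; reads
with two or more equally good placements are excluded as ambiguous
rather than randomly placed, keeping pileups deterministic. Diverged
paralog copies — the biologically relevant failure mode — still map
uniquely onto the single reference copy, carrying their divergent
bases into the pileup. SAM files from an external aligner can be
ingested instead.

Site calls use the likelihood P(b|XX) = 1−ε or ε/3, P(b|XY) = the
average of the homozygote likelihoods, a heterozygote prior of 10⁻³
shared uniformly over the six heterozygous genotypes (configurable;
no mapping-quality weighting, since the mapper emits unique-best
placements only). Calls require coverage strictly >5 and consensus
quality Q strictly >13; loci require mean coverage >5 to count as
present. Heterozygous calls are written as IUPAC codes, ambiguous
sites as N.

Loci heterozygous in ≥2 selfing genotypes are flagged SUSPECT; loci
present in ≤1 selfer are UNTESTABLE. At the default 97% family
identity the flag catches ≈87% of paralogous loci (measured over 10
seeds); the misses are mostly families whose divergent sites cluster
such that mis-mapping reads exceed the mismatch budget.

## Population genetics

The conservative set demands presence in all four samples and zero
heterozygous sites in every selfer. Pairwise SNP counting compares
only sites unambiguous and homozygous in both samples (heterozygous
outcrosser sites are excluded rather than scored as half differences;
a half-difference convention is available). θ_W counts segregating
sites over columns unambiguous in all n samples.

A known bias: the consensus is majority-weighted toward the three
ingroup genotypes, so outgroup reads covering highly diverged windows
exceed the mismatch budget and drop out. The called outgroup
divergence is therefore depressed (≈0.035 at a generating 0.048) —
classic reference bias. Orderings (outgroup ≫ ingroup) are unaffected
and are what the tests assert.

## Expression

FPKM = count·10⁹/(length·total fragments), with one fragment per read
pair mapped to a single locus (pairs split across loci are discarded
and logged). Correlations use Pearson r on log FPKM over loci with
positive FPKM in both samples (log of zero is undefined; a pseudocount
path exists). Bootstrap CIs are percentile intervals over locus-level
resamples, 10,000 replicates by default; empirical coverage of the
95% interval is 92–96% in the package's own simulation.

Differential expression replaces a transcript-level Bayesian model
with an exact two-sided binomial test of each locus's fragment split
against the expected proportion totalA/(totalA+totalB), followed by
Benjamini–Hochberg correction at FDR 0.05 — the same per-locus
decision contract with a simpler, exactly testable statistic.
Fold change is the FPKM ratio (flagged when infinite). GO enrichment
is a per-term two-tailed Fisher's exact test (sum of all tables no
more probable than the observed) with BH correction; the term map is
taken as given, pre-propagated.

## Numerical and scale choices

- All randomness flows from a single integer seed through
  `numpy.random.default_rng`; stage outputs are byte-deterministic.
- The acceptance suite and reproduction script use problem sizes
  chosen to exercise every property at comfortable statistical power
  on a single CPU: 10,000 simulated sites for caller concordance, 10
  seeds × ~9 families for paralog sensitivity, 20 replicates for θ_W
  recovery, 200 datasets × 2,000 resamples for bootstrap coverage,
  1,000 loci for the DE null, a 120-locus end-to-end smoke run and a
  150-locus pipeline pass in the script.

## Known limitations

- Ungapped alignment throughout: real indel variation would break the
  anchor-diagonal consensus stacking and the mapper; the generator
  correspondingly omits indels (a gapped path is out of scope).
- No mapping-quality model; multi-mapped reads are discarded, so
  perfectly identical repeats receive no coverage at all.
- E-value semantics are approximated by identity/length thresholds.
- The enrichment stage annotates consensuses via their best guide
  protein; loci without a guide hit are invisible to enrichment.
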