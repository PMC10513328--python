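# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `snpanchor`. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Probe placement

Array probes (~50–100 bp of flanking sequence around one SNP) are located
on the consensus genome with a deterministic two-stage search: exact k-mer
seeding of every probe k-mer against a prebuilt genome index (both
strands), then full-length *ungapped* extension of each candidate offset
scored by identity (matches / probe length, with genome N never counting
as a match). The location(s) of maximal identity at or above
`min_identity` decide the outcome: one maximum → `unique`, several →
`ambiguous`, none → `unplaced`. Ambiguous probes are never resolved
arbitrarily; their loci simply stay uncalled, the conservative choice for
downstream comparison.

Parameters: `k = 21` (a 21-mer is effectively unique in a non-repetitive
region and guarantees a seed whenever the probe and genome disagree at
most every ~20 bp; for probes with up to 3 mismatches in 70 bp a run of at
least ⌈67/4⌉ = 17 exact bases always exists, so k ≤ 17 makes seeding
provably complete under that mutation load) and `min_identity = 0.95`
(tolerates a couple of consensus errors plus the SNP allele itself while
rejecting paralogous near-matches). Full probe coverage is required; gapped
or spliced placement is out of scope.

The test suite checks the engine against an exhaustive both-strand
Hamming scan over every genome offset — an oracle that shares no code with
the seeded path.

SNP projection is pure coordinate arithmetic on 0-based, half-open
intervals: `snp_pos = start + snp_offset` (plus strand) or
`end − 1 − snp_offset` (minus strand).

Uncalled loci can be clustered into chromosome regions by single linkage
with a configurable gap (`max_gap`, default 10 Mb): runs of consecutive
sorted positions closer than the gap merge into one region. This flags
contiguous stretches where calling failed systematically — a signature of
missing coverage or structural variation rather than scattered probe
failure.

## Genotype extraction and pseudomolecules

The genome is a consensus sequence, so each extracted call is a single
base. Minus-strand hits are complemented so all calls are in chip
orientation, directly comparable with panel genotypes (the panel is
assumed to be chip-oriented). A genome N yields a missing call; a base
matching neither chip allele nor their IUPAC heterozygote letter is an
`allele_mismatch` and is reported as N by default (`--keep-mismatch`
preserves the raw base). Treating mismatches as missing reflects the view
that a consensus base disagreeing with both known alleles is more likely a
placement or consensus artifact than a genuine third allele.

The pseudomolecule is the concatenation of one character per panel locus
in the panel's fixed locus order, N-padded at uncalled loci. Because every
accession's pseudomolecule has the same length and locus order, multiple
sequence alignment is the identity map and is skipped: distances are
computed positionally. Locus dropping is deliberately deferred to the QC
stage.

Call-rate summaries round percentages half-up to two decimals and compute
the uncalled percentage as 100 minus the called percentage, so the pair
always reconciles exactly.

## Distances, neighbor joining, bootstrap

The distance is the p-distance over pairwise-complete sites: for each
accession pair, sites where either call is N are dropped and the distance
is mismatches / comparable sites. Two comparison modes exist:

* **strict** (default): calls compared as literal characters; a
  heterozygote mismatches its constituent homozygote. This is the natural
  metric for the mostly-homozygous inbred material the pipeline targets.
* **allele-aware**: calls expand to diploid allele pairs and the per-site
  distance is 1 − shared/2, so het vs constituent homozygote counts 0.5.

Pairs with fewer than `min_sites` (default 50) comparable sites are an
error naming the pair — too little overlap makes the distance meaningless.

Neighbor joining follows the Saitou–Nei agglomeration: at each step the
pair minimizing Q(i,j) = (n−2)·d(i,j) − Σₖd(i,k) − Σₖd(j,k) is joined,
limb lengths come from the standard formulas, and distances to the new
node from the reduction formula. Ties in Q are broken by the lowest
(row, column) pair in the working matrix and joined rows are replaced
deterministically, so the output is bit-identical across runs and
invariant to label order except at documented ties. Negative limb lengths
are clamped to zero and logged. On additive matrices NJ provably recovers
the generating topology and branch lengths; the suite verifies this on
random additive 5–8 taxon matrices (Robinson–Foulds 0, lengths to 1e−9)
with dendropy-simulated reference trees as the oracle.

Bootstrap supports resample loci with replacement (default 1,000
replicates, explicit seed), recompute distance + NJ per replicate, and
score each internal bipartition of the original tree by the percent of
replicates containing it. Replicates in which some pair has zero
comparable sites are skipped with a warning and excluded from the
denominator. Newick output stores supports as internal node labels and
branch lengths at 6 significant digits; the parser reports the character
index of any syntax error.

## Identity-by-state duplicate QC

Stages, in order: (1) remove accessions with more than 10 % missing
calls; (2) remove markers with heterozygote fraction above 0.1 or a
Hardy–Weinberg chi-square p-value (1 df, no multiple-testing correction)
below 0.05; (3) LD-prune with a sliding window (50 loci, step 5): while
any retained pair in the window has r² above 0.8 — squared Pearson
correlation of minor-allele dosages over pairwise-complete entries — the
lower-MAF member is removed (tie: the later locus); an undefined r² (zero
variance) prunes as if r² = 1, since an uninformative marker cannot be
shown independent; (4) call duplicates: accession pairs whose homozygous
difference (fraction of differing calls among sites where both are
homozygous) is *strictly* below 0.001 become edges, duplicate groups are
the connected components, and the first member in input order represents
each group. A `filter_order` switch swaps stages 2 and 3; a `het_scope`
switch applies the heterozygosity threshold per genotype instead of per
marker. Window and step have no published reference values and are this
package's defaults; all thresholds are exposed in `QCConfig`.

**Known limitation — small panels.** The marker filters interact sharply
with sample size. In a panel of six fully homozygous genotypes no
polymorphic marker can pass stage 2: a single heterozygote already gives
het fraction 1/6 > 0.1, while zero heterozygotes at a polymorphic marker
give χ² = n = 6 (p ≈ 0.014 < 0.05). Only in-sample monomorphic markers
survive, and those cannot separate any pair, so the full chain collapses
such a panel to one genotype. Duplicate calling on small sets should
therefore be run on a marker set filtered in a larger panel (or with the
filters relaxed); `find_duplicates` accepts any matrix that has already
passed marker QC. An exact HWE test (which passes singleton markers at
n = 6) would behave differently; the chi-square test is the documented
choice here.

## Descriptor PCA

CPVO/UPOV descriptors are ordinal scores with heterogeneous ranges, so
the default standardizes each descriptor (correlation PCA); `--no-scale`
switches to covariance PCA. The decomposition is an SVD of the centered
(scaled) matrix; variance explained is σᵢ²/Σσ². Component signs follow a
fixed convention (largest-magnitude loading positive) so outputs are
comparable across runs. Biplot arrows are loadings scaled by the singular
values raised to a configurable exponent (default 1). An independent
eigendecomposition of the covariance/correlation matrix and scikit-learn's
PCA serve as test oracles.

## Synthetic data

All generators are pure functions of an explicit seed
(`numpy.random.default_rng`; no global state), so fixtures are
bit-reproducible.

* `make_genome` — uniform random A/C/G/T chromosomes.
* `implant_probes` — writes random probe footprints into the genome at
  recorded non-overlapping positions and strands; the genome carries a
  randomly chosen true allele at each SNP site and up to a configured
  number of substitutions away from it. With zero noise, placement,
  projection and extraction recover every implant exactly (verified
  end-to-end).
* `simulate_panel` — per-locus biallelic genotypes from stated allele
  frequencies with configurable heterozygote and missing rates (default
  het 0.05, missing 0.02 — inbred-like material), or at Hardy–Weinberg
  proportions (`hwe_genotypes`) when an outcrossing-like panel that
  survives the HWE filter is needed. Duplicate pairs copy a row and flip
  an exact count round(noise × homozygous sites) of homozygous sites to
  the other allele, so the realised homozygous difference equals the
  requested fraction deterministically (a Bernoulli per-site flip would
  make the sub-0.1 % criterion a coin toss at realistic locus counts).
  Divergent pairs are built the same way at a higher noise level (default
  5 %) to provide near-boundary negatives.
* `simulate_descriptors` — multivariate-normal scores with a full
  covariance, an eigenvalue list (randomly rotated), or identity;
  optionally rounded onto a 1–9 ordinal scale.

Default sizes mirror a realistic chip study at roughly one tenth
(~350 loci, 26 accessions, 10–50 kb genomes) so the full suite runs in
well under a minute of simulation time. What the synthetic data does *not*
model: genome repeat structure and paralogy (placement ambiguity is
exercised only through explicit constructions), realistic wheat LD maps
(LD-pruning counts are therefore structural, not calibrated), genotyping
error beyond the controlled flip model, and population structure in the
panel. Passing tests demonstrate algorithmic correctness on known truth,
not performance on repeat-rich real genomes.

## Acceptance measurements

`scripts/acceptance.py` recomputes, from scratch under `--seed`:
placement agreement with the exhaustive scan (5 genomes × 100 mutated
probes, k = 17 for provably complete seeding), the scaled pipeline
(350 probes on 2 × 50 kb, 26-accession panel + query, 1,000 bootstrap
replicates), the panel-scale call-rate summary for a 3,541-locus chip
with 32 uncalled loci, NJ recovery over 200 random additive matrices,
the Hardy–Weinberg worked example (30/40/30), duplicate sensitivity and
specificity over 50 seeded panels, the six-genotype retention structure
(two duplicate pairs + two singletons → four retained), and PCA variance
reporting on a descriptor table constructed with a prescribed leading
spectrum (25.2 % / 20.6 %; the construction whitens a seeded draw so its
sample covariance equals the target exactly, making the reported
fractions a genuine recovery check of the PCA code). The retention and
spectrum inputs are synthetic stand-ins for unavailable survey data and
are labelled as such where they are generated.
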