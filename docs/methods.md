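# Methods

This note records the statistical model behind `picara`, the parameters
that matter, the design decisions taken where the method left room, and
what the synthetic fixtures do and do not demonstrate.

## Model and assumptions

The pipeline treats a panel of homozygous inbred lines as a set of observed
haplotypes: every genotype call is one allele, heterozygous IUPAC codes are
treated as missing by default (a `reject` policy is available for panels
where heterozygosity indicates a data problem). Coordinates are 1-based
inclusive; distances are absolute differences of point coordinates; a
gene's position is its integer interval midpoint.

### Pairwise LD

r² between two biallelic loci is D²/(p_A p_a p_B p_b) from the 2×2
haplotype count table over lines non-missing at both loci
(pairwise-complete observations). Pairs with fewer than `min_informative`
(default 4) shared lines are dropped — with only 2–3 informative
haplotypes, r² = 1 arises constantly by chance and would corrupt the
perfect-LD block machinery. "Perfect LD" is tested as r² ≥ 1 − 1e-9.
An optional `max_pair_distance` cap bounds the O(n²) pair enumeration;
it is an efficiency device and must simply exceed the LD range of
interest (analyses here use 500 kb at 5,000-SNP-per-chromosome density
and 50 kb where planted blocks span ~2.5 kb).

### Linkage blocks

The chromosome-scale block size is the median (the 90% quantile is also
reported) of distances between all SNP pairs at r² ≥ the threshold,
default 1.0. Per gene, the anchor set S_k is the SNPs inside the gene plus
the single nearest flanking SNP per side ("flanking" is deliberately
minimal; `n_flank` generalises it). The local block is the hull of the
gene interval, the anchors, and every same-chromosome SNP in perfect LD
with an anchor — so blocks are asymmetric where LD is asymmetric, and the
block always contains the gene. When no anchor has a perfect-LD partner
(SNP-poor regions), the block falls back to the gene's chromosome median
width, centred on the gene center; a `genome` scope switches the fallback
to the median over chromosome medians. Inter-chromosomal r² = 1 pairs,
which arise in small synthetic panels, are ignored.

### Co-localization posterior

For gene k, the empirical distribution of d_i = |pos_i − center_k| over
*all* chromosome SNPs is the yardstick for "how far is far" under that
chromosome's SNP geography. The co-localization probability for an
association at distance d is the survival value (#{d_i ≥ d})/n: 1 at the
gene center, non-increasing, 0 strictly beyond the farthest SNP. The
direction (nearer ⇒ higher probability) is required for the block filter
to *eliminate unlinked signals* rather than reward them.

Significant associations on the chromosome are ranked by significance
(RIMP count descending, or p-value ascending; ties share mean ranks) and
given reverse-rank normalised weights

    w_m = (r_max − r_m + 1) / Σ_j (r_max − r_j + 1),

which sum to 1, decrease with rank, and avoid over-emphasising any single
signal; all insignificant loci are treated the same (weight 0). The
posterior for gene k is Σ w_m · P_coloc(d_m) over significant associations
whose position lies inside the gene's linkage block. Both the weight form
and the weighted-sum posterior are reconstructions constrained to the
method's verbal requirements (probability scale, rank-monotone, ties
symmetric); each is isolated behind a single function so alternatives
(e.g. 1 − Π(1 − w·P)) can be swapped in.

### Permutation calibration

Per gene, 1,000 permutations re-draw one SNP locus per association without
replacement from the chromosome's loci and re-attach the observed
significance multiset to the drawn positions; weights depend only on that
multiset, so only positions move. The observed block and distance
distribution are held fixed: the permutation asks where the observed
signal strengths could have landed, not what the genotypes could have
been. perm_p uses the add-one estimator (1 + #{null ≥ obs})/(n_perm + 1),
never zero. The reported `perm_threshold` is the 95th percentile of the
null posterior distribution — the 5% significance tail on the posterior
scale, where *larger* posteriors are more extreme (the analogue, for a
posterior statistic, of taking the 5% quantile of a null of minimum
p-values). A gene "passes" co-localization when perm_p ≤ 0.05.

### Enrichment score

With S_t SNP loci and G_t significant associations on the chromosome, a
block holding x_i loci expects μ_i = x_i·G_t/S_t associations by chance.
The score is

    E_i = log10(g_i / μ_i)              g_i ≥ 1
    E_i = log10(c / (μ_i + c)), c = 0.5  g_i = 0
    E_i = 0                             x_i = 0,

where g_i counts significant in-block associations, and only when the gene
passed its co-localization permutation ("also significantly co-locating"
is operationalised per gene, not per association). The g_i = 0 continuity
branch keeps the score finite and non-positive — an empty or miss-only
block can indicate depletion, never enrichment — and is strictly below the
g_i = 1 value for every μ, so monotonicity in g_i is preserved. The
familiar alternative of adding ½ to all four counts was rejected: when the
chromosome-wide rate G_t/S_t is of order 10⁻⁴, a ½ pseudo-count on a
small block dominates the ratio and assigns strongly *positive* LOD to
genes with zero hits, which both inverts the depletion sign and makes a
random pseudo-candidate control impossible to pass.

The null randomizes association positions uniformly without replacement
while retaining their number, making the null g_i exactly
Hypergeometric(S_t, G_t, x_i); a closed-form `method="exact"` path uses
the scipy hypergeometric tail and is cross-checked against the sampler in
the tests. Significance: E_i ≥ 2 (LOD scale) **and** randomization
p ≤ 0.05, both defaults exposed. S_t and G_t are per-chromosome (a
genome-wide mode is off by default). The pseudo-candidate control reports
the mean of max(E_i, 0) over a random gene set (flooring so depletion
cannot mask enrichment; a raw-mean flag exists).

## Randomness and determinism

One root seed drives everything. Per-gene generator streams are derived
from (seed, CRC32(gene_id)), so results are bit-reproducible and invariant
to gene processing order. Without-replacement draws use duplicate-rejection
when k² ≪ S and random-key selection otherwise; both are exact samplers of
the uniform distinct-tuple law.

## Synthetic fixtures: what they emulate, what they don't

The generator plants perfect-LD blocks by giving every block SNP one
shared genotype column (up to allele relabeling) — exactly the structure
the r² = 1 estimator assumes — with background columns independent
(background r² ≈ 1/n_lines; r² = 1 would require two identical 200-line
columns, probability ~2⁻²⁰⁰). RIMP counts follow a truncated geometric on
{2..15} with an insignificant class at RIMP 1 (probability 0.35); allelic
effects are N(0, 0.1) days, matching a many-small-effects regime. Planted
(enrichment-carrying) associations draw their RIMP from the significant
range — planting a signal means planting a significant one. Associations
sit on MAF-passing loci, placed uniformly without replacement apart from
the planted ones; this is the same law the permutation nulls assume, which
is precisely what makes the calibration experiments interpretable.

Two standard designs encode the study conditions:

* **Null calibration** — ten 50-Mb chromosomes × 5,000 SNPs (25 planted
  blocks of 25 SNPs over 150 kb each), 50 genes per chromosome (half
  anchored in blocks, half background), 150 uniform associations per
  chromosome, 1,000 permutations. 500 genes give the 5% rejection rate a
  Monte-Carlo SE of ~1%, and block/association densities are chosen so
  that the posterior's point mass at zero stays below the 95% null
  quantile — otherwise the permutation test is conservative by
  construction and a calibration experiment would only measure that.
* **Planted enrichment** — ten 250-Mb chromosomes × 100,000 SNPs, one
  50-SNP block of ~2.5 kb per chromosome hosting one enriched gene with 6
  planted significant associations out of 20 per chromosome
  (E ≈ log10((6/50)/(20/100,000)) ≈ 2.8), plus 100 random
  pseudo-candidate genes as the negative control.

What passing these fixtures does **not** show about real data: no LD decay
with distance (blocks are exactly rectangular), no population or family
structure, no relation between genotype and significance (RIMP values are
simulated, the GWAS itself is out of scope), and association placement
that matches the permutation null by construction — real GWAS signals
cluster with gene density and recombination landscape, so real-data
calibration is expected to be conservative rather than exact.

## Numerical choices and degenerate inputs

* r² is clipped to [0, 1] against ~1e-15 float overshoot; oracle agreement
  is asserted to 1e-12.
* Monomorphic-after-missing pairs (zero denominator) are omitted, not 0.
* Even-count medians use the midpoint convention; fallback bounds are
  half-open reals so the block width equals the median exactly.
* A gene on a chromosome with no SNPs is skipped with a warning at the
  pipeline level (reported as `skipped`, never silently dropped); an empty
  anchor set with no partners falls back like any SNP-poor gene.
* Association tables must reference genotyped loci (by snp_id, else by
  chromosome+position); conflicts raise rather than repair.
* The statistical acceptance tests hold each Monte-Carlo comparison to
  2 standard errors and, where many independent settings are checked at
  once, allow the binomially expected number of exceedances rather than
  demanding a simultaneous 2-SE pass, which a correct implementation
  would fail most of the time.

## Known limitations

* The weight, posterior and enrichment formulas are reconstructions of a
  verbally specified procedure (see above); alternatives are pluggable.
* Permutations hold the observed block and distance distribution fixed;
  re-estimating blocks per permutation would require permuting genotypes,
  a different (and much more expensive) null.
* No multiple-testing correction is applied across genes beyond the
  per-gene permutation; the candidate list is assumed a priori.
* D′, LD-decay fitting, Gabriel-style chromosome-wide haplotype blocks,
  genotype imputation and VCF/PLINK ingestion are out of scope.
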