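# Methods

## Coordinate conventions

Genome positions are 1-based inclusive. Gene-local coordinates place the
first base of the start codon at 0, negative upstream; for a minus-strand
gene the translation start is the higher CDS coordinate and gene-local
coordinates run against the contig. All promoter windows, motif distances
and planted-motif positions use this convention. One CDS interval per gene
(bacterial annotation); multi-exon genes are out of scope.

## Identity metric and promoter scan

The binding-site consensus is a 22-mer whose central 4 positions (1-based
10–13) are excluded from comparison: identity = 100 · matches / 18, rounded
half-up to one decimal. Consequences used as test invariants: self-identity
is exactly 100.0, a mutation at an excluded position never changes the
score, and each additional non-excluded mismatch costs exactly one 1/18
step (≈5.56 points). A `denominator="full"` switch divides by 22 instead,
since published tables of this kind are not always internally consistent
about the rule.

The scan window defaults to 300 nt upstream through 150 nt downstream of
the translation start, truncated at contig ends. Every 22-nt frame is
scored forward and (by default) as its reverse complement; the distance
reported is the gene-local coordinate of the frame's 5'-most base. Per
gene, the single best hit is kept: highest identity, ties by smaller
|distance|, then '+' strand. A hit's `matched_sequence` is stored in
consensus orientation so re-scoring it reproduces its identity — for
'-' hits this is the reverse complement of the gene-oriented frame.

The PWM is built from the single consensus sequence with pseudocount 0.25
and uniform background: cell (p, b) = log₂(((count + 0.25)/2)/0.25), i.e.
log₂ 2.5 for the consensus base and log₂ 0.5 otherwise; the log-odds score
sums over non-excluded positions. Identity, not the PWM, drives hit
selection, because identity is the statistic such studies print; the PWM
score is reported alongside.

Gapped comparison (for motifs printed with single indels) does a global
alignment with match +1, mismatch 0, gap −1, at most one indel, by
exhaustive enumeration of gap placements (22 candidates — no DP needed at
this size, and the brute-force enumerator doubles as the test oracle).
Identity keeps the /18 denominator with a gap column counting as a
mismatch. Ties between equal-scoring gap placements resolve to the leftmost
gap; inside a homopolymer run the choice is arbitrary and score-neutral.

Background matches are a real phenomenon: in a random 60.6 %-GC genome the
expected number of ≥16/18-identity frames across a default 120-gene
scenario is ~10⁻³ per scan, so exact planted-truth checks scan at a 90 %
threshold (which background frames essentially cannot reach) while the
default reporting threshold is 50 %, the lowest identity such studies
print.

## Differential expression

The test is a deliberately simple, fully documented replacement for
black-box RNA-Seq differential-expression machinery:

- **Size factors**: median-of-ratios against the geometric-mean reference,
  computed over genes with no zero count; falls back to total-count scaling
  when fewer than 10 such genes exist.
- **Dispersion**: per-gene method-of-moments φ̂ = max(0, (s² − m̄)/m̄²) on
  normalized counts, pooled across the two conditions by residual df
  (`estimate_dispersion`). With 3+3 replicates this per-gene estimate has
  only 4 residual df; plugging it into a Wald test gene by gene inflates
  the type-I error severely (measured ≈0.13 at nominal 0.05). The test
  therefore defaults to a **common dispersion**: the across-genes mean of
  the *unclipped* per-gene estimates (clipping first would bias it upward).
  This is the classic common-dispersion compromise for small-replicate
  designs; with it the measured type-I error is ≈0.05 on a 2000-gene null.
  A `dispersion_mode="per-gene"` switch restores the per-gene estimates.
- **Wald test**: two-sided normal test of log μ̂_mut − log μ̂_wt on
  normalized-count condition means, delta-method variance under
  var = μ + φμ², a 0.5/n continuity floor on means so one-sided zeros stay
  finite, p = 1 by convention for all-zero genes and exactly equal means.
  No small-sample t correction is applied; the normal reference at n = 3 is
  part of what the type-I calibration check verifies.
- **FDR**: Benjamini–Hochberg step-up (via statsmodels), validated against
  the hand-computed example p = (0.01, 0.02, 0.03, 0.04) → q ≡ 0.04.
- **Fold change**: log₂((mean FPKM_mut + 0.5)/(mean FPKM_wt + 0.5)) with
  FPKM = count·10⁹/(length·library total). The 0.5-FPKM pseudocount avoids
  infinities; set it to 0 for exact ratio arithmetic.
- **Classification**: up/down require q < α (default 0.05) and
  |log₂FC| > `lfc_threshold` (default 0, i.e. significance alone — observed
  regulon tables contain significant genes well below a 2-fold-change
  cutoff); a stricter threshold is one keyword away.

**Known limitation — FPKM composition bias.** FPKM normalizes by the total
count, so when a large, direction-unbalanced share of the library is
differentially expressed the fold changes shift by −log₂ of the total
ratio (clearly visible in the default scenario, where 25 % of genes are DE
and mostly up). The *test* is unaffected — it runs on median-of-ratios
normalized counts, which are robust to sparse DE — but reported log₂FC
magnitudes are compressed under heavy asymmetric DE. The fold-change
recovery test therefore uses a sparse-DE design (≈7 % DE), the regime the
estimator is meant for.

## COG summaries and regulon integration

Compound COG labels ("NT", "EP", …) increment every constituent letter's
up/down counts, while the classification rate counts each gene once. The
regulon join takes the DE table and the best-hit-per-gene scan table, keeps
significant genes only, marks a gene *direct* iff it has a qualifying hit,
and sorts by COG then |log₂FC|. The repressor score is the fraction of
direct targets up-regulated in the mutant; >0.5 reads "predominantly
repressing". There is no principled universal identity threshold for
"direct"; the scan threshold is explicit, configurable and recorded in the
run manifest.

## Phenotype statistics

Autoaggregation % = 100·(1 − A₂/A₁); negative values (upper phase denser
after settling) are reported, not clamped. Doubling time is 1/slope of a
least-squares fit of log₂(CFU/ml) vs time — base 2 so the slope is directly
in doublings per hour — with r² reported; a nonpositive slope is an error
("no exponential growth"). By default all points are fitted; `window=(lo,
hi)` restricts to a time range, and `window="auto"` picks the contiguous
run of ≥4 points maximizing r² (longer runs win ties), for curves with a
lag phase. The growth simulator applies unit-mean lognormal noise of a
given coefficient of variation to an exact exponential (9 h sampled every
30 min by default, matching plate-count practice); the aggregation
simulator adds truncated Gaussian noise to A₂.

## Synthetic data: what it emulates and what it does not

Generators are pure functions of (parameters, seed). Defaults describe the
study shape the pipeline targets:

| parameter | default | rationale |
|---|---|---|
| GC content | 0.606 | rhizobial genome GC |
| genes / layout | 4 contigs × 30 genes, 900-nt CDS, 600-nt intergenic | window always fits; strands alternate |
| replicates | 3 + 3 | typical bulk design |
| base means | log-normal, median 1000, σ = 1 | median reads/CDS ≈ 1000 |
| dispersion φ | 0.05 | moderate biological variability |
| DE fraction / up-fraction | 0.25 / 0.632 | regulator-knockout shape, mainly repressing |
| |log₂FC| | uniform 2–5 | clear effects; DE base means floored at 200 |
| library sizes | log-normal, sd 0.1 | exercises normalization |
| COG labels | uniform over 20 classes, 89.5 % classified | realistic classification rate |
| planted motifs | 18 % of DE genes, ≤2 mismatches, uniform distance in window | direct-target subset |

The configured up-fraction is applied exactly (round(0.632·n_DE) genes up)
rather than drawn binomially: it is a design quantity of the scenario, and
recovery tests then measure only the pipeline's error, not the generator's
sampling noise. NB sampling uses gamma–Poisson mixing; φ = 0 degenerates to
Poisson.

Not emulated: read-level artifacts (the pipeline starts from counts),
operon structure and correlated expression, mean-dependent dispersion
trends, overlapping genes, ambiguous bases. Passing planted-truth tests
therefore demonstrates correctness of the statistics and coordinate
handling, not robustness to mapping artifacts or annotation errors.

## Problem sizes used in the checks

The calibration and recovery checks run at 2000 genes (type-I error, 300
planted DE genes for recovery), 120-gene scenarios for end-to-end scans,
and 500 seeded growth curves — sizes at which the binomial/MC error bands
quoted in the tests are meaningful for a desk-scale run.
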