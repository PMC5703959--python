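# Methods

## The estimator

Given N SNPs shared by two GWAS, with p-values `p1` (principal trait) and
`p2` (conditioning trait), the per-SNP conditional empirical cdf is

    ccdf_i = #{j : p1_j <= p1_i and p2_j <= p2_i} / #{j : p2_j <= p2_i}

and the conditional FDR estimate is `cFDR_i = min(1, p1_i / ccdf_i)`.
Rationale: under the principal-trait null, `P(P1 <= p1 | P2 <= p2) = p1`
when the traits are independent; the ratio of the observed conditional cdf
to that null value estimates the posterior odds of non-nullity, and
`p1 / ccdf` is the standard empirical plug-in for the FDR among SNPs at
least as extreme in both coordinates. The estimator is model-free (no
parametric alternative is fitted) and conservative: `ccdf <= 1` forces
`cFDR >= p1`, and sample overlap between the two GWAS inflates rather than
deflates it.

Counting conventions, fixed deterministically:

- both counts are **self-inclusive** (j = i counts), so the denominator is
  never zero and `1 <= n_joint <= n_cond <= N`;
- ties are counted inclusively (`<=`) on both sides;
- with a completely uninformative conditioning trait (all p2 equal) the
  estimate reduces exactly to the unconditional `min(1, p1_i N / rank_i)`,
  the Benjamini–Hochberg-style quantity — verified by test;
- a SNP that is strictly smallest in p2 conditions only on itself, so its
  cFDR equals its own p1 (visible in the bundled published table, where
  the TCF7L2 locus has cFDR.A|B equal to its BMI p-value).

The implementation sweeps SNPs in p2 order and counts p1-ranks with a
Fenwick tree (O(N log N), exact integer counts); unit, property and
acceptance tests pin it to an O(N²) direct-counting oracle.

The interpolated two-dimensional lookup-table variant of the cFDR (used by
some published implementations) is deliberately **not** implemented: the
per-SNP empirical estimator is self-contained, exactly testable, and the
bundled published loci are consistent with it (cFDR >= p in every row).

**Conjunction FDR.** `conjFDR_i = max(cFDR_i[A|B], cFDR_i[B|A])`; a SNP is
called pleiotropic when `conjFDR < alpha` (strict inequality; default
`alpha = 0.05`, the `-log10 = 1.3` line). Taking the maximum requires the
association to survive conditioning in both directions and is itself
conservative. What the conjunction FDR controls is non-nullity in each
trait separately; on simulated data a truth-based audit of calls is
available (`evaluate_detection`), and because "not pleiotropic" is a
stricter notion than either directional null, the empirical conjunction
FDR against simulation truth is only softly bounded (observed ≈ 0.07–0.10
at alpha = 0.05 over 10 seeds; the acceptance suite asserts <= 2·alpha).

## Data preparation

Summary tables are whitespace/tab TSVs with configurable column names;
p = 0 is clamped to 1e-300 (the estimator needs p > 0), p outside (0, 1]
or non-numeric rows are dropped with a logged count, duplicate rs ids keep
the first occurrence, chromosome labels lose a leading `chr`, and rows
sort by (chrom, pos). Allele/strand harmonization is deliberately absent:
the method consumes p-values only, which are allele-orientation invariant.
The two traits are inner-joined on rs id (positions from the first table).

**LD pruning.** Per chromosome, a window of `window = 50` surviving SNPs
is scanned; each pair's squared Pearson correlation of reference-panel
dosages (composite LD on unphased 0/1/2 genotypes — the panel is unphased,
so a haplotype-based r² is not available) above `r2_threshold = 0.2`
removes the smaller-MAF member; the window slides `step = 5`; whole-
chromosome passes repeat to a fixpoint, and `verify_pruned` re-scans the
survivors as a postcondition. Free choices fixed for determinism: pairs
are processed in ascending position order with immediate removals;
equal-MAF ties remove the larger-position SNP; SNPs absent from the panel
(or with constant dosages, where r is undefined) are retained
unconditionally and their pairs skipped, with a log entry. Windows are
counted in SNPs, not kb.

## Diagnostics

**Conditional Q-Q.** For nested strata `S_t = {i : p2_i <= t}`
(default t = 1, 0.1, 0.01, 0.001), p1 is sorted ascending and the curve is
`x_k = k/|S_t|` (the empirical quantile) against `y_k = -log10 p1_(k)`;
y therefore *decreases* along increasing x, and enrichment appears as the
stringent strata lying above the all-SNPs curve at small x. Empty strata
are dropped with a warning. `-log10` values are capped at 300 for plotting
only.

**Fold enrichment.** `fold(t, x) = prop(S_t, -log10 p1 >= x) /
prop(all, -log10 p1 >= x)` over a grid x = 0..10 step 0.1; grid points with
an empty denominator are omitted. The headline comparison point is
x = 7.3 = -log10(5e-8), the genome-wide significance level. `fold(1, ·) = 1`
by construction.

**Manhattan.** `-log10` of the chosen FDR column with cumulative
per-chromosome offsets and the significance line at `-log10(alpha)`
(1.301 at the default).

## The synthetic generator

Each SNP independently draws a component from
(pi_null, pi_a, pi_b, pi_ab) = (0.90, 0.04, 0.04, 0.02); causal z-scores
are `N(s·mu, 1)` with a random sign `s` per trait (mu = 3.0 by default, a
moderate GWAS effect at meta-analysis scale), nulls are `N(0, 1)`, and
`p = 2·Phi(-|z|)`. 20,000 SNPs are laid contiguously on 22 chromosomes at
10 kb spacing. The genotype panel (500 samples) draws, per LD block of 10
consecutive SNPs and per haplotype, latent Gaussians with exchangeable
correlation rho = 0.9 and thresholds each SNP's latents at the normal
quantile of its MAF (uniform on [0.05, 0.5]); two haplotypes sum to the
dosage. All randomness flows from a single required seed through named
child streams, so summary statistics and panel can be generated separately
yet reproducibly.

Presets:

- `negative_control_config`: A-causal ~ Bern(pi_a + pi_ab) and B-causal ~
  Bern(pi_b + pi_ab) drawn **independently** — each trait keeps its
  marginal causal fraction (6%) but the designed overlap is removed
  (residual chance overlap 0.36% remains and is labelled pleiotropic in
  the truth table). This emulates conditioning on an unrelated trait.
- `enrichment_config`: mu = 4.0 for both traits. Used for the enrichment
  diagnostics because at mu = 3 the expected count of SNPs past the
  genome-wide line at m = 20,000 is ~1, so tail-ratio statistics such as
  fold(0.001, 7.3) are degenerate; at mu = 4 the tail holds tens of SNPs
  and the fold statistic is informative at desk scale.

What the generator deliberately does **not** model: LD-induced correlation
of the test statistics themselves (effects are independent across SNPs —
pruning is exercised by the panel, not by statistic correlation),
sample-overlap correlation between z_a and z_b, and MAF–effect-size
coupling. Passing tests therefore demonstrate correctness of the
estimator and pipeline under a clean mixture truth, not calibration on
real LD-structured GWAS data.

## Problem sizes and stochastic-check design

Simulation-based checks run at the default study scale, m = 20,000 SNPs.
The regime comparisons (fold enrichment, conjunction-call contrast) use
10 seed pairs and compare medians/means; the conjunction-call contrast is
asserted in >= 9 of 10 pairs. The expected conditional Q-Q separation
under independence is estimated by averaging the signed curve difference
over 30 replicates: a single draw's max gap at x in [0.01, 0.5] has
order-statistic noise of ~0.5 -log10 units at the steep low-x end of a
~900-SNP stratum, so the expected separation (the quantity of interest,
truly 0 under independence) needs that many replicates to resolve at the
0.3 level. The empirical-FDR audit averages 10 seeds of the full pruned
default configuration. Oracle cross-checks use 100 random instances up to
N = 2,000 (exact integer equality) for the counting kernel and 500-SNP
fixtures for pruning.

## Numerical and degenerate-input choices

- p-value floor 1e-300 on load and on simulated p-values.
- Results TSVs are written at 17 significant digits (bit-exact round trip,
  read back with round-trip float parsing).
- `compute_r2` raises on constant vectors; callers treat such pairs as
  unlinked and log them.
- Empty call sets evaluate to (FDR, power) = (0, 0) by convention.
- Gene annotation: smallest enclosing interval wins (alphabetical on
  ties); intergenic SNPs report nearest up/downstream genes within 1 Mb,
  nearer first; 1-based inclusive coordinates, BED input converted on
  read. Sub-genic roles (intronic/UTR) need transcript models and are out
  of scope.

## Known limitations

- The estimator assigns no uncertainty to cFDR values; calls are
  threshold-based, as is standard for this method family.
- "Loci" are post-pruning SNPs; no post-hoc clumping of calls into
  regions is performed.
- Real-data features absent from the simulation (above) mean desk-scale
  results do not predict real-data locus counts.
- The pruning result depends on the documented greedy conventions; other
  tools' orderings can keep a different (equally valid) member of a tied
  pair.
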