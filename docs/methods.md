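# Methods

## Compatibility classification

Each mare–foal pair is classified per MHC class from set containment of
the *distinct* alleles at every locus of the class. Containment on sets
rather than multisets is deliberate: the biological criterion is whether
one immune system sees any allele product it does not itself express, a
presence/absence question, so a mare {a,b} "contains" a foal homozygous
{a,a}. A pattern must hold at all loci of the class to qualify; a pair
satisfying both containments everywhere is MFC only, making the four
categories (MC, FC, MFC, NC) a partition whose counts sum to the group
size.

Missing calls: the default `ignore` policy classifies on the testable loci
and records `loci_used`; `strict` refuses pairs with any untestable locus
in the class. Null alleles are invisible to the classifier — a null-masked
heterozygote is taken at face value as a homozygote. This is a real caveat
of microsatellite-based compatibility typing; the QC report's null-allele
estimates quantify how much of it to expect per locus.

## RFM logistic model

Binomial GLM with logit link, fitted by IRLS (statsmodels, tolerance 1e-8,
≤100 iterations), with five parameters: intercept plus, for each MHC
class, an indicator for MC∪FC (collapsed) and an indicator for MFC, NC
being the referent. Collapsing MC and FC reflects that both are one-sided
compatibility states and keeps the residual df at n−5. Standard errors
come from the observed information; CIs are Wald intervals exponentiated
to the OR scale (symmetric on the log scale). Reported alongside: null and
model deviance (−2ℓ), AIC = deviance + 2k, BIC = deviance + k·ln n, the LR
χ² with its p-value, and four pseudo-R²: McFadden 1 − ℓ/ℓ₀, Cox–Snell
1 − exp(−LR/n), Nagelkerke (Cox–Snell rescaled by its maximum), and Tjur's
discrimination coefficient (difference of mean fitted probabilities
between outcome groups).

Degenerate designs are refused loudly rather than silently shrunk: a
single-class outcome, perfect separation, or diverging estimates raise
`SeparationError`; a rank-deficient design raises `ValidationError`. At
n = 43 with five parameters and correlated class-I/class-II categories,
quasi-separation is a genuinely common event — roughly a third of
simulated null-effect cohorts at the study scale have no finite MLE. This
is a property of the design size, not a software failure, and it is why
the study-scale confidence intervals are wide wherever the model does fit.

## Relatedness

The Queller–Goodnight moment estimator corrects observed allele sharing
(identity by state) for chance sharing under reference allele
frequencies. Per locus and direction, with x = (a,b), y = (c,d) and
I the identity indicator:

    N_{x→y} = ½(I_ac + I_ad + I_bc + I_bd) − p_a − p_b
    D_{x→y} = 1 + I_ab − p_a − p_b

Numerators and denominators are summed over loci within each direction.
The default symmetrisation averages the two directional ratios; a pooled
single-ratio variant is available (`combine="pooled"`). The per-direction
average is the convention of the widely used R implementations and, in
simulation at the generator's study conditions, sits closer to the
parent–offspring expectation of 0.5 (≈0.48 vs ≈0.44 for the pooled ratio
at n = 1000 pairs). The residual deficit from 0.5 is the ratio-estimator
bias expected when nine loci in strong LD contribute only a few effective
dimensions and frequencies are estimated from a relative-laden sample;
empirical cohorts show displacements of the same size in either direction.
Reference frequencies default to all genotyped individuals pooled — the
conventional choice when no external panel exists — and can be supplied
explicitly for sensitivity analyses.

Identities maintained by both conventions (property-tested): r(x,x) = 1
whenever any locus is informative, symmetry in the two arguments,
invariance to locus order, and mean ≈ 0.5 / ≈ 0 for simulated
parent–offspring / unrelated pairs. A pair whose every shared locus is
uninformative (denominator 0) gets NaN and is refused by the group
summary rather than imputed.

## Pedigree inbreeding

Malécot kinship by the standard recursion — f(i,i) = ½(1 + f(sire,dam)),
f(i,j) = ½(f(sire_i,j) + f(dam_i,j)) recursing on the individual that
cannot be an ancestor of the other — with unknown parents contributing 0
(each treated as a unique unrelated founder, the standard convention for
pedigrees of variable depth). A topological order is computed once (cycles
are rejected with the offending individuals named) and results are
memoised, so full kinship matrices for a few hundred individuals are
immediate. F_i = f(sire_i, dam_i). Correctness is pinned three ways:
textbook closed forms (full-sib offspring 0.25, half-sib offspring 0.125),
the Emik–Terrill tabular relationship matrix, and a gene-dropping Monte
Carlo oracle on random pedigrees.

## Locus QC

**Hardy–Weinberg.** The conditional exact *probability* test: given the
observed allele counts, the p-value is the total conditional probability
of all genotype arrays no more probable than the observed one, under the
Levene distribution P(array) ∝ n!·Π c_i!·2^het / ((2n)!·Π a_g!). Small
problems (composition bound ≤ 10⁶ arrays by default; the per-locus report
uses 2×10⁵) are enumerated exactly by constrained depth-first search.
Larger ones use Monte Carlo: random re-pairing of the 2n observed gene
copies draws *independent* samples from exactly this conditional null, so
the estimate is unbiased with binomial error; draws are organised into
GENEPOP-style batches (default 100 × 1000 after the conventional
dememorisation parameter, which independent sampling does not need but the
interface retains) and batch means give the standard error. Agreement
between the two routes and the test's conservatism (type-I rate ≤ nominal)
are both under test. Probability comparisons use a 1e-9 log-space
tolerance to make "no more probable" robust to round-off.

**Linkage disequilibrium.** A permutation exact test on the two-locus
genotype contingency table: the statistic is the table's conditional
probability given its margins, one locus's genotypes are permuted among
the shared typed individuals, and the p-value is the add-one-corrected
fraction of permutations no more probable than observed. Monomorphic loci
are reported untestable with p = 1.

**Null alleles.** Three estimators of the frequency of a non-amplifying
allele: Chakraborty (He−Ho)/(He+Ho), Brookfield-1 (He−Ho)/(1+He), and the
default iterative estimator in the Summers–Amos/CERVUS tradition — an EM
scheme for the single-null-allele model in which apparent homozygote
classes are split between true homozygotes and null carriers and the
unobserved null homozygotes are imputed, iterated to |Δr| < 1e-10. The
closed forms use the plain expected heterozygosity 1 − Σp² so that all
three return 0 on data exactly at Hardy–Weinberg proportions; the QC
report's `H_exp` column is the unbiased (Nei) estimator. Closed-form
estimates go negative under heterozygote excess and are returned as-is;
the EM estimate is bounded below by 0 by construction. Recovery of a true
null frequency 0.15 within ±0.02 at 10,000 individuals is under test.

**Other inference.** Clopper–Pearson intervals come from Beta quantiles
(lower 0 at x = 0, upper 1 at x = n). The group comparison of r_xy is a
two-sided pooled-variance t-test (zero-variance corner cases handled
explicitly); Shapiro–Wilk normality of each group's r_xy is reported to
document that choice. Inbreeding is compared by Mann–Whitney U, reported
as U = min(U_a, U_b): exact null distribution when n_a·n_b ≤ 400 with no
ties, otherwise the normal approximation with tie and continuity
corrections — at the study's group sizes with heavily tied F values the
approximation branch is the operative one. All tests are two-sided at
α = 0.05.

## Synthetic cohort generator

The generator emulates the structure the pipeline must face, not any
particular herd:

- **Haplotype pool.** Founders draw two of 12 nine-locus haplotypes
  organised into five *families*; haplotypes within a family differ at one
  or two loci. The small pool induces the strong pairwise LD expected of a
  conserved MHC region; the family structure and cross-haplotype allele
  sharing (microsatellite size homoplasy) decouple the class I and class
  II compatibility categories, without which the two classes' indicators
  would be nearly collinear and the study-scale model almost never
  identifiable. Pool frequencies range 0.021–0.217. Allele labels are
  integer fragment lengths on a 2-bp grid inside each locus's amplicon
  range.
- **Transmission.** Gametes recombine between adjacent loci at
  configurable rates (default 0.005 per gap — tight linkage). Mares number
  n_pairs; stallions default to the cohort's 43:6 mare:stallion ratio so
  scaled-up simulations remain faithful scale-ups of a stud-farm design.
- **Null alleles.** Assigned on founder haplotypes (so they are heritable,
  as the trio checks and CERVUS-style estimators assume) and masked at
  observation: one null copy shows as an apparent homozygote, two as a
  missing call. Defaults: 0.14 at COR110 and 0.15 at TKY3324, zero
  elsewhere.
- **Outcome model.** RFM is Bernoulli with logit p = β₀ + class-wise
  MC∪FC and MFC effects evaluated on the *true* compatibility categories.
  Defaults: β₀ = logit(14/29 odds) ⇒ ≈33% prevalence, all effects 0 (the
  no-association condition). With realistic effect sizes (e.g. an odds
  ratio of 2.65 for MFC in class I), power at n = 43 is far below 50%,
  which is exactly why study-scale runs reproduce wide CIs rather than
  significance.
- **Pedigrees.** `outbred`: all founders unrelated (F ≡ 0, matching a
  cohort whose median F is ≈0.01 with most values 0). `loops(target_F)`:
  a fraction target_F/0.125 of pairs are half-sib matings via a shared
  grandsire, hitting the target mean F in expectation while the median
  stays 0. Limitation: looped pairs' founder *genotypes* are still drawn
  independently from the pool — the pedigree loop is bookkeeping for the
  F machinery, not a genotypic correlation.
- **Determinism.** One seed drives named sub-streams (founders, meiosis,
  outcomes, assignments) spawned from a single `SeedSequence`, so a given
  seed yields byte-identical studies and adding a consumer to one stream
  cannot perturb the others.

What passing tests on this generator do **not** show: robustness to
allele-binning errors, stepwise mutation, population stratification,
genotyping error beyond single null alleles, or pedigree errors — real
cohorts carry all of these.

## Problem sizes and numerical choices

Test and acceptance computations use: exhaustive classifier enumeration to
3 loci × 3 alleles; 1,000 parent–offspring and 1,000 unrelated pairs for
estimator calibration; 10,000 individuals for null-allele recovery; 5,000
pairs for logistic parameter recovery; 1,000 Hardy–Weinberg replicates
(enumeration route) and 200 LD replicates for type-I calibration; 20,000
gene-dropping replicates for kinship; 250 study-scale replicates for the
null-model CI-coverage check. The full pipeline demo runs one 43-pair
cohort with 20 × 500 Monte-Carlo draws per locus. Monte-Carlo assertions
use 3-standard-error bands throughout (one-sided at nominal for exact
tests, which are conservative by construction).

Known limitations: no Firth penalisation, so separated study-scale designs
are reported as errors rather than fitted; no multiple-testing correction
(matching standard practice for this analysis); exact LD enumeration is
not attempted (permutation only); the compatibility classifier cannot see
null alleles, it can only be warned about them by the QC layer.
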