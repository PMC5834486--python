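# Methods

## The model

`triadscan` analyses nuclear families ascertained through an affected child
(case-parent triads, or dyads when one parent is ungenotyped) with a
retrospective log-linear relative-risk model. For a window of k tightly
linked biallelic SNPs, let `p_h` be the population frequency of haplotype
`h` (one of the 2^k allele strings) and `rr_h` the per-copy relative risk it
confers on the child. Risks multiply across the child's two copies
(homozygotes carry `rr_h^2`, compound carriers `rr_h * rr_h'`). Founders
mate at random with haplotypes drawn independently from `p`
(Hardy-Weinberg), each parent transmits one haplotype with probability 1/2,
and conditioning on the child being affected tilts the configuration
probability:

    P(m1, m2, f1, f2, t_m, t_f | case)
        = p_m1 p_m2 p_f1 p_f2 * 1/4 * rr_tm rr_tf / mu,
    mu = (sum_h p_h rr_h)^2.

Because families are sampled through the case child, the non-transmitted
parental haplotypes act as internal controls and population stratification
does not confound the within-family comparison.

Phase, untransmitted haplotypes, missing calls and missing parents are
never observed. A family's likelihood contribution is the sum of the above
probability over every phased configuration compatible with its observed
unordered genotypes; a dyad simply leaves one parent's pair free to range
over the whole haplotype alphabet. Only ratios of `rr` are identifiable (a
common rescaling cancels through `mu`), so the most frequent haplotype is
the reference with RR fixed at 1.

Gene-environment interaction is the ratio of stratum-specific relative
risks, `RRR = RR(exposed) / RR(unexposed)` for a maternal yes/no exposure,
tested on the log scale with a Wald statistic whose variance is the sum of
the two independent stratum variances. Strata are fitted independently —
including their haplotype frequencies, which genuinely differ under
ascertainment whenever the stratum RRs differ — but the reference haplotype
is fixed from the pooled fit so the stratum RRs are comparable. Families
with unknown exposure contribute only to the pooled (child-effect) fit.

## Estimation

The observed-data log-likelihood is maximised over the frequency simplex
(softmax transform) and the free log-RRs with bounded L-BFGS-B, after a
null-model pre-fit that fixes the reference haplotype and pins haplotypes
rarer than `rare_haplotype_min` (default 0.01) at RR = 1. Windows with
k >= 3 use three perturbed restarts against local optima. The estimation
contract is checked against two oracles in the test suite: a dense
grid search over (frequency, RR) must not beat the optimizer by more than
1e-6 log-likelihood units, and the likelihood itself must match exhaustive
enumeration of every phased configuration to 1e-10.

Families are collapsed into distinct (mother, father, child) genotype
patterns before fitting; configuration lists are enumerated once per
pattern and cached. This makes a 500-SNP scan of 1,000 families run in
seconds, which is what keeps the replicate-based calibration tests and the
acceptance script inside a few minutes on one core.

Standard errors come from the observed information: a central-difference
Hessian of the joint (frequency, log-RR) parameterisation is inverted and
the log-RR block extracted, so frequency estimation is properly charged to
the RR uncertainty. A haplotype seen only in case-transmitted sets
(separation) has its |log RR| capped at `log(rr_cap)` (default cap 1000)
and is flagged; its Wald result is suppressed rather than reported.

Numerical details: convergence at relative log-likelihood 1e-8 within 500
iterations; softmax coordinates bounded at +/-30; Mendelian-inconsistent
families are excluded from the affected window only; a family whose child
is entirely missing in a window is dropped from that window with a warning.

## Quality control

The pruning cascade drops individuals with call rate below 10% (an
intentionally permissive threshold mirroring GWAS-era family QC), then
SNPs with founder-HWE p < 0.001, missingness > 5%, MAF <= 5%, or a
Mendelian-error family fraction >= 1%; finally, residual
Mendelian-inconsistent family genotypes at retained SNPs are set missing.
HWE uses the 1-df chi-square on parents only: affected children are
ascertained and deviate from HWE by design at any true risk locus. The
report counts each criterion separately while removing a multiply-failing
SNP once (union semantics).

A corollary worth knowing: ascertainment tilts the *transmitted* half of
the founder haplotype pool toward `p rr / sum(p rr)`, so at a true risk
locus the founders are not exactly in HWE. With strong effects and large
samples the founder-HWE filter can therefore occasionally remove a real
signal; the parameter-recovery experiments scan the simulated data
directly for this reason, and analysts should treat HWE failures at top
hits with the same suspicion.

## Multiplicity and plots

q-values follow Storey-Tibshirani: `pi0` is estimated from the flat right
tail of the p-value distribution on the lambda grid 0.05..0.95 (step 0.05)
with a cubic least-squares smoother evaluated at the right end of the grid,
clamped to (0, 1]; the q-value of the i-th smallest p is the step-down
minimum of `pi0 * m * p_(j) / j`. For fewer than 100 tests the smoother is
unreliable and `pi0` is forced to 1, which reduces the procedure exactly to
Benjamini-Hochberg. QQ tables use expected quantiles `-log10(i/(m+1))` with
pointwise 95% bands from the Beta(i, m-i+1) law of uniform order
statistics; the bands are pointwise, not simultaneous, so even perfectly
uniform p-values keep only ~95% of points inside *on average* — a single
realization varies widely because order statistics are strongly
correlated, and the calibration tests therefore pool the inside rate over
replicate scans. Manhattan tables carry a cumulative x-coordinate and a
highlight flag at p < 1e-6.

## Power

For a single SNP the 15 possible (mother, father, child) dosage trios have
closed-form ascertained probabilities (Hardy-Weinberg mating x Mendelian
transmission x `rr^c / mu`). The per-family expected Fisher information
for log RR is computed from these, by default from the joint (allele
frequency, log RR) information with the log-RR block extracted by
inversion — charging the frequency estimation, which halves the
information relative to a known-frequency analysis. The Wald RRR test then
has `var(log RRR) = 1/(n1 I1) + 1/(n0 I0)` and two-sided power
`Phi(z - z_{1-a/2}) + Phi(-z - z_{1-a/2})`; at RRR = 1 this is exactly the
nominal level. Stratum information is evaluated at that stratum's
alternative RR, so power at RRR and 1/RRR are close but not identical
mirror images; the exact symmetry is the reparameterisation
`(p, rr) -> (1-p, 1/rr)`, which the tests assert. Monte-Carlo validation
re-runs the full simulate-fit-test pipeline and agrees with the closed
form within Monte-Carlo error.

## The synthetic cohort generator

The generator emulates the structure of a multi-site orofacial-cleft triad
GWAS rather than any particular dataset: 1,908 nuclear families of which
314 are dyads (one parent deleted at random in a fixed-size subset), a
maternal exposure with a 50/50 split and 5% missing (NA) answers, 1%
genotype missingness and 0.1% per-allele symmetric genotyping errors —
error injection happens after ascertainment and deliberately creates
Mendelian inconsistencies for the QC stage to find. Where the emulated
study fixes a number (family counts, dyad count) the default reproduces it
exactly; where it does not (exposure split, error rates) the default is a
representative choice stated here and held fixed. The 50/50 exposure split
follows the power analyses' design point, and published family-based
screens report that power is insensitive to modest departures from 1:1.

Case ascertainment is exact rejection sampling: a proposed family (four
founder haplotypes, uniform transmission) is kept with probability
`child_risk / max_child_risk`. This reproduces the ascertained category
distribution exactly (verified by goodness-of-fit against the closed-form
probabilities at n = 20,000) instead of approximating it with weights. All
randomness derives from one master seed via `SeedSequence.spawn`, so a
config is fully reproducible.

What the generator does *not* emulate: linkage disequilibrium between
loci beyond an explicitly specified multi-SNP window (loci are
independent, so multi-locus LD structure is user-supplied), recombination
within windows, admixture or exposure-ethnicity correlation, platform-
specific error modes, and multi-offspring families. Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated model, not robustness to un-modelled artefacts of real genotype
data.

## Problem sizes used in the checks

The calibration and validation experiments use the sizes of the emulated
analyses: null scans of 500 SNPs x 1,000 triads (type-I error and QQ-band
coverage, the latter pooled over replicate scans because of the band's
realization noise); 200 replicates of a planted protective interaction
(variant frequency 0.40, RR 1.0 vs 0.6, n = 2,000 with the full study
structure including dyads and missingness) for bias and CI coverage; 400
Monte-Carlo scans at the published power design point (MAF 0.2, RRR 1.6,
n = 1,000, alpha 5%); and 20,000 families for the category goodness of
fit. Replicate counts were sized so the Monte-Carlo standard error of each
estimate is small against the property being checked.

## Known limitations

* Child genotype effects only: no maternal-genotype, parent-of-origin or
  imprinting terms, no covariates beyond the exposure stratification, and
  no X chromosome.
* The likelihood assumes random mating and HWE founders within stratum; it
  is the full retrospective likelihood, not the variant conditioned on
  parental genotypes, so founder-frequency misspecification can leak into
  RR estimates in structured samples (mitigated, not eliminated, by the
  within-family design).
* Exposures are binary with exposure-independent genotyping quality.
* Closed-form power covers single SNPs; haplotype-window power is
  Monte-Carlo only.
* The Wald test's finite-sample z is slightly heavy-tailed below ~500
  families per stratum; q-values inherit whatever miscalibration the
  p-values carry.
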