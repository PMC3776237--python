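# Methods

## The model

A microsatellite (MS) locus and the SNPs within 500 kb on either side of it
form an *MS–SNP region*. Over a window of `w` SNPs centered on the MS, each
chromosome carries one SNP haplotype (a string over the Illumina A/B allele
codes) and, in cis, one MS allele (a fragment size in bp). The method
assumes the population-genetic regime in which this is informative: strong
local linkage disequilibrium, so that most window haplotypes descend intact
from a modest pool of ancestral haplotypes, each physically linked to one
MS allele. Haplotypes shared between breeds are identical by descent from
ancestors predating breed formation, which is what lets a reference panel
built from some breeds impute into others.

Departures from perfect linkage come from four sources, all represented in
the simulator and all handled by the table classification: recombination
between the MS and its flanks, stepwise MS mutation (±2 bp), MS genotyping
error (mis-calls, ±2 bp size rounding from indels in the amplified
fragment, and allele dropout producing false homozygotes), and genuinely
rare haplotypes.

## Phasing

Reference animals are phased *jointly* with the MS: the MS enters the
window as one extra multi-allelic site, so phase directly yields the cis
allele per haplotype. Three layers:

1. **Pedigree transmission.** For an animal with genotyped parents, every
   heterozygous site where a parent's genotype forces the transmitted
   allele is fixed beforehand (paternal haplotype in slot 0). Contradictory
   parental genotypes (a Mendelian error at that site) leave the site
   unresolved rather than forcing a wrong phase.
2. **EM over window-haplotype frequencies** (Excoffier–Slatkin style).
   Candidate haplotype pairs compatible with the genotype and the pedigree
   constraints are enumerated per animal; haplotype frequencies are fitted
   by EM (default 20 iterations, matching the common phasing-iteration
   setting; 100 changes nothing detectable on these window sizes) with 5
   random restarts (Dirichlet-random initializations, best likelihood
   kept), and each animal is hard-assigned its maximum-posterior pair.
   Animals whose unresolved heterozygous/missing sites would exceed the
   enumeration cap (default 2^16 combinations) are phased by conditioning
   on the haplotypes already inferred from the rest of the cohort: for each
   known compatible haplotype the complement is determined and the pair
   added as a candidate. Animals with identical genotypes and constraints
   share one EM term, which is what makes thousand-animal windows cheap.
3. **External phase.** Phased VCF (pipe-separated GT only) or the internal
   two-line-per-animal TSV can be loaded directly; files containing any
   unphased GT are rejected.

Numerical choices: posterior ties are broken toward the lexicographically
smallest haplotype-string pair (determinism); a pair of identical SNP
haplotypes with a heterozygous MS has inherently ambiguous MS phase and
contributes weight 0.5 to each orientation, as does any animal whose MS
orientation posterior is tied; missing SNP calls (≤ 20% per animal per
window, more and the animal is excluded from that window) are filled from
the assigned pair. Phasing never alters an observed genotype — the
returned pairs are checked against the input genotypes site by site, every
run. EM that fails the 1e-8 log-likelihood tolerance within `max_iter`
returns the best state with a convergence warning rather than failing.

## Association tables and classification

Every phased reference animal contributes two (haplotype, breed, MS allele,
weight) observations; totals per table are exactly 2x the animal count even
with fractional ambiguity weights. Entries are classified with
`min_count = 4` and `concordance = 0.90`:

| class | rule |
|---|---|
| rare | total < 4 |
| unique | total ≥ 4 and one allele only |
| concordant | total ≥ 4 and primary-allele fraction ≥ 0.90 |
| ambiguous | everything else |

`unique` + `concordant` are the *tallied* haplotypes. Rare entries stay in
the table — the self-correcting workflow promotes them as confirmations
accumulate — but are not imputed from unless explicitly allowed. Primary-
allele ties are broken toward the smaller bp size and flagged. Fractions
are compared with a 1e-9 tolerance since counts can be fractional.

## Window optimization

Candidate total window sizes default to {20, 40, 50, …, 110}, evaluated in
increasing order; windows are centered, with the odd SNP going to the flank
that has more SNPs available. The scan stops when (1) the tallied count at
the previous size is a strict maximum of the trace and the current size
decreases it, or (2) the relative growth in tallied haplotypes from the
previous size is ≤ 1% (plateau). A confirmed maximum at the earlier size
takes precedence over a plateau at the current one; an exhausted scan
returns the first size achieving the maximum tally.

## Imputation and back-off

Lookup is per haplotype, independently for the two haplotypes of an animal,
and is a pure function of (pair, table, settings). A haplotype absent from
the table is retried after trimming `backoff_step` SNPs (default 10, split
evenly between the ends) and re-aggregating the table at the shorter
length, down to a `backoff_floor` of 20 SNPs; each back-off match is
flagged with its depth, and its confidence/support are those of the
aggregated entry — a back-off result is never presented as a full-window
match. The full-region ("1 Mb") strategy simply uses all region SNPs as
the window.

Concordance scoring is strict: both imputed alleles must equal the reported
pair as an unordered multiset; per-breed summaries report mean/max/min of
per-animal concordance percentages.

## Parentage verification

A duo conflict is "no offspring allele matches any parent allele"; a trio
conflict is "no assignment of the two offspring alleles to the two parents
is consistent" (checked exhaustively; a brute-force gamete-enumeration
oracle is kept in the code and the equivalence is tested over all 216
genotype triples of a 3-allele system). Verdicts: 0 conflicts = verified,
1 = pass, ≥ `exclude_at` (default 2) = excluded — the two-conflict
convention follows from the error algebra: at 1% per-marker error,
P(≥1 error in 11 markers) = 1 − 0.99¹¹ > 10%, so single conflicts are
expected noise. Markers with a missing genotype on either side are
excluded from the denominator and reported separately. A ±bp tolerance
(for the 2 bp rounding phenomenon) is exposed as `tolerance_bp` but
defaults to 0: tolerance changes exclusion power and must be explicit.

`haplotype_assisted_review` re-examines conflicted pairs: if offspring and
parent share a window haplotype whose table distribution concentrates
(≥ the concordance threshold) on an allele absent from the parent's
reported genotype, the conflict is flagged as a probable parent mis-score;
with no shared haplotype the conflict is corroborated.

The workflow state machine: verification failure queues the animal for MS
genotyping; a confirmed genotype matching the imputation flags the parent
for re-test; a confirmed genotype contradicting the imputation (including
the case where the lookup found nothing) merges the animal's phased
haplotypes with its confirmed alleles into the panel and bumps the panel
version. Because each diploid animal contributes two observations, a novel
haplotype–allele pair becomes imputable after ⌈min_count/2⌉ ingested
animals.

## The simulator

What it emulates: a pool of `n_ancestral_haplotypes` distinct random SNP
haplotypes per region, each carrying one MS allele drawn from a 2 bp-spaced
ladder (dinucleotide convention — so rounding errors collide with real
alleles); a `fraction_shared` of them assigned to ≥ 2 breeds (2 plus a
binomial extra), the rest breed-specific round-robin; per-breed frequencies
from a symmetric Dirichlet with concentration 5 (one-step drift — moderate
differentiation without routinely losing haplotypes); founders drawn from
those frequencies; per-breed trios bred with at most one crossover per
region per meiosis (uniform breakpoint over the ordered SNP+MS sites, so
SNP–MS recombinants arise) and stepwise ±2 bp MS mutation. Observed MS
calls are corrupted per called genotype: mis-call to a random other ladder
allele (default 1%, the low end of reported MS error), ±2 bp rounding slip
(0.5%), allele dropout to a false homozygote (0, exposed as a knob). Every
corruption is logged exactly once; truth stays recoverable.

What it does *not* emulate: coalescent demography (drift is a one-step
Dirichlet perturbation), SNP genotyping error (SNP call rates are
essentially perfect compared with MS), SNP missingness beyond what the
readers and phaser handle, mutation at SNPs, and linkage between regions.
Passing tests on this generator therefore demonstrate the machinery —
phasing, tallying, lookup, conflict counting, self-correction — under the
LD structure the method assumes; they do not predict accuracy numbers for
any real breed, which depend on real haplotype diversity and reference
depth.

## Problem sizes used in the checks

The bundled checks run at desk scale, chosen to keep the full suite in the
low minutes while leaving sampling noise well inside the asserted
tolerances: closed-world recovery uses 2,000 animals (5 breeds, 12
ancestral haplotypes, 20-SNP windows, 50/50 random holdout);
shared-fraction recovery uses 400 ancestral haplotypes over 8 breeds with
600 founders per breed, enough that near-every haplotype is observed ≥ 4
times and the ±3-point tolerance is dominated by assignment sampling;
leave-breed-out monotonicity uses 5 breeds of 120 founders at sharing 0.2 /
0.4 / 0.6 with matched seeds; error-propagation calibration uses 10,000
single-breed animals over 12 markers, where the binomial standard error on
the ≥1-error fraction is ~0.3 points.

## Known limitations

* The EM phaser is a window-scale substitute for a full localized-haplotype
  -cluster HMM phaser: it is exact in spirit on ≤ ~110-SNP windows with
  strong LD but has no recombination model inside the window; production
  users with an external phaser should load its output via `load_phased`.
* Back-off trimming is symmetric; a recombinant with one long intact flank
  could in principle be rescued by asymmetric trimming, at the cost of a
  larger search space.
* Imputation confidence is the matched entry's primary-allele fraction,
  not a calibrated posterior.
* The AB allele coding is taken verbatim (REF→A, ALT→B from VCF); no
  Illumina TOP/BOT strand resolution or assembly liftover is attempted, so
  reference panel and query genotypes must share coding and assembly.
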