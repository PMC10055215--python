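# Methods

## Model

`rarephase` treats a pair of biallelic variants in one gene as a two-locus
system with haplotypes AB, Ab, aB, ab (capitals = major alleles). Assuming
random union of haplotypes (Hardy–Weinberg equilibrium, HWE) in the
reference cohort, the nine joint genotype classes have probabilities that
are quadratic forms in the haplotype frequencies f = (f_AB, f_Ab, f_aB,
f_ab); only the double heterozygote AaBb is a mixture of two configurations,
P(AaBb) = 2 f_AB f_ab + 2 f_Ab f_aB. The multinomial likelihood of the 3×3
genotype-count table is maximized by EM:

- initialization: the AaBb count is split equally between the cis (AB|ab)
  and trans (Ab|aB) configurations, and a single M-step gives the starting
  frequencies;
- E-step: the cis fraction of double heterozygotes is
  p = f_AB f_ab / (f_AB f_ab + f_Ab f_aB), defined as 0.5 when the
  denominator is zero (no information — keeps the iteration total);
- M-step: haplotype counts are the unambiguous contributions of the eight
  resolved cells plus p·n_AaBb split as (AB, ab) and (1−p)·n_AaBb split as
  (Ab, aB), normalized by 2·n_total;
- stopping: |Δ log L| < 1e-7 (default) or 1000 iterations, with a
  `converged` flag reporting which occurred. A table with no double
  heterozygotes is a closed form: the single M-step is the exact MLE and the
  EM stops immediately.

The probability that a doubly heterozygous carrier is compound heterozygous
is Ptrans = f_Ab f_aB / (f_AB f_ab + f_Ab f_aB), undefined (reported as
`no_prediction`) when both configuration products are zero, e.g. when a
variant is absent from the group. Classification uses closed intervals:
cis when Ptrans ≤ t_cis (default 0.02), trans when Ptrans ≥ t_trans
(default 0.55), indeterminate between. Pairs whose two variants are both
singletons carried by the same reference individual get no prediction — a
single shared carrier cannot distinguish a shared haplotype from a
coincidence, although empirically such pairs are usually cis.

The likelihood can be bimodal for sparse tables. The equal-split start is
the only start used, matching the estimator's definition; the test suite's
oracle comparisons therefore compare log-likelihoods, not frequencies, when
two optima tie.

## Ingest and quality control

The cohort is read from a pre-split biallelic VCF (multiallelic records are
a hard error, because the major/minor dichotomy behind the 3×3 table
requires biallelic sites) joined to an annotation TSV (gene, consequence
class, REVEL, methylation, trinucleotide context, per-group AC/AN) and a
sample→group table. Genotype QC keeps genotypes with GQ > 20 and DP > 10,
and heterozygotes additionally with allele balance > 0.2 (all strict
inequalities); failures become missing. The rare-variant filter keeps
coding / flanking-intronic / UTR classes with global AF < 5% (strict), with
an optional population-specific AF < 5% restriction and sex-chromosome
exclusion. Pairs are all unordered within-gene combinations; a variant
annotated to two overlapping genes pairs within each gene independently.
Individuals missing a genotype at either site of a pair are excluded from
the table and from n_total (the alternative — imputing homozygous
reference — is not used).

## Trio phase-by-transmission

For a child heterozygous at a site, the parental origin of the minor allele
is forced whenever exactly one parent can have donated it under Mendelian
transmission; sites heterozygous in all three members are ambiguous, and
impossible configurations are flagged as violations and excluded rather
than failing the trio. A doubly heterozygous child's pair is cis when both
minor alleles share an origin, trans when they differ, and unphaseable when
either site is ambiguous, violating or missing. A secondary mode phases a
*parent's* double-het pair through the haplotype that parent demonstrably
transmitted to the child; both the child-pair and parental-pair units are
exposed because either can serve as the validation unit. Accuracy is
correct / (correct + incorrect) over pairs with a cis/trans truth and a
cis/trans prediction, reported in unique-pair and per-occurrence modes.

## Threshold calibration

Pairs carrying both a Ptrans value and a trio truth label are binned in
Ptrans increments of 0.01 (half-open bins, top bin closed at 1). The trans
threshold is the lower edge of the minimum bin whose trans fraction reaches
90%, the cis threshold the upper edge of the maximum bin whose cis fraction
reaches 90%; bins below a minimum count (default 10) are skipped as
unstable, and calibration conventionally restricts to pairs with both
population AFs ≥ 1e-4 and to odd autosomes, leaving even autosomes for
held-out scoring. Thresholds are reported as bin edges, matching the 0.01
granularity of the binning; derivation fails loudly when no bin qualifies
or the two thresholds cross.

## Stratified evaluation

Accuracy is stratified by pairwise AF bin (rarer × more frequent variant;
singletons form their own bin, then decade bins with landmarks at 1e-4,
1e-3, 1e-2, 5e-2 — the edges are this package's defaults, configurable),
physical distance, interpolated genetic distance, and mutation-class pairs.
Genetic distance uses piecewise-linear interpolation of a HapMap-style
cumulative-cM map, clamping positions beyond the map ends to the terminal
values (exome variants routinely flank map ends). SNVs are classed as
transversion, non-CpG transition, or CpG transition (C>T with 3' G, or G>A
with 5' C, from the 3-mer reference context) tiered by mean methylation:
low (missing or < 0.2), medium (0.2–0.6), high (> 0.6). Heavily methylated
CpG sites mutate recurrently at the highest single-nucleotide rates, which
erodes cis signals specifically. ROC and precision-recall curves sweep the
observed Ptrans values with tied scores grouped; AUC uses the trapezoidal
rule and equals the Mann–Whitney concordance.

## Co-occurrence counts

Per gene, AF threshold (0.5%, 1%, 1.5%, 2%, 5%) and severity tier
(pLoF > strong REVEL ≥ 0.932 > moderate ≥ 0.773 > weak ≥ 0.644 >
missense-any > synonymous, cut points inclusive), the package counts
individuals carrying a qualifying heterozygous pair by predicted phase,
with singleton-singleton and indeterminate pairs reported as unphased. A
pair qualifies for a tier when its least severe variant reaches the tier,
so a pLoF/pLoF pair counts under every tier. AF qualification takes the
worse of each variant's global and popmax AF (popmax = highest AF among
non-bottlenecked ancestry groups; ASJ, FIN and Remaining are excluded from
popmax but any of them exceeding 5% disqualifies the variant outright).
Exclusive-priority counting places each individual in their best cell with
priority trans > unphased > cis; multi-mode counts an individual in every
phase cell they have a pair for. Both a deduplicated individual total and a
raw pair-occurrence total are emitted, since "individuals irrespective of
phase" is ambiguous in multi mode. Homozygote counts are the analogous
single-variant tabulation. Consequences outside the six-tier lattice (UTR,
flanking intronic, other) do not enter co-occurrence counts.

## Synthetic data

The generator draws, per pair, 2n haplotypes from configured frequencies
and pairs them at random (exactly the HWE sampling the model assumes), so
every individual's phase truth is known. Trios draw two parents the same
way; each transmits one haplotype, recombined between the two sites with a
configurable fraction and hit by a symmetric allele flip with a configurable
recurrent-mutation rate. `evolve_frequencies` provides deterministic
recombination dynamics: D_g = D_0 (1−r)^g with allele frequencies
preserved, moving the haplotype distribution toward linkage equilibrium.
Sampling both a finite reference panel and held-out targets from the
evolved frequencies reproduces the field-observed asymmetry — recombination
erodes the rare doubly-minor haplotype of a cis pair quickly relative to
its frequency, while assembling one for a trans pair is vanishingly rare,
so cis classification degrades with r while trans classification persists.
Fixtures are written as plain-text VCF 4.2 (GT:GQ:DP:AD, passing-QC values
by default with hooks to plant failing genotypes), PED, annotation TSV,
group TSV and truth TSV; identical seeds give byte-identical files.

What the generator does *not* emulate: linkage to flanking common variants,
genotyping error beyond the planted QC failures, population structure or
admixture within a group, overlapping pairs sharing a variant (each
simulated pair introduces its own two sites), and genealogical correlation
between panel and targets beyond shared frequencies. Passing tests
therefore demonstrate correctness of the estimator and pipeline under the
model's own assumptions, not robustness to real-data artifacts.

## Problem sizes and numerical choices

The test and acceptance runs use scaled-down study conditions chosen to
make sampling noise negligible relative to the effects measured: reference
panels of 20,000–25,000 individuals, 1,000 pairs for frequency recovery at
n = 10,000, 240 pairs × 50 held-out targets per recombination level, and
10,000 trios. Frequency-recovery checks use three multinomial standard
errors plus a 1e-8 absolute floor (components whose true frequency is zero
have zero SE; the EM drives them to ~1e-16 rather than bitwise zero). The
end-to-end calibration study in `scripts/acceptance.py` restricts its
calibration set to pairs with ≥ 20 panel carriers per variant and raises
the per-bin count floor to 50 — the scaled analogues of the AF ≥ 1e-4
restriction and the minimum-bin-count guard at reference-cohort scale —
because with a few thousand calibration records a 0.01-wide bin otherwise
contains a single pair, and single-pair bins are dominated by the known
rare-variant failure mode (a coincidental double carrier pulls the estimate
toward cis). Its pair population is dominated by intact coupling (70% no
decay) with a minority of partially decayed pairs, modeling the tight
linkage of within-gene pairs.

## Known limitations

- Population-based evidence breaks down exactly where it is most wanted:
  for very rare cis pairs, a recombination or recurrent mutation event is
  far more likely to have disrupted the shared haplotype than for two rare
  variants to have met on one haplotype, so cis pairs at mutable or distant
  sites are the dominant error mode (misclassified as trans — the
  clinically conservative direction).
- Ptrans is a point estimate; no uncertainty interval is propagated from
  the multinomial sampling noise of the panel.
- The EM estimates each pair independently; no information is shared across
  pairs or borrowed from flanking variation.
- Group labels are discrete; admixed individuals are served only by the
  cosmopolitan estimate.
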