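# Methods

This note documents the models and procedures rohscan implements, the
defaults and why they are set where they are, what the synthetic cohorts
do and do not emulate, and the numerical and design choices made where
more than one defensible option existed.

## Genotype model and file dialect

Genotypes are biallelic autosomal SNP calls coded 0 (hom A), 1 (het),
2 (hom B), −1 (missing), with markers sorted by chromosome and strictly
increasing physical position (1-based bp; duplicate positions rejected).
Input/output is text PLINK PED/MAP. Allele letters are recoded per marker
by first appearance: the first non-missing allele encountered becomes
allele A. The orientation is arbitrary but stable; every downstream
computation depends only on the hom/het/missing trichotomy, never on which
homozygote is which (tested). One consequence: a dataset whose first
non-missing call at some marker is the code-2 homozygote cannot survive a
write→read round trip with identical codes, since the reader necessarily
codes the first-seen homozygote as 0. `GenotypeDataset.
canonicalize_orientation()` relabels such columns; the simulator applies
it, so all package-produced data round-trip exactly. Half-missing PED
pairs ("A 0") are treated as missing. Only autosomes are supported; sex
chromosomes, multi-allelic markers and binary BED/BIM/FAM are out of
scope.

## Quality control

Three filters in a fixed order: sample call rate, SNP call rate, then the
Hardy–Weinberg exact test. The order matters (dropping a bad sample can
rescue a marker's call rate) and mirrors the single-pass semantics of the
standard array-QC tooling; HWE counts use only samples retained at that
point. Defaults: 0.90, 0.90, p < 10⁻⁶. No minor-allele-frequency filter
is applied, deliberately — ROH islands are regions of extreme allele-
frequency skew, and a MAF filter would erode exactly the signal the
pipeline looks for.

The HWE test is the standard exact SNP test: conditional on the observed
allele counts, the probability of each compatible heterozygote count
(stepping by 2, parity fixed by the minor-allele count) is computed by the
usual recurrence, and the p-value is the sum of probabilities no greater
than the observed table's (ties included; no mid-p). The test is
two-sided in this ≤-probable sense, symmetric in the two homozygote
counts, and returns exactly 1 for monomorphic markers. The implementation
is validated against a full enumeration in exact rational arithmetic on
every table with up to 40 alleles, and against the 1-df chi-square
asymptote on large balanced tables. Note the asymptote converges slowly
for central p-values: at 1,000 genotypes the exact and asymptotic values
still differ by ~0.05 simply because the conditional het distribution is
discrete; agreement to 0.02 sets in around 10,000 genotypes. For
deep-tail tables at very large n the summed probability can underflow;
the p-value is then clamped to the smallest positive float rather than 0,
keeping p ∈ (0, 1].

## ROH detection

The consecutive-SNP (sequential) method, not the sliding-window score. A
candidate run grows marker by marker while the cumulative heterozygote
count stays ≤ 1, the cumulative missing count stays ≤ 1, and each
inter-marker gap is ≤ 1 Mb; runs are trimmed so both ends are homozygous
calls (a run flanked by a heterozygote should not claim that marker's
position). A trimmed candidate is emitted if it spans ≥ 500 kb
(end − start, no +1 — a convention fixed by published island tables whose
printed lengths equal exactly end − start) and contains at least
`min_snps` markers, counting tolerated het/missing markers in the total.

The detector emits **all maximal qualifying windows**: windows not
contained in any other qualifying window. Two maximal runs may overlap
(e.g. around two nearby heterozygotes when one is allowed per run); both
are reported. The implementation is a two-pointer scan (the farthest
feasible end is monotone in the start), emitting a window only when its
trimmed end strictly exceeds every previously emitted end; it is proven
equivalent to an O(n²) brute-force enumerator on randomized chromosomes
and configurations (200 random panels in the acceptance suite, plus a
derandomized hypothesis property).

Parameters and defaults:

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.05 | dataset-wide false-positive budget for chance runs |
| `mean_het` | from data | mean per-SNP heterozygosity h̄ (pooled calls) |
| `min_length_bp` | 500,000 | physical floor; set above the ~100 kb scale of strong LD so runs reflect autozygosity, not haplotype structure |
| `max_het_in_run` | 1 | tolerated het calls per run (genotyping error allowance, protects long runs) |
| `max_missing_in_run` | 1 | tolerated missing calls per run |
| `min_snps` | from Eq. below | SNP-count floor |
| `max_gap_bp` | 1,000,000 | maximum inter-marker gap inside a run (the consecutive-method reference default; exposed because the underlying study does not state one) |

The SNP floor is `l = ceil( ln(α/(nₛ·nᵢ)) / ln(1−h̄) )`, floored at 1:
(1−h̄)^l is the chance of l consecutive homozygous calls at independent
markers in one individual, and nₛ·nᵢ bounds the number of opportunities.
Ceiling rounding because l is a minimum count. The formula ignores LD
(markers are not independent), so it is conservative in panels with
strong LD. For the motivating cohort's printed inputs (nₛ = 106,828,
nᵢ = 189, α = 0.05) any plausible array heterozygosity (0.3–0.4) gives
l ≈ 43–47; the study reports l = 20 without printing h̄, a value no
plausible h̄ reproduces, so h̄ (and, if desired, `min_snps` itself) is
an explicit input rather than a hard-coded constant.

No separate rule for runs longer than 8 Mb is applied, and no
ROH-based inbreeding coefficient is computed.

## Descriptive statistics

Lengths are binned into half-open Mb classes (default bounds 0, 0.5, 1,
2, 4, 8, 16). Per class: count, percent of all summarized lengths, mean,
sample SD (n−1 — verified to reproduce the published class SD where the
population SD would not), min, max; plus a totals row. Classes with one
member report SD as not-available (the motivating table echoes the length
itself in that cell, which this package declines to do). The percent
denominator can be overridden when summarizing a published subset of a
larger, partially tabulated collection. Per-chromosome coverage is the
mean over individuals of summed ROH bp divided by the chromosome extent,
×100; the extent defaults to the last mapped marker position (assembly
lengths are not part of the input) and can be overridden. Mean-per-
individual rather than pooled coverage is the default reading; the two
coincide for equal-extent cohorts.

## Islands

Support of a marker = fraction of all retained individuals (not just
those with any ROH) whose ROH covers its position, closed interval on
trimmed run bounds. Islands are maximal stretches of consecutive same-
chromosome markers with support ≥ threshold (default 0.5; 0.7 as the
strict variant). Deliberately **no** minimum island length or SNP count,
and adjacent qualifying markers merge regardless of physical gap —
island extent is defined by marker support alone, which matches the
marker-level support plots and SNP-count accounting of the motivating
study. Support equals the column means of the association module's
ROH-state matrix by construction (asserted cross-module).

## Gene annotation

BED3+ gene tracks are converted to 1-based closed coordinates. Default
assignment mode is interval overlap ("within or in close proximity");
containment mode and a flank pad (default 0, since no proximity distance
is standard) are provided. Checked against an all-pairs brute force.

## Association

Per marker, OLS of trait on the 0/1 ROH-coverage indicator; two-sided
t-test with n−2 df on the slope, which for a binary regressor equals the
covered-vs-uncovered mean difference (asserted, and cross-checked against
statsmodels). Default genome-wide threshold p < 1.5 × 10⁻⁶, kept as the
conventional constant for ~150K arrays rather than recomputed (it is not
0.05/nₛ for any panel size used here; callers can pass 0.05/n_tests).
Markers with fewer than 5 phenotyped samples in either ROH state are
skipped (configurable) — group sizes that small make the t-test
uninformative. Zero-residual (perfect-fit) markers are flagged
`degenerate` with p = 0 (slope ≠ 0) or 1 (slope = 0) rather than raising.
ROH state, not SNP genotype, is the regressor, matching the stated aim of
associating ROH with the phenotype; no covariates by default (the
motivating cohort is same-sex, same-age, single-herd). Mixed-model/
kinship correction is out of scope.

## Synthetic cohorts

The generator draws marker positions uniformly (sorted, distinct) over
each chromosome extent, per-marker MAF ~ Uniform(0.05, 0.5), background
genotypes in exact HWE proportions independently across markers, then
forces planted tracts homozygous (per-marker major allele) in a random
⌈carrier_fraction·n⌉ subset, applies within-tract heterozygous
genotyping error (default 0.002 per call — this erosion is what the
1-het run allowance exists to absorb), uniform missingness everywhere
(default 0.005), and an additive Gaussian trait (default mean 130,
SD 4 — a height-like scale) with per-tract carrier effects. One global
seed drives everything; identical configs are byte-identical.

What it does **not** emulate: linkage disequilibrium (background markers
are independent), realistic ROH length distributions from pedigree or
coalescent history, allele-frequency spectra of real arrays, or
population structure. Passing tests therefore demonstrate the pipeline's
contracts — recovery of planted autozygosity at the designed carrier
fractions, calibration of the scan under the null — not performance on
LD-structured real data, where chance-run rates are higher than the
independence-based floor predicts.

Defaults mirror the motivating cohort where stated (189 individuals;
thresholds as above) and are chosen once at field-realistic values where
not: 2,000 markers per 50 Mb chromosome (≈25 kb spacing, the density of a
150K bovine array), carrier fractions 0.6/0.9/0.35 in the scripted
analysis to straddle the 50% and 70% support thresholds.

## Study-scale experiments (`rohscan.experiments`)

* **Island recovery**: 100 individuals × 2,000 markers/50 Mb, one 1.5 Mb
  tract at carrier fraction 0.6; full pipeline per seed. Expected: at the
  50% threshold exactly one island genome-wide, overlapping the tract; at
  70% (above the carrier fraction) none. 20 seeded replicates.
* **Null calibration**: n = 200, 1,000 markers, 30%-coverage random state
  matrices, standard-normal trait; pooled fraction of p < 0.05 across 20
  seeds should sit at 0.05.
* **Power**: 189 individuals, a 1.5 Mb tract at carrier fraction 0.5,
  carriers +1.5 residual SDs. Success when the scan's minimum-p marker
  tags the planted signal, measured against the generator's truth as
  correlation > 0.5 between that marker's ROH-state column and true
  carrier status. A bp-window criterion would be slightly wrong on
  principle: detected carrier runs legitimately extend a marker or two
  past the planted boundary through chance-homozygous flanks, so the
  signal's physical footprint is the carrier state itself, not the
  planted interval's endpoints.

These sizes keep the whole suite and the acceptance script inside a few
tens of seconds while leaving each binomial success criterion
(19/20, 18/20) far from its expected value under failure.

## Known limitations

* The minimum-SNP formula assumes marker independence; on LD-dense panels
  it under-counts chance runs relative to reality.
* Exact-test p-values below ~1e-300 are clamped rather than represented.
* The island caller has no concept of assembly gaps: a support run
  spanning an unassayed region merges across it (by design, but worth
  knowing when interpreting island lengths).
* Association assumes an i.i.d. Gaussian residual; related individuals
  or structure inflate the test statistic.
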