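# Methods

## The comparison being made

Each patient contributes three variant call sets: resected tumor tissue
(tDNA), plasma cell-free DNA (ctDNA) and white-blood-cell DNA (the
germline reference). After filtering, tumor tissue is treated as the
reference standard and plasma as the index test. Mutation identity is
`(chrom, pos, ref, alt)` after trimming shared allele prefix/suffix;
VAFs and gene labels never enter matching. This makes the comparison a
set comparison per pair, which is what the fractional allocation below
requires.

## Filtering model

Filtering is a cascade of pure per-call predicates plus one sample-level
QC gate:

1. **Thresholds** (all strict, as printed in the protocols this scheme
   follows): sample mean depth — tissue >1000x, plasma >10000x — and
   per-call alt-read count (>20 tissue / >10 plasma), VAF (>5% / >0.1%)
   and caller p-value (<0.01 both). A sample failing the mean-depth gate
   loses all its calls (QC semantics, disposition `mean_depth`), it is
   not an error. A zero-depth call has undefined VAF and fails the VAF
   step by definition.
2. **Strand bias**: a two-sided Fisher exact test on
   `[[ref_fwd, ref_rev], [alt_fwd, alt_rev]]`, dropping calls with
   p < 1e-3. This replaces the manual IGV review such pipelines
   traditionally perform with an automated, reproducible proxy; the
   conservative alpha reflects that genuine strand imbalance at high
   depth is extreme. Strand counts are read-orientation counts; no
   reference-strand normalization is attempted. All-zero tables carry no
   evidence and are kept.
3. **Hotspot restriction**: calls must fall inside the 739-interval
   panel (BED, 0-based half-open; a 1-based variant position p is inside
   `[start, end)` iff `start < p <= end`; the conversion lives in one
   function).
4. **Germline subtraction**: any key present in the (threshold-filtered)
   WBC call set is removed. WBC calls themselves pass only threshold
   filtering, since they serve as a reference rather than a somatic
   profile.

Because steps 1–3 are pure predicates on the call, the surviving set is
independent of stage order; only the attributed dispositions depend on
it (property-tested). Every input call receives exactly one disposition.

**The p-value stand-in.** Upstream callers attach a proprietary
confidence p-value. Where a call carries none, we use the one-sided
binomial tail P[X ≥ alt_reads], X ~ Binomial(depth, e), with e the
assumed per-base error rate (default 1e-3, configurable per profile):
the probability that error alone explains the alt support. It is
evaluated through the regularized incomplete beta function, which is
exact to float precision at any depth (verified against exact rational
summation to <1e-12 relative error). Limiting cases: alt_reads = 0
gives p = 1; e = 0 with alt_reads > 0 gives p = 0.

## Fractional confusion-matrix allocation

With C concordant, Fp plasma-only and Fn tumor-only mutations in a pair
and T = C + Fp + Fn > 0, every mutation carries weight 1/T toward its
group: tp = C/T, fp = Fp/T, fn = Fn/T. A mutation-free pair is one true
negative. Each pair therefore contributes exactly one pair-equivalent
and cohort totals sum to n. Weights are exact `Fraction`s, so
conservation holds identically rather than to tolerance. TP uses the
same weight as FP/FN: the rule's only published worked example has no
concordant mutations, but the formula names all three groups and
symmetry is the only reading that conserves weight.

Aggregates follow directly: concordance (TP+TN)/n, sensitivity
TP/(TP+FN), specificity TN/(TN+FP), plasma PPV TP/(TP+FP). A metric
whose denominator is zero is reported as undefined (`null`), never
as 0 — an all-negative cohort has no sensitivity, rather than a
sensitivity of zero.

**Confidence intervals** default to the Wilson score interval with
z = 1.959964, evaluated on the fractional effective counts directly
(Wilson and Wald are closed forms in p̂ and n and accept non-integer n;
Clopper-Pearson needs integer counts and rounds first). Wilson is the
default because it behaves well at small effective n and near the
boundaries. The method used is recorded in every summary. Published
intervals of this kind rarely state their method or effective n, so
reproduced intervals should be expected to be close to, not identical
with, printed ones.

**Mutation accounting.** Compartment tallies double-count concordant
mutations; the distinct-mutation count is
n_tdna + n_ctdna − n_concordant, and the per-positive-pair average
divides by pairs with ≥1 mutation. Both tallies are reported because
published totals of this kind are ambiguous between the two readings
(e.g. totals of 59 + 76 with 34 concordant give 101 distinct, and
101/45 = 2.24 per positive pair — consistent only with the distinct
reading).

## Limit of detection

Reference standards are modelled as plasmid mixtures at nominal mutant
fractions (default 0, 0.1, 0.5, 1.0%) sequenced in 12 replicates at
10,000x over six control driver mutations (KRAS G12C, PIK3CA
E545K/H1047R, BRAF V600E, EGFR L858R, EGFR E746_A750del). Alt reads at
each site are Binomial(depth, f + (1−f)·e). A site is "detected" when
its evidence passes the per-variant plasma thresholds; standards bypass
the sample-level depth gate (each site carries its own depth), the
hotspot filter and germline subtraction (the six loci are the universe;
plasmids have no germline).

- **Accuracy** = fraction of 0% replicates with zero calls anywhere on
  the control panel.
- **LoD** = lowest tested non-zero fraction satisfying the detection
  rule. The rule is explicit because published detection-limit claims
  rarely state one: `majority` (mean per-site detection rate ≥ 0.5, the
  default), `all`, and `any` (at least one detection).

Because every criterion is monotone in the alt-read count, the per-site
pass probability has a closed form (the binomial upper tail above the
smallest passing count), used both as an independent test oracle and for
threshold-sensitivity analysis. The instructive regime: at f = 0.1% and
10,000x the expected alt count is 10 — exactly at the strict `>10`
bound — so the per-site pass probability is ≈0.42 (the strict VAF bound
forces ≥11 reads; a `≥10` reading would give ≈0.54). Hence a 0.1% LoD
claim is supported under the `any`-replicate rule (P ≈ 1 across 12
replicates) but not under the majority rule, which yields 0.5%. Both
readings are exposed; the default stays `majority` as the more
conservative criterion.

## Clinical associations

Each feature induces a two-group split (age dichotomized at 65; stage
I = IA+IB vs II = IIA; GGO-dominant means GGO proportion strictly >50%;
sex; histology AC/SCC; differentiation; vascular invasion; VPI) and
group cfDNA concentrations are compared with the Mann-Whitney U test: U
from midranks; p exact by enumeration for pooled n ≤ 12 without ties,
otherwise the tie-corrected, continuity-corrected normal approximation
(cohort-scale groups such as 46 vs 12 always use the approximation).
Pooled all-equal samples carry no ordering information and return p = 1.
Rows report mean ± SD alongside median/IQR — cfDNA concentrations are
strongly right-skewed, so the medians are the better summary even where
published tables print means. Raw p-values only; no multiplicity
correction is applied across feature rows, deliberately matching how
such exploratory tables are reported, and stated here so readers treat
borderline rows accordingly.

**Markers.** A serum marker is positive at value ≥ cut-off (CA125 35,
CA19-9 39 U/ml; CEA 4.7, CYFRA21-1 3.3, NSE 16.3 ng/ml) — the clinical
rule defines *negativity* by strict `<`, and positivity is its
complement. "cfDNA positive" means concentration above a quantification
floor, default 0 ng/ml and configurable, because the criterion behind
published "positive by cfDNA" rates is typically unstated. In an
all-cancer cohort every detection rate is also that test's positive
predictive value; reports label the quantity detection rate and note the
equivalence.

## Synthetic cohort: what it emulates, and what it does not

Defaults describe a 58-patient early-stage NSCLC surgical cohort:
stages 30/16/12 (IA/IB/IIA), 51 AC / 7 SCC, 22 smokers, 8 GGO-dominant,
age ~N(64.5, 9.3²) clipped to 40–84, with exact-count assignment for the
categorical marginals (shuffled deterministically) rather than Bernoulli
draws, so small-cohort tests see the intended group sizes.

Mutations: ~Poisson(59/58) somatic mutations per tumor drawn from a
739-site, 50-gene catalogue weighted so EGFR > TP53 > PIK3CA > KRAS,
with EGFR-only 15-bp deletions and KRAS-only MNVs mirroring the variant
classes seen in such panels; tissue VAF ~ U(5%, 60%). Each tumor
mutation sheds into plasma with probability 0.58 at a log-normal VAF
(median 0.9%, σ = 1.25, ≈95% of draws in 0.1–16%, clipped at 50%);
plasma-private mutations arrive at rate 0.72/patient with a 2× higher
VAF scale (discordant plasma mutations run hotter than concordant ones
in published cohorts). Those rates are the printed cohort aggregates
re-expressed per patient: 59 tumor mutations, 34/59 shed, (76−34)/58
private. Two germline SNPs per patient (VAF 0.5 or 1.0) are planted
identically in all three compartments, inside the panel footprint so
that germline subtraction — not the hotspot filter — must remove them.

Read evidence everywhere is Binomial(depth, v + (1−v)e) with
Poisson-drawn per-site depth (means 2,000x tissue / 12,000x plasma —
set above the strict QC floors, since a sample at exactly the floor
would fail its own QC) and e = 1e-3. Calls with zero alt reads are not
emitted (a caller reports nothing without alt support); the truth table
still records the planted mutation, which is exactly how false
negatives arise. Spurious calls give the filters real work: Poisson(3)
noise calls per sample at error-level VAF (removed by the p-value/VAF
bounds), Poisson(0.3) single-strand artifacts per plasma sample
(removed by the Fisher step) and Poisson(0.3) off-panel calls (removed
by the hotspot step).

cfDNA concentration is log-normal with arithmetic mean 5.5 ng/ml ×3.0
for stage II ×0.1 for GGO dominance, CV 1.5 (at CV = 0 the draw
degenerates to the exact group mean, giving exact multiplier-recovery
tests). Serum markers are log-normal with scales calibrated to the
positivity counts early-stage cohorts report at the standard cut-offs
(≈0/2/8/16/4 positives of 58 for CA125/CA19-9/CEA/CYFRA21-1/NSE).

Randomness: one master seed; per-patient substreams spawned via
`SeedSequence`, so outputs are identical across runs and independent of
iteration order.

**Not modelled**: UMI/consensus error correction, trinucleotide error
spectra, CNVs/SVs, FFPE artifacts, tumor heterogeneity between tissue
sections, clonal hematopoiesis in WBC, inter-run batch effects.
Passing tests on this generator show the *bookkeeping and statistics*
are correct under the stated stochastic model; they do not certify
performance on real sequencing data, where error structure is not
binomial and germline/CH contamination is richer.

## Numerical choices and degenerate inputs

- All threshold comparisons strict, exactly as the printed inequalities.
- Allocation in exact rational arithmetic; aggregation converts to float
  only for the final metrics.
- Undefined metrics and intervals are `null`, never 0.
- Duplicate mutation keys within a compartment collapse to one with a
  warning (matching is set-based).
- Indel identity via prefix/suffix trimming (reference-free
  left-alignment); sufficient for the single-allele spellings the
  pipeline produces, but not a substitute for full reference-aware
  normalization of complex alleles.
- Fisher and binomial tails via scipy; Mann-Whitney exactness delegated
  to scipy's exact method, verified against full permutation
  enumeration for pooled n ≤ 8.
- Problem sizes in the test suite (58-patient cohorts, 100-replicate
  dilution series, 10⁴-pair property sweeps) are chosen to hold
  Monte-Carlo error near 3-SE resolution while keeping the default
  suite in the minutes range.

## Known limitations

- The hotspot panel ships with synthetic coordinates; real analyses
  must supply their own BED (genome build is the user's contract).
- Strand-bias filtering is a statistical proxy for visual review; it
  will keep systematic artifacts that happen to be strand-balanced.
- Fractional allocation weights every mutation in a pair equally; a
  VAF-weighted variant would change aggregate sensitivity and is out of
  scope.
- The Wilson interval on fractional counts treats pair-equivalents as
  independent Bernoulli mass, which is an approximation — pairs, not
  mutations, are the sampling unit.
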