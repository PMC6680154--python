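# Methods

## The genetic model

`trilink` analyses three-point testcrosses: an informative parent
heterozygous at three linked loci is crossed to a tester whose gametes are
phenotypically silent, so each progeny phenotype reads out one informative
gamete. Loci are either ordinary Mendelian loci (mutant allele dominant or
recessive to wild type) or the composite *S* locus of heterostylous
*Primula*, modelled classically as three tightly linked diallelic genes:
*G/g* (style length), *P/p* (pollen size) and *A/a* (anther height), in the
fixed sub-order G–P–A. Thrums are *GPA/gpa*, pins *gpa/gpa*. The
genotype-to-phenotype map is: style short iff ≥1 *G*, anthers high iff ≥1
*A*, pollen large iff ≥1 *P*; thrum = short style + high anthers, pin =
long + low, and the two homostyle classes (self-fertile flowers with anthers
and stigma at the same level) fill the off-diagonal. Pollen size is carried
through reports because it identifies the classical short-homostyle
description, but it is never used to classify progeny.

Phase is represented only by the two explicit parental haplotypes;
coupling/repulsion wording is derived output (`phase_description`). A
tester is valid only if homozygous for the silent allele at every locus
(recessive allele at dominant-mutant loci, the mutant allele at
recessive-mutant loci, *gpa* at *S*); under that condition the eight
gametes of the triple heterozygote map to eight distinct phenotypes, which
is what makes the testcross informative.

## Inference

The eight gametes form four reciprocal (allele-wise complement) pairs. The
pairing is independent of the assumed order; the three candidate orders
differ only in which pair is the double-crossover class. Gene order is
therefore inferred by taking the rarest non-parental reciprocal pair as the
doubles; the locus whose allele "switches" relative to the nearer parental
haplotype in that pair is the middle one. Ties for rarest set an explicit
ambiguity flag; absence of non-parental progeny gives an indeterminate
result, not an exception. Orders are reported canonically (flanking loci in
their declared order) and comparisons are made up to reversal.

Map distances are simple recombination percentages (1 cM = 1% recombinant
gametes), with no Haldane/Kosambi correction — at the sub-3-cM scale of
this region the correction is negligible, and the study tables use raw
percentages. `haldane_cm`/`kosambi_cm` are provided as clearly labelled
optional transforms. Distances are estimated per informative parent
(recombination rate is genotype-dependent), pooling crosses that share a
parent regardless of whether it served as seed or pollen parent; the map
summary reports per-interval min–max ranges across parents. Zero-recombinant
cells are upper bounds — the distance one hypothetical recombinant would
give, 100/N cM, printed with "<" — rather than estimates, and they do not
enter the range endpoints. Homostyle progeny form an exceptional class
attributed to recombination within the *S* locus; they are excluded from
flanking-interval counts and given their own distance (count over the pool
total), conventionally printed as a plain 0.00 when absent.

Two counting conventions are available because published three-point tables
are often silent on whether tabulated interval counts include doubles.
`column_as_printed` (default) takes tabulated counts verbatim — the
arithmetic of the packaged tables, whose distances equal 100·count/N
exactly; when counts must instead be derived from classified progeny it
uses the interval's single-crossover class alone, while
`singles_plus_doubles` adds the double class (the unbiased estimator of the
interval recombination fraction, and the arithmetic the combined rows of
the smaller cross table follow: 7 = 6 + 1, 3 = 2 + 1). Simulation-based
validation uses `singles_plus_doubles`.

Interference is summarised by the coefficient of coincidence
c = observed doubles / (r1·r2·N), with interference I = 1 − c exactly;
c > 1 (negative interference) means an excess of doubles. A zero
product-rule expectation yields a defined "undefined" result rather than an
exception. The historically reported coefficients for these crosses cannot
be recomputed from the tabulated counts because the per-parent double
counts are not part of the tabulated data; they are retained in the
published-values file as reference and the estimator is validated by
parameter recovery instead.

### Published-value reconciliation

Fitted values can be checked against a dictionary of printed pooled counts
and distances. Discrepancies become first-class annotations on the results
(and in written reports), not log noise. On the packaged six-cross table
this flags exactly one cell: the printed pooled S-to-flank2 count (6)
disagrees with the per-cross sum (5); the printed distance 0.39 cM equals
5/1291, whereas 6/1291 would round to 0.46 cM. Similarly, one per-cross
total is recorded as 117 rather than the printed 116 canonical-class count,
because the single short homostyle must be included for the printed pooled
totals (784, 2075) to hold; the fixture header documents this.

## Marker placement

Single-crossover recombinants between *S* and a flanking phenotypic locus
localize codominant markers. The informative parent carries the marker's
thrum-specific RFLP allele in coupling with *S*; the morph of a recombinant
reveals which *S* allele its informative gamete carried, hence the expected
marker state if the marker stayed with *S* (thrum → heterozygous, pin →
pin-allele homozygote). Verdicts per flank F combine as: any retention
excludes "distal to F"; retention plus recombination places the marker
between F and *S*; recombination in every informative F-recombinant places
it distal to F. (The last rule is required for positional recovery: a
marker beyond the flank recombines in *all* flank recombinants, so "any
recombination ⇒ between" would misplace it.) Novel band shifts are never
auto-interpreted: the recombination reading (a distance) and the mutation
reading (an upper bound) are reported side by side. Dominant
presence/absence markers are refused for segregation-based placement with
an explanatory error, since heterozygotes cannot be distinguished.
Marker distances use the full screened progeny count as denominator — the
recombinant subset only selects which individuals are blotted.

## The simulator

`simulate_cross` draws progeny from the generative model the estimators
assume: gamete classes multinomial with P(double) = c·r1·r2,
P(single_i) = r_i − c·r1·r2, P(parental) the remainder (a configuration
with a negative class probability is rejected with the feasibility bound on
c); reciprocal gametes split Binomial(1/2) as in meiotic sampling, not
forced to equality. Interference is modelled solely through the coincidence
multiplier c so that the simulator's parameter is identical to the
estimator's output. Intra-*S* events are drawn first, independently, with
probability h per meiosis (default 0; the study-scale value is about 1/784,
the observed homostyle frequency in the larger cross); the crossover point
is uniform over the G–P and P–A sub-intervals and the exchange is confined
to the sub-locus — the flanking loci retain the donor strand. That choice
(rather than a strict flank-exchanging crossover) reproduces the observed
coupled-flank short homostyle class (*GPa* with the coupled dominant
flank) and reflects the absence of joint flank/intra-*S* data; intra-*S*
events are attributed to the informative parent's meiosis, since the data
cannot distinguish the alternative. Marker calls cosegregate with the
*S*-side or flank-side strand of each gamete according to the marker's
position; within an interval, a crossover falls between marker and *S* with
probability marker_r/r_interval (uniform placement in recombination-fraction
units). All draws flow from one seeded NumPy generator, so a fixed seed and
configuration reproduce tables bitwise.

What the simulator does *not* emulate: sex-specific recombination rates
(pools are per-parent, so a per-parent r suffices), viability selection,
scoring error, and any dependence between intra-*S* events and flanking
crossovers. Passing parameter-recovery tests therefore demonstrate
estimator correctness under the stated sampling model, not robustness to
those real-data effects.

## Problem sizes and numerical choices

Validation uses: parameter recovery at N = 10⁵ progeny, 200 seeds
(r1 = 0.01, r2 = 0.005, c = 1), requiring both interval estimates within 3
binomial standard errors of truth in ≥ 99% of seeds; coincidence-estimator
calibration at N = 10⁵, r1 = r2 = 0.05, c = 1, mean fitted c over 200 seeds
within 10% of 1; marker-position recovery on 100 simulated crosses of
N = 5000 at the study-scale recombination fractions (r1 = 0.0135,
r2 = 0.0082). Gamete-class enumeration and classifier/phenotype round-trip
identity are checked against brute force over all 2³ strand choices for 50
randomised designs (random dominance modes, phases and locus names, with
and without a composite *S* locus). Reported cM values are rounded half-up
to two decimals and kb ratios half-up to integers, matching conventional
table precision; raw floats are kept alongside on every estimate object.

## Known limitations

* Only three-locus designs are supported; the classical study needs no
  more, and multipoint likelihood/LOD analysis is out of scope.
* Order inference requires phenotype- or pair-level counts; tabulated
  interval counts presuppose an order and are analysed under the declared
  one.
* The intra-*S* model is deliberately minimal (uniform sub-interval,
  donor-strand flanks, independence of flanking crossovers); homostyle
  frequencies are too low in realistic designs to identify anything richer.
* Self-incompatibility is represented only implicitly (homostyles are
  self-fertile by morphology); there is no pollination model.
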