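# trilink

Three-point testcross linkage mapping around the *Primula vulgaris* *S*
locus: phase- and dominance-aware progeny classification, gene-order
inference, per-parent map distances, crossover interference, placement of
molecular markers from recombinants, and genetic-to-physical map scaling.

## The problem

Heterostyly in *Primula* — the reciprocal pin/thrum arrangement of anthers
and stigma — is controlled by the *S* locus, classically modelled as three
tightly linked genes *G/g* (style), *P/p* (pollen) and *A/a* (anthers),
with thrums *GPA/gpa* and pins *gpa/gpa*; rare crossovers inside the
cluster produce self-fertile homostyles. Mapping this supergene with
flanking phenotypic markers (*Oakleaf*, *Hose in Hose*, *sepaloid*) and
RFLP markers requires classical three-point testcross analysis:

* the informative parent is heterozygous at three linked loci and crossed
  to a phenotypically silent tester, so each progeny reads out one gamete;
* the eight gamete classes form four reciprocal pairs; the rarest
  non-parental pair marks the double crossovers and identifies the middle
  locus;
* interval distances are percent recombinants, d(cM) = 100·k/N, estimated
  per parent because recombination rates differ between individuals;
* with no recombinant observed, the distance is bounded above by the value
  one hypothetical recombinant would give, < 100/N cM;
* interference is summarised by the coefficient of coincidence
  c = observed doubles / (r₁·r₂·N), interference I = 1 − c;
* markers are placed relative to *S* by asking whether their *S*-coupled
  allele travelled with the *S* side or the flank side of each
  recombinant's crossover, and anchored contig lengths convert cM to kb.

`trilink` implements this pipeline as a library (a `ThreePointCross` model
whose `fit()` returns a results object), a seeded meiosis simulator for
validating every estimator by parameter recovery, and a small CLI. The
progeny tables, marker calls and contig lengths of the original study ship
as plain-text fixtures, so the full analysis is reproducible offline.

## Worked example

```python
from trilink import datasets, ThreePointCross

design, parents = datasets.okl_s_hih_design()
model = ThreePointCross.from_interval_counts(
    datasets.okl_s_hih_interval_counts(), design, parents=parents,
    published=datasets.okl_s_hih_published(),
)
print(model.fit().summary())
```

prints

```
Gene order: OKL-S-HIH (assumed)

            row female_parent male_parent  total  rec_OKL-S  cM_OKL-S  rec_S-HIH  cM_S-HIH  intra_S cM_intra_S
        cross_1         pin-1     thrum-1    413          3         -          2         -        0          -
        cross_2         pin-2     thrum-1    430          2         -          0         -        0          -
        cross_3       thrum-1       pin-3    448          3         -          3         -        0          -
totals[thrum-1]                             1291          8      0.62          5      0.39        0       0.00
        cross_4         pin-4     thrum-2    500          6         -          5         -        0          -
        cross_5         pin-5     thrum-2    117          3         -          6         -        1          -
        cross_6       thrum-2       pin-4    167         11         -          1         -        0          -
totals[thrum-2]                              784         20      2.55         12      1.53        1       0.13
       combined                             2075         28 0.62-2.55         17 0.39-1.53        1       0.05

NOTE [thrum-1:S-HIH] published recombinant count 6 disagrees with the per-cross sum 5
NOTE [thrum-1:S-HIH] published distance 0.39 cM is not reproducible from the published count (6/1291 = 0.46 cM)
```

Reading the output: each informative thrum parent gets its own pool (its
meioses alone generate the scored recombinants), giving *Oakleaf*-to-*S*
distances of 0.62 and 2.55 cM and *S*-to-*Hose in Hose* distances of 0.39
and 1.53 cM — the spread reflects genuinely different recombination rates
in different parents. The single short homostyle is the exceptional
intra-*S* class (0.13 cM in its pool, 0.05 cM over all 2075 progeny). The
`NOTE` lines are first-class annotations: one published pooled count is
internally inconsistent with its own per-cross rows, and the report says
so rather than silently matching either number.

Marker placement and scaling follow the same pattern:

```python
from trilink import datasets, analyse_marker, range_scaling

p = analyse_marker("PvSLL2", datasets.marker_recombinants(),
                   datasets.marker_calls()["PvSLL2"],
                   datasets.marker_phases()["PvSLL2"], total_progeny=2075)
# -> between Oakleaf and S, 0.05 cM

low, high = range_scaling(888, (0.39, 1.53))
# -> 580 and 2277 kb per cM
```

The same operations are available from the shell:

```bash
trilink fixtures --out fixtures/
trilink analyze --design fixtures/design_okl_s_hih.yaml \
    --progeny fixtures/okl_s_hih_interval_counts.csv \
    --published fixtures/okl_s_hih_published.yaml --out out/
trilink simulate --config sim.yaml --seed 7 --out progeny.csv
trilink scale --contig-kb 888 --cm-range 0.39,1.53 --segments 119,888,325,178
```

## Layout

* `src/trilink/genetics.py` — loci, phased genotypes, G/P/A dominance,
  gamete enumeration, progeny classification
* `src/trilink/simulate.py` — multinomial meiosis simulator (interference,
  intra-*S* events, marker cosegregation)
* `src/trilink/threepoint.py` — the `ThreePointCross` model: pooling, order
  inference, distances, bounds, coincidence, map summary
* `src/trilink/markers.py` — cosegregation verdicts and marker placement
* `src/trilink/scaling.py` — kb-per-cM scaling and separation bounds
* `src/trilink/io.py`, `src/trilink/cli.py`, `src/trilink/datasets.py` —
  formats, command line, packaged study inputs

See `docs/methods.md` for the model assumptions, numerical conventions and
known limitations.
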