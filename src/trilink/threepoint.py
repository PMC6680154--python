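"""Three-point testcross inference: gene order, map distances, interference.

The workflow mirrors classical linkage practice:

* progeny phenotype classes are grouped into the four reciprocal gamete
  pairs; the rarest non-parental pair is the double-crossover class, which
  identifies the middle locus and hence the gene order;
* per-parent pools of crosses give interval recombination fractions as
  simple percentages (1 cM = 1 % recombinant gametes, no mapping-function
  correction);
* zero-recombinant cells are reported as one-hypothetical-recombinant upper
  bounds (``< 100/N`` cM);
* the coefficient of coincidence ``c = observed doubles / (r1 * r2 * N)``
  and interference ``I = 1 - c`` quantify crossover interference (``c > 1``:
  negative interference, an excess of doubles);
* rare homostyle progeny form their own exceptional class, attributed to
  recombination within the composite *S* locus and excluded from the
  flanking-interval counts.

The public surface is the :class:`ThreePointCross` model (built from
tabulated interval counts, from per-individual/class progeny data, or from
phenotype-pair counts) whose :meth:`~ThreePointCross.fit` returns a
:class:`ThreePointResults` carrying per-pool estimates, the inferred order,
coincidence diagnostics, a map summary and data-consistency annotations.
"""

from __future__ import annotations

import enum
import math
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import fmt_cm, round_half_up
from .errors import AmbiguousPhenotypeError, DataError, DesignError
from .genetics import (
    CrossDesign,
    CrossoverCategory,
    ParentGenotype,
    PhenotypeVector,
    classify_progeny,
    enumerate_gamete_classes,
    phenotype_of,
    phenotypes_match,
    validate_tester,
)

INTERVAL_1 = "interval_1"
INTERVAL_2 = "interval_2"
INTRA_S = "intra_s"


class Convention(enum.Enum):
    """How interval recombinant counts are obtained.

    ``COLUMN_AS_PRINTED`` takes tabulated per-interval counts at face value
    (the arithmetic of the study tables, where distance = 100 * count / N
    exactly); when counts must be derived from classified progeny it uses the
    interval's single-crossover class alone.  ``SINGLES_PLUS_DOUBLES`` adds
    the double-crossover class to each interval, the textbook convention for
    estimating interval recombination fractions from classified data.
    """

    COLUMN_AS_PRINTED = "column_as_printed"
    SINGLES_PLUS_DOUBLES = "singles_plus_doubles"


# ---------------------------------------------------------------------------
# elementary estimators


@dataclass(frozen=True)
class IntervalEstimate:
    """Recombinant count, total and cM distance for one interval in one pool.

    ``is_bound`` marks a zero-recombinant upper bound (one hypothetical
    recombinant), printed with a ``<`` qualifier.  ``bound_cm`` accompanies a
    genuine zero-count estimate with the corresponding upper bound.
    """

    interval: str
    count: int
    total: int
    is_bound: bool = False
    convention: Convention = Convention.COLUMN_AS_PRINTED
    #: print a "(< bound)" alongside genuine zero-count estimates; the
    #: exceptional (intra-S) class is conventionally printed as a plain 0.00
    show_bound_on_zero: bool = True

    @property
    def distance_cm(self) -> float:
        if self.is_bound:
            return 100.0 / self.total
        return 100.0 * self.count / self.total

    @property
    def printed_cm(self) -> float:
        """Distance rounded half-up to two decimals, as tabulated."""
        return round_half_up(self.distance_cm, 2)

    @property
    def bound_cm(self) -> float | None:
        """Zero-recombinant upper bound where no recombinant was seen."""
        if self.count == 0:
            return round_half_up(100.0 / self.total, 2)
        return None

    @property
    def printed(self) -> str:
        if self.is_bound:
            return f"< {fmt_cm(100.0 / self.total)}"
        if self.count == 0 and self.show_bound_on_zero:
            return f"0.00 (< {fmt_cm(100.0 / self.total)})"
        return fmt_cm(self.distance_cm)


def interval_distance(
    count: int,
    total: int,
    interval: str = "",
    convention: Convention = Convention.COLUMN_AS_PRINTED,
) -> IntervalEstimate:
    """Map distance in cM as percent recombinants: ``100 * count / total``."""
    if total <= 0:
        raise DataError("interval distance needs a positive progeny total")
    if not (0 <= count <= total):
        raise DataError(f"recombinant count {count} outside [0, {total}]")
    return IntervalEstimate(interval=interval, count=int(count), total=int(total),
                            convention=convention)


def zero_recombinant_bound(total: int, interval: str = "") -> IntervalEstimate:
    """Upper bound on the map distance when no recombinant was observed.

    The bound is the distance one hypothetical recombinant would give,
    ``100 / total`` cM, reported with a ``<`` qualifier rather than as an
    estimate.
    """
    if total <= 0:
        raise DataError("zero-recombinant bound needs a positive progeny total")
    return IntervalEstimate(interval=interval, count=0, total=int(total), is_bound=True)


def exceptional_class_distance(count: int, total: int) -> IntervalEstimate:
    """Distance attributed to recombination within the composite *S* locus
    (homostyle progeny), as percent of the progeny total."""
    if total <= 0:
        raise DataError("exceptional-class distance needs a positive progeny total")
    if not (0 <= count <= total):
        raise DataError(f"exceptional-class count {count} outside [0, {total}]")
    return IntervalEstimate(interval=INTRA_S, count=int(count), total=int(total),
                            show_bound_on_zero=False)


@dataclass(frozen=True)
class CoincidenceResult:
    """Observed vs expected double crossovers.

    ``c`` is the coefficient of coincidence (observed / expected under
    independence) and ``interference`` is ``1 - c`` exactly; ``c > 1`` means
    negative interference.  ``defined`` is False when the product-rule
    expectation is zero.
    """

    observed_doubles: int
    expected_doubles: float
    defined: bool = True

    @property
    def c(self) -> float:
        if not self.defined:
            return math.nan
        return self.observed_doubles / self.expected_doubles

    @property
    def interference(self) -> float:
        return 1.0 - self.c


def coincidence(
    observed_doubles: int,
    est1: IntervalEstimate,
    est2: IntervalEstimate,
) -> CoincidenceResult:
    """Coefficient of coincidence from two interval estimates on the same pool."""
    if est1.total != est2.total:
        raise DataError(
            f"interval estimates come from different totals ({est1.total} vs {est2.total})"
        )
    n = est1.total
    expected = (est1.distance_cm / 100.0) * (est2.distance_cm / 100.0) * n
    if expected == 0:
        return CoincidenceResult(observed_doubles, 0.0, defined=False)
    return CoincidenceResult(observed_doubles, expected)


def haldane_cm(r: float) -> float:
    """Haldane map-function transform of a recombination fraction (cM).

    Optional: the standard reports here use raw recombination percentages;
    this transform is offered for comparison with map-function-based maps.
    """
    if not (0 <= r < 0.5):
        raise DataError("Haldane transform requires r in [0, 0.5)")
    return -50.0 * math.log(1.0 - 2.0 * r)


def kosambi_cm(r: float) -> float:
    """Kosambi map-function transform of a recombination fraction (cM); see
    :func:`haldane_cm` for scope."""
    if not (0 <= r < 0.5):
        raise DataError("Kosambi transform requires r in [0, 0.5)")
    return 25.0 * math.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))


# ---------------------------------------------------------------------------
# records and pools


@dataclass
class CrossRecord:
    """One cross's progeny summary at whatever granularity is available.

    Exactly the granularities present are used downstream: tabulated
    ``interval_counts`` (keys ``interval_1``/``interval_2``/``intra_s``),
    classified ``category_counts``, raw ``phenotype_counts`` and/or
    reciprocal ``pair_counts``.
    """

    cross_id: str
    informative_parent: str
    total: int
    female_parent: str = ""
    male_parent: str = ""
    interval_counts: dict[str, int] | None = None
    category_counts: dict[CrossoverCategory, int] | None = None
    phenotype_counts: dict[PhenotypeVector, int] | None = None
    pair_counts: dict[frozenset, int] | None = None
    n_unclassified: int = 0

    def __post_init__(self):
        if self.total <= 0:
            raise DataError(f"cross {self.cross_id!r}: progeny total must be positive")
        for counts in (self.category_counts, self.phenotype_counts, self.pair_counts):
            if counts is not None:
                s = sum(counts.values()) + self.n_unclassified
                if s != self.total:
                    raise DataError(
                        f"cross {self.cross_id!r}: class counts sum to {s}, "
                        f"declared total is {self.total}"
                    )


@dataclass
class ParentPool:
    """Crosses sharing one informative parent, with elementwise-summed counts."""

    informative_parent: str
    cross_ids: tuple[str, ...]
    total: int
    interval_counts: dict[str, int] | None = None
    category_counts: dict[CrossoverCategory, int] | None = None
    phenotype_counts: dict[PhenotypeVector, int] | None = None
    pair_counts: dict[frozenset, int] | None = None


def _sum_dicts(dicts):
    out: dict = defaultdict(int)
    for d in dicts:
        if d is None:
            return None
        for k, v in d.items():
            out[k] += v
    return dict(out)


def pool_by_parent(records: list[CrossRecord]) -> list[ParentPool]:
    """One pool per informative parent (crosses where that parent served as
    female or as male pool together; only its meioses generate the scored
    recombinants)."""
    if not records:
        raise DataError("no cross records to pool")
    by_parent: dict[str, list[CrossRecord]] = defaultdict(list)
    for rec in records:
        by_parent[rec.informative_parent].append(rec)
    pools = []
    for parent, recs in by_parent.items():
        pools.append(
            ParentPool(
                informative_parent=parent,
                cross_ids=tuple(r.cross_id for r in recs),
                total=sum(r.total for r in recs),
                interval_counts=_sum_dicts([r.interval_counts for r in recs]),
                category_counts=_sum_dicts([r.category_counts for r in recs]),
                phenotype_counts=_sum_dicts([r.phenotype_counts for r in recs]),
                pair_counts=_sum_dicts([r.pair_counts for r in recs]),
            )
        )
    return pools


# ---------------------------------------------------------------------------
# gene order


@dataclass(frozen=True)
class OrderResult:
    """Inferred gene order from the rarest reciprocal progeny pair."""

    order: tuple[str, ...]
    middle: str | None
    double_pair_count: int | None = None
    ambiguous: bool = False
    indeterminate: bool = False
    inferred: bool = True  # False when the order was supplied, not inferred

    def canonical(self) -> tuple[str, ...]:
        rev = tuple(reversed(self.order))
        return min(self.order, rev)


def _reciprocal_pairs(informative: ParentGenotype, tester: ParentGenotype,
                      design: CrossDesign):
    """The four reciprocal (complement) gamete pairs with their phenotypes.

    The pairing is independent of any assumed order; each non-parental pair
    is tagged with the design index of the single locus at which its gametes
    differ from the nearer parental haplotype (the locus that 'switches')."""
    classes = enumerate_gamete_classes(informative, design)
    tester_gamete = tester.haplotype_1
    pairs = []
    h1, h2 = informative.haplotypes
    for category, (g_a, g_b) in classes.items():
        ph_a = phenotype_of(g_a, tester_gamete, design)
        ph_b = phenotype_of(g_b, tester_gamete, design)
        if category is CrossoverCategory.PARENTAL:
            switch = None
        else:
            diffs = [i for i in range(len(g_a)) if g_a[i] != h1[i]]
            if len(diffs) != 1:
                diffs = [i for i in range(len(g_a)) if g_a[i] != h2[i]]
            assert len(diffs) == 1
            switch = diffs[0]
        pairs.append((category, (ph_a, ph_b), switch))
    return pairs


def infer_order(
    pool: ParentPool,
    design: CrossDesign,
    informative: ParentGenotype,
    tester: ParentGenotype,
) -> OrderResult:
    """Identify the middle locus from the rarest non-parental reciprocal pair.

    The three candidate orders partition the eight gametes into the same four
    complement pairs; they differ only in which pair is labelled the double
    crossover.  The observed rarest non-parental pair is taken as the double
    class, and the locus whose allele switches in that pair is the middle
    one.  Ties for rarest set ``ambiguous``; no non-parental progeny at all
    sets ``indeterminate``.  The returned order keeps the flanking loci in
    their design order.
    """
    validate_tester(tester, design)
    pairs = _reciprocal_pairs(informative, tester, design)

    def pair_count(ph_pair) -> int:
        if pool.pair_counts is not None:
            for key, count in pool.pair_counts.items():
                members = tuple(key)
                if all(any(phenotypes_match(m, p) for p in ph_pair) for m in members):
                    return count
            return 0
        if pool.phenotype_counts is not None:
            total = 0
            for observed, count in pool.phenotype_counts.items():
                if any(phenotypes_match(observed, p) for p in ph_pair):
                    total += count
            return total
        raise DataError(
            "gene-order inference needs phenotype-level or pair-level counts; "
            "tabulated interval counts presuppose an order"
        )

    nonparental = [
        (pair_count(ph_pair), switch)
        for category, ph_pair, switch in pairs
        if category is not CrossoverCategory.PARENTAL
    ]
    counts = sorted(c for c, _ in nonparental)
    if all(c == 0 for c in counts):
        return OrderResult(order=design.locus_order, middle=None, indeterminate=True)
    rarest, switch = min(nonparental, key=lambda t: t[0])
    ambiguous = counts[0] == counts[1]
    middle = design.loci[switch].name
    flanks = [l.name for i, l in enumerate(design.loci) if i != switch]
    order = (flanks[0], middle, flanks[1])
    return OrderResult(order=order, middle=middle, double_pair_count=rarest,
                       ambiguous=ambiguous)


# ---------------------------------------------------------------------------
# record construction from progeny data


def records_from_progeny(
    df: pd.DataFrame,
    design: CrossDesign,
    parents: dict[str, ParentGenotype],
    order: tuple[str, ...] | None = None,
) -> list[CrossRecord]:
    """Classify per-individual (or per-class ``count``) progeny rows.

    Expected columns: ``cross_id``, ``informative_parent`` (or
    ``female_parent``/``male_parent`` with roles resolvable from
    ``parents``), one column per locus, optional ``count``.
    Individuals whose partially scored phenotype is compatible with more
    than one gamete class are excluded from the counts and tallied in
    ``n_unclassified``.
    """
    from .genetics import Role

    records = []
    for cross_id, group in df.groupby("cross_id", sort=True):
        first = group.iloc[0]
        if "informative_parent" in group.columns and not pd.isna(first.get("informative_parent")):
            informative_id = str(first["informative_parent"])
        else:
            ids = [str(first.get("female_parent", "")), str(first.get("male_parent", ""))]
            informative_id = next(
                (i for i in ids if i in parents and parents[i].role is Role.INFORMATIVE), None
            )
            if informative_id is None:
                raise DataError(f"cross {cross_id!r}: cannot identify the informative parent")
        informative = parents[informative_id]
        tester_id = None
        for cand in (str(first.get("female_parent", "")), str(first.get("male_parent", ""))):
            if cand in parents and cand != informative_id:
                tester_id = cand
        tester = parents[tester_id] if tester_id else next(
            p for p in parents.values() if p.role is Role.TESTER
        )

        category_counts: dict[CrossoverCategory, int] = defaultdict(int)
        phenotype_counts: dict[PhenotypeVector, int] = defaultdict(int)
        n_unclassified = 0
        total = 0
        for _, row in group.iterrows():
            count = int(row["count"]) if "count" in group.columns and not pd.isna(row.get("count")) else 1
            labels = {name: row.get(name) for name in design.locus_order if name in group.columns}
            for name in design.locus_order:
                pollen_col = f"{name}_pollen"
                if pollen_col in group.columns:
                    labels[pollen_col] = row.get(pollen_col)
            phenotype = PhenotypeVector.from_labels(design, labels)
            phenotype_counts[phenotype] += count
            total += count
            try:
                cat = classify_progeny(
                    phenotype, informative, tester, design, order,
                    individual_id=str(row.get("individual_id", "")) or None,
                )
            except AmbiguousPhenotypeError:
                n_unclassified += count
            else:
                category_counts[cat] += count
        records.append(
            CrossRecord(
                cross_id=str(cross_id),
                informative_parent=informative_id,
                female_parent=str(first.get("female_parent", "")),
                male_parent=str(first.get("male_parent", "")),
                total=total,
                category_counts=dict(category_counts),
                phenotype_counts=dict(phenotype_counts),
                n_unclassified=n_unclassified,
            )
        )
    return records


def records_from_interval_counts(df: pd.DataFrame) -> list[CrossRecord]:
    """Build records from tabulated per-cross interval recombinant counts.

    Expected columns: ``cross_id``, ``informative_parent``, ``total``,
    ``rec_interval_1``, ``rec_interval_2`` and optional ``intra_s``,
    ``female_parent``, ``male_parent``.
    """
    required = {"cross_id", "informative_parent", "total", "rec_interval_1", "rec_interval_2"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"interval-count table lacks columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        counts = {
            INTERVAL_1: int(row["rec_interval_1"]),
            INTERVAL_2: int(row["rec_interval_2"]),
            INTRA_S: int(row["intra_s"]) if "intra_s" in df.columns and not pd.isna(row.get("intra_s")) else 0,
        }
        total = int(row["total"])
        for key, c in counts.items():
            if not (0 <= c <= total):
                raise DataError(f"cross {row['cross_id']!r}: count {c} for {key} outside [0, {total}]")
        records.append(
            CrossRecord(
                cross_id=str(row["cross_id"]),
                informative_parent=str(row["informative_parent"]),
                female_parent=str(row.get("female_parent", "")),
                male_parent=str(row.get("male_parent", "")),
                total=total,
                interval_counts=counts,
            )
        )
    return records


# ---------------------------------------------------------------------------
# model and results


@dataclass
class PoolEstimate:
    """Interval and exceptional-class estimates for one informative parent."""

    pool: ParentPool
    est1: IntervalEstimate
    est2: IntervalEstimate
    intra: IntervalEstimate
    coincidence: CoincidenceResult | None = None
    order: OrderResult | None = None


@dataclass(frozen=True)
class Annotation:
    """A first-class data-consistency note attached to the results."""

    location: str
    message: str

    def __str__(self) -> str:  # pragma: no cover
        return f"[{self.location}] {self.message}"


@dataclass
class MapReport:
    """Per-interval cM ranges across parent pools plus combined quantities."""

    order: tuple[str, ...]
    interval_names: tuple[str, str]
    range_1: tuple[float, float]
    range_2: tuple[float, float]
    combined_total: int
    combined_counts: dict[str, int]
    combined_intra: IntervalEstimate | None


class ThreePointCross:
    """Three-point testcross model over a set of crosses sharing one design.

    Parameters
    ----------
    records:
        One :class:`CrossRecord` per cross.
    design:
        The shared :class:`~trilink.genetics.CrossDesign`.
    parents:
        Parent genotypes by id; required for gene-order inference and for
        classification-based records.
    convention:
        Counting convention for interval recombinants (see
        :class:`Convention`).
    published:
        Optional dict of printed pooled counts/distances to check the fitted
        values against; discrepancies become :class:`Annotation` objects on
        the results rather than silent log lines.
    interval_names:
        Display names for the two intervals (default derived from the order,
        e.g. ``OKL-S``/``S-HIH``).
    """

    def __init__(
        self,
        records: list[CrossRecord],
        design: CrossDesign,
        parents: dict[str, ParentGenotype] | None = None,
        convention: Convention = Convention.COLUMN_AS_PRINTED,
        published: dict | None = None,
        order: tuple[str, ...] | None = None,
        interval_names: tuple[str, str] | None = None,
    ):
        if not records:
            raise DataError("a ThreePointCross model needs at least one cross record")
        self.records = list(records)
        self.design = design
        self.parents = dict(parents or {})
        self.convention = convention
        self.published = published
        self.order = tuple(order) if order else None
        self._interval_names = interval_names

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_interval_counts(cls, df: pd.DataFrame, design: CrossDesign, **kwargs) -> "ThreePointCross":
        return cls(records_from_interval_counts(df), design, **kwargs)

    @classmethod
    def from_progeny(
        cls,
        df: pd.DataFrame,
        design: CrossDesign,
        parents: dict[str, ParentGenotype],
        **kwargs,
    ) -> "ThreePointCross":
        records = records_from_progeny(df, design, parents, order=kwargs.get("order"))
        return cls(records, design, parents=parents, **kwargs)

    @classmethod
    def from_pair_counts(
        cls,
        df: pd.DataFrame,
        design: CrossDesign,
        parents: dict[str, ParentGenotype],
        **kwargs,
    ) -> "ThreePointCross":
        """Rows: ``cross_id``, ``class_a``, ``class_b`` (phenotype labels of a
        reciprocal pair, e.g. ``"OKL=mutant;S=thrum;SEP=wild_type"``), ``count``."""
        from .genetics import parse_phenotype_label

        records = []
        for cross_id, group in df.groupby("cross_id", sort=True):
            pair_counts: dict[frozenset, int] = {}
            for _, row in group.iterrows():
                ph_a = parse_phenotype_label(design, str(row["class_a"]))
                ph_b = parse_phenotype_label(design, str(row["class_b"]))
                pair_counts[frozenset((ph_a, ph_b))] = int(row["count"])
            first = group.iloc[0]
            records.append(
                CrossRecord(
                    cross_id=str(cross_id),
                    informative_parent=str(first["informative_parent"]),
                    total=sum(pair_counts.values()),
                    pair_counts=pair_counts,
                )
            )
        return cls(records, design, parents=parents, **kwargs)

    # -- fitting -----------------------------------------------------------

    def _interval_counts_for(self, pool: ParentPool) -> dict[str, int]:
        if pool.interval_counts is not None:
            return dict(pool.interval_counts)
        if pool.category_counts is not None:
            cat = pool.category_counts
            s1 = cat.get(CrossoverCategory.SINGLE_INTERVAL_1, 0)
            s2 = cat.get(CrossoverCategory.SINGLE_INTERVAL_2, 0)
            d = cat.get(CrossoverCategory.DOUBLE, 0)
            extra = d if self.convention is Convention.SINGLES_PLUS_DOUBLES else 0
            return {
                INTERVAL_1: s1 + extra,
                INTERVAL_2: s2 + extra,
                INTRA_S: cat.get(CrossoverCategory.INTRA_S, 0),
            }
        if pool.pair_counts is not None and self._order_result is not None:
            # map reciprocal pairs onto categories under the inferred order
            # (an indeterminate order falls back to the declared one; only
            # parental pairs exist in that case, so the counts are zero)
            informative = self.parents[pool.informative_parent]
            tester = self._tester()
            pairs = _reciprocal_pairs(informative, tester, self.design)
            order = self._order_result.order
            cat_counts: dict[CrossoverCategory, int] = defaultdict(int)
            for category, ph_pair, switch in pairs:
                if category is CrossoverCategory.PARENTAL:
                    target = CrossoverCategory.PARENTAL
                else:
                    name = self.design.loci[switch].name
                    if name == order[1]:
                        target = CrossoverCategory.DOUBLE
                    elif name == order[0]:
                        target = CrossoverCategory.SINGLE_INTERVAL_1
                    else:
                        target = CrossoverCategory.SINGLE_INTERVAL_2
                for key, count in (pool.pair_counts or {}).items():
                    members = tuple(key)
                    if all(any(phenotypes_match(m, p) for p in ph_pair) for m in members):
                        cat_counts[target] += count
            s1 = cat_counts.get(CrossoverCategory.SINGLE_INTERVAL_1, 0)
            s2 = cat_counts.get(CrossoverCategory.SINGLE_INTERVAL_2, 0)
            d = cat_counts.get(CrossoverCategory.DOUBLE, 0)
            extra = d if self.convention is Convention.SINGLES_PLUS_DOUBLES else 0
            return {INTERVAL_1: s1 + extra, INTERVAL_2: s2 + extra, INTRA_S: 0}
        raise DataError(
            f"pool {pool.informative_parent!r} carries no usable counts for interval estimates"
        )

    def _tester(self) -> ParentGenotype:
        from .genetics import Role

        testers = [p for p in self.parents.values() if p.role is Role.TESTER]
        if not testers:
            raise DesignError("no tester parent declared in the design's parents")
        return testers[0]

    def fit(self) -> "ThreePointResults":
        pools = pool_by_parent(self.records)
        pools.sort(key=lambda p: p.informative_parent)

        # gene order: inferred from pooled phenotype/pair counts when present
        self._order_result = None
        order_pool = None
        if any(p.phenotype_counts is not None or p.pair_counts is not None for p in pools):
            grand = ParentPool(
                informative_parent="(pooled)",
                cross_ids=tuple(r.cross_id for r in self.records),
                total=sum(p.total for p in pools),
                phenotype_counts=_sum_dicts(
                    [p.phenotype_counts for p in pools]
                ) if all(p.phenotype_counts is not None for p in pools) else None,
                pair_counts=_sum_dicts(
                    [p.pair_counts for p in pools]
                ) if all(p.pair_counts is not None for p in pools) else None,
            )
            informative = self.parents[pools[0].informative_parent] \
                if pools[0].informative_parent in self.parents else None
            if informative is not None:
                order_result = infer_order(grand, self.design, informative, self._tester())
                self._order_result = order_result
                order_pool = grand
        if self._order_result is None:
            order = self.order or self.design.locus_order
            self._order_result = OrderResult(order=order, middle=order[1], inferred=False)

        order = self._order_result.order
        names = self._interval_names or (f"{order[0]}-{order[1]}", f"{order[1]}-{order[2]}")

        estimates = []
        for pool in pools:
            counts = self._interval_counts_for(pool)
            est1 = interval_distance(counts[INTERVAL_1], pool.total, names[0], self.convention)
            est2 = interval_distance(counts[INTERVAL_2], pool.total, names[1], self.convention)
            intra = exceptional_class_distance(counts.get(INTRA_S, 0), pool.total)
            coin = None
            if pool.category_counts is not None:
                d = pool.category_counts.get(CrossoverCategory.DOUBLE, 0)
                coin = coincidence(d, est1, est2)
            estimates.append(PoolEstimate(pool=pool, est1=est1, est2=est2, intra=intra,
                                          coincidence=coin, order=self._order_result))

        report = summarize_map(estimates, order, names)
        annotations = self._check_published(estimates, report, names)
        return ThreePointResults(
            model=self,
            pools=estimates,
            order_result=self._order_result,
            map_report=report,
            annotations=annotations,
        )

    # -- published-value reconciliation ------------------------------------

    def _check_published(self, estimates, report: MapReport, names) -> list[Annotation]:
        if not self.published:
            return []
        ann: list[Annotation] = []
        slots = {INTERVAL_1: names[0], INTERVAL_2: names[1], INTRA_S: "intra-S"}
        by_parent = {e.pool.informative_parent: e for e in estimates}
        for parent, pub in (self.published.get("pools") or {}).items():
            est = by_parent.get(parent)
            if est is None:
                ann.append(Annotation(parent, "published pool absent from the fitted data"))
                continue
            if int(pub.get("total", est.pool.total)) != est.pool.total:
                ann.append(Annotation(
                    parent,
                    f"published total {pub['total']} != pooled total {est.pool.total}",
                ))
            for slot, estimate in ((INTERVAL_1, est.est1), (INTERVAL_2, est.est2),
                                   (INTRA_S, est.intra)):
                if slot not in pub:
                    continue
                loc = f"{parent}:{slots[slot]}"
                pub_count = pub[slot].get("count")
                pub_cm = pub[slot].get("distance_cm")
                if pub_count is not None and int(pub_count) != estimate.count:
                    ann.append(Annotation(
                        loc,
                        f"published recombinant count {pub_count} disagrees with the "
                        f"per-cross sum {estimate.count}",
                    ))
                if pub_cm is not None:
                    if pub_count is not None:
                        implied = round_half_up(100.0 * int(pub_count) / est.pool.total, 2)
                        if implied != float(pub_cm):
                            ann.append(Annotation(
                                loc,
                                f"published distance {pub_cm} cM is not reproducible from the "
                                f"published count ({pub_count}/{est.pool.total} = {implied} cM)",
                            ))
                    if float(pub_cm) != estimate.printed_cm:
                        ann.append(Annotation(
                            loc,
                            f"published distance {pub_cm} cM differs from the fitted "
                            f"{estimate.printed_cm} cM",
                        ))
        comb = self.published.get("combined") or {}
        if comb:
            if int(comb.get("total", report.combined_total)) != report.combined_total:
                ann.append(Annotation(
                    "combined", f"published total {comb['total']} != {report.combined_total}"
                ))
            for slot, rng in ((INTERVAL_1, report.range_1), (INTERVAL_2, report.range_2)):
                pub_slot = comb.get(slot) or {}
                if "count" in pub_slot and int(pub_slot["count"]) != report.combined_counts[slot]:
                    ann.append(Annotation(
                        f"combined:{slots[slot]}",
                        f"published combined count {pub_slot['count']} disagrees with the "
                        f"summed {report.combined_counts[slot]}",
                    ))
                if "range_cm" in pub_slot:
                    pub_rng = tuple(float(x) for x in pub_slot["range_cm"])
                    got = (round_half_up(rng[0], 2), round_half_up(rng[1], 2))
                    if pub_rng != got:
                        ann.append(Annotation(
                            f"combined:{slots[slot]}",
                            f"published range {pub_rng} cM differs from the fitted {got} cM",
                        ))
            if "intra_s" in comb and report.combined_intra is not None:
                pub_cm = comb["intra_s"].get("distance_cm")
                if pub_cm is not None and float(pub_cm) != report.combined_intra.printed_cm:
                    ann.append(Annotation(
                        "combined:intra-S",
                        f"published homostyle distance {pub_cm} differs from "
                        f"{report.combined_intra.printed_cm}",
                    ))
        return ann


def summarize_map(
    estimates: list[PoolEstimate],
    order: tuple[str, ...],
    interval_names: tuple[str, str],
) -> MapReport:
    """Merge per-pool estimates into interval ranges and combined quantities.

    Pools must agree on the inferred order; the interval ranges are the
    min-max of the per-pool distances and the exceptional (intra-*S*) class
    is re-estimated against the combined progeny total.
    """
    if not estimates:
        raise DataError("no pool estimates to summarize")
    orders = {e.order.canonical() for e in estimates if e.order is not None}
    if len(orders) > 1:
        raise DataError(f"conflicting gene orders across pools: {sorted(orders)}")

    def _range(ests):
        # zero-recombinant pools contribute an upper bound, not an estimate,
        # so the range spans the pools where recombinants were observed
        observed = [e.distance_cm for e in ests if e.count > 0]
        values = observed or [e.distance_cm for e in ests]
        return values

    d1 = _range([e.est1 for e in estimates])
    d2 = _range([e.est2 for e in estimates])
    combined_total = sum(e.pool.total for e in estimates)
    combined_counts = {
        INTERVAL_1: sum(e.est1.count for e in estimates),
        INTERVAL_2: sum(e.est2.count for e in estimates),
        INTRA_S: sum(e.intra.count for e in estimates),
    }
    combined_intra = exceptional_class_distance(combined_counts[INTRA_S], combined_total)
    return MapReport(
        order=order,
        interval_names=interval_names,
        range_1=(min(d1), max(d1)),
        range_2=(min(d2), max(d2)),
        combined_total=combined_total,
        combined_counts=combined_counts,
        combined_intra=combined_intra,
    )


class ThreePointResults:
    """Fitted three-point cross: per-pool estimates, order, map and notes."""

    def __init__(self, model, pools, order_result, map_report, annotations):
        self.model = model
        self.pools: list[PoolEstimate] = pools
        self.order_result: OrderResult = order_result
        self.map_report: MapReport = map_report
        self.annotations: list[Annotation] = annotations

    @property
    def design(self) -> CrossDesign:
        return self.model.design

    def pool(self, informative_parent: str) -> PoolEstimate:
        for est in self.pools:
            if est.pool.informative_parent == informative_parent:
                return est
        raise KeyError(informative_parent)

    def to_frame(self) -> pd.DataFrame:
        """Tabular layout mirroring classical three-point cross tables."""
        names = self.map_report.interval_names
        rows = []
        by_parent: dict[str, list[CrossRecord]] = defaultdict(list)
        for rec in self.model.records:
            by_parent[rec.informative_parent].append(rec)
        for est in self.pools:
            recs = by_parent[est.pool.informative_parent]
            single = len(recs) == 1
            for rec in recs:
                counts = rec.interval_counts
                if counts is None and rec.category_counts is not None:
                    tmp_pool = ParentPool(rec.informative_parent, (rec.cross_id,), rec.total,
                                          category_counts=rec.category_counts)
                    counts = self.model._interval_counts_for(tmp_pool)
                rows.append({
                    "row": rec.cross_id,
                    "female_parent": rec.female_parent,
                    "male_parent": rec.male_parent,
                    "total": rec.total,
                    f"rec_{names[0]}": counts[INTERVAL_1] if counts else None,
                    f"cM_{names[0]}": est.est1.printed if single else "-",
                    f"rec_{names[1]}": counts[INTERVAL_2] if counts else None,
                    f"cM_{names[1]}": est.est2.printed if single else "-",
                    "intra_S": counts.get(INTRA_S, 0) if counts else None,
                    "cM_intra_S": est.intra.printed if single else "-",
                })
            if not single:
                rows.append({
                    "row": f"totals[{est.pool.informative_parent}]",
                    "female_parent": "",
                    "male_parent": "",
                    "total": est.pool.total,
                    f"rec_{names[0]}": est.est1.count,
                    f"cM_{names[0]}": est.est1.printed,
                    f"rec_{names[1]}": est.est2.count,
                    f"cM_{names[1]}": est.est2.printed,
                    "intra_S": est.intra.count,
                    "cM_intra_S": est.intra.printed,
                })
        rep = self.map_report
        rows.append({
            "row": "combined",
            "female_parent": "",
            "male_parent": "",
            "total": rep.combined_total,
            f"rec_{names[0]}": rep.combined_counts[INTERVAL_1],
            f"cM_{names[0]}": f"{fmt_cm(rep.range_1[0])}-{fmt_cm(rep.range_1[1])}",
            f"rec_{names[1]}": rep.combined_counts[INTERVAL_2],
            f"cM_{names[1]}": f"{fmt_cm(rep.range_2[0])}-{fmt_cm(rep.range_2[1])}",
            "intra_S": rep.combined_counts[INTRA_S],
            "cM_intra_S": rep.combined_intra.printed if rep.combined_intra else "-",
        })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable report: order, per-pool table, coincidence, notes."""
        lines = []
        o = self.order_result
        order_str = "-".join(o.order)
        how = "inferred from rarest reciprocal pair" if o.inferred else "assumed"
        qual = " (AMBIGUOUS: tie for rarest class)" if o.ambiguous else ""
        if o.indeterminate:
            lines.append("Gene order: indeterminate (no non-parental progeny)")
        else:
            lines.append(f"Gene order: {order_str} ({how}){qual}")
        lines.append("")
        lines.append(self.to_frame().to_string(index=False))
        lines.append("")
        for est in self.pools:
            if est.coincidence is not None:
                c = est.coincidence
                if not c.defined:
                    lines.append(
                        f"Coincidence [{est.pool.informative_parent}]: undefined "
                        "(zero expected doubles)"
                    )
                else:
                    lines.append(
                        f"Coincidence [{est.pool.informative_parent}]: "
                        f"c = {c.c:.1f} (observed {c.observed_doubles}, expected "
                        f"{c.expected_doubles:.3f}), interference I = {c.interference:.1f}"
                    )
        for ann in self.annotations:
            lines.append(f"NOTE {ann}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# single-marker cosegregation (two-point) summaries


def marker_cosegregation_summary(df: pd.DataFrame) -> pd.DataFrame:
    """Two-point marker-vs-*S* summary with zero-recombinant bounds.

    Input columns: ``marker``, ``total``, ``recombinants``.  Markers with
    observed recombinants get a distance estimate; markers with none get the
    one-hypothetical-recombinant upper bound, printed with ``<``.
    """
    rows = []
    for _, row in df.iterrows():
        total = int(row["total"])
        k = int(row["recombinants"])
        if k == 0:
            est = zero_recombinant_bound(total)
        else:
            est = interval_distance(k, total)
        rows.append({
            "marker": row["marker"],
            "total": total,
            "recombinants": k,
            "distance_cm": est.printed_cm,
            "is_bound": est.is_bound,
            "printed": est.printed if est.is_bound else fmt_cm(est.distance_cm),
        })
    return pd.DataFrame(rows)
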