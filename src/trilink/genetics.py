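"""Loci, phased genotypes and dominance rules for three-point testcrosses.

The model covers ordinary Mendelian loci (a mutant allele that is either
dominant or recessive to wild type) and the composite *S* locus of
heterostylous *Primula*, classically resolved into three tightly linked
diallelic genes controlling style length (*G/g*), pollen size (*P/p*) and
anther height (*A/a*).  Thrum plants are heterozygous ``GPA/gpa`` and pins
homozygous ``gpa/gpa``; rare crossovers between the sub-genes produce
self-fertile homostyles.

Phase (coupling vs repulsion) is always encoded by the two explicit parental
haplotypes; textual phase descriptions are derived output only.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import AmbiguousPhenotypeError, DataError, DesignError

UNSCORED = "unscored"
MUTANT = "mutant"
WILD_TYPE = "wild_type"


class Dominance(enum.Enum):
    """How a locus maps genotype to phenotype."""

    MUTANT_DOMINANT = "mutant_dominant"
    MUTANT_RECESSIVE = "mutant_recessive"
    COMPOSITE_S = "composite_S"


class Morph(enum.Enum):
    """Floral morph at the *S* locus."""

    PIN = "pin"
    THRUM = "thrum"
    SHORT_HOMOSTYLE = "short_homostyle"
    LONG_HOMOSTYLE = "long_homostyle"


#: Morphs produced without recombination inside the S locus.
PARENTAL_MORPHS = frozenset({Morph.PIN, Morph.THRUM})


class Role(enum.Enum):
    INFORMATIVE = "informative"
    TESTER = "tester"


class CrossoverCategory(enum.Enum):
    """Crossover placement of a gamete from a triple heterozygote.

    ``SINGLE_INTERVAL_1`` is a crossover between the first and second locus
    of the working order, ``SINGLE_INTERVAL_2`` between the second and third.
    ``INTRA_S`` marks recombination inside the composite *S* locus
    (homostyle-generating events), handled outside the eight canonical
    three-locus gamete classes.
    """

    PARENTAL = "parental"
    SINGLE_INTERVAL_1 = "single_interval_1"
    SINGLE_INTERVAL_2 = "single_interval_2"
    DOUBLE = "double"
    INTRA_S = "intra_S"


#: Strand-choice patterns for the eight gametes of a triple heterozygote,
#: expressed over the three positions of the working locus order.  Pattern
#: entry 0/1 selects haplotype_1/haplotype_2 of the informative parent; the
#: two patterns of a category are allele-wise complements (reciprocal pair).
GAMETE_PATTERNS: dict[CrossoverCategory, tuple[tuple[int, int, int], tuple[int, int, int]]] = {
    CrossoverCategory.PARENTAL: ((0, 0, 0), (1, 1, 1)),
    CrossoverCategory.SINGLE_INTERVAL_1: ((1, 0, 0), (0, 1, 1)),
    CrossoverCategory.SINGLE_INTERVAL_2: ((0, 0, 1), (1, 1, 0)),
    CrossoverCategory.DOUBLE: ((0, 1, 0), (1, 0, 1)),
}


@dataclass(frozen=True)
class SHaplotype:
    """Ordered G-P-A allele triple of one *S*-locus haplotype.

    ``True`` marks the dominant allele.  The two parental haplotypes are
    ``GPA`` (thrum-determining) and ``gpa`` (pin); any other combination is
    an intra-*S* recombinant.
    """

    g: bool
    p: bool
    a: bool

    @classmethod
    def thrum(cls) -> "SHaplotype":
        return cls(True, True, True)

    @classmethod
    def pin(cls) -> "SHaplotype":
        return cls(False, False, False)

    @classmethod
    def from_label(cls, label: str) -> "SHaplotype":
        if label == "S":
            return cls.thrum()
        if label == "s":
            return cls.pin()
        if len(label) == 3 and label[0] in "Gg" and label[1] in "Pp" and label[2] in "Aa":
            return cls(label[0] == "G", label[1] == "P", label[2] == "A")
        raise DesignError(
            f"cannot parse S-locus haplotype {label!r}: use 'S', 's' or a G/P/A "
            "triple such as 'GPa'"
        )

    @property
    def label(self) -> str:
        return ("G" if self.g else "g") + ("P" if self.p else "p") + ("A" if self.a else "a")

    @property
    def is_parental(self) -> bool:
        return self in (SHaplotype.thrum(), SHaplotype.pin())

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return self.label


def all_s_haplotypes() -> list[SHaplotype]:
    """All eight G/P/A haplotypes (brute-force enumeration helper)."""
    return [SHaplotype(g, p, a) for g, p, a in itertools.product([True, False], repeat=3)]


def intra_s_recombinant(donor: SHaplotype, other: SHaplotype, interval: str) -> SHaplotype:
    """Single-crossover product inside the *S* locus.

    ``interval`` is ``"G-P"`` or ``"P-A"``; the G-side sub-alleles come from
    ``donor`` and the remainder from ``other``.
    """
    if interval == "G-P":
        return SHaplotype(donor.g, other.p, other.a)
    if interval == "P-A":
        return SHaplotype(donor.g, donor.p, other.a)
    raise DesignError(f"unknown intra-S interval {interval!r}; use 'G-P' or 'P-A'")


@dataclass(frozen=True)
class Locus:
    """A scored locus with its dominance mode and allele symbols.

    For ordinary loci ``dominant_symbol``/``recessive_symbol`` name the two
    alleles; for a ``MUTANT_RECESSIVE`` locus the *mutant* allele is the
    recessive symbol (e.g. ``sep``) and the dominant symbol is wild type.
    The composite *S* locus carries :class:`SHaplotype` alleles instead.
    """

    name: str
    dominance: Dominance
    dominant_symbol: str | None = None
    recessive_symbol: str | None = None

    def __post_init__(self):
        if self.dominance is not Dominance.COMPOSITE_S:
            if not self.dominant_symbol or not self.recessive_symbol:
                raise DesignError(f"locus {self.name!r} needs dominant and recessive allele symbols")
            if self.dominant_symbol == self.recessive_symbol:
                raise DesignError(f"locus {self.name!r} allele symbols must differ")


# A haplotype is an ordered tuple of alleles following the design's locus
# order; the S position carries an SHaplotype, other positions str symbols.
Haplotype = tuple


@dataclass(frozen=True)
class CrossDesign:
    """The loci scored in a set of crosses, in an explicit order."""

    loci: tuple[Locus, ...]
    name: str = "design"

    def __post_init__(self):
        names = [l.name for l in self.loci]
        if len(set(names)) != len(names):
            raise DesignError(f"duplicate locus names in design: {names}")
        n_s = sum(l.dominance is Dominance.COMPOSITE_S for l in self.loci)
        if n_s > 1:
            raise DesignError("at most one composite S locus per design")

    @property
    def locus_order(self) -> tuple[str, ...]:
        return tuple(l.name for l in self.loci)

    @property
    def s_index(self) -> int | None:
        for i, l in enumerate(self.loci):
            if l.dominance is Dominance.COMPOSITE_S:
                return i
        return None

    def index(self, name: str) -> int:
        try:
            return self.locus_order.index(name)
        except ValueError:
            raise DesignError(f"locus {name!r} not in design {self.locus_order}") from None

    def locus(self, name: str) -> Locus:
        return self.loci[self.index(name)]

    def parse_haplotype(self, text: str | Sequence) -> Haplotype:
        """Parse ``"okl,S,HIH"`` (or a pre-split sequence) into a haplotype."""
        parts = [p.strip() for p in text.split(",")] if isinstance(text, str) else list(text)
        if len(parts) != len(self.loci):
            raise DesignError(
                f"haplotype {text!r} has {len(parts)} alleles for {len(self.loci)} loci"
            )
        alleles = []
        for locus, part in zip(self.loci, parts):
            if locus.dominance is Dominance.COMPOSITE_S:
                alleles.append(part if isinstance(part, SHaplotype) else SHaplotype.from_label(part))
            else:
                if part not in (locus.dominant_symbol, locus.recessive_symbol):
                    raise DesignError(
                        f"allele {part!r} unknown at locus {locus.name!r} "
                        f"(expected {locus.dominant_symbol!r} or {locus.recessive_symbol!r})"
                    )
                alleles.append(part)
        return tuple(alleles)


@dataclass(frozen=True)
class ParentGenotype:
    """A parent as two phased haplotypes plus its role in the testcross."""

    id: str
    haplotype_1: Haplotype
    haplotype_2: Haplotype
    role: Role = Role.INFORMATIVE

    @property
    def haplotypes(self) -> tuple[Haplotype, Haplotype]:
        return (self.haplotype_1, self.haplotype_2)

    def heterozygous_at(self, design: CrossDesign, name: str) -> bool:
        i = design.index(name)
        return self.haplotype_1[i] != self.haplotype_2[i]


@dataclass(frozen=True)
class SPhenotype:
    """Observable state at the *S* locus: morph plus (descriptive) pollen size.

    Pollen size accompanies the morph so the classical short-homostyle
    description ("short homostyle with large pollen") can be reproduced, but
    it is never used when classifying progeny.
    """

    morph: Morph
    pollen: str = UNSCORED  # "large" / "small" / "unscored"

    def __str__(self) -> str:  # pragma: no cover
        return f"{self.morph.value}({self.pollen})"


@dataclass(frozen=True)
class PhenotypeVector:
    """Per-locus phenotype labels, aligned to a design's locus order.

    Ordinary loci carry ``"mutant"``/``"wild_type"``/``"unscored"``; the *S*
    position carries an :class:`SPhenotype` (or ``"unscored"``).
    """

    values: tuple

    @classmethod
    def from_labels(cls, design: CrossDesign, labels: Mapping[str, str]) -> "PhenotypeVector":
        vals = []
        for locus in design.loci:
            raw = labels.get(locus.name, UNSCORED)
            raw = UNSCORED if raw is None or raw == "" else str(raw).strip()
            if locus.dominance is Dominance.COMPOSITE_S:
                if raw == UNSCORED:
                    vals.append(UNSCORED)
                else:
                    try:
                        morph = Morph(raw)
                    except ValueError:
                        raise DataError(
                            f"unknown morph {raw!r} at locus {locus.name!r}; expected one of "
                            f"{[m.value for m in Morph]} or 'unscored'"
                        ) from None
                    pollen = str(labels.get(f"{locus.name}_pollen", UNSCORED)).strip() or UNSCORED
                    vals.append(SPhenotype(morph, pollen))
            else:
                if raw not in (MUTANT, WILD_TYPE, UNSCORED):
                    raise DataError(
                        f"unknown phenotype {raw!r} at locus {locus.name!r}; expected "
                        f"'mutant', 'wild_type' or 'unscored'"
                    )
                vals.append(raw)
        return cls(tuple(vals))

    def label(self, design: CrossDesign) -> str:
        parts = []
        for locus, v in zip(design.loci, self.values):
            if isinstance(v, SPhenotype):
                parts.append(f"{locus.name}={v.morph.value}")
            else:
                parts.append(f"{locus.name}={v}")
        return ";".join(parts)

    @property
    def morph(self) -> Morph | None:
        for v in self.values:
            if isinstance(v, SPhenotype):
                return v.morph
        return None


def parse_phenotype_label(design: CrossDesign, text: str) -> PhenotypeVector:
    """Parse ``"OKL=mutant;S=thrum;HIH=wild_type"`` into a PhenotypeVector."""
    labels: dict[str, str] = {}
    for chunk in text.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" not in chunk:
            raise DataError(f"bad phenotype label fragment {chunk!r} in {text!r}")
        k, v = chunk.split("=", 1)
        labels[k.strip()] = v.strip()
    unknown = set(labels) - set(design.locus_order) - {f"{n}_pollen" for n in design.locus_order}
    if unknown:
        raise DataError(f"phenotype label {text!r} names unknown loci {sorted(unknown)}")
    return PhenotypeVector.from_labels(design, labels)


def morph_of(s1: SHaplotype, s2: SHaplotype) -> SPhenotype:
    """Morph and pollen size of an *S*-locus diploid under G/P/A dominance.

    Style is short iff at least one *G*; anthers are high iff at least one
    *A*; pollen is large iff at least one *P*.  thrum = short style + high
    anthers, pin = long + low, with the two homostyle classes completing the
    two-by-two table.
    """
    short_style = s1.g or s2.g
    high_anthers = s1.a or s2.a
    large_pollen = s1.p or s2.p
    if short_style and high_anthers:
        morph = Morph.THRUM
    elif not short_style and not high_anthers:
        morph = Morph.PIN
    elif short_style:
        morph = Morph.SHORT_HOMOSTYLE
    else:
        morph = Morph.LONG_HOMOSTYLE
    return SPhenotype(morph, "large" if large_pollen else "small")


def phenotype_of(h1: Haplotype, h2: Haplotype, design: CrossDesign) -> PhenotypeVector:
    """Deterministic genotype-to-phenotype map under the design's dominance rules."""
    if len(h1) != len(design.loci) or len(h2) != len(design.loci):
        raise DesignError("haplotype length does not match design")
    vals = []
    for i, locus in enumerate(design.loci):
        a1, a2 = h1[i], h2[i]
        if locus.dominance is Dominance.COMPOSITE_S:
            if not isinstance(a1, SHaplotype) or not isinstance(a2, SHaplotype):
                raise DesignError(f"locus {locus.name!r} requires SHaplotype alleles")
            vals.append(morph_of(a1, a2))
        elif locus.dominance is Dominance.MUTANT_DOMINANT:
            vals.append(MUTANT if locus.dominant_symbol in (a1, a2) else WILD_TYPE)
        elif locus.dominance is Dominance.MUTANT_RECESSIVE:
            vals.append(MUTANT if a1 == a2 == locus.recessive_symbol else WILD_TYPE)
        else:  # pragma: no cover - enum is closed
            raise DesignError(f"unknown dominance mode {locus.dominance!r}")
    return PhenotypeVector(tuple(vals))


def phenotypes_match(observed: PhenotypeVector, candidate: PhenotypeVector) -> bool:
    """Observed-vs-expected comparison: unscored positions match anything and
    pollen size is ignored (morph alone identifies the *S* state)."""
    for obs, exp in zip(observed.values, candidate.values):
        if obs == UNSCORED:
            continue
        if isinstance(exp, SPhenotype):
            obs_morph = obs.morph if isinstance(obs, SPhenotype) else obs
            if obs_morph != exp.morph:
                return False
        elif obs != exp:
            return False
    return True


def validate_tester(tester: ParentGenotype, design: CrossDesign) -> None:
    """A tester must be homozygous for the phenotypically silent allele at
    every scored locus so its gamete never masks the informative parent's."""
    for i, locus in enumerate(design.loci):
        a1, a2 = tester.haplotype_1[i], tester.haplotype_2[i]
        if a1 != a2:
            raise DesignError(f"tester {tester.id!r} heterozygous at locus {locus.name!r}")
        if locus.dominance is Dominance.MUTANT_DOMINANT and a1 != locus.recessive_symbol:
            raise DesignError(
                f"tester {tester.id!r} carries the dominant allele at {locus.name!r} "
                "and would mask the informative parent"
            )
        if locus.dominance is Dominance.MUTANT_RECESSIVE and a1 != locus.recessive_symbol:
            raise DesignError(
                f"tester {tester.id!r} is wild type at recessive locus {locus.name!r} "
                "and would mask the informative parent"
            )
        if locus.dominance is Dominance.COMPOSITE_S and a1 != SHaplotype.pin():
            raise DesignError(
                f"tester {tester.id!r} must be homozygous pin (gpa/gpa) at {locus.name!r}"
            )


def enumerate_gamete_classes(
    parent: ParentGenotype,
    design: CrossDesign,
    order: Sequence[str] | None = None,
) -> dict[CrossoverCategory, tuple[Haplotype, Haplotype]]:
    """The eight gametes of a triple heterozygote, grouped into the four
    reciprocal pairs defined by crossover placement under ``order``.

    Intra-*S* recombinant gametes are not part of this enumeration; they are
    generated separately (see :func:`intra_s_recombinant`).
    """
    if len(design.loci) != 3:
        raise DesignError("gamete-class enumeration requires a three-locus design")
    order = tuple(order) if order is not None else design.locus_order
    if sorted(order) != sorted(design.locus_order):
        raise DesignError(f"order {order} is not a permutation of {design.locus_order}")
    idx = [design.index(n) for n in order]
    for n, i in zip(order, idx):
        if parent.haplotype_1[i] == parent.haplotype_2[i]:
            raise DesignError(
                f"parent {parent.id!r} is homozygous at locus {n!r}: "
                "three-point analysis needs a triple heterozygote"
            )
    haps = parent.haplotypes
    out: dict[CrossoverCategory, tuple[Haplotype, Haplotype]] = {}
    for category, patterns in GAMETE_PATTERNS.items():
        pair = []
        for pattern in patterns:
            gamete = [None] * len(design.loci)
            for pos, choice in zip(idx, pattern):
                gamete[pos] = haps[choice][pos]
            pair.append(tuple(gamete))
        out[category] = (pair[0], pair[1])
    return out


def classify_progeny(
    phenotype: PhenotypeVector,
    informative: ParentGenotype,
    tester: ParentGenotype,
    design: CrossDesign,
    order: Sequence[str] | None = None,
    individual_id: str | None = None,
) -> CrossoverCategory:
    """Assign a testcross progeny phenotype to its crossover category.

    Homostyle morphs are returned as ``INTRA_S`` directly (they cannot arise
    from the eight canonical gametes).  A phenotype reproducible by no gamete
    raises :class:`DataError`; a partially unscored phenotype compatible with
    more than one category raises :class:`AmbiguousPhenotypeError`.
    """
    validate_tester(tester, design)
    morph = phenotype.morph
    if isinstance(morph, Morph) and morph not in PARENTAL_MORPHS:
        return CrossoverCategory.INTRA_S
    tester_gamete = tester.haplotype_1
    matches = []
    for category, pair in enumerate_gamete_classes(informative, design, order).items():
        for gamete in pair:
            if phenotypes_match(phenotype, phenotype_of(gamete, tester_gamete, design)):
                matches.append(category)
                break
    who = f" (individual {individual_id})" if individual_id else ""
    if not matches:
        raise DataError(
            f"phenotype {phenotype.label(design)!r}{who} matches no gamete of parent "
            f"{informative.id!r}: possible contaminant or selfing"
        )
    if len(set(matches)) > 1:
        raise AmbiguousPhenotypeError(
            f"phenotype {phenotype.label(design)!r}{who} is compatible with several "
            f"gamete classes {sorted(c.value for c in set(matches))}; unscored loci "
            "exclude it from the affected interval counts",
            candidates=set(matches),
        )
    return matches[0]


def phase_description(parent: ParentGenotype, design: CrossDesign) -> dict[str, str]:
    """Derived coupling/repulsion summary of each heterozygous mutant locus
    relative to the dominant *S* allele (output only, never input)."""
    s_idx = design.s_index
    if s_idx is None:
        return {}
    out = {}
    for hap in parent.haplotypes:
        if isinstance(hap[s_idx], SHaplotype) and hap[s_idx] == SHaplotype.thrum():
            s_hap = hap
            break
    else:
        return {}
    for i, locus in enumerate(design.loci):
        if i == s_idx or not parent.heterozygous_at(design, locus.name):
            continue
        mutant_allele = (
            locus.dominant_symbol
            if locus.dominance is Dominance.MUTANT_DOMINANT
            else locus.recessive_symbol
        )
        out[locus.name] = "coupling" if s_hap[i] == mutant_allele else "repulsion"
    return out
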