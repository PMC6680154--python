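"""Multinomial meiosis simulator for three-point testcross progeny.

Gametes from the informative (triple-heterozygous) parent fall into four
reciprocal-pair classes with probabilities

    P(double)      = c * r1 * r2
    P(single_1)    = r1 - c * r1 * r2
    P(single_2)    = r2 - c * r1 * r2
    P(parental)    = 1 - r1 - r2 + c * r1 * r2

where ``r1``/``r2`` are the recombination fractions of the two flanking
intervals and ``c`` the coefficient of coincidence (c = 1: no interference;
c > 1: negative interference, as observed around the *S* locus).  Each class
is split between its two reciprocal gametes with probability one half, as in
meiotic sampling.  Independently of the flanking intervals, a rare intra-*S*
recombination occurs with probability ``h`` per meiosis and yields a
homostyle-determining recombinant *S* haplotype; the exchange is confined to
the G-P or P-A sub-interval (flanking loci retain the donor strand, which
reproduces the observed coupled-flank homostyle class).

All randomness flows from a single :class:`numpy.random.Generator` seeded by
``SimConfig.seed``, so a fixed seed and configuration reproduce the progeny
table bit for bit.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DesignError
from .genetics import (
    GAMETE_PATTERNS,
    CrossDesign,
    CrossoverCategory,
    Haplotype,
    Morph,
    ParentGenotype,
    SHaplotype,
    SPhenotype,
    enumerate_gamete_classes,
    intra_s_recombinant,
    phenotype_of,
    validate_tester,
)

class MarkerPosition(enum.Enum):
    """Where a molecular marker sits relative to the order flank1 - S - flank2."""
    DISTAL_TO_FLANK1 = "distal_to_flank1"
    BETWEEN_FLANK1_AND_S = "between_flank1_and_S"
    BETWEEN_S_AND_FLANK2 = "between_S_and_flank2"
    DISTAL_TO_FLANK2 = "distal_to_flank2"


_CATEGORY_ORDER = (
    CrossoverCategory.PARENTAL,
    CrossoverCategory.SINGLE_INTERVAL_1,
    CrossoverCategory.SINGLE_INTERVAL_2,
    CrossoverCategory.DOUBLE,
)


@dataclass
class SimConfig:
    """Configuration of one simulated testcross.

    Defaults mirror the study conditions of the *Oakleaf - S - Hose in Hose*
    crosses: interval recombination fractions of order 1e-2, no interference
    modelled away from c (coincidence multiplier), and an intra-*S* rate of
    zero unless homostyles are wanted.
    """

    design: CrossDesign
    informative: ParentGenotype
    tester: ParentGenotype
    r1: float
    r2: float
    n: int
    seed: int
    c: float = 1.0
    h: float = 0.0
    order: tuple[str, ...] | None = None

    def __post_init__(self):
        if not (0.0 <= self.r1 <= 0.5) or not (0.0 <= self.r2 <= 0.5):
            raise ConfigError("recombination fractions must lie in [0, 0.5]")
        if self.c < 0:
            raise ConfigError("coefficient of coincidence must be >= 0")
        if not (0.0 <= self.h <= 1.0):
            raise ConfigError("intra-S recombination probability must lie in [0, 1]")
        if self.n <= 0:
            raise ConfigError("progeny count must be positive")
        if self.order is None:
            self.order = self.design.locus_order
        self.class_probabilities()  # feasibility check

    def class_probabilities(self) -> dict[CrossoverCategory, float]:
        """The four gamete-class probabilities; raises if c is infeasible."""
        p_d = self.c * self.r1 * self.r2
        probs = {
            CrossoverCategory.PARENTAL: 1.0 - self.r1 - self.r2 + p_d,
            CrossoverCategory.SINGLE_INTERVAL_1: self.r1 - p_d,
            CrossoverCategory.SINGLE_INTERVAL_2: self.r2 - p_d,
            CrossoverCategory.DOUBLE: p_d,
        }
        if min(probs.values()) < 0:
            bounds = [1.0 / r for r in (self.r1, self.r2) if r > 0]
            c_max = min(bounds) if bounds else float("inf")
            raise ConfigError(
                f"coincidence c={self.c} infeasible for r1={self.r1}, r2={self.r2}: "
                f"a class probability is negative (requires c <= {c_max:g})"
            )
        return probs


@dataclass
class SimulatedProgenyTable:
    """Per-individual simulated progeny with the generating truth recorded.

    ``individuals`` columns: ``individual_id``, one phenotype column per
    locus (morph at *S* plus ``<S>_pollen``), ``true_category`` and internal
    bookkeeping columns ``_member`` (which reciprocal gamete / donor strand)
    and ``_intra_interval`` (G-P / P-A for intra-*S* events).
    """

    config: SimConfig
    individuals: pd.DataFrame
    rng: np.random.Generator = field(repr=False, default=None)

    @property
    def n(self) -> int:
        return len(self.individuals)

    def category_counts(self) -> dict[CrossoverCategory, int]:
        counts = self.individuals["true_category"].value_counts()
        return {cat: int(counts.get(cat.value, 0)) for cat in CrossoverCategory}

    def class_counts(self) -> pd.DataFrame:
        """Phenotype-class counts (the publishable view of the progeny)."""
        cols = list(self.config.design.locus_order)
        out = (
            self.individuals.groupby(cols, sort=True, observed=True)
            .size()
            .reset_index(name="count")
        )
        return out


def simulate_gamete_counts(config: SimConfig) -> dict[CrossoverCategory, int]:
    """One multinomial draw of the four gamete-class counts (no intra-*S*)."""
    rng = np.random.default_rng(config.seed)
    return _draw_counts(config, config.n, rng)


def _draw_counts(config: SimConfig, n: int, rng: np.random.Generator) -> dict[CrossoverCategory, int]:
    probs = config.class_probabilities()
    draw = rng.multinomial(n, [probs[c] for c in _CATEGORY_ORDER])
    return dict(zip(_CATEGORY_ORDER, (int(x) for x in draw)))


def simulate_cross(config: SimConfig) -> SimulatedProgenyTable:
    """Simulate a full testcross progeny table.

    Intra-*S* events are drawn first (binomially with probability ``h``);
    the remaining progeny receive one of the eight canonical gametes.  Every
    gamete is combined with the tester gamete and phenotyped.
    """
    validate_tester(config.tester, config.design)
    rng = np.random.default_rng(config.seed)
    n_intra = int(rng.binomial(config.n, config.h)) if config.h > 0 else 0
    counts = _draw_counts(config, config.n - n_intra, rng)

    design = config.design
    tester_gamete = config.tester.haplotype_1
    classes = enumerate_gamete_classes(config.informative, design, config.order)

    rows: list[dict] = []

    def pheno_row(gamete: Haplotype, category: CrossoverCategory, member: int,
                  intra_interval: str = "") -> dict:
        ph = phenotype_of(gamete, tester_gamete, design)
        row: dict = {}
        for locus, val in zip(design.loci, ph.values):
            if isinstance(val, SPhenotype):
                row[locus.name] = val.morph.value
                row[f"{locus.name}_pollen"] = val.pollen
            else:
                row[locus.name] = val
        row["true_category"] = category.value
        row["_member"] = member
        row["_intra_interval"] = intra_interval
        return row

    for category in _CATEGORY_ORDER:
        total = counts[category]
        k0 = int(rng.binomial(total, 0.5)) if total else 0
        for member, k in ((0, k0), (1, total - k0)):
            if k == 0:
                continue
            row = pheno_row(classes[category][member], category, member)
            rows.extend([row] * k)

    if n_intra:
        s_idx = design.s_index
        if s_idx is None:
            raise DesignError("intra-S simulation requires a composite S locus in the design")
        strands = rng.integers(0, 2, size=n_intra)
        intervals = rng.integers(0, 2, size=n_intra)  # 0: G-P, 1: P-A
        haps = config.informative.haplotypes
        for strand, iv in zip(strands, intervals):
            donor = haps[strand]
            other = haps[1 - strand]
            interval = "G-P" if iv == 0 else "P-A"
            s_rec = intra_s_recombinant(donor[s_idx], other[s_idx], interval)
            gamete = tuple(
                s_rec if i == s_idx else donor[i] for i in range(len(design.loci))
            )
            rows.append(pheno_row(gamete, CrossoverCategory.INTRA_S, int(strand), interval))

    df = pd.DataFrame(rows)
    if df.empty:
        df = pd.DataFrame(
            columns=[l.name for l in design.loci] + ["true_category", "_member", "_intra_interval"]
        )
    perm = rng.permutation(len(df))
    df = df.iloc[perm].reset_index(drop=True)
    df.insert(0, "individual_id", [f"ind{i + 1:06d}" for i in range(len(df))])
    return SimulatedProgenyTable(config=config, individuals=df, rng=rng)


def simulate_marker_calls(
    table: SimulatedProgenyTable,
    marker_position: MarkerPosition,
    marker_r_to_s: float,
    marker_id: str = "M1",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate RFLP-style allele calls for a marker linked to the *S* locus.

    The marker is heterozygous in the informative parent, its thrum allele in
    coupling with the *S* haplotype.  The marker allele transmitted in each
    gamete cosegregates with the *S*-side or flank-side strand according to
    ``marker_position``; for a marker inside a flanking interval, a crossover
    in that interval falls between marker and *S* with probability
    ``marker_r_to_s / r_interval`` (uniform placement along the interval in
    recombination-fraction units).

    Returns a data frame with ``individual_id``, ``marker_id`` and
    ``allele_state`` (``thrum_pin_heterozygous`` when the informative gamete
    carried the *S*-coupled thrum allele, else ``pin_only_homozygous``).
    """
    config = table.config
    rng = rng if rng is not None else (table.rng or np.random.default_rng(config.seed + 1))
    design = config.design
    s_idx_design = design.s_index
    if s_idx_design is None:
        raise DesignError("marker simulation requires a composite S locus")
    order = config.order
    s_pos = order.index(design.loci[s_idx_design].name)
    if s_pos != 1:
        raise ConfigError("marker simulation expects the S locus in the middle of the order")

    if marker_position is MarkerPosition.BETWEEN_FLANK1_AND_S:
        r_int = config.r1
    elif marker_position is MarkerPosition.BETWEEN_S_AND_FLANK2:
        r_int = config.r2
    else:
        r_int = None
    theta = None
    if r_int is not None:
        if r_int == 0:
            theta = 0.0
        elif not (0.0 <= marker_r_to_s <= r_int):
            raise ConfigError(
                f"marker_r_to_s={marker_r_to_s} must lie within its interval's "
                f"recombination fraction ({r_int})"
            )
        else:
            theta = marker_r_to_s / r_int

    # Which informative haplotype carries the thrum (S-bearing) strand.
    thrum_strand = 0 if config.informative.haplotype_1[s_idx_design] == SHaplotype.thrum() else 1

    df = table.individuals
    states = []
    for cat_val, member in zip(df["true_category"].to_numpy(), df["_member"].to_numpy()):
        if cat_val == CrossoverCategory.INTRA_S.value:
            # exchange confined to the S sub-genes: flanks and marker stay
            # with the donor strand
            strand = int(member)
        else:
            pattern = GAMETE_PATTERNS[CrossoverCategory(cat_val)][int(member)]
            f1, s, f2 = pattern
            if marker_position is MarkerPosition.DISTAL_TO_FLANK1:
                strand = f1
            elif marker_position is MarkerPosition.DISTAL_TO_FLANK2:
                strand = f2
            elif marker_position is MarkerPosition.BETWEEN_FLANK1_AND_S:
                if f1 == s:
                    strand = s
                else:
                    strand = f1 if rng.random() < theta else s
            else:  # BETWEEN_S_AND_FLANK2
                if f2 == s:
                    strand = s
                else:
                    strand = f2 if rng.random() < theta else s
        states.append(
            "thrum_pin_heterozygous" if strand == thrum_strand else "pin_only_homozygous"
        )
    return pd.DataFrame(
        {
            "individual_id": df["individual_id"].to_numpy(),
            "marker_id": marker_id,
            "allele_state": states,
        }
    )
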