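"""Placement of molecular markers relative to the *S* locus from recombinants.

Individuals recombinant between the *S* locus and one flanking phenotypic
locus carry a crossover of known interval; whether the marker's *S*-coupled
allele travelled with the *S* side or the flank side of that crossover
localizes the marker:

* every informative recombinant retaining the *S*-coupled allele pattern
  excludes a position distal to that flank;
* a mixture of retained and recombined patterns among F-to-*S* recombinants
  places the marker strictly between F and *S*;
* recombination in every F-to-*S* recombinant places the marker distal to F.

Marker-to-*S* distances use the full screened progeny count as denominator
(the recombinants merely identify which individuals are worth blotting).
Novel (band-shift) RFLPs are never auto-interpreted as recombination: both
the recombination reading (a distance) and the mutation reading (an upper
bound) are reported side by side.
"""

from __future__ import annotations

import enum
from collections import defaultdict
from dataclasses import dataclass, field

import pandas as pd

from ._util import fmt_cm
from .errors import DataError, DesignError
from .genetics import Morph
from .simulate import MarkerPosition
from .threepoint import IntervalEstimate, interval_distance, zero_recombinant_bound


class AlleleState(enum.Enum):
    """RFLP call for one individual at one codominant marker."""

    PIN_ONLY_HOMOZYGOUS = "pin_only_homozygous"
    THRUM_PIN_HETEROZYGOUS = "thrum_pin_heterozygous"
    NOVEL_BAND = "novel_band"
    MISSING = "missing"


class Verdict(enum.Enum):
    MARKER_WITH_S = "marker_with_S"
    MARKER_RECOMBINED_FROM_S = "marker_recombined_from_S"
    UNINFORMATIVE = "uninformative"


class RecombinantInterval(enum.Enum):
    FLANK1_TO_S = "flank1_to_S"
    S_TO_FLANK2 = "S_to_flank2"


@dataclass(frozen=True)
class MarkerCall:
    """One gel-blot call: individual x marker, with free-text band sizes."""

    individual_id: str
    marker_id: str
    allele_state: AlleleState
    bands: str = ""


@dataclass(frozen=True)
class MarkerPhase:
    """Phase of a codominant marker in the informative parent.

    ``thrum_allele_with_s`` records that the thrum-specific allele is in
    coupling with the dominant *S* haplotype (the configuration of all the
    markers scored here).  Dominant presence/absence markers cannot be
    phased this way and are refused for placement.
    """

    marker_id: str
    thrum_allele_with_s: bool = True
    codominant: bool = True


@dataclass(frozen=True)
class RecombinantRecord:
    """A classified single-crossover individual used as a mapping reagent."""

    individual_id: str
    crossover_interval: RecombinantInterval
    morph: Morph


@dataclass
class PlacementResult:
    """Where a marker can and cannot sit relative to *S* and its flanks."""

    marker_id: str
    excluded_positions: set[MarkerPosition] = field(default_factory=set)
    supported_position: MarkerPosition | None = None  # None = indeterminate
    evidence: list[tuple[RecombinantRecord, Verdict]] = field(default_factory=list)
    novel_individuals: tuple[str, ...] = ()
    distance: IntervalEstimate | None = None
    distance_if_novel_is_recombination: IntervalEstimate | None = None

    def __post_init__(self):
        if self.supported_position in self.excluded_positions:
            raise DataError(
                f"marker {self.marker_id!r}: supported position contradicts exclusions"
            )


def cosegregation_verdict(
    rec: RecombinantRecord,
    call: MarkerCall,
    phase: MarkerPhase | None,
) -> Verdict:
    """Did the marker stay coupled to its *S*-side allele in this recombinant?

    The informative gamete's *S* allele is read off the morph (thrum progeny
    received the dominant *S* haplotype, pin progeny the recessive one, the
    tester always contributing a pin gamete).  A thrum recombinant retaining
    thrum/pin heterozygosity, or a pin recombinant homozygous for the pin
    allele, kept the marker with *S*; the opposite state means the marker
    recombined away.  Novel or missing calls are uninformative (novel bands
    are flagged separately, never silently interpreted).
    """
    if phase is None:
        raise DesignError(f"marker {call.marker_id!r}: phase in the informative parent required")
    if not phase.codominant:
        raise DesignError(
            f"marker {call.marker_id!r} is a dominant presence/absence marker; its "
            "segregation cannot distinguish heterozygotes, so placement from allele "
            "calls is refused (position it by physical/sequence evidence instead)"
        )
    if call.allele_state in (AlleleState.NOVEL_BAND, AlleleState.MISSING):
        return Verdict.UNINFORMATIVE
    if rec.morph not in (Morph.PIN, Morph.THRUM):
        return Verdict.UNINFORMATIVE
    gamete_carried_s = rec.morph is Morph.THRUM
    if not phase.thrum_allele_with_s:
        gamete_carried_s = not gamete_carried_s
    expected = (
        AlleleState.THRUM_PIN_HETEROZYGOUS if gamete_carried_s
        else AlleleState.PIN_ONLY_HOMOZYGOUS
    )
    return Verdict.MARKER_WITH_S if call.allele_state is expected \
        else Verdict.MARKER_RECOMBINED_FROM_S


def place_marker(
    marker_id: str,
    verdicts: list[tuple[RecombinantRecord, Verdict]],
    novel_individuals: tuple[str, ...] = (),
) -> PlacementResult:
    """Combine per-recombinant verdicts into a placement.

    Per flank F: any retained (``MARKER_WITH_S``) verdict among F-to-*S*
    recombinants excludes ``distal to F``; retained and recombined verdicts
    together support ``between F and S``; recombined verdicts only (no
    retention) support ``distal to F``.  With no recombined verdict anywhere
    the placement is indeterminate within the non-excluded region.
    """
    if not any(v is not Verdict.UNINFORMATIVE for _, v in verdicts):
        raise DataError(f"marker {marker_id!r}: no informative verdicts")
    seen: dict[str, Verdict] = {}
    for rec, v in verdicts:
        if v is Verdict.UNINFORMATIVE:
            continue
        prev = seen.get(rec.individual_id)
        if prev is not None and prev is not v:
            raise DataError(
                f"marker {marker_id!r}: contradictory verdicts for individual "
                f"{rec.individual_id!r}"
            )
        seen[rec.individual_id] = v

    tallies: dict[RecombinantInterval, dict[Verdict, int]] = {
        iv: defaultdict(int) for iv in RecombinantInterval
    }
    for rec, v in verdicts:
        if v is not Verdict.UNINFORMATIVE:
            tallies[rec.crossover_interval][v] += 1

    flank_map = {
        RecombinantInterval.FLANK1_TO_S: (
            MarkerPosition.DISTAL_TO_FLANK1, MarkerPosition.BETWEEN_FLANK1_AND_S),
        RecombinantInterval.S_TO_FLANK2: (
            MarkerPosition.DISTAL_TO_FLANK2, MarkerPosition.BETWEEN_S_AND_FLANK2),
    }
    excluded: set[MarkerPosition] = set()
    supported: list[MarkerPosition] = []
    for iv, (distal, between) in flank_map.items():
        n_with = tallies[iv][Verdict.MARKER_WITH_S]
        n_rec = tallies[iv][Verdict.MARKER_RECOMBINED_FROM_S]
        if n_with > 0:
            excluded.add(distal)
        if n_rec > 0 and n_with > 0:
            supported.append(between)
        elif n_rec > 0 and n_with == 0:
            supported.append(distal)
    if len(supported) > 1:
        raise DataError(
            f"marker {marker_id!r}: evidence supports conflicting positions {supported}"
        )
    return PlacementResult(
        marker_id=marker_id,
        excluded_positions=excluded,
        supported_position=supported[0] if supported else None,
        evidence=list(verdicts),
        novel_individuals=tuple(novel_individuals),
    )


def marker_distance(
    marker_recombinants: int,
    total_progeny: int,
    novel_caveat: bool = False,
) -> IntervalEstimate:
    """Marker-to-*S* distance against the full screened progeny count.

    With ``novel_caveat`` the single putative event may be a mutation rather
    than a crossover, so the value is an upper bound (printed with ``<=``).
    """
    if marker_recombinants == 0:
        return zero_recombinant_bound(total_progeny)
    est = interval_distance(marker_recombinants, total_progeny)
    if novel_caveat:
        return IntervalEstimate(
            interval=est.interval, count=est.count, total=est.total, is_bound=False,
            convention=est.convention,
        )
    return est


def placement_report(
    placements: list[PlacementResult],
    flank_names: tuple[str, str] = ("flank1", "flank2"),
    s_name: str = "S",
) -> pd.DataFrame:
    """Human-oriented table of placements and distances."""
    pos_label = {
        MarkerPosition.DISTAL_TO_FLANK1: f"distal to {flank_names[0]}",
        MarkerPosition.BETWEEN_FLANK1_AND_S: f"between {flank_names[0]} and {s_name}",
        MarkerPosition.BETWEEN_S_AND_FLANK2: f"between {s_name} and {flank_names[1]}",
        MarkerPosition.DISTAL_TO_FLANK2: f"distal to {flank_names[1]}",
        None: "indeterminate",
    }
    rows = []
    for p in placements:
        parts = []
        if p.distance is not None:
            parts.append(p.distance.printed)
        if p.distance_if_novel_is_recombination is not None:
            alt = p.distance_if_novel_is_recombination
            # recombination reading gives the distance, mutation reading a bound
            parts.append(f"{fmt_cm(alt.distance_cm)} / <= {fmt_cm(alt.distance_cm)}")
        dist = " ; ".join(parts)
        rows.append({
            "marker": p.marker_id,
            "position": pos_label[p.supported_position],
            "excluded": "; ".join(sorted(pos_label[e] for e in p.excluded_positions)),
            "novel_bands": "; ".join(p.novel_individuals),
            "distance_cm": dist,
        })
    return pd.DataFrame(rows)


def analyse_marker(
    marker_id: str,
    recombinants: list[RecombinantRecord],
    calls: dict[str, MarkerCall],
    phase: MarkerPhase,
    total_progeny: int,
) -> PlacementResult:
    """End-to-end placement of one marker from recombinants and their calls.

    ``calls`` maps individual id to that individual's call for this marker;
    recombinants without a call are skipped.  The distance uses the number
    of ``MARKER_RECOMBINED_FROM_S`` verdicts over ``total_progeny``; when
    the only putative events are novel bands, the dual reading (distance if
    recombination, bound if mutation) is attached instead.
    """
    if not phase.codominant:
        raise DesignError(
            f"marker {marker_id!r} is a dominant presence/absence marker; its "
            "segregation cannot distinguish heterozygotes, so placement from allele "
            "calls is refused (position it by physical/sequence evidence instead)"
        )
    verdicts = []
    novel = []
    for rec in recombinants:
        call = calls.get(rec.individual_id)
        if call is None:
            continue
        v = cosegregation_verdict(rec, call, phase)
        verdicts.append((rec, v))
        if call.allele_state is AlleleState.NOVEL_BAND:
            novel.append(rec.individual_id)
    placement = place_marker(marker_id, verdicts, tuple(novel))
    n_rec = sum(1 for _, v in verdicts if v is Verdict.MARKER_RECOMBINED_FROM_S)
    if n_rec > 0:
        placement.distance = marker_distance(n_rec, total_progeny)
    if novel:
        placement.distance_if_novel_is_recombination = marker_distance(
            n_rec + len(novel), total_progeny, novel_caveat=True
        )
    if n_rec == 0 and not novel:
        placement.distance = marker_distance(0, total_progeny)
    return placement
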