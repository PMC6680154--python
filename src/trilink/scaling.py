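"""Genetic-to-physical map scaling: kb of anchored sequence per cM.

A contig of known physical length anchored between two mapped points gives
a local kb/cM relationship; because the genetic distance is itself only
known as a range across parents, the relationship is reported as a range.
Summed anchored segment lengths give a lower bound on the physical
separation of loci on opposite ends of an assembly gap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from ._util import round_half_up
from .errors import DataError


@dataclass(frozen=True)
class ScalingResult:
    """kb-per-cM ratio for one contig/distance pairing."""

    contig_kb: float
    distance_cm: float

    @property
    def kb_per_cm(self) -> float:
        return self.contig_kb / self.distance_cm

    @property
    def kb_per_cm_rounded(self) -> int:
        """Ratio rounded half-up to integer kb, as reported."""
        return int(round_half_up(self.kb_per_cm, 0))


def kb_per_cm(contig_kb: float, distance_cm: float) -> ScalingResult:
    """Physical length per map unit; errors on zero distance (a zero-
    recombinant locus pair has no ratio, only a separation bound)."""
    if contig_kb <= 0:
        raise DataError("contig length must be positive kb")
    if distance_cm <= 0:
        raise DataError(
            "genetic distance must be positive; for zero-recombinant pairs use "
            "separation_bound on the anchored segment lengths instead"
        )
    return ScalingResult(contig_kb=float(contig_kb), distance_cm=float(distance_cm))


def range_scaling(
    contig_kb: float, distance_range_cm: tuple[float, float]
) -> tuple[ScalingResult, ScalingResult]:
    """kb/cM interval implied by a cM range: [kb/high, kb/low]."""
    low, high = distance_range_cm
    if not (0 < low <= high):
        raise DataError(f"invalid cM range {distance_range_cm}: need 0 < low <= high")
    return (kb_per_cm(contig_kb, high), kb_per_cm(contig_kb, low))


def separation_bound(anchored_segments_kb: Sequence[float]) -> float:
    """Lower bound (kb) on the physical separation spanned by anchored
    segments: their summed length (gaps only add distance)."""
    segments = list(anchored_segments_kb)
    if not segments:
        raise DataError("separation bound needs at least one anchored segment")
    if any(s < 0 for s in segments):
        raise DataError("segment lengths must be non-negative")
    return float(sum(segments))


def format_mb(kb: float) -> str:
    """Render kb at one-decimal Mb, e.g. 1510 -> '1.5 Mb'."""
    return f"{round_half_up(kb / 1000.0, 1):.1f} Mb"
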