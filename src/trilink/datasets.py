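"""Packaged study datasets: the *Primula vulgaris* S-locus crosses.

Everything here is tabulated plain text shipped with the package (progeny
class and recombinant counts of the two three-point crosses, single-marker
cosegregation totals, RFLP calls on blotted recombinants, and contig
lengths for physical scaling), so the full analysis is reproducible
offline.  Rows standing in for individuals reported only in aggregate are
marked synthetic in the fixture file comments.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd
import yaml

from .genetics import CrossDesign, Morph, ParentGenotype
from .markers import (
    AlleleState,
    MarkerCall,
    MarkerPhase,
    RecombinantInterval,
    RecombinantRecord,
)

#: Total progeny screened in the Oakleaf-S-Hose in Hose crosses; the
#: denominator for marker-to-S distances.
OKL_S_HIH_TOTAL_PROGENY = 2075


def _path(name: str):
    return resources.files("trilink.data").joinpath(name)


def _read_csv(name: str) -> pd.DataFrame:
    with resources.as_file(_path(name)) as p:
        return pd.read_csv(p, comment="#")


def _read_yaml(name: str) -> dict:
    return yaml.safe_load(_path(name).read_text())


def load_design(name: str) -> tuple[CrossDesign, dict[str, ParentGenotype]]:
    """Load a packaged cross design (``okl_s_hih`` or ``okl_s_sep``)."""
    from .io import design_from_dict

    return design_from_dict(_read_yaml(f"design_{name}.yaml"))


def okl_s_hih_design() -> tuple[CrossDesign, dict[str, ParentGenotype]]:
    return load_design("okl_s_hih")


def okl_s_sep_design() -> tuple[CrossDesign, dict[str, ParentGenotype]]:
    return load_design("okl_s_sep")


def okl_s_hih_interval_counts() -> pd.DataFrame:
    """Per-cross recombinant counts of the six Oakleaf-S-Hose in Hose crosses."""
    return _read_csv("okl_s_hih_interval_counts.csv")


def okl_s_hih_published() -> dict:
    """Printed pooled rows for reconciliation (including the inconsistent
    thrum-1 S-to-HIH cell)."""
    return _read_yaml("okl_s_hih_published.yaml")


def okl_s_sep_interval_counts() -> pd.DataFrame:
    return _read_csv("okl_s_sep_interval_counts.csv")


def okl_s_sep_published() -> dict:
    return _read_yaml("okl_s_sep_published.yaml")


def okl_s_sep_pair_counts() -> pd.DataFrame:
    """Pooled reciprocal-pair counts of the Oakleaf-S-sepaloid progeny
    (592 parental, 6 + 2 single-crossover, 1 double)."""
    return _read_csv("okl_s_sep_pair_counts.csv")


def single_marker_cosegregation() -> pd.DataFrame:
    """F2 cosegregation totals of the four S-linked molecular markers."""
    return _read_csv("single_marker_cosegregation.csv")


def marker_recombinants() -> list[RecombinantRecord]:
    """Blotted single-crossover recombinants as placement reagents."""
    df = _read_csv("marker_recombinants.csv")
    return [
        RecombinantRecord(
            individual_id=str(r.individual_id),
            crossover_interval=RecombinantInterval(r.crossover_interval),
            morph=Morph(r.morph),
        )
        for r in df.itertuples()
    ]


def marker_calls() -> dict[str, dict[str, MarkerCall]]:
    """RFLP calls keyed by marker id then individual id."""
    df = _read_csv("marker_calls.csv")
    out: dict[str, dict[str, MarkerCall]] = {}
    for r in df.itertuples():
        call = MarkerCall(
            individual_id=str(r.individual_id),
            marker_id=str(r.marker_id),
            allele_state=AlleleState(r.allele_state),
            bands=str(r.bands),
        )
        out.setdefault(call.marker_id, {})[call.individual_id] = call
    return out


def marker_phases() -> dict[str, MarkerPhase]:
    """Phases of the scored markers: thrum-specific RFLP alleles in coupling
    with the dominant *S* haplotype.  PvSLP1 is a dominant (presence/absence)
    marker and cannot be placed by segregation."""
    return {
        "PvSLL1": MarkerPhase("PvSLL1", thrum_allele_with_s=True),
        "PvSLL2": MarkerPhase("PvSLL2", thrum_allele_with_s=True),
        "PvSLP1": MarkerPhase("PvSLP1", thrum_allele_with_s=True, codominant=False),
    }


def contig_lengths() -> dict:
    """Assembled sequence-group lengths (kb) and scaling inputs."""
    return _read_yaml("contig_lengths.yaml")


def fixture_names() -> list[str]:
    """File names of all packaged fixtures (for the ``fixtures`` CLI)."""
    return sorted(
        p.name for p in resources.files("trilink.data").iterdir()
        if p.name.endswith((".csv", ".yaml"))
    )


def fixture_text(name: str) -> str:
    return _path(name).read_text()
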