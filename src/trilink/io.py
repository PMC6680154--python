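"""Readers and writers: design configs, progeny tables, reports.

The data of a testcross study are phenotype class counts and marker calls,
so the interchange formats are plain CSV with explicit headers and a small
controlled vocabulary, plus YAML for cross designs.  Reports are TSV with
``#`` header comments echoing the configuration and seed, and rerunning
with the same inputs produces byte-identical files.
"""

from __future__ import annotations

import sys
from pathlib import Path

import pandas as pd
import yaml

from .errors import DataError, DesignError
from .genetics import CrossDesign, Dominance, Locus, ParentGenotype, Role
from .threepoint import CrossRecord, records_from_interval_counts, records_from_progeny


def design_from_dict(cfg: dict) -> tuple[CrossDesign, dict[str, ParentGenotype]]:
    """Build a design and its parents from a parsed config mapping."""
    try:
        loci_cfg = cfg["loci"]
    except KeyError:
        raise DesignError("design config needs a 'loci' list") from None
    loci = []
    for lc in loci_cfg:
        dominance = Dominance(lc["dominance"])
        symbols = lc.get("symbols") or (None, None)
        loci.append(
            Locus(
                name=str(lc["name"]),
                dominance=dominance,
                dominant_symbol=symbols[0],
                recessive_symbol=symbols[1],
            )
        )
    design = CrossDesign(loci=tuple(loci), name=str(cfg.get("name", "design")))
    parents: dict[str, ParentGenotype] = {}
    for pc in cfg.get("parents", []):
        parents[str(pc["id"])] = ParentGenotype(
            id=str(pc["id"]),
            haplotype_1=design.parse_haplotype(pc["haplotypes"][0]),
            haplotype_2=design.parse_haplotype(pc["haplotypes"][1]),
            role=Role(pc.get("role", "informative")),
        )
    return design, parents


def read_design(path: str | Path) -> tuple[CrossDesign, dict[str, ParentGenotype]]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return design_from_dict(cfg)


def read_progeny_table(
    path: str | Path,
    design: CrossDesign,
    parents: dict[str, ParentGenotype],
) -> list[CrossRecord]:
    """Read a progeny CSV into cross records.

    Two schemas are accepted, distinguished by the columns present:

    * tabulated interval counts: ``cross_id, informative_parent, total,
      rec_interval_1, rec_interval_2[, intra_s]``;
    * per-individual or per-class phenotype rows: ``cross_id`` plus one
      column per locus (values ``mutant``/``wild_type``/``unscored``, morph
      names at *S*) and optional ``count``/``individual_id``.

    Unknown phenotype labels are rejected with the offending CSV line.
    """
    df = pd.read_csv(path, comment="#")
    if df.empty:
        raise DataError(f"{path}: empty progeny table")
    if "rec_interval_1" in df.columns:
        return records_from_interval_counts(df)
    missing = [n for n in design.locus_order if n not in df.columns]
    if missing:
        raise DataError(f"{path}: progeny table lacks locus columns {missing}")
    try:
        return records_from_progeny(df, design, parents)
    except DataError as err:
        raise DataError(f"{path}: {err}") from err


def write_progeny_table(df: pd.DataFrame, path: str | Path, header: dict | None = None,
                        omit_truth: bool = False) -> None:
    """Write a simulated (or observed) per-individual progeny table."""
    out = df.drop(columns=[c for c in df.columns if c.startswith("_")], errors="ignore")
    if omit_truth:
        out = out.drop(columns=["true_category"], errors="ignore")
    _write_with_header(out, path, header, sep=",")


def write_report(df: pd.DataFrame, path: str | Path, header: dict | None = None) -> None:
    """Write a TSV report with deterministic column order and a comment
    header echoing the run configuration."""
    _write_with_header(df, path, header, sep="\t")


def _write_with_header(df: pd.DataFrame, path: str | Path, header: dict | None, sep: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        for key in sorted(header or {}):
            fh.write(f"# {key}: {header[key]}\n")
        df.to_csv(fh, sep=sep, index=False)


def write_text_report(text: str, path: str | Path, header: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key in sorted(header or {}):
            fh.write(f"# {key}: {header[key]}\n")
        fh.write(text)
        if not text.endswith("\n"):
            fh.write("\n")


def log(message: str) -> None:
    """Context-bearing warnings go to stderr; report-worthy inconsistencies
    are emitted as annotations in the report itself, not hidden here."""
    print(f"trilink: {message}", file=sys.stderr)
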