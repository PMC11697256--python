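"""Proteome-wide cysteine enumeration, in-silico tryptic digestion and
annotation joins.

Trypsin cleaves C-terminal to lysine or arginine unless the next residue is
proline.  A fully cleaved peptide of 7-40 residues is classed as
MS-detectable; a cysteine is "detectable" when it lies inside such a peptide.
A wider regime (7-52 residues, up to two missed cleavages) mirrors the
search-space configuration of the DIA library and is available as a preset.

Annotation tables (UniProt PTM/disulfide, Pharos IDG family and target
development level, published pPSE values, abundance flags) are consumed as
user-supplied TSVs and left-joined onto the site table; nothing is ever
downloaded.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .aggregate import SiteKey

__all__ = [
    "DigestPeptide",
    "CysteineAnnotation",
    "DigestPreset",
    "DETECTABILITY_PRESET",
    "SEARCH_SPACE_PRESET",
    "tryptic_digest",
    "cysteine_site_table",
    "annotate_sites",
    "sites_frame",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWYU")

TDL_CLASSES = ("Tclin", "Tchem", "Tbio", "Tdark")


@dataclass(frozen=True)
class DigestPreset:
    min_length: int
    max_length: int
    missed_cleavages: int


# Detectability classification: fully cleaved 7-40mers.
DETECTABILITY_PRESET = DigestPreset(7, 40, 0)
# Search-space emulation: 7-52mers with up to two missed cleavages.
SEARCH_SPACE_PRESET = DigestPreset(7, 52, 2)


@dataclass(frozen=True)
class DigestPeptide:
    accession: str
    start: int  # 1-based inclusive
    end: int
    sequence: str
    missed_cleavages: int
    detectable: bool

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class CysteineAnnotation:
    site: SiteKey
    in_detectable_peptide: bool
    host_peptide: DigestPeptide | None = None
    disulfide: bool | None = None
    ptm: bool | None = None
    abundant_protein: bool | None = None
    ppse: float | None = None
    idg_family: str | None = None
    tdl: str | None = None
    pocket: bool | None = None


def _validate_sequence(sequence: str) -> None:
    for i, ch in enumerate(sequence):
        if ch not in AMINO_ACIDS:
            raise ValueError(
                f"non-amino-acid character {ch!r} at position {i + 1}"
            )


def cleavage_points(sequence: str) -> list[int]:
    """0-based indices *after* which trypsin cuts (K/R not followed by P)."""
    return [
        i
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def tryptic_digest(
    sequence: str,
    missed_cleavages: int = 0,
    accession: str = "",
    min_length: int = 7,
    max_length: int = 40,
    detectable_max_mc: int = 0,
) -> list[DigestPeptide]:
    """Digest a protein, emitting peptides with 0..``missed_cleavages``
    internal missed cleavage sites.

    ``detectable`` marks peptides within the length window and at most
    ``detectable_max_mc`` missed cleavages.  The protein's C-terminal peptide
    has no downstream residue to test and is included as-is.
    """
    if not sequence:
        raise ValueError("empty sequence")
    sequence = sequence.upper()
    _validate_sequence(sequence)
    cuts = cleavage_points(sequence)
    # fragment boundaries as 0-based half-open [start, end)
    starts = [0] + [c + 1 for c in cuts]
    ends = [c + 1 for c in cuts] + [len(sequence)]
    peptides: list[DigestPeptide] = []
    n = len(starts)
    for i in range(n):
        for mc in range(missed_cleavages + 1):
            j = i + mc
            if j >= n:
                break
            start, end = starts[i], ends[j]
            seq = sequence[start:end]
            detectable = (
                min_length <= len(seq) <= max_length and mc <= detectable_max_mc
            )
            peptides.append(
                DigestPeptide(
                    accession=accession,
                    start=start + 1,
                    end=end,
                    sequence=seq,
                    missed_cleavages=mc,
                    detectable=detectable,
                )
            )
    return peptides


def cysteine_site_table(
    proteome: Mapping[str, str],
    missed_cleavages: int = 0,
    preset: DigestPreset | None = None,
) -> list[CysteineAnnotation]:
    """One row per cysteine residue per protein, with detectability from the
    in-silico digest (detectability preset by default)."""
    preset = preset or DigestPreset(7, 40, missed_cleavages if missed_cleavages
                                    else DETECTABILITY_PRESET.missed_cleavages)
    out: list[CysteineAnnotation] = []
    for accession in sorted(proteome):
        sequence = proteome[accession].upper()
        peptides = tryptic_digest(
            sequence,
            missed_cleavages=preset.missed_cleavages,
            accession=accession,
            min_length=preset.min_length,
            max_length=preset.max_length,
            detectable_max_mc=preset.missed_cleavages,
        )
        detectable = [p for p in peptides if p.detectable]
        for idx, ch in enumerate(sequence, start=1):
            if ch != "C":
                continue
            host = next(
                (p for p in detectable if p.start <= idx <= p.end), None
            )
            out.append(
                CysteineAnnotation(
                    site=SiteKey(accession, idx),
                    in_detectable_peptide=host is not None,
                    host_peptide=host,
                )
            )
    return out


def sites_frame(sites: Iterable[CysteineAnnotation]) -> pd.DataFrame:
    rows = []
    for s in sites:
        rows.append(
            {
                "protein_accession": s.site.protein_accession,
                "residue_index": s.site.residue_index,
                "in_detectable_peptide": s.in_detectable_peptide,
                "host_peptide": s.host_peptide.sequence if s.host_peptide else None,
                "disulfide": s.disulfide,
                "ptm": s.ptm,
                "abundant_protein": s.abundant_protein,
                "ppse": s.ppse,
                "idg_family": s.idg_family,
                "tdl": s.tdl,
                "pocket": s.pocket,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "protein_accession",
            "residue_index",
            "in_detectable_peptide",
            "host_peptide",
            "disulfide",
            "ptm",
            "abundant_protein",
            "ppse",
            "idg_family",
            "tdl",
            "pocket",
        ],
    )


# annotation name -> (value column, is residue-level)
_ANNOTATION_SPECS = {
    "disulfide": ("disulfide", True),
    "ptm": ("ptm", True),
    "ppse": ("ppse", True),
    "pocket": ("pocket", True),
    "tdl": ("tdl", False),
    "idg_family": ("idg_family", False),
    "abundant_protein": ("abundant_protein", False),
}


def annotate_sites(
    sites: Sequence[CysteineAnnotation],
    tables: Mapping[str, pd.DataFrame],
) -> pd.DataFrame:
    """Left-join named annotation tables onto the cysteine site table.

    Residue-level tables (``disulfide``, ``ptm``, ``ppse``, ``pocket``) join
    on (accession, residue_index); protein-level tables (``tdl``,
    ``idg_family``, ``abundant_protein``) join on accession.  Tables must
    carry a ``protein_accession`` column, a ``residue_index`` column where
    residue-level, and the value column named after the table.  Unmatched
    sites keep absent (NA) values; duplicate keys are an error.
    """
    df = sites_frame(sites)
    for name, table in tables.items():
        if name not in _ANNOTATION_SPECS:
            raise ValueError(
                f"unknown annotation table {name!r}; expected one of "
                f"{sorted(_ANNOTATION_SPECS)}"
            )
        value_col, residue_level = _ANNOTATION_SPECS[name]
        keys = ["protein_accession"] + (["residue_index"] if residue_level else [])
        missing = [k for k in keys + [value_col] if k not in table.columns]
        if missing:
            raise ValueError(
                f"annotation table {name!r} lacks column(s) {missing}"
            )
        dup = table[table.duplicated(subset=keys, keep=False)]
        if len(dup):
            raise ValueError(
                f"annotation table {name!r} has duplicate keys:\n"
                f"{dup[keys].drop_duplicates().to_string(index=False)}"
            )
        df = df.drop(columns=[value_col]).merge(
            table[keys + [value_col]], on=keys, how="left"
        )
    return df
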