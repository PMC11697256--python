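"""Data model and I/O for competitive cysteine-profiling experiments.

The platform quantifies desthiobiotin (DTB)-tagged cysteine peptides by
label-free DIA mass spectrometry.  The search engine exports a long-format,
precursor-level report (one row per sample x precursor); this module parses
that report together with a sample metadata table and, optionally, a protein
FASTA.  Missing values are represented by the *absence* of a row, never by a
stored zero or sentinel.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, fields
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "Role",
    "SampleMeta",
    "PrecursorRecord",
    "ParsedModifiedSequence",
    "FormatError",
    "ValidationError",
    "DEFAULT_MOD_TOKENS",
    "DEFAULT_SAMPLE_COLUMNS",
    "DEFAULT_REPORT_COLUMNS",
    "read_sample_table",
    "read_precursor_report",
    "records_from_frame",
    "parse_modified_sequence",
    "read_fasta",
    "write_table",
    "read_table",
    "sample_frame",
]


class FormatError(ValueError):
    """A file does not match the expected tabular schema."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


class Role(str, Enum):
    control = "control"
    treated = "treated"


# Logical column name -> default physical column name.  Search-engine exports
# with other headers are adapted by passing a ``dialect`` mapping.
DEFAULT_SAMPLE_COLUMNS: dict[str, str] = {
    "sample_id": "sample_id",
    "role": "role",
    "compound_id": "compound_id",
    "concentration_um": "concentration_um",
    "replicate_index": "replicate_index",
    "context": "context",
    "experiment_id": "experiment_id",
}

DEFAULT_REPORT_COLUMNS: dict[str, str] = {
    "sample_id": "sample_id",
    "protein_accession": "accession",
    "modified_sequence": "modified_sequence",
    "charge": "charge",
    "intensity": "intensity",
}

# Inline modification tokens recognised inside bracketed annotations.  Tags
# not listed here are retained verbatim (class ``other:<tag>``) so that
# unexpected search-engine annotations never crash parsing, while still
# keeping differently modified peptides distinct.
DEFAULT_MOD_TOKENS: dict[str, str] = {
    "DTB": "dtb",
    "IA-DTB": "dtb",
    "Carbamidomethyl": "carbamidomethyl",
    "CAM": "carbamidomethyl",
    "Oxidation": "oxidation",
    "Oxidation (M)": "oxidation",
    "Acetyl": "acetyl",
    "Acetyl (Protein N-term)": "acetyl",
}


@dataclass(frozen=True)
class SampleMeta:
    """One MS run: its role in the screen and, if treated, its compound dose."""

    sample_id: str
    role: Role
    compound_id: str | None = None
    concentration_um: float | None = None
    replicate_index: int = 1
    context: str = ""
    experiment_id: str = "exp1"

    def __post_init__(self) -> None:
        role = Role(self.role)
        object.__setattr__(self, "role", role)
        if role is Role.control:
            if self.compound_id is not None or self.concentration_um is not None:
                raise ValidationError(
                    f"control sample {self.sample_id!r} must not carry a "
                    "compound_id or concentration"
                )
        else:
            if self.compound_id is None or self.concentration_um is None:
                raise ValidationError(
                    f"treated sample {self.sample_id!r} requires both "
                    "compound_id and concentration_um"
                )
            if self.concentration_um <= 0:
                raise ValidationError(
                    f"treated sample {self.sample_id!r} has non-positive "
                    f"concentration {self.concentration_um}"
                )
        if self.replicate_index < 1:
            raise ValidationError(
                f"sample {self.sample_id!r}: replicate_index must be >= 1"
            )


@dataclass(frozen=True)
class ParsedModifiedSequence:
    stripped_sequence: str
    dtb_positions: tuple[int, ...]  # 1-based within the peptide
    metox_count: int
    other_mods: tuple[tuple[int, str], ...]  # identity-defining non-Met-ox mods


@dataclass(frozen=True)
class PrecursorRecord:
    """One quantified precursor observation in one sample (a report row)."""

    sample_id: str
    protein_accession: str
    stripped_sequence: str
    modified_sequence: str
    charge: int
    intensity: float
    dtb_count: int
    metox_count: int
    dtb_positions: tuple[int, ...] = ()
    other_mods: tuple[tuple[int, str], ...] = ()


_MOD_RE = re.compile(r"\[([^\[\]]+)\]")


def parse_modified_sequence(
    modseq: str, tokens: Mapping[str, str] | None = None
) -> ParsedModifiedSequence:
    """Parse an inline-annotated peptide such as ``AC[DTB]DM[Oxidation]EK``.

    Grammar: an optional N-terminal ``[Tag]-`` prefix, then uppercase residues
    each optionally followed by one or more ``[Tag]`` annotations attached to
    the preceding residue.  Returns the stripped sequence, the 1-based
    positions of DTB-tagged residues, the methionine-oxidation count and any
    other identity-defining modifications.
    """
    tokens = DEFAULT_MOD_TOKENS if tokens is None else tokens
    s = modseq.strip()
    other: list[tuple[int, str]] = []
    # N-terminal annotation, conventionally written "[Acetyl]-PEPTIDEK"
    m = re.match(r"^\[([^\[\]]+)\]-", s)
    if m:
        tag = tokens.get(m.group(1), f"other:{m.group(1)}")
        if tag not in ("oxidation",):
            other.append((0, tag))
        s = s[m.end():]

    stripped: list[str] = []
    dtb: list[int] = []
    metox = 0
    i = 0
    while i < len(s):
        ch = s[i]
        if ch == "[":
            end = s.find("]", i)
            if end == -1:
                raise FormatError(f"unterminated modification bracket in {modseq!r}")
            name = s[i + 1 : end]
            if not stripped:
                raise FormatError(
                    f"modification {name!r} not attached to a residue in {modseq!r}"
                )
            pos = len(stripped)
            tag = tokens.get(name, f"other:{name}")
            if tag == "dtb":
                dtb.append(pos)
            elif tag == "oxidation":
                metox += 1
            elif tag == "carbamidomethyl":
                # fixed-type cysteine cap; not identity-defining beyond the tag
                other.append((pos, tag))
            else:
                other.append((pos, tag))
            i = end + 1
        elif ch.isalpha() and ch.isupper():
            stripped.append(ch)
            i += 1
        else:
            raise FormatError(
                f"unexpected character {ch!r} at position {i} in {modseq!r}"
            )
    seq = "".join(stripped)
    if len(dtb) != len(set(dtb)):
        raise FormatError(f"duplicate DTB annotation on one residue in {modseq!r}")
    for p in dtb:
        if seq[p - 1] != "C":
            raise FormatError(
                f"DTB annotation on non-cysteine residue {seq[p - 1]!r} in {modseq!r}"
            )
    if len(dtb) > seq.count("C"):
        raise FormatError(f"more DTB tags than cysteines in {modseq!r}")
    return ParsedModifiedSequence(seq, tuple(sorted(dtb)), metox, tuple(sorted(other)))


def _apply_dialect(
    df: pd.DataFrame, dialect: Mapping[str, str] | None, defaults: Mapping[str, str],
    required: Sequence[str], path: str | Path,
) -> pd.DataFrame:
    colmap = dict(defaults)
    if dialect:
        colmap.update(dialect)
    missing = [colmap[k] for k in required if colmap[k] not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s) {', '.join(missing)}"
        )
    rename = {v: k for k, v in colmap.items() if v in df.columns}
    return df.rename(columns=rename)


def read_sample_table(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> list[SampleMeta]:
    """Read a tab-separated sample metadata table into validated records."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    df = _apply_dialect(
        df, dialect, DEFAULT_SAMPLE_COLUMNS, ["sample_id", "role"], path
    )
    dup = df["sample_id"][df["sample_id"].duplicated()].unique().tolist()
    if dup:
        raise ValidationError(f"{path}: duplicate sample_id(s): {', '.join(dup)}")
    out: list[SampleMeta] = []
    for row in df.itertuples(index=False):
        d = row._asdict()

        def _get(key: str) -> str | None:
            v = d.get(key)
            if v is None or (isinstance(v, float) and pd.isna(v)) or v == "":
                return None
            return v

        try:
            out.append(
                SampleMeta(
                    sample_id=d["sample_id"],
                    role=Role(d["role"]),
                    compound_id=_get("compound_id"),
                    concentration_um=(
                        float(c) if (c := _get("concentration_um")) is not None else None
                    ),
                    replicate_index=int(_get("replicate_index") or 1),
                    context=_get("context") or "",
                    experiment_id=_get("experiment_id") or "exp1",
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}, sample {d['sample_id']!r}: {exc}") from exc
        except ValueError as exc:
            raise FormatError(f"{path}, sample {d['sample_id']!r}: {exc}") from exc
    return out


def sample_frame(samples: Iterable[SampleMeta]) -> pd.DataFrame:
    rows = []
    for s in samples:
        rows.append(
            {
                "sample_id": s.sample_id,
                "role": s.role.value,
                "compound_id": s.compound_id,
                "concentration_um": s.concentration_um,
                "replicate_index": s.replicate_index,
                "context": s.context,
                "experiment_id": s.experiment_id,
            }
        )
    return pd.DataFrame(rows, columns=list(DEFAULT_SAMPLE_COLUMNS))


def records_from_frame(
    df: pd.DataFrame,
    samples: Sequence[SampleMeta] | None = None,
    tokens: Mapping[str, str] | None = None,
) -> list[PrecursorRecord]:
    """Build precursor records from a logical-schema report frame.

    Non-positive or non-numeric intensities are dropped (count logged); the
    modified-sequence grammar is parsed once per unique sequence.
    """
    known = {s.sample_id for s in samples} if samples is not None else None
    intensity = pd.to_numeric(df["intensity"], errors="coerce")
    keep = intensity > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d precursor rows with missing/non-positive intensity",
                    n_dropped)
    df = df.loc[keep]
    intensity = intensity.loc[keep]

    cache: dict[str, ParsedModifiedSequence] = {}
    records: list[PrecursorRecord] = []
    cols = zip(
        df["sample_id"].astype(str),
        df["protein_accession"].astype(str),
        df["modified_sequence"].astype(str),
        df["charge"].astype(int),
        intensity.astype(float),
    )
    for i, (sid, acc, modseq, charge, inten) in enumerate(cols):
        if known is not None and sid not in known:
            raise ValidationError(
                f"report row {i}: sample_id {sid!r} not present in sample metadata"
            )
        parsed = cache.get(modseq)
        if parsed is None:
            try:
                parsed = parse_modified_sequence(modseq, tokens)
            except FormatError as exc:
                raise FormatError(f"report row {i}: {exc}") from exc
            cache[modseq] = parsed
        records.append(
            PrecursorRecord(
                sample_id=sid,
                protein_accession=acc,
                stripped_sequence=parsed.stripped_sequence,
                modified_sequence=modseq,
                charge=charge,
                intensity=inten,
                dtb_count=len(parsed.dtb_positions),
                metox_count=parsed.metox_count,
                dtb_positions=parsed.dtb_positions,
                other_mods=parsed.other_mods,
            )
        )
    return records


def read_precursor_report(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    samples: Sequence[SampleMeta] | None = None,
    tokens: Mapping[str, str] | None = None,
) -> list[PrecursorRecord]:
    """Read a long-format precursor-level quantification report (TSV)."""
    df = pd.read_csv(path, sep="\t")
    df = _apply_dialect(
        df,
        dialect,
        DEFAULT_REPORT_COLUMNS,
        ["sample_id", "protein_accession", "modified_sequence", "charge", "intensity"],
        path,
    )
    return records_from_frame(df, samples=samples, tokens=tokens)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a protein FASTA; the accession is the first token of the defline."""
    proteome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        proteome[rec.id] = str(rec.seq).upper()
    return proteome


def write_table(records, path: str | Path) -> None:
    """Write a result table (DataFrame or dataclass sequence) as TSV.

    Column order is deterministic (dataclass field order, or the frame's own
    order).  Floats are written with Python's shortest round-tripping repr, so
    read-back reproduces every value bit-exactly.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        records = list(records)
        if records and hasattr(records[0], "__dataclass_fields__"):
            cols = [f.name for f in fields(records[0])]
            df = pd.DataFrame(
                [{c: getattr(r, c) for c in cols} for r in records], columns=cols
            )
        else:
            df = pd.DataFrame(records)
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t")
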