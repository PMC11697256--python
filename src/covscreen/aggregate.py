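"""Precursor-to-peptide aggregation and cysteine-site mapping.

Precursors that differ only in charge state or methionine-oxidation state are
the same peptide from the screen's point of view; their intensities are summed
per sample.  Each DTB-tagged peptide is then anchored to a protein cysteine
(1-based residue index), and redundant cleavage forms covering the same site
(missed-cleavage variants) are resolved to the most abundant one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_model import PrecursorRecord, write_table

logger = logging.getLogger(__name__)

__all__ = [
    "SiteKey",
    "SiteQuant",
    "AggregationPolicy",
    "collapse_precursors",
    "map_sites",
    "dedupe_cleavage_forms",
    "audit_frame",
]


@dataclass(frozen=True, order=True)
class SiteKey:
    """A protein cysteine: accession plus 1-based residue index."""

    protein_accession: str
    residue_index: int


@dataclass
class SiteQuant:
    """Per-sample intensities for one DTB-modified peptide, keyed to a site."""

    protein_accession: str
    stripped_sequence: str
    dtb_positions: tuple[int, ...]  # 1-based within the peptide
    other_mods: tuple[tuple[int, str], ...]
    dtb_count: int
    intensity_by_sample: dict[str, float] = field(default_factory=dict)
    site: SiteKey | None = None
    ambiguous_mapping: bool = False
    unmapped: bool = False
    redundant_form: bool = False

    @property
    def peptide_key(self) -> tuple:
        return (
            self.protein_accession,
            self.stripped_sequence,
            self.dtb_positions,
            self.other_mods,
        )

    def detected_in(self, sample_id: str) -> bool:
        return sample_id in self.intensity_by_sample

    def mean_intensity(self) -> float:
        vals = self.intensity_by_sample.values()
        return sum(vals) / len(vals) if vals else 0.0

    def total_intensity(self) -> float:
        return sum(self.intensity_by_sample.values())


@dataclass
class AggregationPolicy:
    """How precursors collapse and how redundant cleavage forms are resolved.

    ``cleavage_form_rule`` picks the representative peptide per site:
    ``most_abundant_mean_all_samples`` (default; mean over samples in which
    the form is detected) or ``most_abundant_total`` (summed intensity).
    """

    cleavage_form_rule: str = "most_abundant_mean_all_samples"
    single_dtb_required: bool = True
    drop_non_dtb: bool = True

    def __post_init__(self) -> None:
        if self.cleavage_form_rule not in (
            "most_abundant_mean_all_samples",
            "most_abundant_total",
        ):
            raise ValueError(f"unknown cleavage_form_rule {self.cleavage_form_rule!r}")


def collapse_precursors(
    records: Iterable[PrecursorRecord], policy: AggregationPolicy | None = None
) -> list[SiteQuant]:
    """Sum precursor intensities over charge and Met-oxidation variants.

    Peptide identity = (accession, stripped sequence, DTB position set, other
    variable modifications).  A peptide counts as detected in a sample iff at
    least one contributing precursor was detected there.  Peptides carrying no
    DTB tag (e.g. carbamidomethylated-only forms) are dropped by default —
    the enrichment step of the platform selects DTB peptides.
    """
    policy = policy or AggregationPolicy()
    by_key: dict[tuple, SiteQuant] = {}
    n_non_dtb = 0
    for rec in records:
        if policy.drop_non_dtb and rec.dtb_count == 0:
            n_non_dtb += 1
            continue
        key = (
            rec.protein_accession,
            rec.stripped_sequence,
            rec.dtb_positions,
            rec.other_mods,
        )
        q = by_key.get(key)
        if q is None:
            q = SiteQuant(
                protein_accession=rec.protein_accession,
                stripped_sequence=rec.stripped_sequence,
                dtb_positions=rec.dtb_positions,
                other_mods=rec.other_mods,
                dtb_count=rec.dtb_count,
            )
            by_key[key] = q
        q.intensity_by_sample[rec.sample_id] = (
            q.intensity_by_sample.get(rec.sample_id, 0.0) + rec.intensity
        )
    if n_non_dtb:
        logger.info("dropped %d precursor rows without a DTB modification", n_non_dtb)
    return list(by_key.values())


def map_sites(
    quants: Sequence[SiteQuant], proteome: Mapping[str, str]
) -> list[SiteQuant]:
    """Anchor each peptide to its protein cysteine residue index.

    The peptide is located by exact substring search in the protein sequence
    (leftmost occurrence; repeated occurrences set ``ambiguous_mapping``).
    For the rare multi-DTB peptide the site is keyed to the first modified
    cysteine.  Peptides whose protein is absent or whose sequence is not found
    are flagged ``unmapped`` and excluded from site-level outputs downstream.
    """
    n_unmapped = 0
    for q in quants:
        seq = proteome.get(q.protein_accession)
        if seq is None:
            q.unmapped = True
            n_unmapped += 1
            continue
        start = seq.find(q.stripped_sequence)
        if start == -1 or not q.dtb_positions:
            q.unmapped = True
            n_unmapped += 1
            continue
        q.site = SiteKey(q.protein_accession, start + 1 + q.dtb_positions[0] - 1)
        if seq.find(q.stripped_sequence, start + 1) != -1:
            q.ambiguous_mapping = True
    if n_unmapped:
        logger.info("flagged %d peptides as unmapped", n_unmapped)
    return list(quants)


def _abundance(q: SiteQuant, policy: AggregationPolicy) -> float:
    if policy.cleavage_form_rule == "most_abundant_total":
        return q.total_intensity()
    return q.mean_intensity()


def dedupe_cleavage_forms(
    quants: Sequence[SiteQuant],
    policy: AggregationPolicy | None = None,
    keep_all: bool = False,
    audit_path=None,
) -> list[SiteQuant]:
    """Resolve missed-cleavage variants covering the same cysteine site.

    For every site represented by more than one peptide, only the most
    abundant form is kept (ties broken by shorter sequence, then
    lexicographically).  With ``keep_all=True`` the losing forms are retained
    but flagged ``redundant_form`` so they surface in audit output and are
    excluded by the hit filter instead of silently vanishing.
    """
    policy = policy or AggregationPolicy()
    by_site: dict[SiteKey, list[SiteQuant]] = {}
    passthrough: list[SiteQuant] = []
    for q in quants:
        if q.site is None or q.unmapped:
            passthrough.append(q)
            continue
        by_site.setdefault(q.site, []).append(q)

    kept: list[SiteQuant] = list(passthrough)
    discarded: list[SiteQuant] = []
    for site, forms in by_site.items():
        winner = min(
            forms,
            key=lambda q: (
                -_abundance(q, policy),
                len(q.stripped_sequence),
                q.stripped_sequence,
            ),
        )
        for q in forms:
            q.redundant_form = q is not winner
            if q is winner or keep_all:
                kept.append(q)
            else:
                discarded.append(q)
    if audit_path is not None:
        write_table(audit_frame(discarded), audit_path)
    return kept


def audit_frame(quants: Sequence[SiteQuant]) -> pd.DataFrame:
    """Tabulate discarded / unmapped peptides for the audit trail."""
    rows = []
    for q in quants:
        rows.append(
            {
                "protein_accession": q.protein_accession,
                "stripped_sequence": q.stripped_sequence,
                "dtb_positions": ";".join(map(str, q.dtb_positions)),
                "residue_index": q.site.residue_index if q.site else None,
                "unmapped": q.unmapped,
                "ambiguous_mapping": q.ambiguous_mapping,
                "redundant_form": q.redundant_form,
                "mean_intensity": q.mean_intensity(),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "protein_accession",
            "stripped_sequence",
            "dtb_positions",
            "residue_index",
            "unmapped",
            "ambiguous_mapping",
            "redundant_form",
            "mean_intensity",
        ],
    )
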