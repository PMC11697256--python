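"""Selectivity scoring of compound-cysteine interactions.

An interaction is selective when it is much stronger than anything else seen
for the same cysteine site (across compounds) and for the same compound
(across sites).  Each interaction's mean log2(CR) is compared against the
mean of the top five strongest *other* interactions along each axis:

    delta_site     = own - mean(top-5 other compounds at this site)
    delta_compound = own - mean(top-5 other sites for this compound)
    score          = min(delta_site, delta_compound)

When fewer than five competitors exist, all available are used and the count
is recorded; when none exist along an axis the delta is unsupported (NaN with
a flag) rather than fabricated.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Iterable, Sequence

import math

import numpy as np
import pandas as pd

from .aggregate import SiteKey
from .competition import CompetitionRecord

__all__ = ["SelectivityRecord", "selectivity_scores", "combine_experiments",
           "selectivity_frame"]

TOP_N = 5


@dataclass(frozen=True)
class SelectivityRecord:
    compound_id: str
    protein_accession: str
    residue_index: int
    log2_cr: float
    delta_site: float
    delta_compound: float
    score: float
    n_used_site: int
    n_used_compound: int
    unsupported: bool

    @property
    def site(self) -> SiteKey:
        return SiteKey(self.protein_accession, self.residue_index)


def _interactions(records) -> list[tuple[str, SiteKey, float]]:
    out = []
    for r in records:
        if isinstance(r, CompetitionRecord):
            out.append((r.compound_id, r.site, float(r.mean_log2_cr)))
        else:  # (compound_id, SiteKey, value) triples
            compound, site, value = r
            out.append((compound, site, float(value)))
    return out


def _top_mean(values: list[float], n: int = TOP_N) -> tuple[float, int]:
    if not values:
        return math.nan, 0
    top = sorted(values, reverse=True)[:n]
    return float(np.mean(top)), len(top)


def selectivity_scores(
    records: Iterable[CompetitionRecord] | Iterable[tuple],
) -> list[SelectivityRecord]:
    """Score every interaction against its strongest competitors.

    Accepts CompetitionRecords (their ``mean_log2_cr`` is used) or bare
    ``(compound_id, SiteKey, log2_cr)`` triples.  The interaction itself is
    excluded from both top-5 sets.
    """
    inter = _interactions(records)
    by_site: dict[SiteKey, list[tuple[str, float]]] = {}
    by_compound: dict[str, list[tuple[SiteKey, float]]] = {}
    for compound, site, value in inter:
        by_site.setdefault(site, []).append((compound, value))
        by_compound.setdefault(compound, []).append((site, value))

    out: list[SelectivityRecord] = []
    for compound, site, value in inter:
        site_others = [v for c, v in by_site[site] if c != compound]
        comp_others = [v for s, v in by_compound[compound] if s != site]
        d_site, n_site = _top_mean(site_others)
        d_comp, n_comp = _top_mean(comp_others)
        d_site = value - d_site if n_site else math.nan
        d_comp = value - d_comp if n_comp else math.nan
        unsupported = n_site == 0 or n_comp == 0
        score = math.nan if unsupported else min(d_site, d_comp)
        out.append(
            SelectivityRecord(
                compound_id=compound,
                protein_accession=site.protein_accession,
                residue_index=site.residue_index,
                log2_cr=value,
                delta_site=d_site,
                delta_compound=d_comp,
                score=score,
                n_used_site=n_site,
                n_used_compound=n_comp,
                unsupported=unsupported,
            )
        )
    out.sort(key=lambda r: (-(r.score if not math.isnan(r.score) else -math.inf),
                            r.compound_id, r.protein_accession, r.residue_index))
    return out


def combine_experiments(
    a: Sequence[SelectivityRecord], b: Sequence[SelectivityRecord]
) -> list[SelectivityRecord]:
    """Intersect two experiments (e.g. two cell lines) on (compound, site),
    keeping for each shared interaction the record with the lower score —
    selectivity must hold in both backgrounds."""
    index_b = {(r.compound_id, r.site): r for r in b}
    out = []
    for r in a:
        other = index_b.get((r.compound_id, r.site))
        if other is None:
            continue
        pick_other = (
            math.isnan(r.score)
            or (not math.isnan(other.score) and other.score < r.score)
        )
        out.append(other if pick_other else r)
    out.sort(key=lambda r: (-(r.score if not math.isnan(r.score) else -math.inf),
                            r.compound_id, r.protein_accession, r.residue_index))
    return out


def selectivity_frame(records: Iterable[SelectivityRecord]) -> pd.DataFrame:
    cols = [f.name for f in fields(SelectivityRecord)]
    return pd.DataFrame(
        [{c: getattr(r, c) for c in cols} for r in records], columns=cols
    )
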