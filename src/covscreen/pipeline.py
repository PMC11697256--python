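"""End-to-end orchestration: report -> sites -> hits / TE50 fits.

These helpers chain the per-module operations in the canonical order
(parse, collapse, map, dedupe, test/fit) and are shared by the CLI and the
demo.  They work on in-memory frames so simulated and file-based inputs run
through identical code.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .aggregate import (
    AggregationPolicy,
    SiteQuant,
    collapse_precursors,
    dedupe_cleavage_forms,
    map_sites,
)
from .competition import CompetitionParams, CompetitionScreen, ScreenResults  # noqa: F401
from .config import RunConfig, config_hash
from .dose_response import (
    DoseResponseFit,
    QualityParams,
    assess_fit,
    count_off_targets,
    fit_4pl,
    relative_intensities,
)
from .io_model import Role, SampleMeta, records_from_frame, write_table
from .selectivity import selectivity_frame, selectivity_scores
from .simulate import SimConfig, SpikeSpec, simulate_screen

__all__ = [
    "quants_from_frames",
    "screen_from_frames",
    "dose_response_fits",
    "fits_frame",
    "run_demo",
]


def quants_from_frames(
    report: pd.DataFrame,
    meta: Sequence[SampleMeta],
    proteome: Mapping[str, str],
    policy: AggregationPolicy | None = None,
    keep_all: bool = True,
) -> list[SiteQuant]:
    """Parse, collapse, site-map and dedupe a logical-schema report frame."""
    policy = policy or AggregationPolicy()
    records = records_from_frame(report, samples=meta)
    quants = collapse_precursors(records, policy)
    quants = map_sites(quants, proteome)
    return dedupe_cleavage_forms(quants, policy, keep_all=keep_all)


def screen_from_frames(
    report: pd.DataFrame,
    meta: Sequence[SampleMeta],
    proteome: Mapping[str, str],
    params: CompetitionParams | None = None,
    policy: AggregationPolicy | None = None,
) -> ScreenResults:
    quants = quants_from_frames(report, meta, proteome, policy)
    return CompetitionScreen(quants, meta, params).fit()


def dose_response_fits(
    quants: Sequence[SiteQuant],
    meta: Sequence[SampleMeta],
    quality: QualityParams | None = None,
) -> list[DoseResponseFit]:
    """Fit the bounded 4PL for every (compound, mapped site) pair with
    enough concentrations, applying the quality filter to each fit."""
    quality = quality or QualityParams()
    compounds = sorted(
        {s.compound_id for s in meta if s.role is Role.treated}
    )
    fits: list[DoseResponseFit] = []
    for q in quants:
        if q.site is None or q.unmapped or q.redundant_form:
            continue
        for compound in compounds:
            try:
                points = relative_intensities(q, meta, compound)
            except ValueError:
                continue
            fit = fit_4pl(
                points,
                compound_id=compound,
                site=q.site,
                n_conc_min=quality.n_conc_min,
            )
            assess_fit(fit, quality)
            fits.append(fit)
    return fits


def fits_frame(fits: Sequence[DoseResponseFit]) -> pd.DataFrame:
    rows = []
    for f in fits:
        rows.append(
            {
                "compound_id": f.compound_id,
                "protein_accession": f.protein_accession,
                "residue_index": f.residue_index,
                "e0": f.e0,
                "e_inf": f.e_inf,
                "slope_n": f.slope_n,
                "log10_te50": f.log10_te50,
                "pte50": f.pte50,
                "stderr_e0": f.stderr_e0,
                "stderr_e_inf": f.stderr_e_inf,
                "stderr_slope_n": f.stderr_slope_n,
                "stderr_log10_te50": f.stderr_log10_te50,
                "r_squared": f.r_squared,
                "n_conc_used": f.n_conc_used,
                "converged": f.converged,
                "at_bounds": f.at_bounds,
                "passes_quality": f.passes_quality,
            }
        )
    return pd.DataFrame(rows)


def _demo_screen_config(seed: int) -> SimConfig:
    occupancies = [0.9, 0.85, 0.8, 0.75, 0.7, 0.6]
    spikes = []
    conc = 50.0
    for k, occ in enumerate(occupancies):
        te50 = conc * (1.0 - occ) / occ
        spikes.append(
            SpikeSpec(
                compound_id=f"PP{k + 1:02d}",
                site_index=3 * k,
                te50_um=te50,
                max_engagement=1.0,
            )
        )
    return SimConfig(
        n_proteins=60,
        n_sites=300,
        n_compounds=6,
        design="single_dose",
        spikes=spikes,
        seed=seed,
        experiment_id="demo_screen",
    )


def _demo_dr_config(seed: int) -> SimConfig:
    spikes = [
        SpikeSpec("PP01", 0, te50_um=10.0, max_engagement=1.0),   # pTE50 5.0
        SpikeSpec("PP01", 5, te50_um=31.62, max_engagement=0.9),  # pTE50 4.5
        SpikeSpec("PP02", 10, te50_um=3.162, max_engagement=1.0), # pTE50 5.5
    ]
    return SimConfig(
        n_proteins=10,
        n_sites=30,
        n_compounds=2,
        design="dose_response",
        spikes=spikes,
        seed=seed + 1,
        experiment_id="demo_dr",
    )


def run_demo(outdir: str | Path, seed: int = 0,
             config: RunConfig | None = None) -> dict[str, Path]:
    """Simulate a screen and a dose-response series, run the full analysis
    chain on each, and write truth-versus-call comparison tables.

    Deterministic for a fixed seed; writes a machine-readable provenance
    record alongside the results.
    """
    config = config or RunConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    # --- single-dose screen -------------------------------------------------
    screen_cfg = _demo_screen_config(seed)
    sim = simulate_screen(screen_cfg)
    sim.write(outdir / "screen_inputs")
    quants = quants_from_frames(
        sim.report, sim.meta, sim.proteome, config.aggregation
    )
    results = CompetitionScreen(quants, sim.meta, config.competition).fit()
    paths["competition"] = outdir / "competition.tsv"
    write_table(results.frame, paths["competition"])

    sel = selectivity_scores(results.records)
    paths["selectivity"] = outdir / "selectivity.tsv"
    write_table(selectivity_frame(sel), paths["selectivity"])

    hit_index = {
        (r.compound_id, r.protein_accession, r.residue_index): r
        for r in results.records
    }
    rows = []
    for t in sim.truth.itertuples(index=False):
        rec = hit_index.get(
            (t.compound_id, t.protein_accession, t.residue_index)
        )
        conc = screen_cfg.concentrations_um[0]
        occ = conc / (conc + t.te50_um)
        expected = -math.log2(1.0 - occ * t.max_engagement)
        rows.append(
            {
                "compound_id": t.compound_id,
                "protein_accession": t.protein_accession,
                "residue_index": t.residue_index,
                "expected_log2_cr": expected,
                "observed_log2_cr": rec.mean_log2_cr if rec else None,
                "called_hit": rec.is_hit if rec else False,
            }
        )
    paths["truth_vs_hits"] = outdir / "truth_vs_hits.tsv"
    write_table(pd.DataFrame(rows), paths["truth_vs_hits"])

    # --- dose-response ------------------------------------------------------
    dr_cfg = _demo_dr_config(seed)
    dr = simulate_screen(dr_cfg)
    dr.write(outdir / "doseresponse_inputs")
    dr_quants = quants_from_frames(
        dr.report, dr.meta, dr.proteome, config.aggregation
    )
    fits = dose_response_fits(dr_quants, dr.meta, config.quality)
    paths["dose_response"] = outdir / "dose_response.tsv"
    write_table(fits_frame(fits), paths["dose_response"])

    fit_index = {
        (f.compound_id, f.protein_accession, f.residue_index): f for f in fits
    }
    rows = []
    for t in dr.truth.itertuples(index=False):
        f = fit_index.get((t.compound_id, t.protein_accession, t.residue_index))
        true_pte50 = 6.0 - math.log10(t.te50_um)
        by_compound = [x for x in fits if x.compound_id == t.compound_id]
        n_off = None
        if f is not None and f.passes_quality:
            n_off = count_off_targets(
                by_compound, f.site, config.off_target_window
            )
        rows.append(
            {
                "compound_id": t.compound_id,
                "protein_accession": t.protein_accession,
                "residue_index": t.residue_index,
                "true_pte50": true_pte50,
                "fitted_pte50": f.pte50 if f else None,
                "stderr_pte50": f.stderr_pte50 if f else None,
                "passes_quality": f.passes_quality if f else False,
                "off_targets_within_window": n_off,
            }
        )
    paths["te50_recovery"] = outdir / "te50_recovery.tsv"
    write_table(pd.DataFrame(rows), paths["te50_recovery"])

    provenance = {
        "tool": "covscreen",
        "version": __version__,
        "seed": seed,
        "config_sha256": config_hash(config),
        "outputs": sorted(str(p.relative_to(outdir)) for p in paths.values()),
    }
    paths["provenance"] = outdir / "provenance.json"
    with open(paths["provenance"], "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
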