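"""Competition ratios, Welch's t-test and hit calling.

A covalent fragment that engages a cysteine blocks probe labelling, lowering
the intensity of that site's DTB peptide in treated samples.  Engagement is
quantified by the competition ratio CR = I_control / I_treated; a liganding
event ("hit") requires mean log2(CR) >= 1 and -log10(p) >= 1.3 (two-sided
Welch's t-test) plus a cascade of robustness filters: at least two treated
detections, detection in >= 90% of all samples in the experiment, control CV
<= 40%, a single DTB modification, and being the selected cleavage form.

The screen is exposed as a model object: ``CompetitionScreen(quants, meta)``
fits all (compound x site) contrasts at once and returns ``ScreenResults``;
``call_hits`` is the equivalent one-call functional interface.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .aggregate import SiteKey, SiteQuant
from .io_model import Role, SampleMeta

__all__ = [
    "CompetitionParams",
    "CompetitionRecord",
    "WelchResult",
    "welch_t",
    "site_competition",
    "call_hits",
    "CompetitionScreen",
    "ScreenResults",
    "records_to_frame",
]

FILTER_FLAGS = (
    "low_treated_n",
    "low_completeness",
    "high_cv",
    "multi_dtb",
    "redundant_form",
)


@dataclass
class CompetitionParams:
    """Thresholds of the hit-calling filter cascade."""

    log2cr_min: float = 1.0
    neglog10p_min: float = 1.3
    min_treated_detected: int = 2
    min_frac_detected_all: float = 0.90
    max_control_cv: float = 0.40
    test_scale: str = "log2"  # or "raw"
    cr_mode: str = "per_replicate_log"  # or "ratio_of_means"
    bh_qvalues: bool = False

    def __post_init__(self) -> None:
        if self.log2cr_min <= 0 or self.neglog10p_min <= 0:
            raise ValueError("thresholds must be positive")
        if not (0 < self.min_frac_detected_all <= 1):
            raise ValueError("min_frac_detected_all must lie in (0, 1]")
        if not (0 < self.max_control_cv <= 1):
            raise ValueError("max_control_cv must lie in (0, 1]")
        if self.test_scale not in ("log2", "raw"):
            raise ValueError(f"unknown test_scale {self.test_scale!r}")
        if self.cr_mode not in ("per_replicate_log", "ratio_of_means"):
            raise ValueError(f"unknown cr_mode {self.cr_mode!r}")


@dataclass(frozen=True)
class CompetitionRecord:
    """One volcano-plot point: a (compound, cysteine site) contrast."""

    compound_id: str
    concentration_um: float
    protein_accession: str
    residue_index: int
    stripped_sequence: str
    n_treated_detected: int
    n_control_detected: int
    mean_log2_cr: float
    p_value: float
    neglog10_p: float
    cv_control: float
    frac_detected_all: float
    filter_flags: str  # comma-joined sorted flag names, "" if clean
    is_hit: bool

    @property
    def site(self) -> SiteKey:
        return SiteKey(self.protein_accession, self.residue_index)

    @property
    def flags(self) -> frozenset[str]:
        return frozenset(f for f in self.filter_flags.split(",") if f)


class WelchResult(NamedTuple):
    t: float
    df: float
    p: float
    degenerate: bool = False


def welch_t(x: Sequence[float], y: Sequence[float]) -> WelchResult:
    """Two-sided Welch's t-test for unequal variances.

    t = (mean(x) - mean(y)) / sqrt(sx^2/nx + sy^2/ny), with degrees of
    freedom from the Welch-Satterthwaite approximation.  When both sample
    variances are zero the test is degenerate: p = 1 if the means agree,
    otherwise p = 0 with the ``degenerate`` flag set.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("welch_t requires at least two values per group")
    nx, ny = x.size, y.size
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    if se2 == 0.0:
        if mx == my:
            return WelchResult(0.0, float(nx + ny - 2), 1.0, False)
        return WelchResult(math.copysign(math.inf, mx - my),
                           float(nx + ny - 2), 0.0, True)
    t = (mx - my) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(float(t), float(df), float(p), False)


def _welch_rows(
    X: np.ndarray, Y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise Welch test on NaN-masked matrices; returns (t, df, p).

    Rows with fewer than two finite values in either matrix yield NaN.
    """
    nx = np.sum(np.isfinite(X), axis=1).astype(float)
    ny = np.sum(np.isfinite(Y), axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mx = np.nanmean(X, axis=1)
        my = np.nanmean(Y, axis=1)
        vx = np.nanvar(X, axis=1, ddof=1)
        vy = np.nanvar(Y, axis=1, ddof=1)
        se2 = vx / nx + vy / ny
        t = (mx - my) / np.sqrt(se2)
        df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    with np.errstate(invalid="ignore"):
        valid = (nx >= 2) & (ny >= 2)
        degen = valid & (se2 == 0.0)
        t = np.where(valid, t, np.nan)
        p = np.where(valid, p, np.nan)
        df = np.where(valid, df, np.nan)
        # zero-variance conventions
        equal = degen & (mx == my)
        t = np.where(equal, 0.0, t)
        p = np.where(equal, 1.0, p)
        diff = degen & (mx != my)
        t = np.where(diff, np.sign(mx - my) * np.inf, t)
        p = np.where(diff, 0.0, p)
        df = np.where(degen, nx + ny - 2, df)
    return t, df, p


@dataclass
class ScreenResults:
    """Hit-calling results for one screen; ``frame`` is volcano-ready."""

    records: list[CompetitionRecord]
    params: CompetitionParams

    @property
    def frame(self) -> pd.DataFrame:
        df = records_to_frame(self.records)
        if self.params.bh_qvalues and len(df):
            # diagnostic only; hit calls stay on the fixed raw-p threshold
            from statsmodels.stats.multitest import multipletests

            ps = df["p_value"].to_numpy()
            ok = np.isfinite(ps)
            q = np.full_like(ps, np.nan, dtype=float)
            if ok.any():
                q[ok] = multipletests(ps[ok], method="fdr_bh")[1]
            df["q_value"] = q
        return df

    @property
    def hits(self) -> list[CompetitionRecord]:
        return [r for r in self.records if r.is_hit]

    def summary(self) -> str:
        n = len(self.records)
        nh = len(self.hits)
        compounds = sorted({r.compound_id for r in self.records})
        lines = [
            "Competition screen results",
            "==========================",
            f"contrasts tested      {n}",
            f"compounds             {len(compounds)}",
            f"hits (liganding)      {nh}",
            f"hit rate              {100.0 * nh / n if n else 0.0:.3f}%",
            f"thresholds            mean log2(CR) >= {self.params.log2cr_min}, "
            f"-log10(p) >= {self.params.neglog10p_min}",
            f"detection filters     >= {self.params.min_treated_detected} treated, "
            f">= {100 * self.params.min_frac_detected_all:.0f}% of all samples, "
            f"control CV <= {100 * self.params.max_control_cv:.0f}%",
        ]
        return "\n".join(lines)


class CompetitionScreen:
    """Model object for a single-dose (or per-dose) competition screen.

    Parameters
    ----------
    quants : sequence of SiteQuant
        Aggregated, site-mapped peptides (redundant forms may be present and
        flagged).
    meta : sequence of SampleMeta
        The full sample table; completeness is evaluated against every sample
        of the peptide's experiment.
    params : CompetitionParams, optional
    """

    def __init__(
        self,
        quants: Sequence[SiteQuant],
        meta: Sequence[SampleMeta],
        params: CompetitionParams | None = None,
    ) -> None:
        self.quants = [q for q in quants if not q.unmapped and q.site is not None]
        self.meta = list(meta)
        self.params = params or CompetitionParams()

    def fit(self, include_undetected: bool = False) -> ScreenResults:
        records: list[CompetitionRecord] = []
        by_exp: dict[str, list[SampleMeta]] = {}
        for s in self.meta:
            by_exp.setdefault(s.experiment_id, []).append(s)
        for exp_samples in by_exp.values():
            records.extend(
                self._fit_experiment(exp_samples, include_undetected)
            )
        records.sort(key=lambda r: (r.compound_id, r.concentration_um,
                                    r.protein_accession, r.residue_index))
        return ScreenResults(records, self.params)

    def _fit_experiment(
        self, samples: list[SampleMeta], include_undetected: bool
    ) -> list[CompetitionRecord]:
        p = self.params
        quants = self.quants
        sample_ids = [s.sample_id for s in samples]
        col = {sid: j for j, sid in enumerate(sample_ids)}
        M = np.full((len(quants), len(sample_ids)), np.nan)
        for i, q in enumerate(quants):
            for sid, v in q.intensity_by_sample.items():
                j = col.get(sid)
                if j is not None:
                    M[i, j] = v
        n_samples = len(sample_ids)
        frac_all = np.sum(np.isfinite(M), axis=1) / n_samples

        ctrl_cols = [j for j, s in enumerate(samples) if s.role is Role.control]
        C = M[:, ctrl_cols]
        n_ctrl = np.sum(np.isfinite(C), axis=1)
        with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            ctrl_mean = np.nanmean(C, axis=1)
            ctrl_sd = np.nanstd(C, axis=1, ddof=1)
            cv_ctrl = ctrl_sd / ctrl_mean
        logC = np.log2(C)

        groups: dict[tuple[str, float], list[int]] = {}
        for j, s in enumerate(samples):
            if s.role is Role.treated:
                groups.setdefault((s.compound_id, s.concentration_um), []).append(j)

        records: list[CompetitionRecord] = []
        for (compound, conc), cols in sorted(groups.items()):
            T = M[:, cols]
            with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                logT = np.log2(T)
                n_trt = np.sum(np.isfinite(T), axis=1)
                if p.cr_mode == "per_replicate_log":
                    mean_cr = np.log2(ctrl_mean) - np.nanmean(logT, axis=1)
                else:
                    mean_cr = np.log2(ctrl_mean) - np.log2(np.nanmean(T, axis=1))
            if p.test_scale == "log2":
                _, _, pvals = _welch_rows(logC, logT)
            else:
                _, _, pvals = _welch_rows(C, T)
            with np.errstate(divide="ignore"):
                neglogp = -np.log10(pvals)

            for i, q in enumerate(quants):
                nt = int(n_trt[i])
                if nt == 0 and not include_undetected:
                    continue
                flags = []
                if nt < p.min_treated_detected:
                    flags.append("low_treated_n")
                if frac_all[i] < p.min_frac_detected_all or n_ctrl[i] < 2:
                    flags.append("low_completeness")
                if np.isfinite(cv_ctrl[i]) and cv_ctrl[i] > p.max_control_cv:
                    flags.append("high_cv")
                if q.dtb_count != 1:
                    flags.append("multi_dtb")
                if q.redundant_form:
                    flags.append("redundant_form")
                pv = float(pvals[i])
                nlp = float(neglogp[i])
                cr = float(mean_cr[i])
                is_hit = (
                    not flags
                    and np.isfinite(cr)
                    and cr >= p.log2cr_min
                    and np.isfinite(nlp)
                    and nlp >= p.neglog10p_min
                )
                records.append(
                    CompetitionRecord(
                        compound_id=compound,
                        concentration_um=float(conc),
                        protein_accession=q.site.protein_accession,
                        residue_index=q.site.residue_index,
                        stripped_sequence=q.stripped_sequence,
                        n_treated_detected=nt,
                        n_control_detected=int(n_ctrl[i]),
                        mean_log2_cr=cr,
                        p_value=pv,
                        neglog10_p=nlp,
                        cv_control=float(cv_ctrl[i]),
                        frac_detected_all=float(frac_all[i]),
                        filter_flags=",".join(sorted(flags)),
                        is_hit=bool(is_hit),
                    )
                )
        return records


def site_competition(
    quant: SiteQuant,
    meta: Sequence[SampleMeta],
    compound: str,
    params: CompetitionParams | None = None,
    concentration_um: float | None = None,
) -> CompetitionRecord:
    """Competition statistics for a single peptide against one compound."""
    params = params or CompetitionParams()
    screen = CompetitionScreen([quant], meta, params)
    recs = [
        r
        for r in screen.fit(include_undetected=True).records
        if r.compound_id == compound
        and (concentration_um is None or r.concentration_um == concentration_um)
    ]
    if not recs:
        raise ValueError(
            f"no treated samples for compound {compound!r} in the metadata"
        )
    return recs[0]


def call_hits(
    quants: Sequence[SiteQuant],
    meta: Sequence[SampleMeta],
    params: CompetitionParams | None = None,
) -> list[CompetitionRecord]:
    """Run the full screen: one record per (compound, site) with any treated
    detection, hit flags per the filter cascade."""
    return CompetitionScreen(quants, meta, params).fit().records


def records_to_frame(records: Iterable[CompetitionRecord]) -> pd.DataFrame:
    cols = [f.name for f in fields(CompetitionRecord)]
    return pd.DataFrame(
        [{c: getattr(r, c) for c in cols} for r in records], columns=cols
    )
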