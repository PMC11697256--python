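"""Concentration-response (TE50) analysis.

For each (compound, cysteine site) pair screened over a dilution series, the
mean treated intensity at each concentration is expressed as a percentage of
the DMSO control and fitted against log10 concentration with a bounded
4-parameter logistic,

    y(x) = E_inf + (E_0 - E_inf) / (1 + 10^(n * (log10(TE50) - x)))

where E_0 is the top plateau (no compound), E_inf the bottom plateau
(saturating compound), n <= 0 the slope, and TE50 the concentration of
half-maximal target engagement.  Bounds follow the screening convention:
60 <= E_0 <= 140, E_inf >= 0, -50 <= n <= 0, and log10(TE50) may move up to
three log units outside the tested concentration range.  Potency is reported
as pTE50 = -log10(TE50 in molar); with concentrations in uM this is
6 - log10(TE50/uM).

Fitting is performed with lmfit (bounded least squares); parameter standard
errors come from the estimated covariance matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from lmfit import Model

from .aggregate import SiteKey, SiteQuant
from .io_model import Role, SampleMeta

__all__ = [
    "QualityParams",
    "DoseResponseFit",
    "FourParamLogistic",
    "logistic4",
    "relative_intensities",
    "fit_4pl",
    "assess_fit",
    "count_off_targets",
]

PTE50_OFFSET_UM = 6.0  # pTE50 = 6 - log10(TE50/uM): micromolar -> molar


def logistic4(x, e0, e_inf, slope_n, log10_te50):
    """The 4-parameter logistic in log10-concentration space."""
    return e_inf + (e0 - e_inf) / (1.0 + 10.0 ** (slope_n * (log10_te50 - x)))


@dataclass
class QualityParams:
    """Post-fit quality filter.

    A fit passes iff it converged, r^2 >= ``r2_min``, the standard error of
    log10(TE50) is <= ``stderr_logte50_max``, the span E_0 - E_inf is at
    least ``span_min`` percentage points, and log10(TE50) does not exceed the
    highest tested concentration by more than ``potency_margin`` log units.
    """

    r2_min: float = 0.8
    stderr_logte50_max: float = 1.0
    span_min: float = 30.0
    potency_margin: float = 0.5
    n_conc_min: int = 5


@dataclass
class DoseResponseFit:
    """Results object for one 4PL fit."""

    compound_id: str = ""
    protein_accession: str = ""
    residue_index: int = 0
    e0: float = math.nan
    e_inf: float = math.nan
    slope_n: float = math.nan
    log10_te50: float = math.nan
    stderr_e0: float = math.nan
    stderr_e_inf: float = math.nan
    stderr_slope_n: float = math.nan
    stderr_log10_te50: float = math.nan
    r_squared: float = math.nan
    n_conc_used: int = 0
    converged: bool = False
    at_bounds: str = ""  # comma-joined parameter names pinned at a bound
    passes_quality: bool = False
    x_min: float = math.nan  # tested log10 concentration range
    x_max: float = math.nan

    @property
    def site(self) -> SiteKey:
        return SiteKey(self.protein_accession, self.residue_index)

    @property
    def pte50(self) -> float:
        return PTE50_OFFSET_UM - self.log10_te50

    @property
    def stderr_pte50(self) -> float:
        return self.stderr_log10_te50

    def predict(self, x) -> np.ndarray:
        return np.asarray(
            logistic4(np.asarray(x, dtype=float), self.e0, self.e_inf,
                      self.slope_n, self.log10_te50)
        )

    def summary(self) -> str:
        def fmt(v, se):
            return f"{v:10.4f} +/- {se:.4f}" if np.isfinite(se) else f"{v:10.4f}"

        lines = [
            "4-parameter logistic fit",
            "========================",
            f"compound / site   {self.compound_id} / "
            f"{self.protein_accession} C{self.residue_index}",
            f"E0 (%)            {fmt(self.e0, self.stderr_e0)}",
            f"Einf (%)          {fmt(self.e_inf, self.stderr_e_inf)}",
            f"slope n           {fmt(self.slope_n, self.stderr_slope_n)}",
            f"log10(TE50/uM)    {fmt(self.log10_te50, self.stderr_log10_te50)}",
            f"pTE50             {fmt(self.pte50, self.stderr_pte50)}",
            f"r^2               {self.r_squared:.6f}",
            f"concentrations    {self.n_conc_used}",
            f"converged         {self.converged}",
            f"at bounds         {self.at_bounds or '-'}",
            f"passes quality    {self.passes_quality}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None, points=None):
        """Convenience curve plot (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        xs = np.linspace(self.x_min - 0.5, self.x_max + 0.5, 200)
        ax.plot(xs, self.predict(xs), "-")
        if points is not None:
            px, py = zip(*points)
            ax.plot(px, py, "o")
        ax.set_xlabel("log10 concentration (uM)")
        ax.set_ylabel("intensity (% of control)")
        ax.set_title(f"{self.compound_id} vs {self.protein_accession} "
                     f"C{self.residue_index}  pTE50={self.pte50:.2f}")
        return ax


def relative_intensities(
    quant: SiteQuant,
    meta: Sequence[SampleMeta],
    compound: str,
) -> list[tuple[float, float]]:
    """Per-concentration mean intensity as percent of the control mean.

    Returns (x, y) points with x = log10(concentration/uM) and
    y = 100 * mean(detected treated) / mean(detected control), one point per
    concentration with at least one detected treated replicate.  Requires at
    least two detected control intensities.
    """
    ctrl = [
        quant.intensity_by_sample[s.sample_id]
        for s in meta
        if s.role is Role.control and quant.detected_in(s.sample_id)
    ]
    if len(ctrl) < 2:
        raise ValueError(
            f"peptide {quant.stripped_sequence!r}: fewer than two detected "
            "control intensities"
        )
    ctrl_mean = float(np.mean(ctrl))
    by_conc: dict[float, list[float]] = {}
    for s in meta:
        if s.role is Role.treated and s.compound_id == compound:
            if quant.detected_in(s.sample_id):
                by_conc.setdefault(s.concentration_um, []).append(
                    quant.intensity_by_sample[s.sample_id]
                )
    points = [
        (math.log10(c), 100.0 * float(np.mean(v)) / ctrl_mean)
        for c, v in sorted(by_conc.items())
    ]
    return points


class FourParamLogistic:
    """Model object: bounded 4PL regression of % intensity on log10 dose.

    Parameters
    ----------
    x, y : array-like
        log10 concentrations (uM) and relative intensities (% of control).
    conc_range : (float, float), optional
        Tested log10 concentration range used for the TE50 bound
        (defaults to the data range).

    ``fit()`` returns a :class:`DoseResponseFit` results object.
    """

    _BOUND_TOL = 1e-6

    def __init__(self, x, y, conc_range: tuple[float, float] | None = None):
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        if self.x.size != self.y.size:
            raise ValueError("x and y must have equal length")
        if conc_range is None:
            conc_range = (float(self.x.min()), float(self.x.max()))
        self.x_min, self.x_max = conc_range

    def fit(
        self,
        compound_id: str = "",
        site: SiteKey | None = None,
        n_conc_min: int = 5,
    ) -> DoseResponseFit:
        out = DoseResponseFit(
            compound_id=compound_id,
            protein_accession=site.protein_accession if site else "",
            residue_index=site.residue_index if site else 0,
            n_conc_used=int(self.x.size),
            x_min=self.x_min,
            x_max=self.x_max,
        )
        if self.x.size < n_conc_min:
            return out

        model = Model(logistic4)
        params = model.make_params(
            e0=dict(value=100.0, min=60.0, max=140.0),
            e_inf=dict(value=0.0, min=0.0),
            slope_n=dict(value=-1.0, min=-50.0, max=0.0),
            log10_te50=dict(
                value=float(np.median(self.x)),
                min=self.x_min - 3.0,
                max=self.x_max + 3.0,
            ),
        )
        # trust-region-reflective: honours the box bounds natively (the
        # MINPACK parameter transform can stall with an at-bound start)
        import warnings

        with warnings.catch_warnings():
            # degenerate fits can yield a non-PSD covariance; their stderr
            # becomes NaN and the quality filter rejects them
            warnings.simplefilter("ignore", RuntimeWarning)
            result = model.fit(self.y, params, x=self.x, method="least_squares")

        bounds = {
            "e0": (60.0, 140.0),
            "e_inf": (0.0, math.inf),
            "slope_n": (-50.0, 0.0),
            "log10_te50": (self.x_min - 3.0, self.x_max + 3.0),
        }
        at_bounds = []
        for name, (lo, hi) in bounds.items():
            v = result.params[name].value
            scale = max(abs(lo) if math.isfinite(lo) else 0.0,
                        abs(hi) if math.isfinite(hi) else 0.0, 1.0)
            if (math.isfinite(lo) and abs(v - lo) <= self._BOUND_TOL * scale) or (
                math.isfinite(hi) and abs(v - hi) <= self._BOUND_TOL * scale
            ):
                at_bounds.append(name)

        resid = self.y - result.best_fit
        ss_res = float(np.sum(resid**2))
        ss_tot = float(np.sum((self.y - self.y.mean()) ** 2))
        if ss_tot > 0:
            r2 = 1.0 - ss_res / ss_tot
        else:
            r2 = 1.0 if ss_res == 0.0 else 0.0

        def _se(name):
            se = result.params[name].stderr
            return float(se) if se is not None else math.nan

        out.e0 = float(result.params["e0"].value)
        out.e_inf = float(result.params["e_inf"].value)
        out.slope_n = float(result.params["slope_n"].value)
        out.log10_te50 = float(result.params["log10_te50"].value)
        out.stderr_e0 = _se("e0")
        out.stderr_e_inf = _se("e_inf")
        out.stderr_slope_n = _se("slope_n")
        out.stderr_log10_te50 = _se("log10_te50")
        out.r_squared = r2
        out.converged = bool(result.success)
        out.at_bounds = ",".join(at_bounds)
        return out


def fit_4pl(
    points: Iterable[tuple[float, float]],
    compound_id: str = "",
    site: SiteKey | None = None,
    n_conc_min: int = 5,
    conc_range: tuple[float, float] | None = None,
) -> DoseResponseFit:
    """Fit the bounded 4PL to (log10 concentration, % intensity) points."""
    pts = sorted(points)
    x = [p[0] for p in pts]
    y = [p[1] for p in pts]
    if len(x) < n_conc_min:
        return DoseResponseFit(
            compound_id=compound_id,
            protein_accession=site.protein_accession if site else "",
            residue_index=site.residue_index if site else 0,
            n_conc_used=len(x),
            x_min=min(x) if x else math.nan,
            x_max=max(x) if x else math.nan,
        )
    return FourParamLogistic(x, y, conc_range).fit(
        compound_id=compound_id, site=site, n_conc_min=n_conc_min
    )


def assess_fit(fit: DoseResponseFit, quality: QualityParams | None = None) -> bool:
    """Apply the quality filter and record the verdict on the fit."""
    q = quality or QualityParams()
    ok = (
        fit.converged
        and fit.n_conc_used >= q.n_conc_min
        and np.isfinite(fit.r_squared)
        and fit.r_squared >= q.r2_min
        and np.isfinite(fit.stderr_log10_te50)
        and fit.stderr_log10_te50 <= q.stderr_logte50_max
        and (fit.e0 - fit.e_inf) >= q.span_min
        and fit.log10_te50 <= fit.x_max + q.potency_margin
    )
    fit.passes_quality = bool(ok)
    return fit.passes_quality


def count_off_targets(
    fits_for_compound: Sequence[DoseResponseFit],
    reference_site: SiteKey,
    window: float = 0.5,
) -> int:
    """Count other sites engaged within ``window`` pTE50 units of the
    reference site (quality-passing fits only)."""
    passing = [f for f in fits_for_compound if f.passes_quality]
    ref = [f for f in passing if f.site == reference_site]
    if not ref:
        raise ValueError(
            f"reference site {reference_site} has no passing fit for this compound"
        )
    ref_pte50 = ref[0].pte50
    return sum(
        1
        for f in passing
        if f.site != reference_site and f.pte50 >= ref_pte50 - window
    )
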