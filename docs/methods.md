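# Methods

This note documents the statistical models and procedures implemented in
`covscreen`, the parameter choices that matter, what the synthetic-data
generator does and does not emulate, and known limitations.

## Competition analysis

**Input model.** Quantification is precursor-level: one intensity per
(sample, modified peptide, charge). Precursors that differ only in charge
state or methionine-oxidation state are summed per sample into a single
peptide-level intensity; other variable modifications (e.g. N-terminal
acetylation, unknown tags) keep peptides distinct. Missing values are the
absence of a row — no zeros, no sentinels, and no imputation anywhere in the
pipeline; detection-based filters take the place of missing-value handling.

**Site mapping.** Each DTB-tagged peptide is located in its protein by
exact substring search (leftmost occurrence; repeats set an ambiguity flag)
and keyed to the 1-based residue index of its modified cysteine. When
several cleavage forms (missed-cleavage variants) cover the same site, only
the most abundant is analysed. "Most abundant" is the highest mean
intensity over the samples in which the form is detected (a summed-intensity
alternative is available); the mean is preferred because it does not reward
forms merely for being detected more often. Ties break deterministically:
shorter peptide, then lexicographic. Losing forms are either dropped (with
an audit table) or retained with a `redundant_form` flag that blocks hit
calls; the pipeline uses the flagging mode so nothing silently disappears.

**Competition ratio.** CR = I_control / I_treated. The default estimator is
the mean of per-replicate log ratios,
`mean_i [ log2(mean control) − log2(treated_i) ]`, over detected treated
replicates; a ratio-of-means mode exists for sensitivity analysis. On a
null peptide with log-normal noise of CV c the per-replicate estimator has a
small positive offset of `ln(1 + c²) / (2 ln 2)` (≈ 0.04 at c = 0.25)
because the control *mean* sits above the log-scale centre; this is
negligible against the log2(CR) ≥ 1 threshold.

**Test.** Welch's unequal-variance *t*-test, two-sided, on log2 intensities
of detected values (log transform stabilises the variance of multiplicative
MS noise; a raw-scale option is kept). Degenerate cases follow fixed
conventions: both variances zero with equal means → p = 1; with unequal
means → p = 0 and a degenerate flag. Raw p-values are reported;
Benjamini–Hochberg q-values are an optional extra column, but hit calling
uses the fixed dual threshold, not FDR.

**Hit filter cascade.** A (compound, site) contrast is a hit iff all of:

| filter            | default | rationale                                   |
|-------------------|---------|---------------------------------------------|
| mean log2(CR)     | ≥ 1     | at least two-fold competition               |
| −log10(p)         | ≥ 1.3   | p ≤ 0.05, Welch two-sided                   |
| treated detections| ≥ 2     | a ratio needs replication                   |
| completeness      | ≥ 90 %  | of *all* samples in the experiment          |
| control CV        | ≤ 40 %  | sd/mean of raw detected control intensities |
| DTB count         | = 1     | unambiguous site assignment                 |
| cleavage form     | selected| one peptide per site                        |

Completeness is evaluated per `experiment_id` against the full sample table
(all compounds plus controls) — the literal "all samples in the experiment"
reading; screens run in different backgrounds should carry different
experiment ids.

## Concentration-response model

Per concentration, the response is the mean detected treated intensity as a
percentage of the mean detected control intensity. The curve is the
variable-slope four-parameter logistic in log10 concentration,

    y(x) = E_inf + (E_0 − E_inf) / (1 + 10^(n (log10 TE50 − x)))

with E_0 the top plateau (no compound, ~100 %), E_inf the bottom plateau,
n ≤ 0 the slope and TE50 the midpoint: y(log10 TE50) = (E_0 + E_inf)/2
exactly. Bounds: E_0 ∈ [60, 140], E_inf ≥ 0, n ∈ [−50, 0], log10 TE50
within the tested range ± 3 log units. Fitting is bounded nonlinear least
squares via lmfit using the trust-region-reflective backend — the
Levenberg–Marquardt bound transform can stall when a parameter starts
exactly on a bound, as E_inf does here. Initialisation is deterministic
(E_0 = 100, E_inf = 0, n = −1, log10 TE50 = median tested
log-concentration); no random restarts by default. Standard errors come
from the estimated covariance; fits whose covariance is degenerate get NaN
errors and fail quality. Parameters that end within 1e-6 (relative) of a
bound are flagged `at_bounds` rather than silently clipped.

Concentrations are µM in all I/O; potency is reported as
pTE50 = −log10(TE50 in molar) = 6 − log10(TE50/µM).

**Quality filter** (all config keys; the defaults are this package's
choice): converged, ≥ 5 concentrations with data, r² ≥ 0.8,
stderr(log10 TE50) ≤ 1.0, span E_0 − E_inf ≥ 30 percentage points, and
log10 TE50 ≤ log10(max conc) + 0.5. **Off-targets** for a reference site
are the other quality-passing sites of the same compound with
pTE50 ≥ pTE50(ref) − 0.5.

**Measured estimator behaviour** (10-point 0.4–200 µM geometric series,
quadruplicate, 25 controls, CV 25 %, 50 replicates per truth, computed by
the test suite): median |pTE50 error| ≈ 0.09–0.13 at true pTE50 ∈
{4.5, 5.0, 5.5}; overall mean bias ≈ +0.03. At the edge of the tested range
(true pTE50 = 4.5, TE50 = 31.6 µM) the estimator shows a +0.06 bias: the
bottom plateau is never reached, and the E_inf ≥ 0 bound truncates the
error distribution one-sidedly. This is a property of the prescribed
bounds and design, not of the optimiser.

## Selectivity

For each interaction, `delta_site` = own log2(CR) − mean of the five
strongest *other* compounds at that site, `delta_compound` likewise across
sites for that compound, and the score is the smaller delta. The
interaction itself is excluded from both top-5 sets, so a unique
interaction is maximally selective instead of self-penalised; with fewer
than five competitors all available are used (count reported), and an axis
with no competitor is marked unsupported (NaN) rather than fabricated.
Scores are computed on log2(CR), keeping deltas interpretable as fold-change
ratios; a raw-CR mode can be had by exponentiating inputs. Two experiments
(e.g. two cell lines) are combined by intersecting on (compound, site) and
keeping the lower score — selectivity must hold in both backgrounds.

## Cysteinome and structures

Tryptic digestion cleaves after K/R unless the next residue is proline; the
C-terminal peptide has no bond to test and is included as-is. Two presets:
*detectability* (fully cleaved peptides of 7–40 residues; a cysteine is
detectable iff inside such a peptide) and *search-space emulation* (7–52
residues, up to 2 missed cleavages), matching common DIA library settings.
Annotation tables are plain user-supplied TSVs joined by accession or
(accession, residue); nothing is downloaded, and unannotated sites keep
absent values, never `False`.

Pocket proximity consumes Fpocket alpha-sphere output (`*_pockets.pqr`,
spheres of radius 3–5 Å) and structure files via gemmi. "Within 1.5 Å of
the closest alpha sphere" is ambiguous between sphere centers and surfaces;
the default is the center distance (deterministic and conservative), the
surface convention (center distance − radius) is a flag, and the convention
used is recorded in every output row.

## The synthetic-screen generator

The generator reproduces the *statistical* operating point of the platform,
not its spectra:

- **Designs.** Single dose: 16 DMSO controls vs 4 treated replicates per
  compound at 50 µM. Dose-response: a 10-point geometric series 0.4–200 µM
  in quadruplicate against 25 shared controls.
- **Abundance.** Per-peptide baseline log10 intensity ~ Normal(4.5, 0.8)
  (arbitrary units spanning ~4 orders of magnitude, as in DIA reports).
- **Noise.** Multiplicative log-normal with σ² = ln(1 + CV²) and unit mean;
  CV defaults to 0.25, matching the platform's median replicate CV (~25 %).
- **Detection.** Bernoulli per (peptide, sample) with logistic probability
  in log10 intensity (slope 0.6 log10 units; midpoint solved numerically so
  the marginal detection rate is 0.9). This yields a mean pairwise Jaccard
  overlap of detected peptides between replicates of ~0.84 — inside the
  platform's reported ~82 % completeness regime — while keeping missingness
  intensity-dependent (MNAR): strongly engaged peptides drop out more, as
  real competition data do. A flatter curve would approach the homogeneous
  limit (0.818 at 0.9 marginal) but lose that coupling.
- **Engagement.** A spiked (compound, site) pair at concentration c has
  occupancy c/(c + TE50) and treated intensity
  baseline · (1 − occupancy · max_engagement); with slope −1 this is exactly
  the 4PL evaluated at log10 c, so noiseless recovery is exact. Engagement
  is equilibrium-style; incubation-time kinetics (lysate vs live-cell
  differences) are not modelled.
- **Report.** Peptides are emitted as two charge states (70/30 split) whose
  intensities sum to the peptide intensity, written in the same TSV schema
  the parsers consume. Proteins are synthesized as concatenations of
  single-cysteine tryptic peptides, so site mapping is exact and
  unambiguous by construction. Everything is deterministic given the seed.

What passing simulated tests do **not** show: robustness to interference
and co-elution, protein inference ambiguity, isoform site collisions,
batch effects or cross-run normalisation drift, and chemistry (reactivity,
hyperreactive cysteines). Test problem sizes (up to ~5,000 sites × 10
compounds for the null screen; 50 replicates per recovery condition) were
chosen as the smallest giving stable rate estimates.

## Numerical and degenerate-input conventions

- Welch with < 2 detected values in either group: no p-value, record
  flagged, never a hit.
- Control CV requires ≥ 2 detected controls (ddof = 1); otherwise the
  completeness flag already applies.
- r² with zero total variance: 1 if residuals are zero, else 0.
- Tables round-trip floats via shortest-repr formatting (bit-exact on
  re-read); flag sets serialise as sorted comma-joined strings.
- TE50 recovery experiments in the tests use certain detection: the
  recovery target measures fitting accuracy under sampling noise, and under
  MNAR detection a few percent of extreme-engagement series lose enough
  points that no fit is attempted (a missing-data outcome reported as such,
  not an estimate).

## Known limitations

- No cross-run intensity normalisation is applied (exported intensities are
  treated as final); a median-normalisation switch exists but defaults off.
- No protein inference or isoform remapping; sites are per-accession.
- Multi-DTB peptides are quantified and reported but excluded from hit
  calls; their site key uses the first modified cysteine.
- The pTE50 estimator is mildly biased (+0.06) when the true TE50
  approaches the top of the tested concentration range (see above).
- Pocket calls depend on an unstated distance convention; both are
  implemented and labelled, but absolute pocket-enrichment fractions depend
  on the structure set and Fpocket run supplied by the user.
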