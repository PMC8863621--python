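# Methods

## Scope and model

`beamaudit` analyses the relationship between an institution's TPS
beam-model parameter choices and its performance in end-to-end phantom
dosimetry audits.  The core model has three parts.

**Community percentile scoring.**  Within an equipment stratum (TPS,
linac class, beam energy, MLC model — matched exactly, case- and
whitespace-insensitively, with no pooled fallback), the community's
reported values for one parameter form an empirical distribution.
Quantiles use the linear-interpolation order-statistic convention
(NumPy's default `method="linear"`); percentile ranks use its inverse,
with midranks for ties, 0 below the sample minimum and 100 above the
maximum.  A value is *atypical* when its percentile is strictly below 10
or strictly above 90, so the central 80% is typical and a value exactly
at a cut is typical.  Strata with fewer than 5 responses (configurable)
are refused rather than scored.  Parameters reported by an institution
but absent from the anchor catalog are excluded from scoring with a
logged warning.

**Dose-effect lookup.**  Each catalogued parameter carries anchors
(percentile, value, effect %) at the 2.5/10/50/90/97.5th community
percentiles; the effect at the median is 0 by construction and a
positive effect means the TPS overestimates dose.  The effect model is
piecewise-linear **in parameter value** between adjacent anchors —
consistent with the observation that the dose distribution changes
linearly with parameter value — and clamps to the terminal anchor
effects outside the 2.5–97.5 range, because the dose response is
characterized only over the reported community spread.  Anchors sharing
one value (flat distribution tails) collapse to a single model point
keeping the lower-percentile effect.  Percentile queries pass through
the community distribution's quantile function first.  Per-parameter
effects are treated as independent, so the institution-level prediction
is their exact arithmetic sum.

*Median defaults.*  The published anchor tables print the dose effect at
the median (0) but not the median parameter value, which the model needs
as its zero point.  The shipped `data/anchors.json` therefore supplies
50th-percentile values as configuration defaults, not survey data: since
the response is linear, each default median is placed at the zero-effect
abscissa implied by the flanking 10th/90th anchors (e.g. DLG 0.1728 cm),
which keeps the model exactly linear across the 10th–90th range; when
the response is flat or one-sided (source size, position gain,
curvature) the value midpoint of the 10th/90th anchors is used so the
median stays strictly inside the range and both community tails remain
identifiable.  Site-specific medians can be supplied via an alternative
anchor file.

*Impactful parameters* are those whose anchored effects exceed 1% in
magnitude (strictly), e.g. the Eclipse DLG and MLC transmission factor,
and the RayStation MLC transmission, tongue-and-groove, leaf-tip width
and MLC position offset.

**Audit outcomes.**  TLD error is `100·(calculated − measured)/measured`
(denominator: the delivered dose; configurable).  An irradiation *fails*
when any TLD error exceeds 7% in magnitude or the film gamma pass rate
falls below 85%; it is *poor* when any TLD exceeds 5% (failing implies
poor).  Audits with a localization offset strictly above 3 mm are
excluded from dose-error estimation.  Gamma analysis is global (dose
criterion normalized to the calculated grid's maximum, 20% low-dose
threshold on that maximum), with a discrete search over grid nodes
within a 3×DTA radius and no subpixel interpolation — deterministic and
adequate at the ≤ 1 mm synthetic grid spacings used here.  A record may
carry either film grids or a precomputed pass rate; grids take
precedence.  Whether film enters the failing definition is configurable
(`use_film`), since association analyses on dose errors are naturally
TLD-driven.

## Association statistics

Pooled any-atypical vs failing/poor comparisons use the chi-square test
(no continuity correction by default; available by flag); per-parameter
comparisons use the two-sided Fisher exact test with probability-mass
ordering (the convention of standard statistical software), reporting
the sample odds ratio ad/bc.  Continuous relationships use Pearson
correlation with a two-sided t-based p-value (n − 2 df).  Records
missing a parameter are dropped pairwise; tests with fewer than 3 usable
records or degenerate tables are reported as not computed rather than
raised.  Raw p-values are primary; a Benjamini–Hochberg column over the
per-parameter Fisher tests is emitted alongside for transparency.

## Synthetic cohorts

The multi-institution audit database this kind of analysis runs on is
not public, so the generator emulates its structure:

* **Communities** are defined by piecewise-linear inverse CDFs through
  the anchor (percentile, value) pairs, extended flat beyond the
  2.5th/97.5th — the weakest assumption consistent with the published
  quantiles.  Draws therefore never leave the anchored range, and flat
  anchor segments produce atoms at the distribution tails, as real
  discrete-valued parameter surveys do.
* **Inter-parameter correlation** uses a Gaussian copula on ranks,
  calibrated via the exact Spearman-to-Gaussian conversion
  ρ_z = 2·sin(π·ρ_s/6).  The default Eclipse AAA community induces rank
  correlation 0.6 between DLG and MLC transmission, emulating the
  observed tendency of high-DLG institutions to adopt high transmission.
* **Audits**: the true systematic error is E = Σ per-parameter effects
  + N(0, σ_resid), where σ_resid lumps all non-TPS error modes (beam
  data, delivery, calibration).  Each TLD reads measured =
  2 Gy·(1 + η) and calculated = measured·(1 + (E + ε)/100) with η, ε ~
  N(0, σ_TLD), so the TLD-error convention round-trips exactly.
  Localization offsets are injected independently of dose error (they
  are a separate, excludable mode): with probability 11/337 a uniform
  offset in 3.5–10 mm, otherwise 0–2 mm.
* **Defaults** define the emulated study conditions: 337 institutions,
  phantom mix 258/34/45 (head-and-neck/spine/prostate), 8 TLDs per
  phantom, σ_resid = 2%, σ_TLD = 1.5%.  σ_resid and σ_TLD are not
  published quantities; they were set once to give a failing rate near
  the reported ~9% and a visibly attenuated estimated-vs-measured
  correlation.  Under these defaults the "poor" rate runs higher than
  the real cohort's — the poor label is sensitive to the TLD count and
  noise model, which is a known infidelity of the generator.
* **Seeding**: one master seed; institutions and audits draw from
  deterministically spawned substreams, so cohorts are reproducible and
  stable under appending institutions.  Generated studies are
  byte-identical on repeat.

What passing synthetic tests do **not** show about real data: real
communities need not follow the piecewise-linear inverse CDF between
printed quantiles; real per-parameter dose responses are only
approximately linear and independent; real audits have plan- and
machine-specific error structure that a single Gaussian residual cannot
carry; and the optimal beam-model value genuinely differs between
machines, so an atypical value is not per se wrong.

## Numerical choices and degenerate inputs

* Anchor tables validate hard: percentiles sorted and complete
  (2.5/10/50/90/97.5), values non-decreasing with percentile, zero
  median effect, finite entries.
* `anchor_matched_distribution` lays n = 201 values on the anchor
  inverse CDF at the equally spaced order-statistic positions, making
  quantile lookups at anchor percentiles exact (anchor round-tripping to
  machine precision).
* Aggregation is an exact float sum; duplicate parameter names are
  rejected.
* Fisher's p uses a relative tie tolerance of ~1e−7 in the
  probability-mass ordering (inherited from the underlying
  implementation); the test suite verifies exact agreement with direct
  hypergeometric enumeration on all 2×2 tables with grand total ≤ 30.
* Correlations with fewer than 3 pairs or zero variance are errors at
  the function level and "not computed" rows at the report level.
* Gamma pass uses γ ≤ 1 with no tolerance; the pass rate is exactly
  invariant under common positive rescaling of both grids.

## Problem sizes in the test suite

Simulation-backed checks use sizes chosen for tight Monte-Carlo error at
interactive runtimes: 10,000-draw communities for quantile calibration,
2,000 scored institutions for the 20%-atypicality check, 100 replicates
of 300-institution cohorts for the correlation-attenuation check, and
500 replicates of 80-institution null cohorts for type-I-error control.

## Known limitations

* The dose-effect catalog covers one equipment stratum (6 MV Varian Base
  class with Millennium120 MLC) for two TPS families; other strata
  require their own anchor files.
* No uncertainty is propagated onto the aggregate estimate — it is a
  point prediction by design.
* The film model is a flat-field/profile gamma comparison; no 2-D plan
  dose simulation, registration or film physics.
* Percentile-space queries between anchors depend on the assumed
  community inverse CDF; only anchor-point queries are
  assumption-free.
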