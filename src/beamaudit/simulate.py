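"""Synthetic audit-cohort generator with known ground truth.

The real audit database behind this kind of analysis is not public, so
every stage of the pipeline is exercised on synthetic cohorts built to
have the statistical structure the analysis assumes:

* community parameter distributions defined by piecewise-linear inverse
  CDFs through the anchor (percentile, value) pairs, flat beyond the
  2.5th/97.5th percentiles — the weakest assumption consistent with the
  published quantiles;
* institutions drawing one value per parameter from that community,
  optionally with rank correlation between parameters via a Gaussian
  copula (emulating the observed tendency of institutions with a high
  leaf gap to also use high MLC transmission);
* audits whose true systematic TPS error is the additive per-parameter
  dose effect plus Gaussian residual noise standing in for non-TPS error
  modes (beam data, delivery, calibration, ...), with per-TLD Gaussian
  measurement noise on top and an occasional localization offset injected
  independently of dose error.

One master seed drives everything; per-institution substreams are
spawned deterministically so a cohort is reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .effects import (EffectEstimate, EffectModel, ParameterAnchorTable,
                      aggregate_error, build_effect_models, default_stratum,
                      load_anchor_tables)
from .outcomes import AuditRecord, TLDMeasurement
from .survey import BeamModelReport, EquipmentStratum

#: Nominal prescription dose at a TLD location (Gy).
NOMINAL_TLD_DOSE_GY = 2.0


@dataclass(frozen=True)
class CommunityConfig:
    """Community model: one inverse CDF per parameter, optional copula.

    ``rank_correlation``, when given, is a symmetric positive
    semi-definite Spearman correlation matrix with unit diagonal over the
    parameters in ``tables`` key order; parameter values are then drawn
    through a Gaussian copula calibrated to those rank correlations.
    """

    stratum: EquipmentStratum
    tables: Mapping[str, ParameterAnchorTable]
    rank_correlation: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.tables:
            raise ValueError("community needs at least one parameter table")
        if self.rank_correlation is not None:
            corr = np.asarray(self.rank_correlation, dtype=float)
            k = len(self.tables)
            if corr.shape != (k, k):
                raise ValueError(f"correlation matrix must be {k}x{k}")
            if not np.allclose(corr, corr.T):
                raise ValueError("correlation matrix must be symmetric")
            if not np.allclose(np.diag(corr), 1.0):
                raise ValueError("correlation matrix must have unit diagonal")
            if np.linalg.eigvalsh(corr).min() < -1e-10:
                raise ValueError("correlation matrix must be positive semi-definite")
            object.__setattr__(self, "rank_correlation", corr)

    @property
    def parameter_names(self) -> list[str]:
        return list(self.tables)


@dataclass(frozen=True)
class CohortConfig:
    """Size and noise structure of a synthetic audit cohort.

    Defaults emulate the study conditions: 337 audits dominated by the
    head-and-neck phantom, a residual (non-TPS) error SD of 2%, 1.5%
    per-TLD measurement noise, and a small fraction of audits with a
    localization offset beyond the 3 mm exclusion cut.
    """

    n_institutions: int = 337
    sigma_residual_pct: float = 2.0
    tld_noise_pct: float = 1.5
    n_tld_per_phantom: int = 8
    localization_error_prob: float = 11 / 337
    localization_offset_range_mm: tuple[float, float] = (3.5, 10.0)
    nominal_offset_range_mm: tuple[float, float] = (0.0, 2.0)
    phantom_mix: Mapping[str, float] = field(default_factory=lambda: {
        "head_and_neck": 258 / 337, "spine": 34 / 337, "prostate": 45 / 337})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_institutions < 0:
            raise ValueError("n_institutions must be non-negative")
        if self.sigma_residual_pct < 0 or self.tld_noise_pct < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.n_tld_per_phantom < 1:
            raise ValueError("need at least one TLD per phantom")
        if not 0.0 <= self.localization_error_prob <= 1.0:
            raise ValueError("localization_error_prob must lie in [0, 1]")
        for rng_name in ("localization_offset_range_mm", "nominal_offset_range_mm"):
            lo, hi = getattr(self, rng_name)
            if not 0 <= lo <= hi:
                raise ValueError(f"{rng_name} must be an ordered non-negative pair")
        total = sum(self.phantom_mix.values())
        if not math.isclose(total, 1.0, rel_tol=1e-9):
            raise ValueError("phantom_mix probabilities must sum to 1")


def inverse_cdf(table: ParameterAnchorTable, percentile) -> np.ndarray:
    """Community quantile function implied by the anchors (flat in the tails)."""
    return np.interp(percentile, table.percentiles, table.values)


def _spearman_to_gauss(corr: np.ndarray) -> np.ndarray:
    # Gaussian-copula correlation reproducing a target Spearman matrix.
    rho = 2.0 * np.sin(np.pi * corr / 6.0)
    np.fill_diagonal(rho, 1.0)
    return rho


def _uniform_percentiles(config: CommunityConfig, n: int,
                         rng: np.random.Generator) -> np.ndarray:
    k = len(config.tables)
    if config.rank_correlation is None:
        return rng.uniform(0.0, 100.0, size=(n, k))
    rho = _spearman_to_gauss(config.rank_correlation)
    # eigendecomposition handles PSD matrices that are not PD
    w, v = np.linalg.eigh(rho)
    factor = v * np.sqrt(np.clip(w, 0.0, None))
    z = rng.standard_normal((n, k)) @ factor.T
    return 100.0 * _sps.norm.cdf(z)


def sample_community(config: CommunityConfig, n: int,
                     seed: int | np.random.Generator = 0) -> dict[str, np.ndarray]:
    """Draw ``n`` community responses per parameter (one shared pool).

    Values come from the anchor-implied inverse CDF applied to (rank-
    correlated) uniforms; draws never leave the anchored value range.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pct = _uniform_percentiles(config, n, rng)
    return {name: inverse_cdf(table, pct[:, j])
            for j, (name, table) in enumerate(config.tables.items())}


def sample_institutions(config: CommunityConfig, n_institutions: int,
                        seed: int | np.random.SeedSequence = 0,
                        id_prefix: str = "inst") -> list[BeamModelReport]:
    """Sample institutional beam-model reports from the community model.

    Each institution draws from its own spawned random substream, so a
    cohort is stable under changes to how many institutions follow it.
    """
    if n_institutions < 0:
        raise ValueError("n_institutions must be non-negative")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n_institutions)
    reports = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        pct = _uniform_percentiles(config, 1, rng)[0]
        params = {name: float(inverse_cdf(table, pct[j]))
                  for j, (name, table) in enumerate(config.tables.items())}
        reports.append(BeamModelReport(
            institution_id=f"{id_prefix}{i + 1:04d}", stratum=config.stratum,
            parameters=params))
    return reports


@dataclass(frozen=True)
class SimulatedAudit:
    """An audit record plus the generative ground truth behind it."""

    record: AuditRecord
    true_error_pct: float       # aggregate model effect + residual mode
    predicted_error_pct: float  # aggregate model effect alone


def simulate_audit(
    report: BeamModelReport,
    effect_models: Mapping[tuple[str, str], EffectModel],
    cohort_config: CohortConfig,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> SimulatedAudit:
    """Simulate one phantom irradiation for an institution.

    The true systematic error is the additive per-parameter dose effect at
    the institution's values plus ``Normal(0, sigma_residual_pct)``; each
    TLD then reads ``measured = 2 Gy * (1 + eta)`` and ``calculated =
    measured * (1 + (E + eps)/100)`` with independent per-TLD noise, so
    the signed TLD error round-trips the sign convention exactly.
    """
    if isinstance(seed, np.random.Generator):
        rng = seed
    else:
        rng = np.random.default_rng(seed)
    tps = report.stratum.tps_name
    components = []
    for name, value in report.parameters.items():
        model = effect_models.get((tps, name))
        if model is None:
            raise ValueError(f"no effect model for parameter {name!r} under TPS {tps!r}")
        components.append(EffectEstimate(parameter_name=name, value=float(value),
                                         effect_pct=model.effect_at_value(value)))
    predicted = aggregate_error(components, report.institution_id).total_pct
    true_error = predicted + rng.normal(0.0, cohort_config.sigma_residual_pct)

    phantoms = list(cohort_config.phantom_mix)
    probs = np.array([cohort_config.phantom_mix[p] for p in phantoms])
    phantom = str(rng.choice(phantoms, p=probs / probs.sum()))

    tlds = []
    for i in range(cohort_config.n_tld_per_phantom):
        eta = rng.normal(0.0, cohort_config.tld_noise_pct) / 100.0
        eps = rng.normal(0.0, cohort_config.tld_noise_pct)
        measured = NOMINAL_TLD_DOSE_GY * (1.0 + eta)
        calculated = measured * (1.0 + (true_error + eps) / 100.0)
        tlds.append(TLDMeasurement(label=f"TLD{i + 1}", measured_dose=measured,
                                   calculated_dose=calculated))

    if rng.random() < cohort_config.localization_error_prob:
        offset = float(rng.uniform(*cohort_config.localization_offset_range_mm))
    else:
        offset = float(rng.uniform(*cohort_config.nominal_offset_range_mm))

    record = AuditRecord(
        institution_id=report.institution_id, phantom=phantom, tlds=tuple(tlds),
        localization_offset_mm=offset, stratum=report.stratum)
    return SimulatedAudit(record=record, true_error_pct=float(true_error),
                          predicted_error_pct=float(predicted))


def simulate_cohort(
    community: CommunityConfig,
    cohort: CohortConfig,
    effect_models: Mapping[tuple[str, str], EffectModel] | None = None,
) -> tuple[list[BeamModelReport], list[SimulatedAudit]]:
    """Sample institutions and one audit each, all from the cohort seed."""
    if effect_models is None:
        effect_models = build_effect_models(load_anchor_tables())
    root = np.random.SeedSequence(cohort.seed)
    inst_seed, audit_seed = root.spawn(2)
    reports = sample_institutions(community, cohort.n_institutions, seed=inst_seed)
    audits = []
    for report, child in zip(reports, audit_seed.spawn(len(reports))):
        audits.append(simulate_audit(report, effect_models, cohort, seed=child))
    return reports, audits


def default_community_config(
    tps_name: str = "Eclipse AAA",
    anchor_tables: Mapping[tuple[str, str], ParameterAnchorTable] | None = None,
    dlg_transmission_rank_corr: float = 0.6,
) -> CommunityConfig:
    """Community model for the shipped anchor catalog of one TPS.

    For Eclipse AAA a rank correlation (default 0.6) is induced between
    the dosimetric leaf gap and the MLC transmission factor, mirroring the
    tendency of institutions that adopt a high leaf gap to also adopt a
    high transmission.
    """
    if anchor_tables is None:
        anchor_tables = load_anchor_tables()
    tables = {param: table for (tps, param), table in anchor_tables.items()
              if tps == tps_name}
    if not tables:
        raise ValueError(f"no anchor tables for TPS {tps_name!r}")
    corr = None
    names = list(tables)
    if (dlg_transmission_rank_corr
            and "Dosimetric Leaf Gap" in names and "MLC Transmission Factor" in names):
        corr = np.eye(len(names))
        i = names.index("Dosimetric Leaf Gap")
        j = names.index("MLC Transmission Factor")
        corr[i, j] = corr[j, i] = dlg_transmission_rank_corr
    return CommunityConfig(stratum=default_stratum(tps_name), tables=tables,
                           rank_correlation=corr)


def generate_study(
    community_config: CommunityConfig,
    cohort_config: CohortConfig,
    out_dir: str | Path,
    effect_models: Mapping[tuple[str, str], EffectModel] | None = None,
) -> dict[str, Path]:
    """Write a complete synthetic study: survey, audit cohort, ground truth.

    Produces ``survey.csv`` (one row per institution-parameter, also the
    community sample the pipeline scores against), ``cohort.csv`` (one row
    per TLD) and ``truth.csv`` (true and model-predicted systematic error
    per institution, for recovery testing).  Byte-identical on repeat for
    a fixed configuration.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reports, audits = simulate_cohort(community_config, cohort_config, effect_models)

    stratum = community_config.stratum
    survey_rows = [
        dict(institution_id=r.institution_id, tps=stratum.tps_name,
             linac_class=stratum.linac_class, beam_energy=stratum.beam_energy,
             mlc_model=stratum.mlc_model, parameter=name, value=value,
             units=community_config.tables[name].units)
        for r in reports for name, value in r.parameters.items()]

    cohort_rows = []
    for sim in audits:
        rec = sim.record
        for tld in rec.tlds:
            cohort_rows.append(dict(
                institution_id=rec.institution_id, phantom=rec.phantom,
                tld_label=tld.label, measured_dose_gy=tld.measured_dose,
                calculated_dose_gy=tld.calculated_dose, film_pass_pct="",
                localization_offset_mm=rec.localization_offset_mm,
                irradiation_date=""))

    truth_rows = [dict(institution_id=sim.record.institution_id,
                       true_error_pct=sim.true_error_pct,
                       predicted_error_pct=sim.predicted_error_pct)
                  for sim in audits]

    paths = {"survey": out / "survey.csv", "cohort": out / "cohort.csv",
             "truth": out / "truth.csv"}
    try:
        pd.DataFrame(survey_rows).to_csv(paths["survey"], index=False)
        pd.DataFrame(cohort_rows).to_csv(paths["cohort"], index=False)
        pd.DataFrame(truth_rows).to_csv(paths["truth"], index=False)
    except OSError as exc:
        raise OSError(f"failed writing study files under {out}: {exc}") from exc
    return paths
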