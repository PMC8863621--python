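"""End-to-end audit analysis: load, score, estimate, classify, test, report.

Input schemas (UTF-8 CSV, header required, '.' decimal separator):

* survey: ``institution_id, tps, linac_class, beam_energy, mlc_model,
  parameter, value, units`` — one row per institution-parameter.  The
  same file defines both the community distributions (pooled within each
  equipment stratum) and the per-institution beam-model reports.
* audit: ``institution_id, phantom, tld_label, measured_dose_gy,
  calculated_dose_gy, film_pass_pct, localization_offset_mm,
  irradiation_date`` — one row per TLD.
* truth (optional, from the synthetic generator): ``institution_id,
  true_error_pct, predicted_error_pct``.

The pipeline scores every institution's parameters against its stratum's
community, predicts the aggregate TPS dose error from the anchor models,
classifies audit outcomes, applies the localization exclusion, runs the
association battery, and writes a summary/association/scatter report
(CSV plus a JSON mirror with provenance).  Re-runs on identical inputs
produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .effects import (EffectEstimate, aggregate_error, build_effect_models,
                      impactful_parameters, load_anchor_tables,
                      DEFAULT_IMPACTFUL_CUT_PCT)
from .outcomes import (AuditRecord, TLDMeasurement, classify_outcome,
                       DEFAULT_FAIL_TLD_PCT, DEFAULT_FILM_PASS_MIN,
                       DEFAULT_MAX_OFFSET_MM, DEFAULT_POOR_TLD_PCT)
from .stats import ScoredAudit, run_association_analysis
from .survey import (BeamModelReport, EquipmentStratum, SurveyDistribution,
                     fit_distribution, score_report,
                     DEFAULT_HIGH_CUT, DEFAULT_LOW_CUT, DEFAULT_MIN_SAMPLE_SIZE)

logger = logging.getLogger(__name__)

SURVEY_COLUMNS = ["institution_id", "tps", "linac_class", "beam_energy",
                  "mlc_model", "parameter", "value", "units"]
AUDIT_COLUMNS = ["institution_id", "phantom", "tld_label", "measured_dose_gy",
                 "calculated_dose_gy", "film_pass_pct", "localization_offset_mm"]


@dataclass(frozen=True)
class RunConfig:
    """All inputs and thresholds of one analysis run."""

    survey_path: str | Path
    audit_path: str | Path
    anchors_path: str | Path | None = None  # None -> shipped anchor tables
    truth_path: str | Path | None = None
    out_dir: str | Path | None = None
    fail_tld_pct: float = DEFAULT_FAIL_TLD_PCT
    poor_tld_pct: float = DEFAULT_POOR_TLD_PCT
    low_cut: float = DEFAULT_LOW_CUT
    high_cut: float = DEFAULT_HIGH_CUT
    impactful_cut_pct: float = DEFAULT_IMPACTFUL_CUT_PCT
    localization_cut_mm: float = DEFAULT_MAX_OFFSET_MM
    film_pass_min: float = DEFAULT_FILM_PASS_MIN
    use_film: bool = True
    min_sample_size: int = DEFAULT_MIN_SAMPLE_SIZE
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.fail_tld_pct < self.poor_tld_pct:
            raise ValueError("fail_tld_pct must be at least poor_tld_pct")
        for name in ("fail_tld_pct", "poor_tld_pct", "impactful_cut_pct",
                     "localization_cut_mm", "film_pass_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class RunReport:
    """Everything one run produces, before serialization."""

    summary: pd.DataFrame
    association: pd.DataFrame
    scatter: pd.DataFrame
    scores: pd.DataFrame
    scored_audits: list[ScoredAudit]
    provenance: dict


def _require_columns(df: pd.DataFrame, columns: Sequence[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def load_survey(
    path: str | Path,
    min_sample_size: int = DEFAULT_MIN_SAMPLE_SIZE,
) -> tuple[list[BeamModelReport], list[SurveyDistribution]]:
    """Read a survey CSV into per-institution reports + community distributions.

    Community distributions pool all responses within each (stratum,
    parameter); strata with fewer than ``min_sample_size`` responses are
    logged and skipped rather than scored.
    """
    df = pd.read_csv(path, dtype={"institution_id": str})
    _require_columns(df, SURVEY_COLUMNS, path)
    if df["value"].isna().any():
        bad = df.index[df["value"].isna()][0] + 2  # header + 1-based
        raise ValueError(f"{path}: missing parameter value at row {bad}")

    reports: list[BeamModelReport] = []
    for inst, grp in df.groupby("institution_id", sort=True):
        strata = grp[["tps", "linac_class", "beam_energy", "mlc_model"]].drop_duplicates()
        if len(strata) != 1:
            raise ValueError(f"{path}: institution {inst!r} reports multiple strata")
        row = strata.iloc[0]
        stratum = EquipmentStratum(row["tps"], row["linac_class"],
                                   row["beam_energy"], row["mlc_model"])
        params = dict(zip(grp["parameter"], grp["value"].astype(float)))
        reports.append(BeamModelReport(institution_id=str(inst), stratum=stratum,
                                       parameters=params))

    distributions: list[SurveyDistribution] = []
    for (tps, linac, energy, mlc, parameter), grp in df.groupby(
            ["tps", "linac_class", "beam_energy", "mlc_model", "parameter"],
            sort=True):
        stratum = EquipmentStratum(tps, linac, energy, mlc)
        values = grp["value"].astype(float).to_numpy()
        if values.size < min_sample_size:
            logger.warning("skipping %s / %r: only %d community responses "
                           "(minimum %d)", stratum, parameter, values.size,
                           min_sample_size)
            continue
        units = str(grp["units"].iloc[0]) if grp["units"].notna().any() else ""
        distributions.append(fit_distribution(values, stratum, str(parameter),
                                              units=units,
                                              min_sample_size=min_sample_size))
    logger.info("survey: %d institutions, %d scoreable (stratum, parameter) pools",
                len(reports), len(distributions))
    return reports, distributions


def load_audits(
    path: str | Path,
    strata: Mapping[str, EquipmentStratum] | None = None,
) -> list[AuditRecord]:
    """Read an audit CSV (one row per TLD) into one record per institution."""
    df = pd.read_csv(path, dtype={"institution_id": str})
    _require_columns(df, AUDIT_COLUMNS, path)
    records: list[AuditRecord] = []
    for inst, grp in df.groupby("institution_id", sort=True):
        phantoms = grp["phantom"].unique()
        if len(phantoms) != 1:
            raise ValueError(f"{path}: institution {inst!r} lists multiple phantoms")
        tlds = tuple(
            TLDMeasurement(label=str(r.tld_label),
                           measured_dose=float(r.measured_dose_gy),
                           calculated_dose=float(r.calculated_dose_gy))
            for r in grp.itertuples())
        film_vals = grp["film_pass_pct"].dropna()
        film_pass = float(film_vals.iloc[0]) if len(film_vals) else None
        offset = float(grp["localization_offset_mm"].iloc[0])
        records.append(AuditRecord(
            institution_id=str(inst), phantom=str(phantoms[0]), tlds=tlds,
            localization_offset_mm=offset, film_pass_pct=film_pass,
            stratum=None if strata is None else strata.get(str(inst))))
    logger.info("audits: %d irradiations (%d TLD rows)", len(records), len(df))
    return records


def load_truth(path: str | Path) -> dict[str, float]:
    df = pd.read_csv(path, dtype={"institution_id": str})
    _require_columns(df, ["institution_id", "true_error_pct"], path)
    return dict(zip(df["institution_id"], df["true_error_pct"].astype(float)))


def summarize_cohort(records: Sequence[AuditRecord]) -> pd.DataFrame:
    """Counts and percentages by TPS, linac class, beam energy and phantom."""
    if not records:
        raise ValueError("no audit records to summarize")
    rows = []
    blocks = {
        "tps": lambda r: r.stratum.tps_name if r.stratum else "unknown",
        "linac_class": lambda r: r.stratum.linac_class if r.stratum else "unknown",
        "beam_energy": lambda r: r.stratum.beam_energy if r.stratum else "unknown",
        "phantom": lambda r: r.phantom,
    }
    total = len(records)
    for block, getter in blocks.items():
        counts: dict[str, int] = {}
        for rec in records:
            key = getter(rec)
            counts[key] = counts.get(key, 0) + 1
        for category in sorted(counts):
            rows.append(dict(block=block, category=category, n=counts[category],
                             pct=round(100.0 * counts[category] / total, 1)))
    return pd.DataFrame(rows)


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _jsonable(df: pd.DataFrame) -> list[dict]:
    out = []
    for rec in df.to_dict(orient="records"):
        out.append({k: (None if isinstance(v, float) and math.isnan(v) else v)
                    for k, v in rec.items()})
    return out


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute score -> estimate -> classify -> filter -> test -> report."""
    logging.basicConfig(level=config.log_level)
    anchors = load_anchor_tables(config.anchors_path)
    models = build_effect_models(anchors)
    known_tps = {tps for tps, _ in anchors}
    catalog_by_tps: dict[str, set[str]] = {}
    for tps, param in anchors:
        catalog_by_tps.setdefault(tps, set()).add(param)

    reports, distributions = load_survey(config.survey_path, config.min_sample_size)
    by_institution = {r.institution_id: r for r in reports}
    for row_no, rep in enumerate(reports, start=1):
        if rep.stratum.tps_name not in known_tps:
            raise ValueError(
                f"{config.survey_path}: institution {rep.institution_id!r} "
                f"(record {row_no}) uses unknown TPS {rep.stratum.tps_name!r}; "
                f"known: {sorted(known_tps)}")

    strata = {i: r.stratum for i, r in by_institution.items()}
    audit_records = load_audits(config.audit_path, strata)
    for row_no, rec in enumerate(audit_records, start=1):
        if rec.institution_id not in by_institution:
            raise ValueError(
                f"{config.audit_path}: record {row_no} names institution "
                f"{rec.institution_id!r} absent from the survey")

    truth = load_truth(config.truth_path) if config.truth_path else {}

    scoreable = {(d.stratum.key, d.parameter_name) for d in distributions}
    scored_audits: list[ScoredAudit] = []
    score_rows = []
    for rec in audit_records:
        rep = by_institution[rec.institution_id]
        tps = rep.stratum.tps_name
        catalog = catalog_by_tps.get(tps, set())
        in_pool = {name for name in rep.parameters
                   if (rep.stratum.key, name) in scoreable}
        scores = score_report(
            dataclasses.replace(rep, parameters={
                k: v for k, v in rep.parameters.items() if k in in_pool}),
            distributions, low_cut=config.low_cut, high_cut=config.high_cut,
            catalog=catalog)
        components = [
            EffectEstimate(parameter_name=name, value=float(value),
                           effect_pct=models[(tps, name)].effect_at_value(value))
            for name, value in rep.parameters.items() if (tps, name) in models]
        estimate = aggregate_error(components, rec.institution_id)
        outcome = classify_outcome(
            rec, fail_tld_pct=config.fail_tld_pct, poor_tld_pct=config.poor_tld_pct,
            film_pass_min=config.film_pass_min,
            max_offset_mm=config.localization_cut_mm, use_film=config.use_film)
        scored_audits.append(ScoredAudit(
            institution_id=rec.institution_id, tps_name=tps,
            scores={s.parameter_name: s for s in scores},
            failing=outcome.failing, poor=outcome.poor,
            excluded_for_localization=outcome.excluded_for_localization,
            mean_tld_error_pct=outcome.mean_tld_error_pct,
            estimated_error_pct=estimate.total_pct if components else None,
            true_error_pct=truth.get(rec.institution_id)))
        for s in scores:
            score_rows.append(dict(
                institution_id=rec.institution_id, tps=tps,
                parameter=s.parameter_name, value=s.value,
                percentile=s.percentile, atypical=s.atypical))

    n_excluded = sum(r.excluded_for_localization for r in scored_audits)
    logger.info("classified %d audits: %d failing, %d poor, %d excluded for "
                "localization", len(scored_audits),
                sum(r.failing for r in scored_audits),
                sum(r.poor for r in scored_audits), n_excluded)

    impactful = impactful_parameters(anchors.values(), config.impactful_cut_pct)
    association = run_association_analysis(scored_audits, impactful=impactful)
    summary = summarize_cohort(audit_records)
    scatter = pd.DataFrame([
        dict(institution_id=r.institution_id, tps=r.tps_name,
             estimated_error_pct=r.estimated_error_pct,
             mean_tld_error_pct=r.mean_tld_error_pct,
             true_error_pct=r.true_error_pct,
             failing=r.failing, poor=r.poor,
             excluded_for_localization=r.excluded_for_localization)
        for r in scored_audits])

    config_dict = {k: (str(v) if isinstance(v, Path) else v)
                   for k, v in dataclasses.asdict(config).items()}
    provenance = {
        "beamaudit_version": __version__,
        "config": config_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(config_dict, sort_keys=True).encode()).hexdigest(),
        "inputs": {
            "survey_sha256": _sha256(config.survey_path),
            "audit_sha256": _sha256(config.audit_path),
            "truth_sha256": _sha256(config.truth_path) if config.truth_path else None,
        },
        "counts": {
            "institutions": len(by_institution),
            "audits": len(scored_audits),
            "failing": int(sum(r.failing for r in scored_audits)),
            "poor": int(sum(r.poor for r in scored_audits)),
            "excluded_for_localization": int(n_excluded),
        },
    }
    report = RunReport(summary=summary, association=association, scatter=scatter,
                       scores=pd.DataFrame(score_rows),
                       scored_audits=scored_audits, provenance=provenance)
    if config.out_dir is not None:
        write_report(report, config.out_dir)
    return report


def write_report(report: RunReport, out_dir: str | Path) -> dict[str, Path]:
    """Serialize a run report: CSV tables plus a JSON mirror with provenance."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {name: out / f"{name}.csv"
             for name in ("summary", "association", "scatter", "scores")}
    report.summary.to_csv(paths["summary"], index=False)
    report.association.to_csv(paths["association"], index=False)
    report.scatter.to_csv(paths["scatter"], index=False)
    report.scores.to_csv(paths["scores"], index=False)
    mirror = {
        "provenance": report.provenance,
        "summary": _jsonable(report.summary),
        "association": _jsonable(report.association),
        "scatter": _jsonable(report.scatter),
    }
    paths["report"] = out / "report.json"
    paths["report"].write_text(json.dumps(mirror, indent=2, sort_keys=True))
    return paths
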