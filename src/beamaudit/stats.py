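"""Association tests between parameter atypicality and audit outcome.

Audits are grouped by whether the institution reported atypical
beam-model parameter values, and the proportion of atypical reporters is
compared between failing and passing (or poor and well-performed)
irradiations with Fisher's exact test (per parameter) or the chi-square
test (pooled groups).  Continuous relationships — parameter percentile
vs mean TLD error, and predicted vs measured dose error — use Pearson
correlation.  Two-sided p-values throughout; no multiple-testing
adjustment is applied to the primary p-values (a Benjamini-Hochberg
column is emitted alongside for transparency).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .survey import PercentileScore


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows = flag yes/no and columns = outcome yes/no."""

    a: int  # flagged & outcome
    b: int  # flagged & not outcome
    c: int  # not flagged & outcome
    d: int  # not flagged & not outcome

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer")
        if self.total == 0:
            raise ValueError("contingency table must have a positive grand total")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


@dataclass(frozen=True)
class TestResult:
    method: str
    statistic: float
    p_value: float
    n: int
    estimate: float | None = None
    note: str = ""

    def __post_init__(self) -> None:
        if not (math.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value must lie in [0, 1]")


def build_table(records_with_flags: Iterable[tuple[bool, bool]]) -> ContingencyTable2x2:
    """Tally (flag, outcome) pairs into a 2x2 table."""
    a = b = c = d = 0
    n = 0
    for flag, outcome in records_with_flags:
        n += 1
        if flag and outcome:
            a += 1
        elif flag:
            b += 1
        elif outcome:
            c += 1
        else:
            d += 1
    if n == 0:
        raise ValueError("no records to tabulate")
    return ContingencyTable2x2(a, b, c, d)


def fisher_exact(table: ContingencyTable2x2) -> TestResult:
    """Two-sided Fisher's exact test (probability-mass ordering).

    The p-value sums hypergeometric probabilities, margins fixed, of all
    tables at most as probable as the observed one.  The reported estimate
    is the sample odds ratio ``ad/bc`` (infinite or zero with an empty
    cell, flagged in ``note``).
    """
    odds, p = _sps.fisher_exact(table.as_array(), alternative="two-sided")
    note = ""
    if table.b * table.c == 0 and table.a * table.d != 0:
        note = "odds ratio infinite (zero off-diagonal cell)"
    elif table.a * table.d == 0 and table.b * table.c != 0:
        note = "odds ratio zero (zero diagonal cell)"
    return TestResult(method="fisher_exact", statistic=float(odds),
                      p_value=float(p), n=table.total, estimate=float(odds),
                      note=note)


def chi_square(table: ContingencyTable2x2,
               continuity_correction: bool = False) -> TestResult:
    """Pearson chi-square test of independence on a 2x2 table (1 df)."""
    arr = table.as_array()
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("chi-square undefined: a margin is zero (expected count 0)")
    res = _sps.chi2_contingency(arr, correction=continuity_correction)
    return TestResult(method="chi_square", statistic=float(res.statistic),
                      p_value=float(res.pvalue), n=table.total)


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Pearson r with a two-sided p from the t-distribution (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("correlation undefined: zero variance")
    res = _sps.pearsonr(x, y)
    r = float(res.statistic)
    return TestResult(method="pearson", statistic=r, p_value=float(res.pvalue),
                      n=int(x.size), estimate=r)


@dataclass(frozen=True)
class ScoredAudit:
    """One audited irradiation joined with its percentile scores and labels.

    The bridge record the association analysis consumes: per-parameter
    percentile scores, outcome flags, the mean signed TLD error, and the
    model-predicted aggregate TPS error (when the TPS has anchor tables).
    """

    institution_id: str
    tps_name: str
    scores: Mapping[str, PercentileScore]
    failing: bool
    poor: bool
    excluded_for_localization: bool = False
    mean_tld_error_pct: float = math.nan
    estimated_error_pct: float | None = None
    true_error_pct: float | None = None

    @property
    def any_atypical(self) -> bool:
        return any(s.atypical for s in self.scores.values())

    def any_atypical_among(self, parameters: Iterable[str]) -> bool:
        params = set(parameters)
        return any(s.atypical for name, s in self.scores.items() if name in params)


_MIN_RECORDS = 3


def _row(test_id: str, method: str, **kw) -> dict:
    base = dict(test_id=test_id, method=method, parameter="", group="",
                outcome="", a=np.nan, b=np.nan, c=np.nan, d=np.nan,
                n=np.nan, statistic=np.nan, p_value=np.nan, estimate=np.nan,
                computed=False, note="")
    base.update(kw)
    return base


def _contingency_row(test_id, method, parameter, outcome_name, pairs, group="") -> dict:
    pairs = list(pairs)
    if len(pairs) < _MIN_RECORDS:
        return _row(test_id, method, parameter=parameter, outcome=outcome_name,
                    group=group, n=len(pairs), note="fewer than 3 usable records")
    table = build_table(pairs)
    try:
        if method == "chi_square":
            res = chi_square(table)
        else:
            res = fisher_exact(table)
    except ValueError as exc:
        return _row(test_id, method, parameter=parameter, outcome=outcome_name,
                    group=group, a=table.a, b=table.b, c=table.c, d=table.d,
                    n=table.total, note=str(exc))
    return _row(test_id, method, parameter=parameter, outcome=outcome_name,
                group=group, a=table.a, b=table.b, c=table.c, d=table.d,
                n=table.total, statistic=res.statistic, p_value=res.p_value,
                estimate=res.estimate if res.estimate is not None else np.nan,
                computed=True, note=res.note)


def _correlation_row(test_id, parameter, x, y, group="") -> dict:
    try:
        res = pearson_correlation(x, y)
    except ValueError as exc:
        return _row(test_id, "pearson", parameter=parameter, group=group,
                    n=len(x), note=str(exc))
    return _row(test_id, "pearson", parameter=parameter, group=group,
                n=res.n, statistic=res.statistic, p_value=res.p_value,
                estimate=res.estimate, computed=True)


def run_association_analysis(
    records: Sequence[ScoredAudit],
    impactful: set[str] | None = None,
) -> pd.DataFrame:
    """Full battery of outcome-association tests on a scored cohort.

    Produces one row per test: pooled any-atypical vs failing/poor
    (chi-square), the same restricted to the ``impactful`` parameter
    subset, per-parameter Fisher tests for both outcomes, per-parameter
    Pearson correlations between percentile score and mean TLD error, and
    (per TPS and overall) the correlation between the model-predicted
    aggregate error and the measured mean TLD error on
    localization-filtered audits.  Tests with fewer than 3 usable records
    or degenerate tables are reported with ``computed=False`` rather than
    raised.  A Benjamini-Hochberg column ``p_bh`` is added over the
    per-parameter Fisher p-values.
    """
    if len(records) == 0:
        raise ValueError("empty cohort")
    rows: list[dict] = []

    for outcome_name in ("failing", "poor"):
        outcome = [getattr(r, outcome_name) for r in records]
        rows.append(_contingency_row(
            "overall_any_atypical", "chi_square", "", outcome_name,
            zip((r.any_atypical for r in records), outcome)))
        if impactful is not None:
            rows.append(_contingency_row(
                "impactful_any_atypical", "chi_square", "", outcome_name,
                zip((r.any_atypical_among(impactful) for r in records), outcome)))

    parameters = sorted({name for r in records for name in r.scores})
    for param in parameters:
        with_param = [r for r in records if param in r.scores]
        for outcome_name in ("failing", "poor"):
            rows.append(_contingency_row(
                "per_parameter_atypical", "fisher_exact", param, outcome_name,
                ((r.scores[param].atypical, getattr(r, outcome_name))
                 for r in with_param)))
        usable = [r for r in with_param if math.isfinite(r.mean_tld_error_pct)]
        rows.append(_correlation_row(
            "percentile_vs_tld_error", param,
            [r.scores[param].percentile for r in usable],
            [r.mean_tld_error_pct for r in usable]))

    kept = [r for r in records
            if not r.excluded_for_localization
            and r.estimated_error_pct is not None
            and math.isfinite(r.mean_tld_error_pct)]
    groups = [("all", kept)] + [
        (tps, [r for r in kept if r.tps_name == tps])
        for tps in sorted({r.tps_name for r in kept})]
    for group_name, group in groups:
        rows.append(_correlation_row(
            "estimated_vs_measured", "",
            [r.estimated_error_pct for r in group],
            [r.mean_tld_error_pct for r in group], group=group_name))

    truth = [r for r in records
             if not r.excluded_for_localization
             and r.estimated_error_pct is not None and r.true_error_pct is not None]
    if truth:
        rows.append(_correlation_row(
            "estimated_vs_true", "",
            [r.estimated_error_pct for r in truth],
            [r.true_error_pct for r in truth], group="all"))

    report = pd.DataFrame(rows)
    report["p_bh"] = np.nan
    mask = (report["test_id"] == "per_parameter_atypical") & report["computed"]
    if mask.any():
        report.loc[mask, "p_bh"] = _sps.false_discovery_control(
            report.loc[mask, "p_value"].to_numpy(), method="bh")
    return report
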