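"""Community survey distributions and percentile scoring of beam-model parameters.

Radiotherapy institutions commission their treatment planning system (TPS)
by tuning beam-model parameters (dosimetric leaf gap, MLC transmission,
source size, ...).  Within a stratum of equivalent equipment — same TPS,
linac class, beam energy and MLC model — the community of institutions
forms an empirical distribution for each parameter.  This module builds
those distributions from survey records, scores a single institution's
reported values as community percentiles, and flags *atypical* values:
those falling in the outer 20% of the community (below the 10th or above
the 90th percentile).

Percentiles use the linear-interpolation order-statistic convention
(NumPy's default ``method="linear"``, often called type 7); its inverse is
used for percentile ranks, with midranks for tied values.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as _sps

logger = logging.getLogger(__name__)

#: Percentile cuts defining "atypical": strictly below the low cut or
#: strictly above the high cut (the central 80% is "typical").
DEFAULT_LOW_CUT = 10.0
DEFAULT_HIGH_CUT = 90.0

#: Strata with fewer community responses than this are refused rather than
#: scored — percentiles from tiny samples are meaningless.
DEFAULT_MIN_SAMPLE_SIZE = 5


def _norm(text: str) -> str:
    return " ".join(text.split()).casefold()


@dataclass(frozen=True, eq=False)
class EquipmentStratum:
    """Equipment combination within which community values are comparable.

    Equality and hashing are case-insensitive and whitespace-normalized on
    all four fields, so ``"Eclipse  AAA"`` and ``"eclipse aaa"`` match.
    """

    tps_name: str
    linac_class: str
    beam_energy: str
    mlc_model: str

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if not isinstance(value, str) or not value.strip():
                raise ValueError(f"EquipmentStratum.{f.name} must be a non-empty string")

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (_norm(self.tps_name), _norm(self.linac_class),
                _norm(self.beam_energy), _norm(self.mlc_model))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EquipmentStratum):
            return NotImplemented
        return self.key == other.key

    def __hash__(self) -> int:
        return hash(self.key)


@dataclass(frozen=True)
class SurveyDistribution:
    """Empirical community sample of one parameter within one stratum."""

    stratum: EquipmentStratum
    parameter_name: str
    values: np.ndarray  # sorted ascending
    units: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size == 0:
            raise ValueError("SurveyDistribution requires a non-empty 1-D sample")
        if not np.all(np.isfinite(values)):
            raise ValueError("SurveyDistribution values must be finite")
        values = np.sort(values)
        object.__setattr__(self, "values", values)

    @property
    def n(self) -> int:
        return int(self.values.size)

    def quantile(self, percentile: float) -> float:
        """Community value at ``percentile`` (linear order-statistic convention)."""
        if not 0.0 <= percentile <= 100.0:
            raise ValueError("percentile must lie in [0, 100]")
        return float(np.quantile(self.values, percentile / 100.0, method="linear"))


@dataclass(frozen=True)
class BeamModelReport:
    """One institution's reported parameter values plus its equipment stratum."""

    institution_id: str
    stratum: EquipmentStratum
    parameters: Mapping[str, float]

    def __post_init__(self) -> None:
        for name, value in self.parameters.items():
            if not math.isfinite(float(value)):
                raise ValueError(
                    f"report {self.institution_id!r}: parameter {name!r} is not finite")


@dataclass(frozen=True)
class PercentileScore:
    """Community percentile rank of one reported parameter value."""

    parameter_name: str
    value: float
    percentile: float
    atypical: bool


def fit_distribution(
    samples: Sequence[float],
    stratum: EquipmentStratum,
    parameter_name: str,
    units: str = "",
    min_sample_size: int = DEFAULT_MIN_SAMPLE_SIZE,
) -> SurveyDistribution:
    """Build the community distribution of one parameter in one stratum.

    Raises ``ValueError`` on empty input, non-finite samples, or a stratum
    smaller than ``min_sample_size``.
    """
    samples = np.asarray(list(samples), dtype=float)
    if samples.size == 0:
        raise ValueError(f"no survey samples for {parameter_name!r} in stratum {stratum}")
    if not np.all(np.isfinite(samples)):
        raise ValueError(f"non-finite survey sample for {parameter_name!r}")
    if samples.size < min_sample_size:
        raise ValueError(
            f"stratum {stratum} has only {samples.size} responses for "
            f"{parameter_name!r}; at least {min_sample_size} are required")
    return SurveyDistribution(stratum=stratum, parameter_name=parameter_name,
                              values=samples, units=units)


def percentile_of(dist: SurveyDistribution, value: float) -> float:
    """Empirical percentile rank of ``value`` within ``dist``.

    Inverse of the linear order-statistic quantile: sorted values sit at
    percentiles ``100*i/(n-1)`` and ranks interpolate linearly between
    them.  Ties receive the midrank percentile; values below the sample
    minimum map to 0 and above the maximum to 100.
    """
    v = float(value)
    if not math.isfinite(v):
        raise ValueError("cannot rank a non-finite value")
    vals = dist.values
    n = vals.size
    if n == 1:
        if v < vals[0]:
            return 0.0
        if v > vals[0]:
            return 100.0
        return 50.0
    positions = np.linspace(0.0, 100.0, n)
    lo = int(np.searchsorted(vals, v, side="left"))
    hi = int(np.searchsorted(vals, v, side="right"))
    if hi > lo:  # exact ties -> midrank
        return float(positions[lo:hi].mean())
    if lo == 0:
        return 0.0
    if lo == n:
        return 100.0
    return float(np.interp(v, vals, positions))


def classify_atypical(
    percentile: float,
    low_cut: float = DEFAULT_LOW_CUT,
    high_cut: float = DEFAULT_HIGH_CUT,
) -> bool:
    """True iff the percentile falls strictly outside the central band.

    With the default 10/90 cuts this flags the outer 20% of the community;
    a value exactly at a cut is typical (strict inequalities).
    """
    if not (0.0 <= low_cut < high_cut <= 100.0):
        raise ValueError("cuts must satisfy 0 <= low_cut < high_cut <= 100")
    if not 0.0 <= percentile <= 100.0:
        raise ValueError("percentile must lie in [0, 100]")
    return percentile < low_cut or percentile > high_cut


def score_report(
    report: BeamModelReport,
    distributions: Iterable[SurveyDistribution],
    low_cut: float = DEFAULT_LOW_CUT,
    high_cut: float = DEFAULT_HIGH_CUT,
    catalog: set[str] | None = None,
) -> list[PercentileScore]:
    """Score every reported parameter against its community distribution.

    ``distributions`` must contain, for each scored parameter, a
    distribution in the *same* equipment stratum as the report (matching is
    exact on all four stratum fields; there is no pooled fallback).  When a
    ``catalog`` of known parameter names is given, reported parameters
    outside it are skipped with a warning instead of raising.
    """
    lookup = {(d.stratum.key, _norm(d.parameter_name)): d for d in distributions}
    scores: list[PercentileScore] = []
    for name, value in report.parameters.items():
        if catalog is not None and name not in catalog:
            logger.warning(
                "report %s: parameter %r is not in the catalog; excluded from scoring",
                report.institution_id, name)
            continue
        dist = lookup.get((report.stratum.key, _norm(name)))
        if dist is None:
            raise ValueError(
                f"report {report.institution_id!r}: no community distribution for "
                f"parameter {name!r} in stratum {report.stratum}")
        pct = percentile_of(dist, float(value))
        scores.append(PercentileScore(
            parameter_name=name, value=float(value), percentile=pct,
            atypical=classify_atypical(pct, low_cut, high_cut)))
    return scores


def any_atypical(scores: Iterable[PercentileScore]) -> bool:
    """Report-level flag: does any scored parameter fall in the outer tails?"""
    return any(s.atypical for s in scores)


def parameter_correlation(
    reports: Sequence[BeamModelReport],
    param_a: str,
    param_b: str,
) -> tuple[float, float, int]:
    """Pearson correlation of two parameters across institutions.

    Institutions missing either parameter are dropped pairwise.  Returns
    ``(r, p, n)`` where ``n`` is the number of complete pairs.
    """
    xs, ys = [], []
    for rep in reports:
        if param_a in rep.parameters and param_b in rep.parameters:
            xs.append(float(rep.parameters[param_a]))
            ys.append(float(rep.parameters[param_b]))
    n = len(xs)
    if n < 3:
        raise ValueError(
            f"need at least 3 institutions reporting both {param_a!r} and "
            f"{param_b!r}; found {n}")
    x = np.asarray(xs)
    y = np.asarray(ys)
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("correlation undefined: a parameter has zero variance")
    res = _sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue), n
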