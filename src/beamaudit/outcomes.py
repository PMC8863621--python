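"""Phantom-audit measurements and pass/fail classification.

An end-to-end phantom audit irradiates an anthropomorphic phantom
(head-and-neck, spine or prostate) containing TLD point dosimeters and
radiochromic film; the measured doses are compared with the institution's
TPS calculation.  An irradiation *fails* when any TLD disagrees by more
than 7% or the film gamma pass rate falls below 85%, and is *poorly
performed* when any TLD disagrees by more than 5% (so every failing audit
is also poor).  Audits with a film-detected localization offset above
3 mm are excluded from dose-error estimation, isolating dose-magnitude
error modes from setup error.

TLD error convention: ``100 * (calculated - measured) / measured`` — a
positive error means the TPS overestimated the delivered dose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

PHANTOM_TYPES = ("head_and_neck", "spine", "prostate")

DEFAULT_FAIL_TLD_PCT = 7.0
DEFAULT_POOR_TLD_PCT = 5.0
DEFAULT_FILM_PASS_MIN = 85.0
DEFAULT_MAX_OFFSET_MM = 3.0
DEFAULT_LOW_DOSE_THRESHOLD = 0.20


@dataclass(frozen=True)
class TLDMeasurement:
    """One TLD point: measured (delivered) vs TPS-calculated dose in Gy."""

    label: str
    measured_dose: float
    calculated_dose: float

    def __post_init__(self) -> None:
        for name in ("measured_dose", "calculated_dose"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"TLD {self.label!r}: {name} must be positive and finite")


def tld_error(m: TLDMeasurement) -> float:
    """Signed TLD dose error (%): positive = TPS overestimates delivery."""
    return 100.0 * (m.calculated_dose - m.measured_dose) / m.measured_dose


@dataclass(frozen=True)
class FilmComparison:
    """Measured vs calculated dose grids plus the gamma criterion to apply.

    Grids are 1-D profiles or 2-D planes of dose (Gy) on a common regular
    grid with ``spacing_mm`` between neighbours.  ``criteria`` is the
    (dose difference %, distance-to-agreement mm) gamma criterion, e.g.
    ``(5, 3)`` or ``(7, 4)``.
    """

    measured: np.ndarray
    calculated: np.ndarray
    spacing_mm: float
    criteria: tuple[float, float] = (7.0, 4.0)
    low_dose_threshold_fraction: float = DEFAULT_LOW_DOSE_THRESHOLD

    def __post_init__(self) -> None:
        measured = np.asarray(self.measured, dtype=float)
        calculated = np.asarray(self.calculated, dtype=float)
        if measured.shape != calculated.shape:
            raise ValueError("film grids must share one shape")
        if measured.ndim not in (1, 2):
            raise ValueError("film grids must be 1-D profiles or 2-D planes")
        if not (self.spacing_mm > 0 and math.isfinite(self.spacing_mm)):
            raise ValueError("grid spacing must be positive")
        dd, dta = self.criteria
        if dd <= 0 or dta <= 0:
            raise ValueError("gamma criteria must be positive")
        if not 0.0 <= self.low_dose_threshold_fraction < 1.0:
            raise ValueError("low-dose threshold fraction must lie in [0, 1)")
        object.__setattr__(self, "measured", measured)
        object.__setattr__(self, "calculated", calculated)


def gamma_pass_rate(film: FilmComparison) -> float:
    """Global gamma pass rate (%) of the measured grid against the calculated.

    For every measured point above the low-dose threshold (a fraction of
    the calculated grid's maximum), gamma is the minimum over calculated
    points within a 3x DTA search radius of
    ``sqrt((dose difference / dD)^2 + (distance / DTA)^2)``, with ``dD``
    the dose criterion as a percentage of the calculated grid's maximum
    (global normalization).  A point passes when gamma <= 1.  The search
    is discrete over grid nodes (no subpixel interpolation), which is
    adequate at millimetre grid spacings.
    """
    meas = np.atleast_2d(film.measured)
    calc = np.atleast_2d(film.calculated)
    dmax = float(calc.max())
    if dmax <= 0:
        raise ValueError("calculated grid maximum must be positive")
    dd_pct, dta = film.criteria
    dd_abs = dd_pct / 100.0 * dmax
    threshold = film.low_dose_threshold_fraction * dmax
    eval_mask = meas >= threshold
    if not eval_mask.any():
        raise ValueError("all measured points fall below the low-dose threshold")

    spacing = film.spacing_mm
    radius = 3.0 * dta
    k = int(np.ceil(radius / spacing))
    h, w = meas.shape
    gamma2 = np.full(meas.shape, np.inf)
    for di in range(-k, k + 1):
        for dj in range(-k, k + 1):
            dist2 = (di * spacing) ** 2 + (dj * spacing) ** 2
            if dist2 > radius**2:
                continue
            i0, i1 = max(0, -di), min(h, h - di)
            j0, j1 = max(0, -dj), min(w, w - dj)
            if i0 >= i1 or j0 >= j1:
                continue
            dose_term = (calc[i0 + di:i1 + di, j0 + dj:j1 + dj]
                         - meas[i0:i1, j0:j1]) / dd_abs
            cand = dose_term**2 + dist2 / dta**2
            np.minimum(gamma2[i0:i1, j0:j1], cand, out=gamma2[i0:i1, j0:j1])
    passing = gamma2[eval_mask] <= 1.0
    return float(100.0 * passing.mean())


@dataclass(frozen=True)
class AuditRecord:
    """One phantom irradiation: TLDs, optional film, localization offset."""

    institution_id: str
    phantom: str
    tlds: tuple[TLDMeasurement, ...]
    localization_offset_mm: float = 0.0
    film: FilmComparison | None = None
    film_pass_pct: float | None = None
    stratum: object | None = None  # EquipmentStratum when known

    def __post_init__(self) -> None:
        if self.phantom not in PHANTOM_TYPES:
            raise ValueError(f"unknown phantom {self.phantom!r}; expected one of {PHANTOM_TYPES}")
        tlds = tuple(self.tlds)
        if not tlds:
            raise ValueError(f"audit {self.institution_id!r}: at least one TLD is required")
        object.__setattr__(self, "tlds", tlds)
        off = self.localization_offset_mm
        if not (math.isfinite(off) and off >= 0):
            raise ValueError("localization offset must be finite and non-negative")
        if self.film_pass_pct is not None and not 0.0 <= self.film_pass_pct <= 100.0:
            raise ValueError("film_pass_pct must lie in [0, 100]")

    def tld_errors(self) -> np.ndarray:
        return np.array([tld_error(t) for t in self.tlds])


@dataclass(frozen=True)
class OutcomeLabel:
    """Derived audit outcome flags; ``failing`` implies ``poor``."""

    failing: bool
    poor: bool
    excluded_for_localization: bool
    mean_tld_error_pct: float

    def __post_init__(self) -> None:
        if self.failing and not self.poor:
            raise ValueError("a failing audit is by definition also poor")


def classify_outcome(
    record: AuditRecord,
    fail_tld_pct: float = DEFAULT_FAIL_TLD_PCT,
    poor_tld_pct: float = DEFAULT_POOR_TLD_PCT,
    film_pass_min: float = DEFAULT_FILM_PASS_MIN,
    max_offset_mm: float = DEFAULT_MAX_OFFSET_MM,
    use_film: bool = True,
) -> OutcomeLabel:
    """Label one irradiation as failing / poorly performed.

    Failing: any TLD error beyond ``fail_tld_pct`` in magnitude, or (when
    film data are present and ``use_film``) a film gamma pass rate below
    ``film_pass_min``.  Poor: any TLD error beyond ``poor_tld_pct``, or
    failing.  Film grids take precedence over a precomputed pass rate.
    """
    if fail_tld_pct < poor_tld_pct:
        raise ValueError("fail threshold must be at least the poor threshold")
    errors = record.tld_errors()
    film_pass: float | None = None
    if use_film:
        if record.film is not None:
            film_pass = gamma_pass_rate(record.film)
        elif record.film_pass_pct is not None:
            film_pass = float(record.film_pass_pct)
    failing = bool(np.any(np.abs(errors) > fail_tld_pct))
    if film_pass is not None and film_pass < film_pass_min:
        failing = True
    poor = failing or bool(np.any(np.abs(errors) > poor_tld_pct))
    return OutcomeLabel(
        failing=failing, poor=poor,
        excluded_for_localization=record.localization_offset_mm > max_offset_mm,
        mean_tld_error_pct=float(errors.mean()))


def exclude_localization(
    records: Sequence[AuditRecord],
    max_offset_mm: float = DEFAULT_MAX_OFFSET_MM,
) -> tuple[list[AuditRecord], list[AuditRecord]]:
    """Partition audits by localization offset (strictly above the cut is out)."""
    kept: list[AuditRecord] = []
    excluded: list[AuditRecord] = []
    for rec in records:
        if rec.localization_offset_mm > max_offset_mm:
            excluded.append(rec)
        else:
            kept.append(rec)
    return kept, excluded
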