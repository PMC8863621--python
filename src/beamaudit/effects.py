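"""Piecewise-linear dose-effect models anchored at community percentiles.

Varying a single TPS beam-model parameter shifts the calculated dose in a
phantom approximately linearly with the parameter value, independently of
the other parameters.  Each parameter therefore gets a lookup model built
from *anchors*: (community percentile, parameter value, dose effect %)
triples at the 2.5th, 10th, 50th, 90th and 97.5th percentiles, with the
community median as the zero-effect baseline.  The model interpolates
linearly **in parameter value** between adjacent anchors and clamps to the
terminal anchor effects outside the characterized range.

Sign convention: a positive effect means the TPS overestimates dose
(calculated exceeds delivered).  Per-parameter effects are treated as
independent, so an institution's aggregate predicted TPS error is the
plain sum of its per-parameter effects — e.g. +1.2% from one parameter
and +0.2% from another aggregate to +1.4%.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .survey import EquipmentStratum, SurveyDistribution

#: Percentiles every anchor table must cover.
REQUIRED_PERCENTILES = (2.5, 10.0, 50.0, 90.0, 97.5)

#: Parameters whose anchor effects exceed this magnitude (%) are "impactful".
DEFAULT_IMPACTFUL_CUT_PCT = 1.0


@dataclass(frozen=True)
class ParameterAnchorTable:
    """Anchor rows ``(percentile, value, effect_pct)`` for one parameter."""

    tps_name: str
    parameter_name: str
    units: str
    anchors: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        anchors = tuple((float(p), float(v), float(e)) for p, v, e in self.anchors)
        object.__setattr__(self, "anchors", anchors)
        pcts = [a[0] for a in anchors]
        if sorted(pcts) != pcts:
            raise ValueError(f"{self._label}: anchors must be sorted by percentile")
        missing = [p for p in REQUIRED_PERCENTILES if p not in pcts]
        if missing:
            raise ValueError(f"{self._label}: missing anchor percentiles {missing} "
                             "(the 50th-percentile value must be supplied in configuration)")
        values = [a[1] for a in anchors]
        if any(b < a for a, b in zip(values, values[1:])):
            raise ValueError(f"{self._label}: anchor values must be non-decreasing "
                             "with percentile")
        median_effect = dict((a[0], a[2]) for a in anchors)[50.0]
        if median_effect != 0.0:
            raise ValueError(f"{self._label}: effect at the 50th percentile must be 0")
        if not all(math.isfinite(x) for a in anchors for x in a):
            raise ValueError(f"{self._label}: non-finite anchor entry")

    @property
    def _label(self) -> str:
        return f"{self.tps_name}/{self.parameter_name}"

    @property
    def percentiles(self) -> np.ndarray:
        return np.array([a[0] for a in self.anchors])

    @property
    def values(self) -> np.ndarray:
        return np.array([a[1] for a in self.anchors])

    @property
    def effects(self) -> np.ndarray:
        return np.array([a[2] for a in self.anchors])

    def max_abs_effect(self) -> float:
        return float(np.max(np.abs(self.effects)))


@dataclass(frozen=True)
class EffectEstimate:
    """Signed dose effect (%) attributed to one parameter value."""

    parameter_name: str
    value: float
    effect_pct: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.value) and math.isfinite(self.effect_pct)):
            raise ValueError("EffectEstimate fields must be finite")


@dataclass(frozen=True)
class AggregateEstimate:
    """Institution-level predicted TPS error: the sum of component effects."""

    institution_id: str
    components: tuple[EffectEstimate, ...]
    total_pct: float


class EffectModel:
    """Callable mapping a parameter value to its dose effect (%).

    Piecewise-linear through the anchor (value, effect) pairs; queries
    outside the anchored value range return the terminal anchor effect
    (clamping — the dose response is characterized only over the reported
    community spread).  Degenerate anchors sharing one value collapse to a
    single point keeping the lower-percentile effect.
    """

    def __init__(self, table: ParameterAnchorTable) -> None:
        self.table = table
        values, effects = [], []
        for _, v, e in table.anchors:  # ordered by percentile, hence by value
            if values and v == values[-1]:
                continue  # keep the lower-percentile anchor at a shared value
            values.append(v)
            effects.append(e)
        self._values = np.asarray(values)
        self._effects = np.asarray(effects)

    @property
    def value_range(self) -> tuple[float, float]:
        return float(self._values[0]), float(self._values[-1])

    def effect_at_value(self, value):
        value = np.asarray(value, dtype=float)
        if not np.all(np.isfinite(value)):
            raise ValueError(f"{self.table._label}: non-finite query value")
        out = np.interp(value, self._values, self._effects)
        return float(out) if out.ndim == 0 else out

    __call__ = effect_at_value


def build_effect_model(anchor_table: ParameterAnchorTable) -> EffectModel:
    """Construct the piecewise-linear dose-effect model for one parameter."""
    return EffectModel(anchor_table)


def effect_at_value(model: EffectModel, value: float) -> float:
    """Dose effect (%) of ``model`` at a parameter value (clamped outside range)."""
    return model.effect_at_value(value)


def effect_at_percentile(model: EffectModel, dist: SurveyDistribution,
                         percentile: float) -> float:
    """Dose effect at a community percentile: quantile lookup then value model."""
    return model.effect_at_value(dist.quantile(percentile))


def aggregate_error(components: Iterable[EffectEstimate],
                    institution_id: str = "") -> AggregateEstimate:
    """Sum independent per-parameter effects into one predicted TPS error.

    Duplicate parameter names are an error (each parameter contributes at
    most one effect).  The empty aggregate is 0%.
    """
    comps = tuple(components)
    names = [c.parameter_name for c in comps]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate parameter effects for {dupes}")
    total = float(sum(c.effect_pct for c in comps))
    return AggregateEstimate(institution_id=institution_id, components=comps,
                             total_pct=total)


def impactful_parameters(
    anchor_tables: Iterable[ParameterAnchorTable],
    threshold_pct: float = DEFAULT_IMPACTFUL_CUT_PCT,
) -> set[str]:
    """Parameters whose anchored dose effects exceed ``threshold_pct`` in magnitude."""
    return {t.parameter_name for t in anchor_tables
            if t.max_abs_effect() > threshold_pct}


def default_stratum(tps_name: str,
                    linac_class: str = "Varian Base",
                    beam_energy: str = "6 MV",
                    mlc_model: str = "Millennium120") -> EquipmentStratum:
    """Equipment stratum the shipped anchor tables characterize."""
    return EquipmentStratum(tps_name=tps_name, linac_class=linac_class,
                            beam_energy=beam_energy, mlc_model=mlc_model)


def anchor_matched_distribution(
    table: ParameterAnchorTable,
    stratum: EquipmentStratum | None = None,
    n: int = 201,
) -> SurveyDistribution:
    """Synthetic community sample whose quantiles reproduce the anchors.

    Values are laid on the inverse CDF implied by the anchor
    (percentile, value) pairs — piecewise linear between anchors, flat
    beyond the 2.5th/97.5th — at the ``n`` equally spaced order-statistic
    positions.  With the default ``n=201`` every anchor percentile is a
    grid node, so quantile lookups at anchor percentiles return the anchor
    values exactly.
    """
    if n < 2:
        raise ValueError("need at least 2 grid points")
    if stratum is None:
        stratum = default_stratum(table.tps_name)
    grid = np.linspace(0.0, 100.0, n)
    values = np.interp(grid, table.percentiles, table.values)
    return SurveyDistribution(stratum=stratum, parameter_name=table.parameter_name,
                              values=values, units=table.units)


def _packaged_anchor_text() -> str:
    return resources.files("beamaudit").joinpath("data/anchors.json").read_text()


def load_anchor_tables(
    path: str | Path | None = None,
) -> dict[tuple[str, str], ParameterAnchorTable]:
    """Load anchor tables keyed by ``(tps_name, parameter_name)``.

    Without a ``path`` the package's shipped tables (6 MV Varian Base
    class, Millennium120 MLC) are used.  Entries listing several names
    (parameter pairs characterized jointly, e.g. X/Y source widths) expand
    to one table per name sharing the same anchors.
    """
    if path is None:
        raw = json.loads(_packaged_anchor_text())
    else:
        raw = json.loads(Path(path).read_text())
    tables: dict[tuple[str, str], ParameterAnchorTable] = {}
    for tps_name, entries in raw["tps"].items():
        for entry in entries:
            for name in entry["names"]:
                tables[(tps_name, name)] = ParameterAnchorTable(
                    tps_name=tps_name, parameter_name=name,
                    units=entry.get("units", ""),
                    anchors=tuple(tuple(a) for a in entry["anchors"]))
    return tables


def build_effect_models(
    tables: Mapping[tuple[str, str], ParameterAnchorTable],
) -> dict[tuple[str, str], EffectModel]:
    """One effect model per ``(tps_name, parameter_name)`` anchor table."""
    return {key: build_effect_model(t) for key, t in tables.items()}
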