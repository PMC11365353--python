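"""Interquartile-range outlier screening with a full audit trail.

A treatment mean is flagged when any screened variable falls outside
[Q1 - f*IQR, Q3 + f*IQR] with factor f = 1.5 by default.  Quartiles use the
linear-interpolation convention (numpy's default), fixed here because fence
membership depends on it.  Screening runs as a single pass over the raw
database: re-screening a screened set could flag new points as the fences
tighten, so the pipeline never iterates it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np

from .database import StudyDatabase

__all__ = ["ScreeningError", "Removal", "VariableScreen", "ScreeningReport", "iqr_fences", "apply_screen"]

MIN_VALUES_FOR_FENCES = 4


class ScreeningError(ValueError):
    pass


def iqr_fences(values, factor: float = 1.5) -> tuple[float, float]:
    """Lower and upper Tukey fences Q1 - f*IQR, Q3 + f*IQR.

    Requires at least 4 non-missing values; with fewer, the quartiles (and
    hence the fences) are too unstable to act on.  ``factor=0`` returns the
    quartiles themselves.
    """
    if factor < 0:
        raise ScreeningError(f"factor must be >= 0 (got {factor})")
    vals = np.asarray([v for v in values if v is not None], dtype=float)
    if vals.size < MIN_VALUES_FOR_FENCES:
        raise ScreeningError(
            f"need >= {MIN_VALUES_FOR_FENCES} non-missing values for stable fences (got {vals.size})"
        )
    q1, q3 = np.quantile(vals, [0.25, 0.75])  # linear interpolation
    iqr = q3 - q1
    return float(q1 - factor * iqr), float(q3 + factor * iqr)


@dataclass(frozen=True)
class Removal:
    record_id: str
    study_id: str
    variable: str     # the variable that triggered removal (first in screen order)
    value: float
    lower_fence: float
    upper_fence: float


@dataclass(frozen=True)
class VariableScreen:
    variable: str
    factor: float
    lower_fence: float
    upper_fence: float
    flagged_record_ids: tuple[str, ...]


@dataclass(frozen=True)
class ScreeningReport:
    screens: tuple[VariableScreen, ...]
    removals: tuple[Removal, ...]
    n_removed: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "screens": [vars(s) | {"flagged_record_ids": list(s.flagged_record_ids)} for s in self.screens],
                "removals": [vars(r) for r in self.removals],
                "n_removed": self.n_removed,
            },
            indent=2,
            sort_keys=True,
        )

    def log_lines(self) -> list[str]:
        lines = []
        for s in self.screens:
            lines.append(
                f"screen variable={s.variable} factor={s.factor:g} "
                f"fences=({s.lower_fence:.4g}, {s.upper_fence:.4g}) flagged={len(s.flagged_record_ids)}"
            )
        for r in self.removals:
            lines.append(
                f"removed record={r.record_id} study={r.study_id} {r.variable}={r.value:g} "
                f"outside ({r.lower_fence:.4g}, {r.upper_fence:.4g})"
            )
        return lines


def apply_screen(
    db: StudyDatabase,
    variables,
    factor: float = 1.5,
    *,
    skip_sparse: bool = False,
) -> tuple[StudyDatabase, ScreeningReport]:
    """Remove whole records outside the IQR fences on ANY listed variable.

    Fences are computed on the input database (one pass); records are removed
    as whole rows, never field-by-field, and output order is preserved.  Every
    removal is reported with the triggering variable and value.  Variables
    with fewer than 4 non-missing values raise, unless ``skip_sparse`` is set
    (the pipeline uses this for optional columns such as urine volume).
    """
    screens: list[VariableScreen] = []
    triggers: dict[str, Removal] = {}  # record_id -> first trigger
    for name in variables:
        vals = [r.get(name) for r in db.records]
        try:
            lo, hi = iqr_fences([v for v in vals if v is not None], factor)
        except ScreeningError:
            if skip_sparse:
                continue
            raise
        flagged: list[str] = []
        for r in db.records:
            v = r.get(name)
            if v is not None and (v < lo or v > hi):
                flagged.append(r.record_id)
                triggers.setdefault(r.record_id, Removal(r.record_id, r.study_id, name, float(v), lo, hi))
        screens.append(VariableScreen(name, factor, lo, hi, tuple(flagged)))
    kept = tuple(r for r in db.records if r.record_id not in triggers)
    removals = tuple(triggers[r.record_id] for r in db.records if r.record_id in triggers)
    if len({r.study_id for r in kept}) < 2:
        raise ScreeningError("screening would leave fewer than 2 studies")
    out = replace(db, records=kept)
    return out, ScreeningReport(tuple(screens), removals, len(removals))
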