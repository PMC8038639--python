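"""Stratified concentration summaries under an explicit left-censoring policy.

Mirrors the classic "mean ± SE per tissue/habitat/season/group" presentation
of trace-element surveys. Values below the detection limit have no measured
magnitude, so every summary states which substitution rule produced it:

``zero``
    censored values replaced by 0 (biases low; excluded from geometric means)
``half_lod``
    censored values replaced by LOD/2 (the default; standard in the
    trace-element literature)
``lod``
    censored values replaced by the LOD (biases high)
``detected_only``
    censored values dropped
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .elements import ConcentrationRecord, default_element_table
from .errors import DomainError, UndefinedInputError

POLICIES = ("zero", "half_lod", "lod", "detected_only")


@dataclass(frozen=True)
class GroupSummary:
    """Summary of one (tissue, habitat, season, group, element) stratum."""

    tissue: str
    habitat: str
    season: str
    group: str
    element: str
    n: int
    n_detected: int
    mean: Optional[float]  # arithmetic mean, µg/g dw; None when all censored
    se: Optional[float]  # standard error of the mean (sd/sqrt(n), sd with n-1)
    gmean: Optional[float]  # geometric mean over positive substituted values
    display: str  # "mean ± se", or "<lod" when the whole cell is censored

    @property
    def stratum(self) -> tuple:
        return (self.tissue, self.habitat, self.season, self.group, self.element)


def _substituted(values, censored, lod: float, policy: str):
    """Apply the censor-substitution rule; returns a float array."""
    if policy not in POLICIES:
        raise DomainError(f"unknown censoring policy {policy!r}; choose from {POLICIES}")
    out = []
    for v, c in zip(values, censored):
        if not c:
            out.append(v)
        elif policy == "zero":
            out.append(0.0)
        elif policy == "half_lod":
            out.append(lod / 2.0)
        elif policy == "lod":
            out.append(lod)
        # detected_only: drop
    return np.asarray(out, dtype=float)


def geometric_mean(
    values: Sequence[float],
    censored: Optional[Sequence[bool]] = None,
    lod: float = 0.0,
    policy: str = "detected_only",
) -> float:
    """exp(mean(ln v)) over substituted values; zero substitutions are excluded.

    With the ``zero`` policy, zero-substituted censored values cannot enter a
    log mean and are dropped; if nothing positive remains the geometric mean
    is undefined and a :class:`DomainError` suggests ``half_lod``.
    """
    values = np.asarray(values, dtype=float)
    if censored is None:
        censored = np.zeros(values.shape, dtype=bool)
    sub = _substituted(values, censored, lod, policy)
    positive = sub[sub > 0]
    if positive.size == 0:
        raise DomainError(
            "geometric mean undefined: no positive values after substitution "
            "(all censored under this policy — consider policy='half_lod')"
        )
    return float(np.exp(np.mean(np.log(positive))))


def _format_quantity(x: float) -> str:
    """Render a concentration the way survey tables do: 2 decimals, >=3 sig figs."""
    if x >= 100:
        return f"{x:,.0f}"
    return f"{x:.2f}"


def summarize(
    records: Iterable[ConcentrationRecord],
    policy: str = "half_lod",
    element_table: Optional[dict] = None,
) -> list:
    """One :class:`GroupSummary` per occupied stratum.

    Censored values are substituted per ``policy`` before the mean and SE are
    taken. A stratum in which every measurement is censored renders as
    ``"<lod"`` (e.g. ``"<0.07"`` for Pb) with no mean.
    """
    table = element_table if element_table is not None else default_element_table()
    if policy not in POLICIES:
        raise DomainError(f"unknown censoring policy {policy!r}; choose from {POLICIES}")
    groups: dict = {}
    for rec in records:
        groups.setdefault(rec.stratum, []).append(rec)

    summaries = []
    for stratum in sorted(groups):
        recs = groups[stratum]
        element = stratum[4]
        lod = table[element].lod
        values = [r.value if r.value is not None else math.nan for r in recs]
        censored = [r.censored for r in recs]
        n = len(recs)
        n_detected = sum(not c for c in censored)
        if n_detected == 0:
            summaries.append(
                GroupSummary(*stratum, n=n, n_detected=0, mean=None, se=None,
                             gmean=None, display=f"<{lod:g}")
            )
            continue
        sub = _substituted(values, censored, lod, policy)
        mean = float(np.mean(sub))
        se = float(np.std(sub, ddof=1) / math.sqrt(sub.size)) if sub.size > 1 else 0.0
        gmean = geometric_mean(values, censored, lod, policy)
        display = f"{_format_quantity(mean)} ± {_format_quantity(se)}"
        summaries.append(
            GroupSummary(*stratum, n=n, n_detected=n_detected,
                         mean=mean, se=se, gmean=gmean, display=display)
        )
    return summaries


def detectable_fraction(
    records: Iterable[ConcentrationRecord], element: str, tissue: str
) -> float:
    """Share of records for (element, tissue) with a value above the LOD."""
    relevant = [r for r in records if r.element == element and r.tissue == tissue]
    if not relevant:
        raise UndefinedInputError(f"no records for element={element}, tissue={tissue}")
    return sum(not r.censored for r in relevant) / len(relevant)


@dataclass(frozen=True)
class FoldRatio:
    """Liver-to-muscle concentration ratio for one element/stratum pairing."""

    element: str
    value: float
    is_lower_bound: bool = False  # True when muscle was all-censored (LOD substituted)


def fold_ratio(liver: GroupSummary, muscle: GroupSummary,
               element_table: Optional[dict] = None) -> FoldRatio:
    """liver mean / muscle mean for matched summaries of the same element.

    When the muscle cell is entirely censored its LOD stands in for the mean,
    making the ratio a flagged lower bound.
    """
    if liver.element != muscle.element:
        raise DomainError(
            f"element mismatch: liver {liver.element} vs muscle {muscle.element}"
        )
    if liver.mean is None:
        raise DomainError("liver summary has no mean (all censored)")
    table = element_table if element_table is not None else default_element_table()
    if muscle.mean is None:
        lod = table[muscle.element].lod
        return FoldRatio(liver.element, liver.mean / lod, is_lower_bound=True)
    if muscle.mean <= 0:
        raise DomainError("muscle mean must be positive")
    return FoldRatio(liver.element, liver.mean / muscle.mean)


def summaries_to_frame(summaries: Sequence[GroupSummary]) -> pd.DataFrame:
    """Long-format machine-readable table, one row per stratum."""
    return pd.DataFrame(
        [
            {
                "tissue": s.tissue,
                "habitat": s.habitat,
                "season": s.season,
                "group": s.group,
                "element": s.element,
                "n": s.n,
                "n_detected": s.n_detected,
                "mean_ug_g_dw": s.mean,
                "se_ug_g_dw": s.se,
                "gmean_ug_g_dw": s.gmean,
                "display": s.display,
            }
            for s in summaries
        ]
    )


def render_survey_table(summaries: Sequence[GroupSummary]) -> pd.DataFrame:
    """Wide display table: one row per (tissue, habitat, season, group), one column per element."""
    frame = summaries_to_frame(summaries)
    wide = frame.pivot_table(
        index=["tissue", "habitat", "season", "group"],
        columns="element",
        values="display",
        aggfunc="first",
    )
    return wide.reset_index()
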