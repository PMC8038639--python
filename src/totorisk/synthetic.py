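"""Synthetic concentration studies with the structure the analysis assumes.

The generator emulates a stratified fish-tissue survey: 3 habitats x 3
seasons x 5 sex/maturity groups, liver and muscle, five elements. Within a
stratum, concentrations are log-normal (positive, right-skewed), and the
measurement process left-censors any draw below the element's detection
limit. The default design transcribes the published survey's group means and
standard errors cell by cell, so a generated study is statistically
exchangeable with the study the downstream stages were built for.

Cells the survey printed only as "<LOD" carry no recoverable mean; they are
given a log-normal whose 90th percentile sits at the LOD (so roughly 10% of
draws are detectable, matching the reported detectable fraction for muscle
cadmium), except lead, which the survey never detected and which is placed
far below its LOD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .elements import ConcentrationRecord, default_element_table
from .errors import DomainError
from .mcs import fit_lognormal_moments

#: default generator seed recorded in configs for reproducible fixtures
DEFAULT_SEED = 20210408

# 90th-percentile standard normal quantile used to calibrate all-censored cells
_Z90 = float(stats.norm.ppf(0.90))
_CENSORED_GSD = 2.0


@dataclass(frozen=True)
class StratumSpec:
    """True distribution of one stratum: log-normal with geometric mean/SD.

    ``gsd = 1`` is the degenerate case where every draw equals ``gmean``.
    ``all_censored_cell`` marks strata standing in for "<LOD" survey cells,
    whose parameters are calibrated conventions rather than transcribed
    moments.
    """

    tissue: str
    habitat: str
    season: str
    group: str
    element: str
    n: int
    gmean: float  # µg/g dry weight
    gsd: float  # dimensionless, >= 1
    all_censored_cell: bool = False

    def __post_init__(self) -> None:
        if self.n < 1:
            raise DomainError(f"n must be >= 1, got {self.n}")
        if self.gmean <= 0:
            raise DomainError(f"gmean must be positive, got {self.gmean}")
        if self.gsd < 1:
            raise DomainError(f"gsd must be >= 1, got {self.gsd}")

    def stratum_key(self) -> tuple:
        return (self.tissue, self.habitat, self.season, self.group, self.element)

    @property
    def sigma(self) -> float:
        return math.log(self.gsd)

    @property
    def mean(self) -> float:
        """Natural-scale mean implied by (gmean, gsd)."""
        return self.gmean * math.exp(self.sigma**2 / 2)

    @property
    def sd(self) -> float:
        """Natural-scale standard deviation implied by (gmean, gsd)."""
        return self.mean * math.sqrt(math.expm1(self.sigma**2))

    @property
    def se(self) -> float:
        return self.sd / math.sqrt(self.n)

    @classmethod
    def from_moments(cls, tissue, habitat, season, group, element, n,
                     mean: float, sd: float) -> "StratumSpec":
        """Back-solve (gmean, gsd) from a natural-scale mean and sd."""
        spec = fit_lognormal_moments(mean, sd)
        return cls(tissue, habitat, season, group, element, n,
                   gmean=math.exp(spec.mu), gsd=math.exp(spec.sigma))

    @classmethod
    def censored_cell(cls, tissue, habitat, season, group, element, n,
                      lod: float, gsd: float = _CENSORED_GSD) -> "StratumSpec":
        """A cell calibrated so the 90th percentile of draws equals the LOD."""
        gmean = lod / gsd**_Z90
        return cls(tissue, habitat, season, group, element, n,
                   gmean=gmean, gsd=gsd, all_censored_cell=True)


def generate(
    design: Sequence[StratumSpec],
    element_table: Optional[dict] = None,
    seed: Optional[int] = DEFAULT_SEED,
) -> list:
    """Draw one synthetic study from a design.

    Per stratum, ``n`` log-normal concentrations are drawn with the stated
    geometric mean and GSD; a draw below the element's LOD is emitted as a
    censored record with no value. Deterministic under ``seed``.
    """
    table = element_table if element_table is not None else default_element_table()
    rng = np.random.default_rng(seed)
    records = []
    counter = 0
    for stratum in design:
        if stratum.element not in table:
            raise DomainError(f"element {stratum.element!r} not in element table")
        lod = table[stratum.element].lod
        if stratum.gsd == 1.0:
            draws = np.full(stratum.n, stratum.gmean)
        else:
            draws = rng.lognormal(math.log(stratum.gmean), stratum.sigma, stratum.n)
        for value in draws:
            counter += 1
            censored = value < lod
            records.append(
                ConcentrationRecord(
                    fish_id=f"SIM{counter:05d}",
                    tissue=stratum.tissue,
                    habitat=stratum.habitat,
                    season=stratum.season,
                    group=stratum.group,
                    element=stratum.element,
                    value=None if censored else float(value),
                    censored=bool(censored),
                    below_loq=bool(not censored and value < table[stratum.element].loq),
                )
            )
    return records


# Published survey cells: (habitat, season, group, n, {element: (mean, se) | None}).
# None marks an all-censored "<LOD" cell. SE is of the mean; sd = se * sqrt(n).
_LIVER_CELLS = [
    ("estuarine", "winter", "MF", 15,
     {"Cu": (44.04, 5.02), "Cd": (1.82, 0.30), "Zn": (116.13, 6.26), "Fe": (1284, 103)}),
    ("estuarine", "winter", "MM", 18,
     {"Cu": (35.84, 2.39), "Cd": (3.18, 1.13), "Zn": (107.98, 4.14), "Fe": (1187, 151)}),
    ("estuarine", "spring", "MF", 8,
     {"Cu": (36.02, 8.05), "Cd": (0.89, 0.38), "Zn": (80.68, 6.81), "Fe": (623, 137)}),
    ("estuarine", "spring", "MM", 3,
     {"Cu": (22.78, 5.83), "Cd": (0.89, 0.73), "Zn": (72.26, 6.58), "Fe": (628, 46)}),
    ("rocky", "spring", "MF", 7,
     {"Cu": (24.23, 2.20), "Cd": (1.64, 0.89), "Zn": (69.41, 1.52), "Fe": (556, 93)}),
    ("rocky", "spring", "MM", 8,
     {"Cu": (20.07, 4.43), "Cd": (1.24, 0.37), "Zn": (79.86, 6.29), "Fe": (813, 173)}),
    ("rocky", "spring", "IF", 11,
     {"Cu": (21.80, 3.34), "Cd": (0.47, 0.36), "Zn": (86.66, 5.95), "Fe": (560, 59)}),
    ("rocky", "spring", "IM", 6,
     {"Cu": (23.40, 6.21), "Cd": (1.06, 0.70), "Zn": (76.55, 11.15), "Fe": (787, 283)}),
    ("rocky", "autumn", "IF", 12,
     {"Cu": (28.87, 4.02), "Cd": (5.53, 0.96), "Zn": (93.89, 11.70), "Fe": (1521, 189)}),
    ("rocky", "autumn", "IM", 11,
     {"Cu": (31.34, 4.32), "Cd": (6.7, 1.01), "Zn": (97.82, 10.29), "Fe": (1961, 336)}),
    ("rocky", "autumn", "UN", 21,
     {"Cu": (25.89, 2.96), "Cd": (5.33, 0.61), "Zn": (96.00, 5.34), "Fe": (1792, 181)}),
    ("continental", "autumn", "IF", 9,
     {"Cu": (16.30, 2.93), "Cd": (1.32, 0.22), "Zn": (89.58, 8.37), "Fe": (400, 63)}),
    ("continental", "autumn", "IM", 7,
     {"Cu": (11.80, 2.64), "Cd": (1.06, 0.09), "Zn": (75.74, 4.26), "Fe": (359, 49)}),
    ("continental", "autumn", "UN", 6,
     {"Cu": (20.90, 4.58), "Cd": (2.38, 0.50), "Zn": (113.62, 12.84), "Fe": (470, 92)}),
]

_MUSCLE_CELLS = [
    ("estuarine", "winter", "MF", 14,
     {"Cu": (1.80, 0.41), "Cd": None, "Zn": (17.74, 1.00), "Fe": (22.99, 2.84)}),
    ("estuarine", "winter", "MM", 18,
     {"Cu": (1.54, 0.32), "Cd": None, "Zn": (17.78, 0.72), "Fe": (20.43, 4.00)}),
    ("estuarine", "spring", "MF", 8,
     {"Cu": (0.86, 0.43), "Cd": None, "Zn": (15.15, 0.61), "Fe": (21.67, 1.95)}),
    ("estuarine", "spring", "MM", 3,
     {"Cu": (1.01, 0.54), "Cd": None, "Zn": (15.73, 1.78), "Fe": (22.49, 3.63)}),
    ("rocky", "spring", "MF", 7,
     {"Cu": (2.00, 0.80), "Cd": (0.03, 0.02), "Zn": (13.86, 3.20), "Fe": (21.90, 5.88)}),
    ("rocky", "spring", "MM", 8,
     {"Cu": (0.39, 0.19), "Cd": None, "Zn": (11.79, 1.16), "Fe": (12.74, 1.55)}),
    ("rocky", "spring", "IF", 12,
     {"Cu": None, "Cd": None, "Zn": (12.42, 0.42), "Fe": (11.73, 2.13)}),
    ("rocky", "spring", "IM", 6,
     {"Cu": (0.32, 0.21), "Cd": None, "Zn": (13.84, 0.49), "Fe": (21.90, 4.47)}),
    ("rocky", "autumn", "IF", 12,
     {"Cu": (0.48, 0.19), "Cd": None, "Zn": (12.23, 1.44), "Fe": (7.96, 2.73)}),
    ("rocky", "autumn", "IM", 11,
     {"Cu": (1.68, 1.06), "Cd": None, "Zn": (11.91, 1.04), "Fe": (15.03, 4.79)}),
    ("rocky", "autumn", "UN", 21,
     {"Cu": (0.04, 0.02), "Cd": None, "Zn": (11.74, 0.59), "Fe": (10.84, 2.54)}),
    ("continental", "autumn", "IF", 9,
     {"Cu": (1.37, 0.62), "Cd": None, "Zn": (11.35, 0.65), "Fe": (18.18, 1.58)}),
    ("continental", "autumn", "IM", 8,
     {"Cu": (0.48, 0.35), "Cd": None, "Zn": (10.95, 0.50), "Fe": (33.17, 6.50)}),
    ("continental", "autumn", "UN", 7,
     {"Cu": (0.69, 0.46), "Cd": (0.15, 0.14), "Zn": (13.07, 0.66), "Fe": (31.19, 5.36)}),
]

# Lead was never detected in any tissue; place its true level far below LOD.
_PB_GMEAN = 0.001
_PB_GSD = 2.0


def default_survey_design(element_table: Optional[dict] = None) -> list:
    """The default design: every published survey cell, moments back-solved.

    Strata with a printed "mean ± se" get a log-normal matched to that mean
    and sd = se * sqrt(n); "<LOD" cells get the calibrated censored-cell
    convention (lead far below LOD).
    """
    table = element_table if element_table is not None else default_element_table()
    design = []
    for tissue, cells in (("liver", _LIVER_CELLS), ("muscle", _MUSCLE_CELLS)):
        for habitat, season, group, n, by_element in cells:
            for element in ("Cu", "Cd", "Zn", "Fe"):
                cell = by_element[element]
                if cell is None:
                    design.append(
                        StratumSpec.censored_cell(
                            tissue, habitat, season, group, element, n,
                            lod=table[element].lod,
                        )
                    )
                else:
                    mean, se = cell
                    design.append(
                        StratumSpec.from_moments(
                            tissue, habitat, season, group, element, n,
                            mean=float(mean), sd=float(se) * math.sqrt(n),
                        )
                    )
            design.append(
                StratumSpec(tissue, habitat, season, group, "Pb", n,
                            gmean=_PB_GMEAN, gsd=_PB_GSD, all_censored_cell=True)
            )
    return design


def design_to_rows(design: Sequence[StratumSpec]) -> list:
    """Design as plain dict rows for the CSV interface."""
    return [
        {
            "tissue": s.tissue,
            "habitat": s.habitat,
            "season": s.season,
            "group": s.group,
            "element": s.element,
            "n": s.n,
            "mean_ug_g": s.mean,
            "se_ug_g": s.se,
        }
        for s in design
    ]


def design_from_rows(rows) -> list:
    """Inverse of :func:`design_to_rows` (moments re-back-solved)."""
    return [
        StratumSpec.from_moments(
            r["tissue"], r["habitat"], r["season"], r["group"], r["element"],
            int(r["n"]), float(r["mean_ug_g"]),
            float(r["se_ug_g"]) * math.sqrt(int(r["n"])),
        )
        for r in rows
    ]
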