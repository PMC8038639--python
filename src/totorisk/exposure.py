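"""Deterministic exposure and risk arithmetic.

The estimated daily intake of an element from fish-muscle consumption is

    EDI = Cm * CR / BW        (mg per kg body weight per day)

with Cm the muscle concentration on a fresh-weight basis (mg/kg), CR the
daily consumption rate (kg/day) and BW body weight (kg). The hazard index
HI = EDI / RfD compares intake to the EPA reference dose; HI < 1 is read as
negligible non-carcinogenic risk. For essential elements the same intake is
also expressed as a percentage of the recommended daily intake (RDI).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .elements import ConcentrationRecord, ElementSpec, default_element_table
from .errors import DomainError, UnsupportedElementError
from .summaries import geometric_mean

RISK_ELEMENTS = ("Cu", "Cd", "Zn", "Fe")  # elements with an established RfD


@dataclass(frozen=True)
class ExposureModel:
    """Consumption-rate and body-weight settings for both risk pathways.

    The deterministic pathway uses the coastal fishermen point consumption
    rate (0.130 kg/day) and the adult point body weight (74 kg). The Monte
    Carlo pathway draws from log-normals matched to CR 0.100 ± 0.030 kg/day
    and BW 74 ± 10 kg. ``dw_to_fw`` converts dry-weight concentrations to
    the fresh-weight basis the intake formula expects; the default of 1.0
    (no conversion) is the conservative, risk-overstating choice.
    """

    cr_det: float = 0.130  # kg/day, deterministic point value
    cr_mean: float = 0.100  # kg/day, Monte Carlo log-normal mean
    cr_sd: float = 0.030  # kg/day, Monte Carlo log-normal sd
    bw_det: float = 74.0  # kg, deterministic point value
    bw_mean: float = 74.0  # kg, Monte Carlo log-normal mean
    bw_sd: float = 10.0  # kg, Monte Carlo log-normal sd
    dw_to_fw: float = 1.0  # dry-to-fresh concentration factor, in (0, 1]

    def __post_init__(self) -> None:
        for name in ("cr_det", "cr_mean", "bw_det", "bw_mean", "dw_to_fw"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("cr_sd", "bw_sd"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be non-negative, got {getattr(self, name)}")
        if self.cr_sd >= self.cr_mean:
            raise DomainError("cr_sd must be smaller than cr_mean")
        if self.bw_sd >= self.bw_mean:
            raise DomainError("bw_sd must be smaller than bw_mean")
        if self.dw_to_fw > 1:
            raise DomainError("dw_to_fw must be in (0, 1]")


@dataclass(frozen=True)
class RiskRow:
    """Deterministic risk figures for one element."""

    element: str
    cm_gmean_dw: float  # geometric-mean concentration, µg/g dry weight
    cm_fw: float  # concentration used in the intake formula, mg/kg fresh weight
    edi: float  # mg per kg body weight per day
    rdi_pct: Optional[float]  # percent of the recommended daily intake
    hi: Optional[float]  # hazard index, dimensionless


def edi(cm_fw: float, cr: float, bw: float) -> float:
    """Estimated daily intake Cm*CR/BW, mg per kg body weight per day."""
    if cm_fw <= 0 or cr <= 0 or bw <= 0:
        raise DomainError(
            f"edi requires positive inputs, got cm_fw={cm_fw}, cr={cr}, bw={bw}"
        )
    return cm_fw * cr / bw


def rdi_contribution(cm_fw: float, cr: float, element: ElementSpec) -> float:
    """Daily intake as a percentage of the element's recommended daily intake.

    ``cm_fw`` in mg/kg fresh weight and ``cr`` in kg/day give an intake of
    ``cm_fw * cr`` mg/day, compared against the RDI in mg/day.
    """
    if element.rdi is None:
        raise UnsupportedElementError(
            f"no recommended daily intake is defined for {element.symbol}"
        )
    if cm_fw <= 0 or cr <= 0:
        raise DomainError("rdi_contribution requires positive cm_fw and cr")
    intake_mg_day = cm_fw * cr
    return 100.0 * intake_mg_day / element.rdi


def hazard_index(edi_value: float, element: ElementSpec) -> float:
    """HI = EDI / RfD; raises for elements with no established reference dose."""
    if element.rfd is None:
        raise UnsupportedElementError(
            f"no EPA reference dose (RfD) is established for {element.symbol}"
        )
    if edi_value < 0:
        raise DomainError(f"edi must be non-negative, got {edi_value}")
    return edi_value / element.rfd


def deterministic_risk_table(
    records: Iterable[ConcentrationRecord],
    exposure: ExposureModel,
    policy: str = "half_lod",
    elements: Sequence[str] = RISK_ELEMENTS,
    element_table: Optional[dict] = None,
) -> list:
    """Per-element deterministic risk rows from muscle concentration records.

    The central concentration estimate is the geometric mean of the muscle
    values (censoring policy applied), converted to fresh weight by
    ``dw_to_fw``; intake uses the deterministic point CR and BW.
    """
    table = element_table if element_table is not None else default_element_table()
    muscle = [r for r in records if r.tissue == "muscle"]
    rows = []
    for symbol in elements:
        spec = table[symbol]
        relevant = [r for r in muscle if r.element == symbol]
        if not relevant:
            raise DomainError(f"no muscle records for element {symbol}")
        values = [r.value if r.value is not None else 0.0 for r in relevant]
        censored = [r.censored for r in relevant]
        gmean_dw = geometric_mean(values, censored, spec.lod, policy)
        cm_fw = gmean_dw * exposure.dw_to_fw  # µg/g == mg/kg
        edi_value = edi(cm_fw, exposure.cr_det, exposure.bw_det)
        rdi_pct = (
            rdi_contribution(cm_fw, exposure.cr_det, spec)
            if spec.rdi is not None
            else None
        )
        hi = hazard_index(edi_value, spec) if spec.rfd is not None else None
        rows.append(RiskRow(symbol, gmean_dw, cm_fw, edi_value, rdi_pct, hi))
    return rows


def risk_table_to_frame(rows: Sequence[RiskRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "element": r.element,
                "cm_gmean_dw": r.cm_gmean_dw,
                "cm_fw": r.cm_fw,
                "edi_mg_kg_day": r.edi,
                "rdi_pct": r.rdi_pct,
                "hi_deterministic": r.hi,
            }
            for r in rows
        ]
    )
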