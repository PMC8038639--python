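"""Rank-correlation sensitivity analysis of the Monte Carlo hazard index.

Each sampled input (consumption rate, body weight, concentration) is
Spearman-correlated against the HI draws; an input's "contribution to
variance" is its squared rank correlation normalised over all inputs —
the variance-attribution heuristic of spreadsheet risk tools. Signs are
reported alongside the (always non-negative) shares, and inputs held fixed
get a correlation of 0 by convention and drop out of the normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, UndefinedInputError
from .mcs import MCSResult


@dataclass(frozen=True)
class SensitivityEntry:
    input_name: str
    rank_correlation: float  # Spearman rho in [-1, 1]
    contribution_pct: float  # normalised rho^2, percent in [0, 100]


@dataclass(frozen=True)
class SensitivityReport:
    element: str
    entries: Tuple[SensitivityEntry, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "element": self.element,
                    "input": e.input_name,
                    "contribution_to_variance_pct": e.contribution_pct,
                    "rank_correlation": e.rank_correlation,
                }
                for e in self.entries
            ]
        )


def rank_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman correlation (Pearson on average ranks); 0 for a constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DomainError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise DomainError(f"need at least 3 paired draws, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    return float(stats.spearmanr(x, y).statistic)


def contribution_to_variance(correlations: Sequence[Tuple[str, float]]) -> list:
    """Normalised squared correlations as percentages.

    pct_i = 100 * rho_i^2 / sum_j rho_j^2. Inputs with rho = 0 contribute
    0% and are effectively outside the normalisation. All-zero input sets
    leave no variance to attribute and raise.
    """
    total = sum(rho**2 for _, rho in correlations)
    if total == 0:
        raise UndefinedInputError(
            "all rank correlations are zero; no variance attributable"
        )
    return [(name, 100.0 * rho**2 / total) for name, rho in correlations]


def analyze(result: MCSResult) -> SensitivityReport:
    """Sensitivity report for one element's Monte Carlo run."""
    inputs = [
        ("consumption_rate", result.cr_draws),
        ("body_weight", result.bw_draws),
        ("concentration", result.c_draws),
    ]
    rhos = [(name, rank_correlation(draws, result.hi_samples)) for name, draws in inputs]
    shares = dict(contribution_to_variance(rhos))
    entries = tuple(
        SensitivityEntry(name, rho, shares[name]) for name, rho in rhos
    )
    return SensitivityReport(element=result.element, entries=entries)


def reports_to_frame(reports: Sequence[SensitivityReport]) -> pd.DataFrame:
    """Concatenated sensitivity table mirroring the survey's layout."""
    return pd.concat([r.to_frame() for r in reports], ignore_index=True)
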