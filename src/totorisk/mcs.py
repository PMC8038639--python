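"""Monte Carlo propagation of log-normal exposure parameters through the
hazard-index model.

Consumption rate and body weight (and optionally the tissue concentration)
are drawn independently from log-normal distributions matched to stated
natural-scale means and standard deviations — the spreadsheet-tool
convention, under which "74 ± 10 kg" parameterises the distribution's own
mean and sd rather than its log-scale location and scale. Each iteration
evaluates HI_i = C_i * dw_to_fw * CR_i / (BW_i * RfD), and the draw vectors
are retained so the sensitivity stage can rank-correlate inputs against the
output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .elements import ElementSpec
from .errors import DomainError, UndefinedInputError, UnsupportedElementError
from .exposure import ExposureModel


@dataclass(frozen=True)
class LognormalSpec:
    """A log-normal distribution carrying both natural- and log-scale parameters.

    ``mean``/``sd`` are the natural-scale moments; ``mu``/``sigma`` the
    log-scale location and scale. ``sd = 0`` gives the degenerate point mass
    at ``mean``.
    """

    mean: float
    sd: float
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.mean < 0 or self.sd < 0:
            raise DomainError("mean and sd must be non-negative")
        if (self.sigma == 0) != (self.sd == 0):
            raise DomainError("sigma must be zero exactly when sd is zero")
        if self.mean > 0:
            implied = math.exp(self.mu + self.sigma**2 / 2)
            if abs(implied - self.mean) > 1e-9 * self.mean:
                raise DomainError(
                    f"inconsistent spec: exp(mu + sigma^2/2) = {implied} != mean {self.mean}"
                )

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.sd == 0:
            return np.full(n, self.mean)
        return rng.lognormal(self.mu, self.sigma, size=n)


def fit_lognormal_moments(mean: float, sd: float) -> LognormalSpec:
    """Log-normal matched to a natural-scale mean and sd.

    Solves the moment equations sigma^2 = ln(1 + (sd/mean)^2) and
    mu = ln(mean) - sigma^2/2, so the resulting distribution reproduces the
    given mean and sd exactly.
    """
    if mean <= 0:
        raise DomainError(f"mean must be positive, got {mean}")
    if sd < 0:
        raise DomainError(f"sd must be non-negative, got {sd}")
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2
    return LognormalSpec(mean=mean, sd=sd, mu=mu, sigma=math.sqrt(sigma2))


@dataclass(frozen=True)
class MCSResult:
    """Hazard-index draws plus the matched input draws that produced them."""

    element: str
    n_iter: int
    seed: Optional[int]
    hi_samples: np.ndarray
    cr_draws: np.ndarray
    bw_draws: np.ndarray
    c_draws: np.ndarray  # constant vector when concentration was fixed

    @property
    def mean(self) -> float:
        return float(np.mean(self.hi_samples))

    @property
    def p5(self) -> float:
        return float(np.quantile(self.hi_samples, 0.05))

    @property
    def p95(self) -> float:
        return float(np.quantile(self.hi_samples, 0.95))

    def summary(self) -> dict:
        return {
            "element": self.element,
            "n_iter": self.n_iter,
            "seed": self.seed,
            "mean": self.mean,
            "p5": self.p5,
            "p95": self.p95,
            "exceedance_prob": float(np.mean(self.hi_samples >= 1.0)),
        }

    def to_json(self) -> str:
        return json.dumps(self.summary(), indent=2, sort_keys=True)


def run_mcs(
    c_dist: Union[float, LognormalSpec],
    exposure: ExposureModel,
    element: ElementSpec,
    n_iter: int = 10_000,
    seed: Optional[int] = None,
) -> MCSResult:
    """Simulate the hazard index for one element.

    ``c_dist`` is either a fixed concentration (µg/g dry weight) or a
    :class:`LognormalSpec` for a distributed concentration. CR and BW are
    drawn from log-normals matched to the exposure model's Monte Carlo
    moments. Identical (seed, n_iter, specs) reproduce the draws bit for bit.
    """
    if element.rfd is None:
        raise UnsupportedElementError(
            f"no EPA reference dose (RfD) is established for {element.symbol}"
        )
    if n_iter < 1:
        raise DomainError(f"n_iter must be >= 1, got {n_iter}")
    rng = np.random.default_rng(seed)
    cr = fit_lognormal_moments(exposure.cr_mean, exposure.cr_sd).draw(rng, n_iter)
    bw = fit_lognormal_moments(exposure.bw_mean, exposure.bw_sd).draw(rng, n_iter)
    if isinstance(c_dist, LognormalSpec):
        c = c_dist.draw(rng, n_iter)
    else:
        if c_dist <= 0:
            raise DomainError(f"fixed concentration must be positive, got {c_dist}")
        c = np.full(n_iter, float(c_dist))
    hi = c * exposure.dw_to_fw * cr / (bw * element.rfd)
    return MCSResult(
        element=element.symbol,
        n_iter=n_iter,
        seed=seed,
        hi_samples=hi,
        cr_draws=cr,
        bw_draws=bw,
        c_draws=c,
    )


def cumulative_curve(result: MCSResult, n_points: int = 200) -> np.ndarray:
    """Empirical CDF of the HI draws on an increasing grid.

    Returns an (n_points, 2) array of (hi_value, cumulative_probability);
    the last grid point covers the sample maximum, so its probability is 1.
    """
    if n_points < 2:
        raise DomainError(f"n_points must be >= 2, got {n_points}")
    samples = np.sort(result.hi_samples)
    if samples.size == 0:
        raise UndefinedInputError("no samples to build a curve from")
    grid = np.linspace(samples[0], samples[-1], n_points)
    probs = np.searchsorted(samples, grid, side="right") / samples.size
    return np.column_stack([grid, probs])


@dataclass(frozen=True)
class ExceedanceCheck:
    """Whether the upper percentile stays under the hazard threshold."""

    below_threshold: bool  # p95 < threshold
    exceedance_prob: float  # fraction of draws at or above threshold


def exceedance_check(result: MCSResult, threshold: float = 1.0) -> ExceedanceCheck:
    """p95-below-threshold flag plus the exceedance probability P(HI >= threshold)."""
    return ExceedanceCheck(
        below_threshold=bool(result.p95 < threshold),
        exceedance_prob=float(np.mean(result.hi_samples >= threshold)),
    )
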