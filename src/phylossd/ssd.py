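"""Lognormal species sensitivity distributions and hazard concentrations.

Fits the lognormal SSD on natural-log endpoints, evaluates hazard
concentrations HCp = exp(xbar + z_p * s), and applies the Aldenberg-Jaworska
small-sample bias correction through one-sided tolerance-limit extrapolation
factors: the gamma-confidence factor for the p-th percentile at sample size
n is

    k = q_gamma[ t'_{n-1}( z_{1-p} * sqrt(n) ) ] / sqrt(n)

with t' the noncentral t distribution. At gamma = 0.5 this is the median
estimator; k exceeds z_{1-p} for every finite n and decreases toward it as
n grows, so the bias-corrected HC5 always sits below the plug-in HC5.
Fractional sample sizes (effective sample sizes) are supported directly by
the continuous noncentral t.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .correction import corrected_variance
from .data_io import ToxicityTable, ValidationError

__all__ = [
    "SSDFit",
    "HCEstimate",
    "fit_ssd",
    "hc",
    "extrapolation_factor",
    "bias_corrected_hc5",
    "ssd_curve",
    "ecdf_points",
]


@dataclass
class SSDFit:
    """Lognormal SSD parameters, uncorrected and autocorrelation-corrected.

    ``mean_log`` and ``sd_log`` are the natural-log sample mean and n-1
    sample SD; ``sd_corrected`` is sqrt(s_a^2) when an effective sample size
    was supplied, else equal to ``sd_log``. Both fits share ``mean_log``:
    the correction touches only the scale.
    """

    n: int
    n_eff: float | None
    mean_log: float
    sd_log: float
    sd_corrected: float
    units: str = ""


@dataclass
class HCEstimate:
    """Hazard concentration at percentile p with confidence gamma."""

    p: float
    gamma: float
    value: float
    bias_corrected: bool
    corrected: bool
    k_used: float


def _endpoints(table) -> np.ndarray:
    if isinstance(table, ToxicityTable):
        return table.endpoints
    return np.asarray(table, dtype=float)


def fit_ssd(table, n_eff: float | None = None, units: str | None = None) -> SSDFit:
    """Fit the lognormal SSD to positive endpoints.

    ``table`` is a :class:`ToxicityTable` or an array of positive endpoint
    values (one per species). When ``n_eff`` is given, the corrected scale
    is computed from it; otherwise corrected and uncorrected scales coincide.
    """
    x = _endpoints(table)
    if units is None:
        units = table.units if isinstance(table, ToxicityTable) else ""
    n = x.size
    if n < 3:
        raise ValidationError(f"SSD fit needs >= 3 species, got {n}")
    if np.any(x <= 0):
        raise ValidationError("endpoints must be positive")
    logs = np.log(x)
    mean_log = float(logs.mean())
    ss = float(((logs - mean_log) ** 2).sum())
    if ss == 0:
        raise ValidationError("zero variance in log endpoints")
    sd_log = float(np.sqrt(ss / (n - 1)))
    if n_eff is None:
        sd_corrected = sd_log
    else:
        sd_corrected = float(np.sqrt(corrected_variance(logs, n_eff)))
    return SSDFit(n=n, n_eff=n_eff, mean_log=mean_log, sd_log=sd_log,
                  sd_corrected=sd_corrected, units=units)


def hc(fit: SSDFit, p: float = 0.05, corrected: bool = False) -> HCEstimate:
    """Plug-in hazard concentration HCp = exp(mean_log + z_p * s).

    ``corrected`` selects the autocorrelation-corrected scale. At p = 0.5
    the z-score vanishes, so HC50 is identical for both scales.
    """
    if not 0 < p < 1:
        raise ValidationError(f"percentile must be in (0, 1), got {p}")
    s = fit.sd_corrected if corrected else fit.sd_log
    z = stats.norm.ppf(p)
    value = float(np.exp(fit.mean_log + z * s))
    return HCEstimate(p=p, gamma=0.5, value=value, bias_corrected=False,
                      corrected=corrected, k_used=-z)


def extrapolation_factor(n: float, p: float = 0.05, gamma: float = 0.5) -> float:
    """Aldenberg-Jaworska extrapolation factor k for HCp at sample size n.

    The gamma-quantile of the noncentral t with n-1 degrees of freedom and
    noncentrality z_{1-p} * sqrt(n), divided by sqrt(n). Fractional n
    (effective sample sizes) is handled by the continuous distribution.
    """
    if n <= 1:
        raise ValidationError(f"sample size must exceed 1, got {n}")
    if not 0 < p < 1:
        raise ValidationError(f"percentile must be in (0, 1), got {p}")
    if not 0 < gamma < 1:
        raise ValidationError(f"confidence must be in (0, 1), got {gamma}")
    ncp = stats.norm.ppf(1 - p) * np.sqrt(n)
    return float(stats.nct.ppf(gamma, df=n - 1, nc=ncp) / np.sqrt(n))


def bias_corrected_hc5(fit: SSDFit, p: float = 0.05, gamma: float = 0.5) -> HCEstimate:
    """Small-sample bias-corrected HCp from the corrected fit.

    Uses the extrapolation factor at the (possibly fractional) effective
    sample size together with the corrected scale:
    HCp = exp(mean_log - k * s_a).
    """
    n_for_k = fit.n_eff if fit.n_eff is not None else fit.n
    k = extrapolation_factor(n_for_k, p=p, gamma=gamma)
    value = float(np.exp(fit.mean_log - k * fit.sd_corrected))
    return HCEstimate(p=p, gamma=gamma, value=value, bias_corrected=True,
                      corrected=fit.n_eff is not None, k_used=k)


def ssd_curve(fit: SSDFit, grid: np.ndarray | None = None, n_points: int = 200) -> pd.DataFrame:
    """Cumulative lognormal SSD evaluated on a concentration grid.

    Returns affected fractions for both the uncorrected and the corrected
    scale. The default grid spans +-4 SD around the log mean.
    """
    if grid is None:
        span = 4 * max(fit.sd_log, fit.sd_corrected)
        grid = np.exp(np.linspace(fit.mean_log - span, fit.mean_log + span, n_points))
    grid = np.asarray(grid, dtype=float)
    logs = np.log(grid)
    return pd.DataFrame(
        {
            "concentration": grid,
            "fraction_affected": stats.norm.cdf(logs, fit.mean_log, fit.sd_log),
            "fraction_affected_corrected": stats.norm.cdf(
                logs, fit.mean_log, fit.sd_corrected
            ),
        }
    )


def ecdf_points(table) -> pd.DataFrame:
    """Hazen plotting positions (i - 0.5)/n against sorted endpoints.

    Display only — the SSD is fitted by moments on the log scale, never by
    regression on plotting positions.
    """
    x = np.sort(_endpoints(table))
    n = x.size
    if n == 0:
        raise ValidationError("empty endpoint table")
    pos = (np.arange(1, n + 1) - 0.5) / n
    return pd.DataFrame({"endpoint": x, "hazen_position": pos})
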