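"""Autocorrelation corrections for the SSD sample.

Converts a first-order autocorrelation estimate (Moran's I) into an
effective sample size — the equivalent number of independent species
endpoints — and adjusts the SSD log-scale variance accordingly.

With rho the first-order autocorrelation parameter, the Cressie effective
sample size is

    n_eff = n / [ 1 + 2 (rho/(1-rho)) (1 - 1/n)
                    - 2 (rho/(1-rho))^2 (1 - rho^(n-1)) / n ] .

rho = 0 gives n_eff = n exactly; positive autocorrelation shrinks the
effective sample, negative autocorrelation inflates it. The corrected
variance of the natural-log endpoints x_i is then

    s_a^2 = n_eff / (n (n_eff - 1)) * sum_i (x_i - xbar)^2 ,

which reduces to the ordinary n-1 sample variance at n_eff = n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_io import ValidationError

__all__ = [
    "EffectiveSampleSize",
    "effective_sample_size",
    "round_half_up",
    "corrected_variance",
]


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero upward."""
    return int(math.floor(x + 0.5))


@dataclass
class EffectiveSampleSize:
    """Effective sample size with its inputs.

    ``n_eff`` is carried as a continuous value into the variance correction
    and the extrapolation factor; ``n_eff_display`` is the half-up integer
    rounding for reporting.
    """

    n: int
    rho: float
    n_eff: float

    @property
    def n_eff_display(self) -> int:
        return round_half_up(self.n_eff)


def effective_sample_size(n: int, rho: float) -> float:
    """Cressie effective sample size under first-order autocorrelation.

    ``rho`` is typically the Moran's I point estimate, used as-is (no
    truncation at zero: negative autocorrelation legitimately yields
    n_eff > n).
    """
    if n < 2:
        raise ValidationError("effective sample size needs n >= 2")
    if not -1.0 < rho < 1.0:
        raise ValidationError(f"rho must be in (-1, 1), got {rho}")
    g = rho / (1.0 - rho)
    denom = 1.0 + 2.0 * g * (1.0 - 1.0 / n) - 2.0 * g * g * (1.0 - rho ** (n - 1)) / n
    if denom <= 0:
        raise ValidationError(
            f"effective-sample-size denominator nonpositive at (n={n}, rho={rho})"
        )
    return n / denom


def corrected_variance(logs: Sequence[float], n_eff: float) -> float:
    """Autocorrelation-corrected variance of the log endpoints (s_a^2)."""
    x = np.asarray(logs, dtype=float)
    n = x.size
    if n < 2:
        raise ValidationError("corrected variance needs n >= 2")
    if n_eff <= 1:
        raise ValidationError(f"n_eff must exceed 1, got {n_eff}")
    ss = float(((x - x.mean()) ** 2).sum())
    if ss == 0:
        raise ValidationError("zero variance in log endpoints")
    return n_eff / (n * (n_eff - 1.0)) * ss
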