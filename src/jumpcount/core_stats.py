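"""Closed-form uncertainty of equilibrium constants and free energy differences.

For a two-state Markovian system the first-passage times out of each state
are exponential, so the total dwell times ``sum(t_A)`` and ``sum(t_B)``
accumulated over ``n_A`` forward and ``n_B`` reverse transitions are
Gamma-distributed.  The ratio of the estimated to the true equilibrium
constant, ``K_hat / K``, then follows an F-distribution with degrees of
freedom ``d1 = 2 n_B`` and ``d2 = 2 n_A``.  Everything in this module —
confidence intervals for K and for ``dG = -kT ln K``, and the trigamma
standard error — is a deterministic function of the two transition counts,
the temperature and the confidence level.  No trajectory data beyond the
counts is needed.

Sign convention: ``K = [B]/[A] = k1/k_-1`` and ``dG(A->B) = -kT ln K``
(natural logarithm throughout).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import polygamma

__all__ = [
    "BOLTZMANN_KCAL",
    "BOLTZMANN_KJ",
    "InsufficientDataError",
    "TransitionCounts",
    "ThermalContext",
    "ConfidenceInterval",
    "FreeEnergyResult",
    "InsufficientTransitions",
    "f_quantile",
    "ci_of_K",
    "ci_of_dG",
    "se_of_dG",
    "free_energy_from_counts",
    "make_lookup_table",
]

#: Boltzmann constant in kcal mol^-1 K^-1.
BOLTZMANN_KCAL = 0.0019872041
#: Boltzmann constant in kJ mol^-1 K^-1.
BOLTZMANN_KJ = 0.0083144626

_UNIT_KB = {
    "kcal/mol": BOLTZMANN_KCAL,
    "kJ/mol": BOLTZMANN_KJ,
}


class InsufficientDataError(ValueError):
    """Raised when an estimator has too few observations to be defined."""


@dataclass(frozen=True)
class TransitionCounts:
    """Numbers of accomplished transitions in each direction.

    Parameters
    ----------
    n_A : int
        Accomplished A -> B transitions (at least 1).
    n_B : int
        Accomplished B -> A transitions (at least 1).

    Notes
    -----
    The F-distribution degrees of freedom are ``d1 = 2 n_B`` and
    ``d2 = 2 n_A``.  The closed-form results are derived for ``n_A = n_B``
    and ``n_A = n_B + 1`` (single trajectory started in A); the formulas
    are applied unchanged for any positive pair, and :func:`ci_of_dG`
    consumers flag larger imbalance as an extrapolated design.
    """

    n_A: int
    n_B: int

    def __post_init__(self) -> None:
        for name, value in (("n_A", self.n_A), ("n_B", self.n_B)):
            if not isinstance(value, (int, np.integer)) or isinstance(value, bool):
                raise TypeError(f"{name} must be an integer, got {value!r}")
            if value < 1:
                raise InsufficientDataError(
                    f"{name} must be >= 1 (no confidence interval exists "
                    f"without at least one transition in each direction); got {value}"
                )

    @property
    def d1(self) -> int:
        """First F degrees of freedom, 2 n_B."""
        return 2 * self.n_B

    @property
    def d2(self) -> int:
        """Second F degrees of freedom, 2 n_A."""
        return 2 * self.n_A

    def swapped(self) -> "TransitionCounts":
        return TransitionCounts(n_A=self.n_B, n_B=self.n_A)

    @property
    def balanced_design(self) -> bool:
        """True for the derived designs n_A = n_B or n_A = n_B + 1."""
        return self.n_A - self.n_B in (0, 1)


@dataclass(frozen=True)
class ThermalContext:
    """Temperature plus the energy unit in which results are expressed.

    ``kT`` is the thermal energy; at 300 K it is 0.596 kcal/mol.  The unit
    ``"kT"`` makes energies dimensionless multiples of the thermal energy.
    """

    temperature: float = 300.0
    energy_unit: str = "kcal/mol"
    boltzmann_constant: Optional[float] = None

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError(f"temperature must be > 0 K, got {self.temperature}")
        if self.boltzmann_constant is None:
            if self.energy_unit == "kT":
                kb = 1.0 / self.temperature
            elif self.energy_unit in _UNIT_KB:
                kb = _UNIT_KB[self.energy_unit]
            else:
                raise ValueError(
                    f"unknown energy unit {self.energy_unit!r}; choose one of "
                    f"{sorted(_UNIT_KB)} or 'kT', or pass boltzmann_constant"
                )
            object.__setattr__(self, "boltzmann_constant", kb)
        elif self.boltzmann_constant <= 0:
            raise ValueError("boltzmann_constant must be > 0")

    @property
    def kT(self) -> float:
        return self.boltzmann_constant * self.temperature

    def to(self, unit: str) -> "ThermalContext":
        """Return an equivalent context expressed in another unit."""
        return ThermalContext(temperature=self.temperature, energy_unit=unit)


@dataclass(frozen=True)
class ConfidenceInterval:
    """An equal-tailed confidence interval ``[lower, upper]`` at ``level``."""

    lower: float
    upper: float
    level: float = 0.95

    def __post_init__(self) -> None:
        if not 0.0 < self.level < 1.0:
            raise ValueError(f"level must be in (0, 1), got {self.level}")
        if self.lower > self.upper:
            raise ValueError(f"lower bound {self.lower} exceeds upper {self.upper}")

    @property
    def width(self) -> float:
        return self.upper - self.lower

    @property
    def half_width(self) -> float:
        return 0.5 * self.width

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


@dataclass(frozen=True)
class FreeEnergyResult:
    """Point estimate of a free energy difference with its uncertainty."""

    estimate: float
    ci: ConfidenceInterval
    standard_error: float
    counts: TransitionCounts
    thermal: ThermalContext
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "estimate": self.estimate,
            "ci_lower": self.ci.lower,
            "ci_upper": self.ci.upper,
            "level": self.ci.level,
            "standard_error": self.standard_error,
            "n_A": self.counts.n_A,
            "n_B": self.counts.n_B,
            "temperature_K": self.thermal.temperature,
            "unit": self.thermal.energy_unit,
            **self.metadata,
        }


@dataclass(frozen=True)
class InsufficientTransitions:
    """Structured stand-in for a result when one direction was never observed.

    Carries the raw counts so callers can report *why* no interval exists
    instead of propagating NaNs.
    """

    n_A: int
    n_B: int
    message: str = "at least one transition in each direction is required"


def f_quantile(p: float, d1: int, d2: int) -> float:
    """Quantile (inverse CDF) of the F-distribution with ``(d1, d2)`` df.

    Raises
    ------
    ValueError
        If ``p`` is outside (0, 1) or the degrees of freedom are not
        positive integers.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must be in (0, 1), got {p}")
    for name, d in (("d1", d1), ("d2", d2)):
        if not float(d).is_integer() or d <= 0:
            raise ValueError(f"{name} must be a positive integer, got {d!r}")
    return float(stats.f.ppf(p, d1, d2))


def ci_of_K(
    K_hat: float, counts: TransitionCounts, level: float = 0.95
) -> ConfidenceInterval:
    """Equal-tailed confidence interval for the equilibrium constant K.

    Because ``K_hat / K ~ F(2 n_B, 2 n_A)``, the interval is

        [ K_hat / qF_{2nB,2nA}(1 - a/2),  K_hat / qF_{2nB,2nA}(a/2) ]

    with ``a = 1 - level``.  It is multiplicative: for ``n_A = n_B`` it is
    symmetric about ``K_hat`` on a log scale.
    """
    if K_hat <= 0:
        raise ValueError(f"K_hat must be > 0, got {K_hat}")
    alpha = 1.0 - level
    q_lo = f_quantile(alpha / 2.0, counts.d1, counts.d2)
    q_hi = f_quantile(1.0 - alpha / 2.0, counts.d1, counts.d2)
    return ConfidenceInterval(lower=K_hat / q_hi, upper=K_hat / q_lo, level=level)


def ci_of_dG(
    counts: TransitionCounts,
    thermal: ThermalContext,
    level: float = 0.95,
    dG_hat: float = 0.0,
) -> ConfidenceInterval:
    """Confidence interval for ``dG = -kT ln K`` centred on ``dG_hat``.

    The interval is ``[dG_hat + kT ln qF(a/2), dG_hat + kT ln qF(1-a/2)]``
    with df ``(2 n_B, 2 n_A)``.  Its width depends only on the transition
    counts, the temperature and the level — not on the estimate itself.
    For ``n_A = n_B`` it is symmetric about ``dG_hat`` (at 300 K and 95%:
    ±2.18 kcal/mol for one transition each way, ±1.35 for two); for
    ``n_A = n_B + 1`` it is asymmetric.
    """
    if not math.isfinite(dG_hat):
        raise ValueError(f"dG_hat must be finite, got {dG_hat}")
    alpha = 1.0 - level
    kT = thermal.kT
    lo = dG_hat + kT * math.log(f_quantile(alpha / 2.0, counts.d1, counts.d2))
    hi = dG_hat + kT * math.log(f_quantile(1.0 - alpha / 2.0, counts.d1, counts.d2))
    return ConfidenceInterval(lower=lo, upper=hi, level=level)


def se_of_dG(counts: TransitionCounts, thermal: ThermalContext) -> float:
    """Standard error of the free energy estimate from the trigamma function.

    ``ln K_hat`` is a difference of two independent log-gamma variates, so

        SE(dG) = kT * sqrt( psi1(n_A) + psi1(n_B) )

    where ``psi1`` is the trigamma function.  The true K contributes no
    variance; only the sampling variability of the estimator enters.
    """
    t = polygamma(1, counts.n_A) + polygamma(1, counts.n_B)
    return thermal.kT * math.sqrt(float(t))


def free_energy_from_counts(
    n_A: int,
    n_B: int,
    thermal: ThermalContext = ThermalContext(),
    level: float = 0.95,
    dG_hat: float = 0.0,
):
    """Build a :class:`FreeEnergyResult` directly from transition counts.

    Returns an :class:`InsufficientTransitions` record (not NaN, not an
    exception) when either count is zero, since no interval exists then.
    """
    if n_A < 1 or n_B < 1:
        return InsufficientTransitions(n_A=n_A, n_B=n_B)
    counts = TransitionCounts(n_A=n_A, n_B=n_B)
    meta = {}
    if not counts.balanced_design:
        meta["design"] = "extrapolated"
    if counts.n_A != counts.n_B:
        meta["asymmetric_ci"] = True
    return FreeEnergyResult(
        estimate=dG_hat,
        ci=ci_of_dG(counts, thermal, level=level, dG_hat=dG_hat),
        standard_error=se_of_dG(counts, thermal),
        counts=counts,
        thermal=thermal,
        metadata=meta,
    )


def make_lookup_table(
    n_max: int,
    thermal: ThermalContext = ThermalContext(),
    level: float = 0.95,
) -> pd.DataFrame:
    """Tabulate CI offsets and standard errors for small transition counts.

    One row per ``n_A = n_B = n`` and per ``n_A = n + 1, n_B = n`` for
    ``n = 1..n_max``.  Offsets are relative to the point estimate, so the
    symmetric rows read as ``dG_hat ± |offset|``.
    """
    if n_max < 1:
        raise ValueError(f"n_max must be >= 1, got {n_max}")
    rows = []
    for n in range(1, n_max + 1):
        for n_A, n_B in ((n, n), (n + 1, n)):
            counts = TransitionCounts(n_A=n_A, n_B=n_B)
            ci = ci_of_dG(counts, thermal, level=level)
            rows.append(
                {
                    "n_A": n_A,
                    "n_B": n_B,
                    "dG_lower_offset": ci.lower,
                    "dG_upper_offset": ci.upper,
                    "se": se_of_dG(counts, thermal),
                    "unit": thermal.energy_unit,
                    "temperature_K": thermal.temperature,
                    "level": level,
                }
            )
    return pd.DataFrame(rows)
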