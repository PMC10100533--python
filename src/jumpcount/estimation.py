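"""Point estimators from first-passage times.

Rate constants (including the right-censored maximum-likelihood form for
ensembles of independent simulations that were stopped at ``t_max`` before
a transition occurred), the equilibrium constant and free energy difference,
the binding dissociation constant, root-sum-of-squares error combination for
chained states, and a Kolmogorov-Smirnov diagnostic for the exponential
passage-time assumption.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_stats import (
    ConfidenceInterval,
    FreeEnergyResult,
    InsufficientDataError,
    ThermalContext,
    TransitionCounts,
    ci_of_dG,
    ci_of_K,
    se_of_dG,
)

__all__ = [
    "PassageTimes",
    "BindingObservation",
    "rate_constant",
    "rate_constant_censored",
    "estimate_K",
    "estimate_dG",
    "dissociation_constant",
    "dissociation_constant_ci",
    "binding_free_energy",
    "ligand_concentration_from_box",
    "combine_errors",
    "exponentiality_test",
    "read_passage_times",
    "read_censored_json",
]

#: Avogadro constant, mol^-1.
AVOGADRO = 6.02214076e23


def _as_positive_array(values: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if arr.size and np.any(arr <= 0):
        raise ValueError(f"all {name} must be > 0")
    return arr


@dataclass(frozen=True)
class PassageTimes:
    """First-passage times out of states A and B, optionally right-censored.

    ``censored_A`` holds the run lengths ``t_max`` of simulations started in
    A that ended without reaching B; analogously for ``censored_B``.  The
    censoring times may differ between runs — the general right-censoring
    likelihood simply sums them.
    """

    times_A: Sequence[float]
    times_B: Sequence[float]
    censored_A: Sequence[float] = field(default_factory=tuple)
    censored_B: Sequence[float] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for name in ("times_A", "times_B", "censored_A", "censored_B"):
            arr = _as_positive_array(getattr(self, name), name)
            object.__setattr__(self, name, arr)

    @property
    def n_A(self) -> int:
        return int(self.times_A.size)

    @property
    def n_B(self) -> int:
        return int(self.times_B.size)

    @property
    def m_A(self) -> int:
        return int(self.censored_A.size)

    @property
    def m_B(self) -> int:
        return int(self.censored_B.size)

    @property
    def total_time_A(self) -> float:
        """Total observation time credited to state A, censored runs included."""
        return float(self.times_A.sum() + self.censored_A.sum())

    @property
    def total_time_B(self) -> float:
        return float(self.times_B.sum() + self.censored_B.sum())

    def swapped(self) -> "PassageTimes":
        return PassageTimes(
            times_A=self.times_B,
            times_B=self.times_A,
            censored_A=self.censored_B,
            censored_B=self.censored_A,
        )


@dataclass(frozen=True)
class BindingObservation:
    """Dwell-time totals for a binding equilibrium PL <-> P + L.

    ``ligand_concentration`` is the concentration of the free ligand in the
    simulation box (mol/L); for a single ligand molecule it is
    ``1 / (N_Avogadro * V_box)``, see :func:`ligand_concentration_from_box`.
    """

    time_unbound_total: float
    time_bound_total: float
    ligand_concentration: float

    def __post_init__(self) -> None:
        for name in ("time_unbound_total", "time_bound_total", "ligand_concentration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def rate_constant(times: Sequence[float]) -> float:
    """Maximum-likelihood rate constant ``n / sum(t)`` for exponential times."""
    arr = _as_positive_array(times, "times")
    if arr.size == 0:
        raise InsufficientDataError("need at least one observed passage time")
    return arr.size / float(arr.sum())


def rate_constant_censored(
    times: Sequence[float], censored: Sequence[float]
) -> float:
    """Right-censored exponential MLE: ``n / (sum(t_i) + sum(t_max_j))``.

    Every censored run contributes its full elapsed time to the denominator
    but nothing to the count.  Discarding unfinished runs instead biases the
    rate upward — badly so when most runs are censored.  Reduces exactly to
    :func:`rate_constant` when there are no censored runs.
    """
    arr = _as_positive_array(times, "times")
    cens = _as_positive_array(censored, "censored")
    if arr.size == 0:
        raise InsufficientDataError(
            "no transition was observed; only an upper bound on the rate "
            f"exists (k < 1 / total censored time = {1.0 / cens.sum() if cens.size else math.inf:.4g})"
        )
    return arr.size / float(arr.sum() + cens.sum())


def estimate_K(pt: PassageTimes) -> float:
    """Estimate the equilibrium constant ``K = [B]/[A] = k1 / k_-1``.

    ``K_hat = (n_A * T_B) / (n_B * T_A)`` where ``T_A``, ``T_B`` are the
    total dwell times including any censored observation time, so the
    censored rate estimators are used automatically when censored runs are
    present.
    """
    if pt.n_A < 1 or pt.n_B < 1:
        raise InsufficientDataError(
            f"need at least one accomplished transition each way, "
            f"got n_A={pt.n_A}, n_B={pt.n_B}"
        )
    k1 = rate_constant_censored(pt.times_A, pt.censored_A)
    k_minus1 = rate_constant_censored(pt.times_B, pt.censored_B)
    return k1 / k_minus1


def estimate_dG(
    pt: PassageTimes,
    thermal: ThermalContext = ThermalContext(),
    level: float = 0.95,
) -> FreeEnergyResult:
    """Free energy difference ``dG = -kT ln K_hat`` with exact CI and SE.

    The confidence interval and standard error depend only on the counts
    ``(n_A, n_B)`` and the temperature; the passage times set the centre.
    """
    K_hat = estimate_K(pt)
    counts = TransitionCounts(n_A=pt.n_A, n_B=pt.n_B)
    dG_hat = -thermal.kT * math.log(K_hat)
    meta = {"K_hat": K_hat}
    if pt.m_A or pt.m_B:
        meta["censored"] = {"m_A": pt.m_A, "m_B": pt.m_B}
    if not counts.balanced_design:
        meta["design"] = "extrapolated"
    return FreeEnergyResult(
        estimate=dG_hat,
        ci=ci_of_dG(counts, thermal, level=level, dG_hat=dG_hat),
        standard_error=se_of_dG(counts, thermal),
        counts=counts,
        thermal=thermal,
        metadata=meta,
    )


def dissociation_constant(obs: BindingObservation) -> float:
    """Dissociation constant ``K_d = c_L * sum(t_P) / sum(t_PL)``.

    Reported in the concentration units of ``c_L``.  The associated binding
    free energy is ``kT ln K_d`` (see :func:`binding_free_energy` for the
    standard-state caveat).
    """
    return (
        obs.ligand_concentration * obs.time_unbound_total / obs.time_bound_total
    )


def dissociation_constant_ci(
    obs: BindingObservation,
    n_unbinding: int,
    n_binding: int,
    level: float = 0.95,
) -> ConfidenceInterval:
    """Multiplicative confidence interval for ``K_d``.

    The dwell-time totals are gamma sums exactly as in the conformational
    case, so the F-distribution interval for K applies to the ratio
    ``sum(t_P)/sum(t_PL)`` with ``n_A = n_binding`` (PL formed, entering the
    bound state) and ``n_B = n_unbinding``.  Exact for the alternating
    design ``n_binding = n_unbinding``.
    """
    counts = TransitionCounts(n_A=n_binding, n_B=n_unbinding)
    return ci_of_K(dissociation_constant(obs), counts, level=level)


def binding_free_energy(K_d: float, thermal: ThermalContext = ThermalContext()) -> float:
    """Binding free energy ``kT ln K_d`` with ``K_d`` in the units of ``c_L``.

    No standard-state (1 M) correction is applied; if ``c_L`` is expressed in
    mol/L the result is relative to a 1 M reference concentration.
    """
    if K_d <= 0:
        raise ValueError("K_d must be > 0")
    return thermal.kT * math.log(K_d)


def ligand_concentration_from_box(volume_litres: float) -> float:
    """Concentration (mol/L) of a single ligand molecule in a box of given volume."""
    if volume_litres <= 0:
        raise ValueError("volume must be > 0")
    return 1.0 / (AVOGADRO * volume_litres)


def combine_errors(sigmas: Sequence[float]) -> float:
    """Root-sum-of-squares combination of standard errors of chained steps.

    Rigorous for normally distributed estimates; the free energy estimates
    here are only asymptotically normal, so treat the combined value as an
    approximation that improves with the number of transitions.
    """
    arr = np.asarray(sigmas, dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one standard error to combine")
    if np.any(arr < 0):
        raise ValueError("standard errors must be non-negative")
    return float(np.sqrt(np.sum(arr**2)))


class ExponentialityResult(NamedTuple):
    statistic: float
    p_value: float


def exponentiality_test(
    times: Sequence[float],
    method: str = "ks",
    n_bootstrap: int = 999,
    rng: Optional[np.random.Generator] = None,
) -> ExponentialityResult:
    """Kolmogorov-Smirnov test of the exponential passage-time assumption.

    A rejection signals non-Markovian kinetics (or poorly chosen state
    boundaries).  Two caveats: the power of the KS test is low, so a
    non-rejection with few transitions neither confirms nor refutes
    Markovianity; and because the rate is fitted from the same sample, the
    plain KS p-value (``method="ks"``) is conservative.  Use
    ``method="bootstrap"`` for a parametric-bootstrap p-value that accounts
    for the fitted rate.
    """
    arr = _as_positive_array(times, "times")
    if arr.size < 3:
        raise InsufficientDataError("need at least 3 passage times")
    scale = float(arr.mean())
    stat, p = stats.kstest(arr, "expon", args=(0.0, scale))
    if method == "ks":
        return ExponentialityResult(float(stat), float(p))
    if method != "bootstrap":
        raise ValueError(f"unknown method {method!r}; use 'ks' or 'bootstrap'")
    rng = np.random.default_rng() if rng is None else rng
    exceed = 0
    for _ in range(n_bootstrap):
        sample = rng.exponential(scale, size=arr.size)
        s, _ = stats.kstest(sample, "expon", args=(0.0, float(sample.mean())))
        if s >= stat:
            exceed += 1
    return ExponentialityResult(float(stat), (exceed + 1) / (n_bootstrap + 1))


def read_passage_times(
    path, state_a: Optional[str] = None, state_b: Optional[str] = None
) -> PassageTimes | np.ndarray:
    """Read passage times from a plain numeric or labelled CSV/TSV file.

    A single numeric column yields a bare array of times.  A two-column
    file (state label, dwell time) yields a :class:`PassageTimes` with the
    rows labelled ``state_a`` / ``state_b``; the two labels default to the
    first two distinct labels in order of appearance.
    """
    with open(path) as fh:
        first_data = next(
            (line for line in fh if line.strip() and not line.startswith("#")), ""
        )
    # csv.Sniffer misreads the decimal point in bare numeric columns,
    # so pick the delimiter explicitly
    sep = "," if "," in first_data else (r"\t" if "\t" in first_data else r"\s+")
    df = pd.read_csv(path, sep=sep, engine="python", comment="#", header=None)
    if df.shape[1] == 1:
        return _as_positive_array(df.iloc[:, 0].to_numpy(dtype=float), "times")
    if df.shape[1] != 2:
        raise ValueError(
            f"{path}: expected 1 (times) or 2 (label, time) columns, got {df.shape[1]}"
        )
    labels = df.iloc[:, 0].astype(str)
    seen = list(dict.fromkeys(labels))
    if state_a is None:
        state_a = seen[0]
    if state_b is None:
        remaining = [s for s in seen if s != state_a]
        if not remaining:
            raise ValueError(f"{path}: only one state label present ({state_a!r})")
        state_b = remaining[0]
    times = df.iloc[:, 1].to_numpy(dtype=float)
    return PassageTimes(
        times_A=times[labels == state_a],
        times_B=times[labels == state_b],
    )


def read_censored_json(path) -> PassageTimes:
    """Read a censored ensemble from a JSON record.

    Expected shape::

        {"A": {"times": [...], "censored": [...]},
         "B": {"times": [...], "censored": [...]}}
    """
    record = json.loads(Path(path).read_text())
    def side(key):
        entry = record.get(key, {})
        return entry.get("times", []), entry.get("censored", [])
    times_a, cens_a = side("A")
    times_b, cens_b = side("B")
    return PassageTimes(
        times_A=times_a, times_B=times_b, censored_A=cens_a, censored_B=cens_b
    )
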