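"""Correlating Michaelis-Menten parameters with interaction energies.

The framework links computable interaction energies to kinetic constants
through effective-temperature linear relations:

    ln K_M        =  IE_S / (RT)_S        + c1
    ln(kcat/K_M)  = -IE_TSA / (RT)_TSA    + c2
    ln kcat       = -IE_TSA/(RT)_TSA + IE_S/(RT)_S + c3

where IE_S is the enzyme-substrate interaction energy, IE_TSA the
interaction energy with the transition-state analogue, and the (RT) values
are empirical scale factors recovered by ordinary least squares. The
effective temperatures T = (RT)/R that correspond to fitted (RT) values are
far above physical temperatures; they are regression scales, not
thermodynamic temperatures.

Natural logarithms throughout; K_M in mM, kcat in 1/s.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .constants import H_PLANCK, K_BOLTZMANN, R_GAS

logger = logging.getLogger(__name__)


class InsufficientDataError(ValueError):
    """Too few observations for the requested fit."""


class DegenerateFitError(ValueError):
    """Zero-variance or collinear predictors."""


@dataclass
class IEObservation:
    """Per-variant interaction energies, kJ/mol (either may be absent)."""

    variant_id: str
    ie_s: float | None = None
    ie_tsa: float | None = None

    def __post_init__(self) -> None:
        if self.ie_s is None and self.ie_tsa is None:
            raise ValueError(f"{self.variant_id}: at least one IE must be present")


@dataclass
class KineticObservation:
    """Per-variant kinetic constants: K_M (mM), kcat (1/s), kcat/K_M (1/(mM·s))."""

    variant_id: str
    km: float | None = None
    kcat: float | None = None
    kcat_over_km: float | None = None

    def __post_init__(self) -> None:
        for name in ("km", "kcat", "kcat_over_km"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{self.variant_id}: {name} must be > 0, got {v}")
        if self.km and self.kcat and self.kcat_over_km:
            implied = self.kcat / self.km
            if abs(implied - self.kcat_over_km) > 0.01 * self.kcat_over_km:
                logger.warning(
                    "%s: kcat/km (%.4g) inconsistent with kcat_over_km (%.4g)",
                    self.variant_id, implied, self.kcat_over_km,
                )

    def efficiency(self) -> float | None:
        if self.kcat_over_km is not None:
            return self.kcat_over_km
        if self.kcat is not None and self.km is not None:
            return self.kcat / self.km
        return None


@dataclass
class LinearFitResult:
    """One-predictor OLS fit on the ln scale.

    ``effective_rt`` = 1/|slope| (kJ/mol); ``effective_temperature`` is its
    conversion through T = RT/R.
    """

    slope: float
    intercept: float
    r_squared: float
    degenerate: bool = False

    @property
    def effective_rt(self) -> float:
        if self.slope == 0.0:
            return math.inf
        return 1.0 / abs(self.slope)

    @property
    def effective_temperature(self) -> float:
        return self.effective_rt / R_GAS


@dataclass
class KcatFitResult:
    """Two-predictor fit ln kcat = -IE_TSA/rt_tsa + IE_S/rt_s + intercept."""

    rt_s: float
    rt_tsa: float
    intercept: float
    r_squared: float

    @property
    def physically_sensible(self) -> bool:
        return self.rt_s > 0 and self.rt_tsa > 0


def eyring_rate(delta_g_dagger: float, temperature: float, kappa: float = 1.0) -> float:
    """Eyring-Polanyi rate: k = kappa * (k_B T / h) * exp(-dG‡ / RT), 1/s.

    ``delta_g_dagger`` in kJ/mol, ``temperature`` in K, ``kappa`` the
    transmission coefficient in [0, 1].
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be > 0, got {temperature}")
    if not (0.0 <= kappa <= 1.0):
        raise ValueError(f"kappa must be in [0, 1], got {kappa}")
    prefactor = K_BOLTZMANN * temperature / H_PLANCK
    return kappa * prefactor * math.exp(-delta_g_dagger / (R_GAS * temperature))


def rt_to_temperature(rt: float) -> float:
    """Convert an effective RT (kJ/mol) to a temperature via T = RT / R."""
    if rt <= 0:
        raise ValueError(f"rt must be > 0, got {rt}")
    return rt / R_GAS


def _ols_1d(x: np.ndarray, y: np.ndarray) -> LinearFitResult:
    if len(x) < 3:
        raise InsufficientDataError(f"need >= 3 points, got {len(x)}")
    if np.ptp(x) == 0.0:
        raise DegenerateFitError("zero variance in predictor")
    if np.ptp(y) == 0.0:
        logger.warning("constant response: R^2 reported as 0")
        return LinearFitResult(0.0, float(y[0]), 0.0, degenerate=True)
    fit = stats.linregress(x, y)
    return LinearFitResult(float(fit.slope), float(fit.intercept), float(fit.rvalue**2))


def fit_ln_km(
    ie_s: Sequence[float], km: Sequence[float]
) -> LinearFitResult:
    """OLS of ln(K_M) on IE_S; slope is interpreted as 1/(RT)_S."""
    km = np.asarray(km, dtype=float)
    if np.any(km <= 0):
        raise ValueError("K_M values must be > 0")
    return _ols_1d(np.asarray(ie_s, dtype=float), np.log(km))


def fit_ln_efficiency(
    ie_tsa: Sequence[float], kcat_over_km: Sequence[float]
) -> LinearFitResult:
    """OLS of ln(kcat/K_M) on IE_TSA; slope is interpreted as -1/(RT)_TSA
    (a more negative IE_TSA means tighter analogue binding, hence higher
    catalytic efficiency)."""
    eff = np.asarray(kcat_over_km, dtype=float)
    if np.any(eff <= 0):
        raise ValueError("kcat/K_M values must be > 0")
    return _ols_1d(np.asarray(ie_tsa, dtype=float), np.log(eff))


def fit_ln_kcat(
    ie_s: Sequence[float], ie_tsa: Sequence[float], kcat: Sequence[float]
) -> KcatFitResult:
    """OLS of ln(kcat) on (IE_TSA, IE_S) under
    ln kcat = -IE_TSA/rt_tsa + IE_S/rt_s + c; returns the recovered rt values.
    """
    ie_s = np.asarray(ie_s, dtype=float)
    ie_tsa = np.asarray(ie_tsa, dtype=float)
    kcat = np.asarray(kcat, dtype=float)
    if len(ie_s) < 4:
        raise InsufficientDataError(f"need >= 4 triples, got {len(ie_s)}")
    if np.any(kcat <= 0):
        raise ValueError("kcat values must be > 0")
    y = np.log(kcat)
    X = np.column_stack([ie_tsa, ie_s, np.ones_like(ie_s)])
    if np.linalg.matrix_rank(X) < 3:
        raise DegenerateFitError("collinear predictors")
    beta, _res, _rank, _sv = np.linalg.lstsq(X, y, rcond=None)
    b_tsa, b_s, intercept = (float(v) for v in beta)
    yhat = X @ beta
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    rt_tsa = math.inf if b_tsa == 0 else -1.0 / b_tsa
    rt_s = math.inf if b_s == 0 else 1.0 / b_s
    result = KcatFitResult(rt_s=rt_s, rt_tsa=rt_tsa, intercept=intercept, r_squared=r2)
    if not result.physically_sensible:
        logger.warning("fit_ln_kcat: recovered rt values are not both positive")
    return result


def predict_deltas(
    mutant: IEObservation,
    wildtype: IEObservation,
    rt_s: float,
    rt_tsa: float,
) -> tuple[float, float, float]:
    """Mutant-minus-wild-type predictions on the ln scale:

        dln K_M        =  dIE_S / rt_s
        dln(kcat/K_M)  = -dIE_TSA / rt_tsa
        dln kcat       =  dln(kcat/K_M) + dln K_M
    """
    for obs in (mutant, wildtype):
        if obs.ie_s is None or obs.ie_tsa is None:
            raise ValueError(f"{obs.variant_id}: both IE_S and IE_TSA required")
    d_ie_s = mutant.ie_s - wildtype.ie_s
    d_ie_tsa = mutant.ie_tsa - wildtype.ie_tsa
    dln_km = d_ie_s / rt_s
    dln_eff = -d_ie_tsa / rt_tsa
    return dln_km, dln_eff, dln_eff + dln_km
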