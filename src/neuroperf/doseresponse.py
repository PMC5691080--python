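"""Concentration–response analysis: peak normalisation and Hill fitting.

Mean evoked peak magnitudes at each agonist concentration are normalised to
the mean peak at the highest (reference) concentration and fitted with the
increasing Hill sigmoid

    y(x) = R_max · xⁿ / (EC50ⁿ + xⁿ)

where EC50 is the concentration producing the half-maximal response and n
the Hill coefficient.  Antagonist efficacy is summarised as the treated
response as a percentage of the control response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import DomainError, ValidationError

__all__ = [
    "DoseResponseSet",
    "HillFit",
    "hill_response",
    "normalize_peaks",
    "fit_hill",
    "percent_of_control",
]


@dataclass
class DoseResponseSet:
    """Per-neuron peak magnitudes across agonist concentrations.

    ``points`` carries columns ``concentration_M``, ``neuron``, ``peak``;
    ``reference_concentration_M`` is the normalising dose (1 mM in the
    study's glutamate series).
    """

    points: pd.DataFrame
    reference_concentration_M: float = 1e-3

    def __post_init__(self) -> None:
        required = {"concentration_M", "neuron", "peak"}
        if not required.issubset(self.points.columns):
            raise ValidationError(f"points must have columns {sorted(required)}")
        if (self.points["concentration_M"] <= 0).any():
            raise DomainError("concentrations must be positive")


@dataclass
class HillFit:
    """Fitted Hill parameters with asymptotic standard errors."""

    r_max: float
    ec50: float
    hill_n: float
    r_max_se: float
    ec50_se: float
    hill_n_se: float
    converged: bool

    def predict(self, x: np.ndarray) -> np.ndarray:
        return hill_response(x, self.r_max, self.ec50, self.hill_n)


def hill_response(x, r_max: float, ec50: float, hill_n: float):
    """Increasing Hill sigmoid R_max·xⁿ/(EC50ⁿ + xⁿ); y(EC50) = R_max/2.

    Evaluated in log-concentration space for numerical stability over the
    10 nM–1 mM range.
    """
    if r_max <= 0 or ec50 <= 0 or hill_n <= 0:
        raise DomainError("Hill parameters must be positive")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise DomainError("concentrations must be non-negative")
    with np.errstate(divide="ignore"):
        # x^n/(ec50^n + x^n) = 1/(1 + exp(-n(ln x - ln ec50)))
        logratio = np.where(x > 0, np.log(x) - np.log(ec50), -np.inf)
    out = r_max / (1.0 + np.exp(-hill_n * logratio))
    return out if out.ndim else float(out)


def normalize_peaks(dset: DoseResponseSet, rtol: float = 1e-6) -> DoseResponseSet:
    """Divide every peak by the mean peak at the reference concentration."""
    conc = dset.points["concentration_M"].to_numpy()
    ref_mask = np.isclose(conc, dset.reference_concentration_M, rtol=rtol)
    if not ref_mask.any():
        raise ValidationError(
            f"reference concentration {dset.reference_concentration_M} M absent from data"
        )
    ref_mean = dset.points.loc[ref_mask, "peak"].mean()
    if ref_mean <= 0:
        raise DomainError("mean peak at the reference concentration must be positive")
    out = dset.points.copy()
    out["peak"] = out["peak"] / ref_mean
    return DoseResponseSet(points=out, reference_concentration_M=dset.reference_concentration_M)


def fit_hill(dset: DoseResponseSet, init: tuple[float, float, float] | None = None) -> HillFit:
    """Weighted least-squares Hill fit to per-concentration mean responses.

    The fit targets the mean peak at each concentration, weighted by the
    per-concentration neuron count (as responses are reported as cohort
    means).  Initialisation defaults to R_max = max mean response, EC50 =
    geometric median concentration, n = 1, with all parameters bounded
    positive.  Non-convergence yields ``converged=False`` with NaN
    estimates rather than an exception.
    """
    grouped = dset.points.groupby("concentration_M")["peak"]
    means = grouped.mean()
    counts = grouped.count()
    if len(means) < 3:
        raise ValidationError("need at least 3 distinct concentrations to fit")
    x = means.index.to_numpy(dtype=float)
    y = means.to_numpy(dtype=float)
    n_per = counts.to_numpy(dtype=float)
    if init is None:
        init = (
            max(y.max(), 1e-12),
            float(np.exp(np.median(np.log(x)))),
            1.0,
        )
    try:
        popt, pcov = curve_fit(
            hill_response,
            x,
            y,
            p0=init,
            sigma=1.0 / np.sqrt(n_per),
            absolute_sigma=False,
            bounds=([1e-12, 1e-15, 1e-3], [np.inf, np.inf, 20.0]),
            maxfev=20000,
        )
    except RuntimeError:
        nan = float("nan")
        return HillFit(nan, nan, nan, nan, nan, nan, converged=False)
    ses = np.sqrt(np.diag(pcov))
    return HillFit(
        r_max=float(popt[0]),
        ec50=float(popt[1]),
        hill_n=float(popt[2]),
        r_max_se=float(ses[0]),
        ec50_se=float(ses[1]),
        hill_n_se=float(ses[2]),
        converged=bool(np.all(np.isfinite(ses))),
    )


def percent_of_control(treated_peaks, control_peaks) -> tuple[float, float]:
    """Treated response as % of control: 100·mean(treated)/mean(control) ± SEM.

    The SEM is propagated from the per-cohort SEMs of the two means assuming
    independence between the numerator and denominator errors.
    """
    t = np.asarray(treated_peaks, dtype=float)
    c = np.asarray(control_peaks, dtype=float)
    if t.size == 0 or c.size == 0:
        raise ValidationError("treated and control cohorts must be non-empty")
    mt, mc = t.mean(), c.mean()
    if mc == 0:
        raise DomainError("control mean is zero; percent of control undefined")
    pct = 100.0 * mt / mc
    sem_t = t.std(ddof=1) / np.sqrt(t.size) if t.size > 1 else 0.0
    sem_c = c.std(ddof=1) / np.sqrt(c.size) if c.size > 1 else 0.0
    sem = 100.0 * np.hypot(sem_t / mc, mt * sem_c / mc**2)
    return float(pct), float(sem)
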