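"""Functional antagonism from cAMP dose-response data.

Three-parameter logistic fits of agonist concentration-response curves,
antagonist affinity (pKB) from the Gaddum dose-ratio equation, and full
Schild regression (pA2 and Schild slope).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import lmfit
import numpy as np
from scipy import stats

from .binding_kinetics import FitFailure

__all__ = [
    "DoseResponseCurve",
    "DoseResponseSet",
    "LogisticFit",
    "SchildResult",
    "normalize_camp",
    "fit_logistic3",
    "pkb_dose_ratio",
    "schild_regression",
]


@dataclass
class DoseResponseCurve:
    """One agonist concentration-response curve at a fixed antagonist conc."""

    agonist_conc: np.ndarray
    response: np.ndarray
    antagonist_conc: float = 0.0
    mode: str = "stimulation"

    def __post_init__(self) -> None:
        self.agonist_conc = np.asarray(self.agonist_conc, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.agonist_conc.shape != self.response.shape:
            raise ValueError("agonist_conc and response lengths differ")
        if self.agonist_conc.size < 6:
            raise ValueError("need >=6 points per curve")
        if np.any(self.agonist_conc <= 0):
            raise ValueError("agonist concentrations must be > 0")
        if self.antagonist_conc < 0:
            raise ValueError("antagonist concentration must be >= 0")
        if self.mode not in ("stimulation", "inhibition"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class DoseResponseSet:
    """Curves at zero or more antagonist concentrations (control first)."""

    curves: list[DoseResponseCurve]

    def __post_init__(self) -> None:
        if not self.curves:
            raise ValueError("empty dose-response set")
        self.curves = sorted(self.curves, key=lambda c: c.antagonist_conc)

    @property
    def control(self) -> DoseResponseCurve:
        if self.curves[0].antagonist_conc != 0:
            raise ValueError("no antagonist-free control curve in the set")
        return self.curves[0]


@dataclass
class LogisticFit:
    basal: float
    emax: float
    pec50: float
    pec50_sem: float | None = None

    @property
    def ec50(self) -> float:
        return 10.0 ** (-self.pec50)


@dataclass
class SchildResult:
    """Schild regression of log10(DR-1) on log10[B]; pA2 is the x-intercept."""

    pa2: float
    slope: float
    points: list[tuple[float, float]]


def normalize_camp(raw, fsk_max: float, mode: str = "stimulation"):
    """Express a cAMP signal as % of the 100 uM forskolin response.

    ``stimulation``: 100*raw/fsk_max (Gs-coupled readout).  ``inhibition``:
    100*(1 - raw/fsk_max), so that Gi-coupled inhibition is a rising curve.
    """
    if fsk_max <= 0:
        raise ValueError("fsk_max must be > 0")
    raw = np.asarray(raw, dtype=float)
    pct = 100.0 * raw / fsk_max
    if mode == "stimulation":
        return pct
    if mode == "inhibition":
        return 100.0 - pct
    raise ValueError(f"unknown mode {mode!r}")


def logistic3(agonist_conc, basal, emax, pec50):
    """Three-parameter logistic (Hill slope 1) on the molar scale."""
    conc = np.asarray(agonist_conc, dtype=float)
    return basal + (emax - basal) / (1.0 + 10.0 ** (-pec50 - np.log10(conc)))


def fit_logistic3(curve: DoseResponseCurve) -> LogisticFit:
    """Least-squares 3-parameter logistic fit with Hill slope fixed at 1."""
    conc, resp = curve.agonist_conc, curve.response
    span = resp.max() - resp.min()
    if span <= 0:
        raise FitFailure("flat dose-response data")

    half = 0.5 * (resp.max() + resp.min())
    ec50_0 = conc[np.argmin(np.abs(resp - half))]

    params = lmfit.Parameters()
    params.add("basal", value=float(resp.min()))
    params.add("emax", value=float(resp.max()))
    params.add("pec50", value=float(-np.log10(ec50_0)), min=0.0, max=15.0)

    def residual(p):
        return logistic3(conc, p["basal"].value, p["emax"].value, p["pec50"].value) - resp

    result = lmfit.minimize(residual, params, method="leastsq")
    if not result.success:
        raise FitFailure(f"logistic fit did not converge: {result.message}")
    return LogisticFit(
        basal=result.params["basal"].value,
        emax=result.params["emax"].value,
        pec50=result.params["pec50"].value,
        pec50_sem=result.params["pec50"].stderr,
    )


def pkb_dose_ratio(ec50_antagonist: float, ec50_control: float, b_conc: float) -> float:
    """Antagonist affinity from a single-concentration dose-ratio shift.

    DR = EC50(+antagonist)/EC50(control); pKB = -log10([B]/(DR-1)).  A
    competitive antagonist at [B] = KB doubles the EC50 (DR = 2).
    """
    if b_conc <= 0:
        raise ValueError("antagonist concentration must be > 0")
    if ec50_control <= 0:
        raise ValueError("control EC50 must be > 0")
    dr = ec50_antagonist / ec50_control
    if dr <= 1.0:
        raise ValueError(
            f"dose ratio {dr:.3g} <= 1: antagonist produced no rightward shift"
        )
    return -np.log10(b_conc / (dr - 1.0))


def schild_regression(drs: list[tuple[float, float]]) -> SchildResult:
    """Full Schild analysis from (antagonist conc [M], dose ratio) pairs.

    Ordinary least squares of log10(DR-1) on log10[B]; pA2 is the x-intercept
    -intercept/slope.  Points with DR <= 1 carry no shift information and are
    excluded with a warning; at least 3 usable concentrations are required.
    A slope indistinguishable from 1 supports simple competitive antagonism.
    """
    usable = []
    for b, dr in drs:
        if dr <= 1.0:
            warnings.warn(f"excluding [B]={b:g} M with dose ratio {dr:g} <= 1")
            continue
        if b <= 0:
            raise ValueError("antagonist concentrations must be > 0")
        usable.append((np.log10(b), np.log10(dr - 1.0)))
    if len(usable) < 3:
        raise ValueError("need >=3 concentrations with dose ratio > 1")
    x = np.array([p[0] for p in usable])
    y = np.array([p[1] for p in usable])
    fit = stats.linregress(x, y)
    # pA2 is the negative of the x-intercept: -(-intercept/slope)
    pa2 = fit.intercept / fit.slope
    return SchildResult(pa2=float(pa2), slope=float(fit.slope), points=usable)
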