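"""In-vitro ADME calculators.

Equilibrium-dialysis plasma protein binding, bidirectional Caco-2 apparent
permeability (Papp) with percent recovery, depletion half-life from the
log-linear initial range, and microsomal intrinsic clearance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "DialysisInputs",
    "PermeabilityInputs",
    "PKRecord",
    "protein_binding",
    "papp",
    "uptake_ratio",
    "half_life",
    "clint",
]

#: Default human-liver-microsome protein concentration (mg/mL).
DEFAULT_MICROSOME_CONC = 0.1


@dataclass(frozen=True)
class DialysisInputs:
    """HPLC peak areas from equilibrium dialysis.

    area_p: analyte in the protein matrix; area_b: in buffer; area_c: in
    the no-dialysis control.
    """

    area_p: float
    area_b: float
    area_c: float

    def __post_init__(self) -> None:
        if self.area_p < 0 or self.area_b < 0:
            raise ValueError("peak areas must be >= 0")
        if self.area_c <= 0:
            raise ValueError("control peak area must be > 0")


@dataclass(frozen=True)
class PermeabilityInputs:
    """Bidirectional monolayer transfer measurements.

    Volumes in mL, concentrations in uM, incubation time dt in s, monolayer
    surface area in cm^2.
    """

    v_r: float
    v_d: float
    c_r_end: float
    c_d_end: float
    c_d0: float
    dt: float
    area: float

    def __post_init__(self) -> None:
        for name in ("v_r", "v_d", "dt", "area", "c_d0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.c_r_end < 0 or self.c_d_end < 0:
            raise ValueError("end-point concentrations must be >= 0")


@dataclass
class PKRecord:
    """Assembled ADME profile for one compound."""

    compound_id: str = ""
    pct_bound: float | None = None
    pct_recovery_binding: float | None = None
    papp_ab: float | None = None  # 1e-6 cm/s
    papp_ba: float | None = None
    pct_recovery_ab: float | None = None
    pct_recovery_ba: float | None = None
    t_half: float | None = None  # min
    clint: float | None = None  # uL/min/mg

    @property
    def uptake_ratio(self) -> float | None:
        if self.papp_ab is None or self.papp_ba is None:
            return None
        return uptake_ratio(self.papp_ab, self.papp_ba)


def protein_binding(d: DialysisInputs) -> tuple[float, float]:
    """Percent protein bound and percent recovery from dialysis peak areas.

    % bound = 100*(area_p - area_b)/area_p; % recovery =
    100*(area_p + area_b)/area_c.  A buffer area exceeding the protein-side
    area would imply negative binding; it is floored at 0 with a warning.
    """
    if d.area_p == 0:
        raise ValueError("protein-matrix peak area is zero; binding undefined")
    bound = 100.0 * (d.area_p - d.area_b) / d.area_p
    if bound < 0:
        warnings.warn("buffer peak area exceeds protein-side area; flooring % bound at 0")
        bound = 0.0
    recovery = 100.0 * (d.area_p + d.area_b) / d.area_c
    return bound, recovery


def papp(p: PermeabilityInputs, use_midpoint_donor: bool = False) -> tuple[float, float]:
    """Apparent permeability (1e-6 cm/s) and % recovery for one direction.

    Papp = (V_R * C_R,end) / (dt * A * C_D0) with the receiver amount
    accumulated over the incubation; recovery is the end-point mass in both
    chambers over the donor load.  ``use_midpoint_donor`` replaces C_D0 by
    the mean of the initial and final donor concentrations.
    """
    c_driving = p.c_d0 if not use_midpoint_donor else 0.5 * (p.c_d0 + p.c_d_end)
    papp_cm_s = (p.v_r * p.c_r_end) / (p.dt * p.area * c_driving)
    recovery = 100.0 * (p.v_r * p.c_r_end + p.v_d * p.c_d_end) / (p.v_d * p.c_d0)
    return papp_cm_s * 1e6, recovery


def uptake_ratio(papp_ab: float, papp_ba: float) -> float:
    """Papp(A->B)/Papp(B->A); > 1 means no apparent efflux."""
    if papp_ba <= 0:
        raise ValueError("Papp(B->A) must be > 0")
    return papp_ab / papp_ba


def half_life(times, pct_remaining, linear_range_min_pct: float = 10.0) -> float:
    """Depletion half-life (min) from the log-linear initial range.

    Ordinary least squares of ln(% remaining) on time restricted to points
    with at least ``linear_range_min_pct`` percent remaining (the initial
    first-order range); t1/2 = ln2/|slope|.
    """
    t = np.asarray(times, dtype=float)
    pct = np.asarray(pct_remaining, dtype=float)
    if t.shape != pct.shape:
        raise ValueError("times and pct_remaining lengths differ")
    keep = pct >= linear_range_min_pct
    if keep.sum() < 3:
        raise ValueError("need >=3 points in the initial linear range")
    fit = stats.linregress(t[keep], np.log(pct[keep]))
    if fit.slope >= 0:
        raise ValueError("no depletion observed (non-negative slope)")
    return float(np.log(2.0) / abs(fit.slope))


def clint(t_half: float, microsome_conc: float = DEFAULT_MICROSOME_CONC) -> float:
    """Apparent intrinsic clearance in uL/min per mg microsomal protein.

    CLint = (ln2/t1/2)/[microsomal protein] * 1000, converting the
    first-order depletion rate to a volume cleared per minute per mg.
    """
    if t_half <= 0 or microsome_conc <= 0:
        raise ValueError("t_half and microsome_conc must be > 0")
    return (np.log(2.0) / t_half) / microsome_conc * 1000.0
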