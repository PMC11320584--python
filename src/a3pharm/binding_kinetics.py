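"""Competition-binding kinetics for NanoBRET tracer-displacement assays.

The time course of a labeled tracer binding to a receptor in the presence
of an unlabeled competitor follows the two-ligand competition scheme

    R + L  <-> RL   (k1, k2)    tracer, constants known from prior work
    R + I  <-> RI   (k3, k4)    test compound, constants to be fitted

whose closed-form solution (Motulsky & Mahan) is implemented in
:func:`competitive_binding_signal`.  A global least-squares fit of that
expression over traces recorded at several competitor concentrations yields
the competitor association rate ``k3`` (kon), dissociation rate ``k4``
(koff), and hence the residence time RT = 1/koff and the kinetically
determined affinity pKd = -log10(koff/kon).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import lmfit
import numpy as np

__all__ = [
    "TracerParams",
    "KineticTraceSet",
    "KineticEstimate",
    "FitFailure",
    "competitive_binding_signal",
    "fit_competitor_kinetics",
    "residence_time",
    "kinetic_pkd",
]

#: Default tracer constants (CA200645 at the Nluc-tagged A3 receptor):
#: kon (k1) = 3.25e6 M^-1 min^-1, koff (k2) = 0.019 min^-1, used at 5 nM
#: against a 5 nM equilibrium Kd.
DEFAULT_TRACER_K1 = 3.25e6
DEFAULT_TRACER_K2 = 0.019

# Fitting bounds for the competitor rate constants; generous margins around
# the range observed for small-molecule GPCR antagonists.
K3_BOUNDS = (1e3, 1e10)
K4_BOUNDS = (1e-4, 10.0)


class FitFailure(RuntimeError):
    """A nonlinear fit failed to converge; carries solver diagnostics."""


@dataclass(frozen=True)
class TracerParams:
    """Labeled-tracer constants: concentration, equilibrium Kd and rates.

    All concentrations are molar; rates in M^-1 min^-1 (k1) and min^-1 (k2).
    ``kd`` may be omitted when both rates are given (then kd = k2/k1), and
    conversely the rates may be omitted for purely equilibrium work.
    """

    conc: float
    kd: float | None = None
    k1: float | None = None
    k2: float | None = None

    def __post_init__(self) -> None:
        if self.conc <= 0:
            raise ValueError(f"tracer concentration must be > 0, got {self.conc}")
        kd = self.kd
        if kd is None:
            if self.k1 is None or self.k2 is None:
                raise ValueError("either kd or both k1 and k2 must be given")
            kd = self.k2 / self.k1
            object.__setattr__(self, "kd", kd)
        if kd <= 0:
            raise ValueError(f"tracer kd must be > 0, got {kd}")
        for name in ("k1", "k2"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"tracer {name} must be > 0, got {v}")
        if self.k1 is not None and self.k2 is not None:
            implied = self.k2 / self.k1
            if abs(kd - implied) / kd > 1e-6:
                raise ValueError(
                    f"inconsistent tracer constants: kd={kd} but k2/k1={implied}"
                )

    def require_rates(self) -> tuple[float, float]:
        if self.k1 is None or self.k2 is None:
            raise ValueError("tracer rate constants k1, k2 are required here")
        return self.k1, self.k2


def default_tracer(conc: float = 5e-9) -> TracerParams:
    """Tracer at ``conc`` M with the standard CA200645 constants."""
    return TracerParams(conc=conc, k1=DEFAULT_TRACER_K1, k2=DEFAULT_TRACER_K2)


@dataclass
class KineticTraceSet:
    """Time-resolved tracer-binding signal over competitor concentrations.

    ``signal`` has shape (n_times, n_concs); ``competitor_concs`` must
    include 0 (the tracer-only association control).
    """

    times: np.ndarray
    competitor_concs: np.ndarray
    signal: np.ndarray
    tracer: TracerParams
    bmax: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.competitor_concs = np.asarray(self.competitor_concs, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.times[0] != 0:
            raise ValueError("times must start at 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.signal.shape != (self.times.size, self.competitor_concs.size):
            raise ValueError(
                f"signal shape {self.signal.shape} does not match "
                f"(n_times={self.times.size}, n_concs={self.competitor_concs.size})"
            )


@dataclass
class KineticEstimate:
    """Fitted competitor kinetics with derived residence time and pKd."""

    kon: float
    koff: float
    kon_sem: float | None = None
    koff_sem: float | None = None
    bmax: float | None = None
    koff_at_bound: bool = False
    rt: float = field(init=False)
    pkd: float = field(init=False)

    def __post_init__(self) -> None:
        self.rt = residence_time(self.koff)
        self.pkd = kinetic_pkd(self.kon, self.koff)


def _association_signal(t, k1, k2, tracer_conc, bmax):
    kobs = k1 * tracer_conc + k2
    return bmax * (k1 * tracer_conc / kobs) * (1.0 - np.exp(-kobs * t))


def competitive_binding_signal(
    t,
    tracer: TracerParams,
    i_conc: float,
    k3: float,
    k4: float,
    bmax: float,
):
    """Expected tracer-bound signal under competition at time(s) ``t``.

    Closed-form solution of the coupled rate equations for tracer L and
    competitor I binding the same receptor pool, starting from zero
    occupancy.  With KA = k1*L + k2, KB = k3*I + k4,
    S = sqrt((KA-KB)^2 + 4*k1*k3*L*I), KF = (KA+KB+S)/2, KS = (KA+KB-S)/2:

        B(t) = bmax * k1*L/(KF-KS) * [ k4*(KF-KS)/(KF*KS)
               + (k4-KF)/KF * exp(-KF*t) - (k4-KS)/KS * exp(-KS*t) ]

    The no-competitor case (I = 0) reduces to simple tracer association and
    is handled by that limit rather than by the degenerate general formula.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if k3 <= 0 or k4 <= 0:
        raise ValueError("competitor rate constants must be > 0")
    if i_conc < 0:
        raise ValueError("competitor concentration must be >= 0")
    k1, k2 = tracer.require_rates()
    L = tracer.conc

    if i_conc == 0:
        return _association_signal(t, k1, k2, L, bmax)

    KA = k1 * L + k2
    KB = k3 * i_conc + k4
    S = np.sqrt((KA - KB) ** 2 + 4.0 * k1 * k3 * L * i_conc)
    KF = 0.5 * (KA + KB + S)
    KS = 0.5 * (KA + KB - S)
    if KS <= 0 or (KF - KS) / KF < 1e-12:
        # KF ~ KS only when the discriminant vanishes, i.e. I -> 0 with
        # KA = KB; fall back to the analytic confluent limit.
        return _association_signal(t, k1, k2, L, bmax)
    pre = bmax * k1 * L / (KF - KS)
    return pre * (
        k4 * (KF - KS) / (KF * KS)
        + ((k4 - KF) / KF) * np.exp(-KF * t)
        - ((k4 - KS) / KS) * np.exp(-KS * t)
    )


def fit_competitor_kinetics(traces: KineticTraceSet) -> KineticEstimate:
    """Globally fit k3, k4 and bmax across all traces of a set.

    The tracer constants k1, k2 are held fixed at their known values; all
    traces share one bmax, k3 and k4 (uniform weighting, untransformed
    signal).  Initialization: k3 = k1, k4 = k2, bmax from the observed
    plateau of the zero-competitor trace.
    """
    k1, k2 = traces.tracer.require_rates()
    if traces.competitor_concs.size < 3 or 0.0 not in traces.competitor_concs:
        raise ValueError(
            "need the zero-competitor trace plus >=2 competitor concentrations"
        )
    if traces.times.size < 8:
        raise ValueError("need >=8 time points")

    L = traces.tracer.conc
    occ = k1 * L / (k1 * L + k2)
    zero_col = int(np.nonzero(traces.competitor_concs == 0.0)[0][0])
    bmax0 = max(float(traces.signal[-1, zero_col]) / occ, 1e-12)

    params = lmfit.Parameters()
    params.add("log10_k3", value=np.log10(k1), min=np.log10(K3_BOUNDS[0]), max=np.log10(K3_BOUNDS[1]))
    params.add("log10_k4", value=np.log10(k2), min=np.log10(K4_BOUNDS[0]), max=np.log10(K4_BOUNDS[1]))
    params.add("bmax", value=bmax0, min=0.0)

    def residual(p):
        k3 = 10.0 ** p["log10_k3"].value
        k4 = 10.0 ** p["log10_k4"].value
        bmax = p["bmax"].value
        model = np.column_stack(
            [
                competitive_binding_signal(traces.times, traces.tracer, c, k3, k4, bmax)
                for c in traces.competitor_concs
            ]
        )
        return (model - traces.signal).ravel()

    result = lmfit.minimize(residual, params, method="leastsq")
    if not result.success:
        raise FitFailure(f"kinetic fit did not converge: {result.message}")

    k3 = 10.0 ** result.params["log10_k3"].value
    k4 = 10.0 ** result.params["log10_k4"].value
    ln10 = np.log(10.0)

    def _sem(name, value):
        err = result.params[name].stderr
        return None if err is None else value * ln10 * err

    koff_at_bound = k4 <= K4_BOUNDS[0] * (1 + 1e-6)
    return KineticEstimate(
        kon=k3,
        koff=k4,
        kon_sem=_sem("log10_k3", k3),
        koff_sem=_sem("log10_k4", k4),
        bmax=result.params["bmax"].value,
        koff_at_bound=koff_at_bound,
    )


def residence_time(koff: float) -> float:
    """Residence time RT = 1/koff (min); the mean receptor-complex lifetime."""
    if koff <= 0:
        raise ValueError(f"koff must be > 0, got {koff}")
    return 1.0 / koff


def kinetic_pkd(kon: float, koff: float) -> float:
    """Kinetically determined affinity, pKd = -log10(koff/kon)."""
    if kon <= 0 or koff <= 0:
        raise ValueError("kon and koff must be > 0")
    return -np.log10(koff / kon)
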