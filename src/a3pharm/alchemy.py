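"""Alchemical relative binding free energies.

Estimators for the free-energy change along an alchemical coupling
parameter lambda — thermodynamic integration (TI) over per-state mean
dU/dlambda, and the multistate Bennett acceptance ratio (MBAR) solved
self-consistently from cross-evaluated reduced potentials — plus the
two-state Bennett acceptance ratio (BAR) used as an independent check.

Relative binding free energies come from the thermodynamic cycle

    ddG_bind(0 -> 1) = dA_bound(0 -> 1) - dA_solvent(0 -> 1)

and are compared against experimental values derived from measured
affinities, ddG_exp = R*T*ln(Ki_1/Ki_0).

The MBAR self-consistency equations are

    f_k = -ln sum_n exp(-u_k(x_n)) / sum_l N_l exp(f_l - u_l(x_n))

iterated with log-sum-exp stabilization until max|df| < tol, with f_0
pinned to zero; the asymptotic covariance of the f_k is computed from the
sample weight matrix.  Production sampling is out of scope: ensembles come
from files or from the synthetic generators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.special import logsumexp

__all__ = [
    "LambdaEnsemble",
    "FreeEnergyLeg",
    "PerturbationResult",
    "CorrelationSummary",
    "ti_estimate",
    "mbar_free_energies",
    "bar_free_energy",
    "cycle_ddg",
    "ddg_exp_from_affinities",
    "correlation_summary",
    "write_ensemble",
    "read_ensemble",
]

#: Gas constant in kcal mol^-1 K^-1.
R_KCAL = 1.98720e-3

#: Default temperature (K) for converting affinities to free energies;
#: matches the membrane-protein simulation temperature.
DEFAULT_TEMPERATURE = 310.0


class ConvergenceError(RuntimeError):
    """Iterative estimator failed to converge; carries the residual."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


@dataclass
class LambdaEnsemble:
    """Samples from a ladder of alchemical intermediate states.

    ``u_kn[k, n]`` is the reduced (dimensionless) potential of sample ``n``
    evaluated in state ``k``; samples are concatenated in state order with
    ``n_k`` samples from each state.  ``dudl`` holds per-sample dU/dlambda
    in kcal/mol (may be None for ensembles meant only for MBAR), and
    ``beta`` is the inverse temperature in mol/kcal.
    """

    lambdas: np.ndarray
    n_k: np.ndarray
    u_kn: np.ndarray
    beta: float
    dudl: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        self.n_k = np.asarray(self.n_k, dtype=int)
        self.u_kn = np.asarray(self.u_kn, dtype=float)
        K = self.lambdas.size
        if K < 2:
            raise ValueError("need at least 2 lambda states")
        if np.any(np.diff(self.lambdas) <= 0):
            raise ValueError("lambdas must be strictly increasing")
        if not (self.lambdas[0] == 0.0 and self.lambdas[-1] == 1.0):
            raise ValueError("lambda grid must span [0, 1]")
        if self.n_k.size != K:
            raise ValueError("n_k length must equal number of states")
        N = int(self.n_k.sum())
        if self.u_kn.shape != (K, N):
            raise ValueError(f"u_kn shape {self.u_kn.shape} != ({K}, {N})")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if self.dudl is not None:
            self.dudl = np.asarray(self.dudl, dtype=float)
            if self.dudl.shape != (N,):
                raise ValueError("dudl must have one value per sample")

    @property
    def n_states(self) -> int:
        return self.lambdas.size

    def state_slices(self):
        edges = np.concatenate([[0], np.cumsum(self.n_k)])
        return [slice(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]


@dataclass
class FreeEnergyLeg:
    """Free-energy change of one alchemical transformation leg (kcal/mol)."""

    delta_a: float
    stderr: float
    leg: str = "bound"  # "bound" | "solvent"
    estimator: str = "TI"  # "TI" | "MBAR" | "BAR"
    label: str = ""


@dataclass
class PerturbationResult:
    """Calculated vs experimental ddG for one perturbation 'X -> Y'."""

    label: str
    ddg_calc: float
    ddg_exp: float
    ddg_calc_stderr: float | None = None

    @property
    def deviation(self) -> float:
        return abs(self.ddg_calc - self.ddg_exp)


@dataclass
class CorrelationSummary:
    """Agreement statistics between calculated and experimental ddG values."""

    r: float
    slope: float
    mue: float
    n: int


def ti_estimate(ensemble: LambdaEnsemble, leg: str = "bound", label: str = "") -> FreeEnergyLeg:
    """Thermodynamic integration: dA = integral of <dU/dlambda> over lambda.

    Trapezoidal quadrature over the per-state sample means; the standard
    error combines per-state standard errors with the trapezoid weights.
    """
    if ensemble.dudl is None:
        raise ValueError("ensemble carries no dU/dlambda samples; TI inapplicable")
    means = np.empty(ensemble.n_states)
    sems = np.empty(ensemble.n_states)
    for k, sl in enumerate(ensemble.state_slices()):
        x = ensemble.dudl[sl]
        means[k] = x.mean()
        sems[k] = x.std(ddof=1) / np.sqrt(x.size) if x.size > 1 else 0.0
    lam = ensemble.lambdas
    # trapezoid weights: w_k = (lam_{k+1} - lam_{k-1})/2 at interior points
    w = np.zeros_like(lam)
    w[0] = (lam[1] - lam[0]) / 2.0
    w[-1] = (lam[-1] - lam[-2]) / 2.0
    w[1:-1] = (lam[2:] - lam[:-2]) / 2.0
    delta_a = float(np.dot(w, means))
    stderr = float(np.sqrt(np.sum((w * sems) ** 2)))
    return FreeEnergyLeg(delta_a=delta_a, stderr=stderr, leg=leg, estimator="TI", label=label)


def _mbar_solve(u_kn, n_k, tol, max_iter):
    """Damped self-consistent iteration for the MBAR free energies f_k."""
    K = u_kn.shape[0]
    f = np.zeros(K)
    log_n = np.log(n_k)
    residual = np.inf
    for _ in range(max_iter):
        # log of the mixture denominator for each sample
        log_denom = logsumexp(log_n[:, None] + f[:, None] - u_kn, axis=0)
        f_new = -logsumexp(-u_kn - log_denom[None, :], axis=1)
        f_new -= f_new[0]
        residual = float(np.max(np.abs(f_new - f)))
        f = 0.5 * f + 0.5 * f_new  # damping guards oscillation on poor overlap
        f -= f[0]
        if residual < tol:
            # one clean undamped step so the returned f satisfies the
            # fixed point to ~tol
            log_denom = logsumexp(log_n[:, None] + f[:, None] - u_kn, axis=0)
            f = -logsumexp(-u_kn - log_denom[None, :], axis=1)
            f -= f[0]
            return f
    raise ConvergenceError(
        f"MBAR did not converge in {max_iter} iterations (residual {residual:.3e})",
        residual,
    )


def _mbar_covariance(u_kn, n_k, f):
    """Asymptotic covariance of the f_k from the N x K weight matrix."""
    log_n = np.log(n_k)
    log_denom = logsumexp(log_n[:, None] + f[:, None] - u_kn, axis=0)
    log_w = f[:, None] - u_kn - log_denom[None, :]  # K x N
    W = np.exp(log_w).T  # N x K, columns sum to 1/N_k scale: sum_n N_k W_nk = 1
    U, s, Vt = np.linalg.svd(W, full_matrices=False)
    V = Vt.T
    S = np.diag(s)
    inner = np.eye(len(s)) - S @ Vt @ np.diag(n_k) @ V @ S
    theta = V @ S @ np.linalg.pinv(inner, rcond=1e-10) @ S @ Vt
    return theta


def _overlap_warning(u_kn, n_k, f):
    """Warn when adjacent states share essentially no configuration space."""
    log_n = np.log(n_k)
    log_denom = logsumexp(log_n[:, None] + f[:, None] - u_kn, axis=0)
    log_w = f[:, None] - u_kn - log_denom[None, :]
    W = np.exp(log_w)  # K x N
    O = (n_k[:, None] * W) @ W.T  # K x K overlap matrix
    off = np.diag(O, 1)
    return bool(off.size and np.min(off) < 1e-3)


def mbar_free_energies(
    ensemble: LambdaEnsemble,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> tuple[np.ndarray, FreeEnergyLeg]:
    """Solve MBAR for all state free energies and the 0 -> 1 leg.

    Returns the dimensionless per-state free energies ``f_k`` (f_0 = 0) and
    a :class:`FreeEnergyLeg` for the end-state difference in kcal/mol with
    its covariance-based standard error.
    """
    u_kn = ensemble.u_kn
    n_k = ensemble.n_k.astype(float)
    f = _mbar_solve(u_kn, n_k, tol, max_iter)
    theta = _mbar_covariance(u_kn, n_k, f)
    var = theta[-1, -1] + theta[0, 0] - 2.0 * theta[0, -1]
    var = max(var, 0.0)
    if _overlap_warning(u_kn, n_k, f):
        warnings.warn(
            "poor phase-space overlap between adjacent lambda states; "
            "the MBAR standard error is unreliable (inflated 10x)"
        )
        var *= 100.0
    delta_a = (f[-1] - f[0]) / ensemble.beta
    stderr = float(np.sqrt(var)) / ensemble.beta
    leg = FreeEnergyLeg(delta_a=float(delta_a), stderr=stderr, estimator="MBAR")
    return f, leg


def bar_free_energy(w_forward, w_reverse) -> float:
    """Two-state Bennett acceptance ratio estimate of df (dimensionless).

    ``w_forward`` are reduced work values u_1(x) - u_0(x) for samples from
    state 0; ``w_reverse`` are u_0(x) - u_1(x) for samples from state 1.
    Solves the implicit BAR equation by bracketing root search.
    """
    w_f = np.asarray(w_forward, dtype=float)
    w_r = np.asarray(w_reverse, dtype=float)
    m = np.log(w_f.size / w_r.size)

    def bar_zero(df):
        # sum of Fermi functions; zero at the BAR solution
        lhs = logsumexp(-np.logaddexp(0.0, m + w_f - df))
        rhs = logsumexp(-np.logaddexp(0.0, -m + w_r + df))
        return lhs - rhs

    # exponential-averaging estimates bracket the BAR root generously
    lo = -logsumexp(-w_f) + np.log(w_f.size) - 50.0
    hi = logsumexp(-w_r) - np.log(w_r.size) + 50.0
    return float(optimize.brentq(bar_zero, lo, hi, xtol=1e-12, rtol=1e-14))


def cycle_ddg(bound: FreeEnergyLeg, solvent: FreeEnergyLeg) -> tuple[float, float]:
    """Thermodynamic-cycle relative binding free energy (kcal/mol).

    ddG_bind(0 -> 1) = dA_bound - dA_solvent; standard errors combine in
    quadrature.  Both legs must describe the same perturbation.
    """
    if bound.label != solvent.label:
        raise ValueError(
            f"mismatched perturbation labels: {bound.label!r} vs {solvent.label!r}"
        )
    ddg = bound.delta_a - solvent.delta_a
    err = float(np.hypot(bound.stderr, solvent.stderr))
    return float(ddg), err


def ddg_exp_from_affinities(
    ki_0: float, ki_1: float, temperature: float = DEFAULT_TEMPERATURE
) -> float:
    """Experimental ddG (kcal/mol) from two binding affinities.

    ddG(0 -> 1) = R*T*ln(Ki_1/Ki_0); negative means compound 1 binds
    tighter than compound 0.  Any common affinity unit works (the ratio is
    dimensionless).
    """
    if ki_0 <= 0 or ki_1 <= 0:
        raise ValueError("affinities must be > 0")
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    return R_KCAL * temperature * float(np.log(ki_1 / ki_0))


def correlation_summary(results: list[PerturbationResult]) -> CorrelationSummary:
    """Pearson r, regression slope (calc on exp) and mean unsigned error."""
    if len(results) < 3:
        raise ValueError("need >=3 perturbations for a correlation summary")
    calc = np.array([p.ddg_calc for p in results])
    exp = np.array([p.ddg_exp for p in results])
    r = stats.pearsonr(exp, calc).statistic
    slope = stats.linregress(exp, calc).slope
    mue = float(np.mean(np.abs(calc - exp)))
    return CorrelationSummary(r=float(r), slope=float(slope), mue=mue, n=len(results))


def write_ensemble(path, ensemble: LambdaEnsemble) -> None:
    """Write an ensemble to the plain-text exchange format.

    Header: ``# lambdas=l0,l1,... beta=<beta>``; one row per sample:
    state index, dU/dlambda (or nan), then u evaluated at every state.
    """
    K = ensemble.n_states
    with open(path, "w") as fh:
        lam = ",".join(f"{x:.10g}" for x in ensemble.lambdas)
        fh.write(f"# lambdas={lam} beta={ensemble.beta:.10g}\n")
        n = 0
        for k, sl in enumerate(ensemble.state_slices()):
            for j in range(sl.start, sl.stop):
                du = ensemble.dudl[j] if ensemble.dudl is not None else np.nan
                us = " ".join(f"{ensemble.u_kn[i, j]:.12g}" for i in range(K))
                fh.write(f"{k} {du:.12g} {us}\n")
                n += 1


def read_ensemble(path) -> LambdaEnsemble:
    """Read an ensemble written by :func:`write_ensemble`."""
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise ValueError("missing ensemble header line")
        fields = dict(tok.split("=") for tok in header[1:].split())
        lambdas = np.array([float(x) for x in fields["lambdas"].split(",")])
        beta = float(fields["beta"])
        data = np.loadtxt(fh, ndmin=2)
    K = lambdas.size
    states = data[:, 0].astype(int)
    order = np.argsort(states, kind="stable")
    data = data[order]
    states = states[order]
    n_k = np.bincount(states, minlength=K)
    dudl = data[:, 1]
    if np.all(np.isnan(dudl)):
        dudl = None
    u_kn = data[:, 2 : 2 + K].T
    return LambdaEnsemble(lambdas=lambdas, n_k=n_k, u_kn=u_kn, beta=beta, dudl=dudl)
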