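"""Synthetic assay-data generators with analytic ground truth.

Each generator produces data with exactly the statistical structure its
paired fitter assumes — the noise-free output lies on the fitter's model
surface to machine precision — plus a :class:`GroundTruth` record of the
true parameters, so that every downstream stage can be oracle-tested by
round-trip recovery.

Noise is additive Gaussian on the normalized response scale (assay data
are reported as mean +/- SEM of duplicates; no richer noise model is
warranted), and every generator is bit-reproducible under a fixed seed.
Replicates are independent noise draws sharing one ground truth, mirroring
assays conducted in duplicate.  Concentrations are molar throughout; nM
appears only at report boundaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import binding_kinetics as bk
from .binding_equilibrium import CompetitionBindingCurve, _one_site_response
from .binding_kinetics import KineticTraceSet, TracerParams
from .functional_pharm import DoseResponseCurve, DoseResponseSet, logistic3
from .alchemy import LambdaEnsemble

__all__ = [
    "NoiseSpec",
    "GroundTruth",
    "HarmonicModel",
    "GaussianModel",
    "UnsupportedModelError",
    "gen_equilibrium_curve",
    "gen_kinetic_traces",
    "gen_dose_response",
    "gen_lambda_ensemble",
    "gen_pk_timecourse",
    "write_curve_csv",
    "read_curve_csv",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian noise of standard deviation ``sd`` under ``seed``."""

    sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("noise sd must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class GroundTruth:
    """True parameter values behind a generated dataset."""

    params: dict = field(default_factory=dict)

    def __getitem__(self, key):
        return self.params[key]


class UnsupportedModelError(ValueError):
    """The requested toy model admits no closed-form free energy."""


# --------------------------------------------------------------------------
# equilibrium competition curves


def gen_equilibrium_curve(
    pki_true: float,
    tracer: TracerParams,
    conc_grid,
    noise: NoiseSpec = NoiseSpec(),
    top: float = 1.0,
    bottom: float = 0.0,
    n_replicates: int = 1,
) -> tuple[CompetitionBindingCurve, GroundTruth]:
    """One-site competition displacement curve(s) with known pKi.

    Noise-free response: top - (top-bottom)*[I]/([I] + IC50) with
    IC50 = Ki*(1 + [L]/Kd) — the exact surface the one-site fitter assumes.
    """
    conc = np.asarray(conc_grid, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("competitor concentrations must be strictly positive")
    if conc.size < 6 or np.log10(conc.max() / conc.min()) < 4:
        raise ValueError("conc_grid must have >=6 points spanning >=4 log units")
    clean = _one_site_response(conc, pki_true, top, bottom, tracer)
    rng = noise.rng()
    concs, resps, reps = [], [], []
    for r in range(n_replicates):
        y = clean + rng.normal(0.0, noise.sd, size=conc.size) if noise.sd > 0 else clean.copy()
        concs.append(conc)
        resps.append(y)
        reps.append(np.full(conc.size, r))
    curve = CompetitionBindingCurve(
        np.concatenate(concs), np.concatenate(resps), tracer, np.concatenate(reps)
    )
    truth = GroundTruth(
        {
            "pki": pki_true,
            "top": top,
            "bottom": bottom,
            "ic50": 10.0 ** (-pki_true) * (1.0 + tracer.conc / tracer.kd),
        }
    )
    return curve, truth


# --------------------------------------------------------------------------
# kinetic competition traces

#: Canonical kinetic assay design: plate-reader acquisition every 30 s over
#: a 2 h time course, competitor at 0 and 3-1000 nM, wells in duplicate.
#: Chosen by information analysis of the competition model: the competitor
#: off-rate is encoded in the decay of the early overshoot, so dense early
#: reads and concentrations bracketing the competitor Ki dominate the
#: attainable precision.
KINETIC_TIMES = np.arange(0.0, 120.0001, 0.5)
KINETIC_CONC_PANEL = np.array([0.0, 3e-9, 1e-8, 3e-8, 1e-7, 3e-7, 1e-6])


def gen_kinetic_traces(
    tracer: TracerParams,
    k3: float,
    k4: float,
    bmax: float,
    competitor_concs=None,
    times=None,
    noise: NoiseSpec = NoiseSpec(),
    n_replicates: int = 1,
) -> tuple[KineticTraceSet, GroundTruth]:
    """Time-resolved competition traces from the closed-form kinetic model.

    Defaults to the canonical design (KINETIC_TIMES x KINETIC_CONC_PANEL).
    Replicate wells appear as additional columns sharing a concentration.
    """
    if k3 <= 0 or k4 <= 0:
        raise ValueError("rate constants must be > 0")
    concs = np.asarray(
        KINETIC_CONC_PANEL if competitor_concs is None else competitor_concs, dtype=float
    )
    if 0.0 not in concs:
        raise ValueError("competitor_concs must include 0 (tracer-only control)")
    t = np.asarray(KINETIC_TIMES if times is None else times, dtype=float)
    clean = np.column_stack(
        [bk.competitive_binding_signal(t, tracer, c, k3, k4, bmax) for c in concs]
    )
    rng = noise.rng()
    cols = []
    for _ in range(n_replicates):
        cols.append(clean + rng.normal(0.0, noise.sd, size=clean.shape) if noise.sd > 0 else clean)
    signal = np.column_stack(cols)
    traces = KineticTraceSet(t, np.tile(concs, n_replicates), signal, tracer, bmax)
    truth = GroundTruth({"k3": k3, "k4": k4, "bmax": bmax})
    return traces, truth


def kinetic_recovery_study(
    tracer: TracerParams,
    k3: float,
    k4: float,
    sd: float,
    seed: int,
    n_experiments: int = 3,
):
    """Mean fitted (kon, koff) over independent duplicate experiments.

    Mirrors the assay convention of n independent repeats conducted in
    duplicate, each fitted separately and averaged.
    """
    kons, koffs = [], []
    for j in range(n_experiments):
        traces, _ = gen_kinetic_traces(
            tracer, k3, k4, 1.0, noise=NoiseSpec(sd, seed + j), n_replicates=2
        )
        est = bk.fit_competitor_kinetics(traces)
        kons.append(est.kon)
        koffs.append(est.koff)
    return float(np.mean(kons)), float(np.mean(koffs))


# --------------------------------------------------------------------------
# functional dose-response sets


def gen_dose_response(
    pec50: float,
    emax: float,
    basal: float,
    pkb_true: float,
    antagonist_concs,
    agonist_grid,
    noise: NoiseSpec = NoiseSpec(),
    mode: str = "stimulation",
    n_replicates: int = 1,
) -> tuple[DoseResponseSet, GroundTruth]:
    """Agonist curves shifted by a competitive antagonist with known pKB.

    Each curve is a three-parameter logistic whose EC50 is multiplied by the
    Gaddum dose ratio 1 + [B]/KB.  Replicate wells are concatenated points
    sharing the agonist grid.
    """
    if emax <= basal:
        raise ValueError("emax must exceed basal")
    b_concs = np.asarray(antagonist_concs, dtype=float)
    if np.any(b_concs < 0):
        raise ValueError("antagonist concentrations must be >= 0")
    agonist = np.asarray(agonist_grid, dtype=float)
    kb = 10.0 ** (-pkb_true)
    rng = noise.rng()
    curves = []
    for b in b_concs:
        shift = 1.0 + b / kb
        pec50_shifted = pec50 - np.log10(shift)
        clean = np.tile(logistic3(agonist, basal, emax, pec50_shifted), n_replicates)
        y = clean + rng.normal(0.0, noise.sd, size=clean.size) if noise.sd > 0 else clean
        curves.append(
            DoseResponseCurve(np.tile(agonist, n_replicates), y, antagonist_conc=float(b), mode=mode)
        )
    truth = GroundTruth(
        {"pec50": pec50, "emax": emax, "basal": basal, "pkb": pkb_true, "kb": kb}
    )
    return DoseResponseSet(curves), truth


#: Canonical functional-assay design: 16 agonist concentrations spanning
#: 0.1 pM - 1 mM, each well in duplicate.  The wide grid keeps the shifted
#: curves' plateaus observable out to a ~1000-fold dose ratio.
FUNCTIONAL_AGONIST_GRID = np.logspace(-13.0, -3.0, 16)


def schild_study(
    pkb_true: float,
    antagonist_concs,
    sd: float,
    seed: int,
    pec50: float = 8.0,
):
    """Generate and analyze one full Schild experiment; returns SchildResult.

    Duplicate wells on the canonical agonist grid; each curve fitted by the
    three-parameter logistic, dose ratios taken against the antagonist-free
    control.
    """
    from .functional_pharm import fit_logistic3, schild_regression

    drs, _ = gen_dose_response(
        pec50, 100.0, 0.0, pkb_true, [0.0] + list(antagonist_concs),
        FUNCTIONAL_AGONIST_GRID, NoiseSpec(sd, seed), n_replicates=2,
    )
    control = fit_logistic3(drs.curves[0])
    pairs = [
        (c.antagonist_conc, fit_logistic3(c).ec50 / control.ec50)
        for c in drs.curves[1:]
    ]
    return schild_regression(pairs)


# --------------------------------------------------------------------------
# alchemical toy ensembles


@dataclass(frozen=True)
class HarmonicModel:
    """1-D harmonic well with lambda-interpolated stiffness and center.

    U(lambda, x) = 1/2 * K(lambda) * (x - c(lambda))^2, K and c linear in
    lambda.  Analytic end-state free-energy difference:
    dA = (1/(2*beta)) * ln(K1/K0) kcal/mol (the center shift contributes
    nothing).  Supplies both dU/dlambda samples (TI) and cross-evaluated
    reduced potentials (MBAR).
    """

    k0: float = 1.0  # kcal/mol per unit length^2
    k1: float = 4.0
    c0: float = 0.0
    c1: float = 0.0
    beta: float = 1.0 / 0.61602  # mol/kcal at 310 K

    def __post_init__(self) -> None:
        if self.k0 <= 0 or self.k1 <= 0:
            raise ValueError("stiffnesses must be > 0")

    def stiffness(self, lam):
        return self.k0 + (self.k1 - self.k0) * lam

    def center(self, lam):
        return self.c0 + (self.c1 - self.c0) * lam

    @property
    def analytic_delta_a(self) -> float:
        return 0.5 * np.log(self.k1 / self.k0) / self.beta


@dataclass(frozen=True)
class GaussianModel:
    """Per-state Gaussian reduced potentials with stated means and widths.

    u_k(x) = (x - mu_k)^2 / (2 sigma_k^2); analytic
    dA = ln(sigma_0/sigma_K-1)/beta.  No dU/dlambda (MBAR/BAR only).
    """

    means: tuple
    sigmas: tuple
    beta: float = 1.0 / 0.61602

    def __post_init__(self) -> None:
        if len(self.means) != len(self.sigmas):
            raise ValueError("means and sigmas must have equal length")
        if any(s <= 0 for s in self.sigmas):
            raise ValueError("sigmas must be > 0")

    @property
    def analytic_delta_a(self) -> float:
        return np.log(self.sigmas[0] / self.sigmas[-1]) / self.beta


def gen_lambda_ensemble(
    n_states: int,
    samples_per_state: int,
    model,
    seed: int = 0,
) -> tuple[LambdaEnsemble, GroundTruth]:
    """Sample a toy alchemical ladder with a closed-form free energy.

    Supported models: :class:`HarmonicModel` (TI + MBAR) and
    :class:`GaussianModel` (MBAR only; its state count overrides
    ``n_states``).  Every sample's reduced potential is evaluated in every
    state (complete u_kn), and the analytic end-state dA is stored in the
    ground truth.
    """
    if n_states < 2:
        raise ValueError("need at least 2 lambda states")
    rng = np.random.default_rng(seed)

    if isinstance(model, HarmonicModel):
        lambdas = np.linspace(0.0, 1.0, n_states)
        beta = model.beta
        ks = model.stiffness(lambdas)
        cs = model.center(lambdas)
        dk = model.k1 - model.k0
        dc = model.c1 - model.c0
        xs, dudl = [], []
        for k_state in range(n_states):
            sd = 1.0 / np.sqrt(beta * ks[k_state])
            x = rng.normal(cs[k_state], sd, size=samples_per_state)
            disp = x - cs[k_state]
            xs.append(x)
            dudl.append(0.5 * dk * disp**2 - ks[k_state] * disp * dc)
        x_all = np.concatenate(xs)
        dudl = np.concatenate(dudl)
        u_kn = np.array([beta * 0.5 * ks[i] * (x_all - cs[i]) ** 2 for i in range(n_states)])
        n_k = np.full(n_states, samples_per_state)
        ens = LambdaEnsemble(lambdas, n_k, u_kn, beta, dudl)
        truth = GroundTruth({"delta_a": model.analytic_delta_a, "model": "harmonic"})
        return ens, truth

    if isinstance(model, GaussianModel):
        K = len(model.means)
        lambdas = np.linspace(0.0, 1.0, K)
        mus = np.asarray(model.means, dtype=float)
        sigmas = np.asarray(model.sigmas, dtype=float)
        xs = [rng.normal(mus[k], sigmas[k], size=samples_per_state) for k in range(K)]
        x_all = np.concatenate(xs)
        u_kn = np.array([(x_all - mus[i]) ** 2 / (2.0 * sigmas[i] ** 2) for i in range(K)])
        n_k = np.full(K, samples_per_state)
        ens = LambdaEnsemble(lambdas, n_k, u_kn, model.beta, None)
        truth = GroundTruth({"delta_a": model.analytic_delta_a, "model": "gaussian"})
        return ens, truth

    raise UnsupportedModelError(
        f"no closed-form free energy for model {type(model).__name__}"
    )


# --------------------------------------------------------------------------
# metabolic depletion time courses


def gen_pk_timecourse(
    t_half: float,
    times,
    noise: NoiseSpec = NoiseSpec(),
) -> tuple[pd.DataFrame, GroundTruth]:
    """First-order metabolic depletion: % remaining = 100*exp(-ln2*t/t_half)."""
    if t_half <= 0:
        raise ValueError("t_half must be > 0")
    t = np.asarray(times, dtype=float)
    clean = 100.0 * np.exp(-np.log(2.0) * t / t_half)
    rng = noise.rng()
    pct = clean + rng.normal(0.0, noise.sd, size=t.size) if noise.sd > 0 else clean
    df = pd.DataFrame({"time_min": t, "pct_remaining": pct})
    truth = GroundTruth({"t_half": t_half})
    return df, truth


# --------------------------------------------------------------------------
# plain-text exchange


def write_curve_csv(path, curve: CompetitionBindingCurve, truth: GroundTruth, noise: NoiseSpec | None = None, series_id: str = "curve") -> None:
    """Long-format CSV (series_id, x, y, replicate) plus a JSON sidecar."""
    df = pd.DataFrame(
        {
            "series_id": series_id,
            "x": curve.competitor_conc,
            "y": curve.response,
            "replicate": curve.replicate_id,
        }
    )
    df.to_csv(path, index=False)
    sidecar = {
        "ground_truth": truth.params,
        "tracer": {
            "conc": curve.tracer.conc,
            "kd": curve.tracer.kd,
            "k1": curve.tracer.k1,
            "k2": curve.tracer.k2,
        },
    }
    if noise is not None:
        sidecar["noise"] = {"sd": noise.sd, "seed": noise.seed}
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_curve_csv(path) -> tuple[CompetitionBindingCurve, GroundTruth]:
    """Read a curve + sidecar written by :func:`write_curve_csv`."""
    df = pd.read_csv(path)
    with open(str(path) + ".json") as fh:
        side = json.load(fh)
    tr = side["tracer"]
    tracer = TracerParams(conc=tr["conc"], kd=tr["kd"], k1=tr.get("k1"), k2=tr.get("k2"))
    curve = CompetitionBindingCurve(
        df["x"].to_numpy(), df["y"].to_numpy(), tracer, df["replicate"].to_numpy()
    )
    return curve, GroundTruth(side["ground_truth"])
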