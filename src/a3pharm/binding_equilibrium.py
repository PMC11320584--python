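"""Equilibrium competition-binding analysis.

Baseline correction of BRET ratios, one-site competition fitting with the
Cheng-Prusoff correction (IC50 -> Ki given the tracer concentration and
Kd), affinity-scale conversions, and mutant Delta-pKi records.
"""

from __future__ import annotations

from dataclasses import dataclass

import lmfit
import numpy as np

from .binding_kinetics import FitFailure, TracerParams

__all__ = [
    "CompetitionBindingCurve",
    "AffinityEstimate",
    "MutantRecord",
    "baseline_correct",
    "cheng_prusoff",
    "fit_one_site_ki",
    "pool_replicates",
    "pki_to_ki_nm",
    "ki_nm_to_pki",
    "delta_pki",
]


@dataclass
class CompetitionBindingCurve:
    """Baseline-corrected competition curve: response vs competitor conc (M)."""

    competitor_conc: np.ndarray
    response: np.ndarray
    tracer: TracerParams
    replicate_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.competitor_conc = np.asarray(self.competitor_conc, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.competitor_conc.shape != self.response.shape:
            raise ValueError("competitor_conc and response lengths differ")
        if np.any(self.competitor_conc <= 0):
            raise ValueError("competitor concentrations must be strictly positive")
        if self.replicate_id is None:
            self.replicate_id = np.zeros(self.response.shape, dtype=int)
        else:
            self.replicate_id = np.asarray(self.replicate_id)

    def replicates(self):
        """Yield (replicate label, single-replicate curve) pairs."""
        for rid in np.unique(self.replicate_id):
            m = self.replicate_id == rid
            order = np.argsort(self.competitor_conc[m])
            yield rid, CompetitionBindingCurve(
                self.competitor_conc[m][order],
                self.response[m][order],
                self.tracer,
            )


@dataclass
class AffinityEstimate:
    """One-site fit result on the pKi scale, with nM affinity for reporting."""

    pki: float
    pki_sem: float | None
    top: float
    bottom: float
    flagged_inestimable: bool = False

    @property
    def ki_nm(self) -> float:
        return pki_to_ki_nm(self.pki)


@dataclass
class MutantRecord:
    """Affinity change at a receptor point mutant relative to wild type.

    ``label`` carries the Ballesteros-Weinstein position, e.g. "L246(6.51)A";
    ``delta_pki`` = pKi(mutant) - pKi(WT), so negative means lost affinity.
    """

    label: str
    pki_mut: float
    pki_wt: float
    surface_expression_pct_wt: float | None = None

    @property
    def delta_pki(self) -> float:
        return delta_pki(self.pki_mut, self.pki_wt)

    @property
    def fold_change(self) -> float:
        """Fold change of Ki, always >= 1 (direction given by delta_pki sign)."""
        return 10.0 ** abs(self.delta_pki)


def baseline_correct(raw, nsb):
    """Subtract the nonspecific-binding signal ``nsb`` from a raw series."""
    raw = np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(raw)):
        raise ValueError("raw responses must be finite")
    return raw - nsb


def cheng_prusoff(ic50: float, tracer_conc: float, tracer_kd: float) -> float:
    """Ki = IC50 / (1 + [L]/Kd): competition IC50 corrected for tracer occupancy."""
    if ic50 <= 0 or tracer_conc <= 0 or tracer_kd <= 0:
        raise ValueError("ic50, tracer_conc and tracer_kd must all be > 0")
    return ic50 / (1.0 + tracer_conc / tracer_kd)


def _one_site_response(conc, pki, top, bottom, tracer: TracerParams):
    ki = 10.0 ** (-pki)
    ic50 = ki * (1.0 + tracer.conc / tracer.kd)
    return top - (top - bottom) * conc / (conc + ic50)


def fit_one_site_ki(curve: CompetitionBindingCurve) -> AffinityEstimate:
    """Least-squares one-site competition fit, parameterized directly in pKi.

    The displacement curve response = bottom + (top-bottom)/(1 + [I]/IC50)
    is fitted with IC50 tied to Ki through the Cheng-Prusoff relation, Hill
    slope fixed at 1.  Initialization: top/bottom from the response extrema,
    IC50 from the concentration closest to half-range.  Curves whose dynamic
    range is below ~3x the residual noise are flagged inestimable.
    """
    conc = curve.competitor_conc
    resp = curve.response
    if np.unique(conc).size < 6:
        raise ValueError("need >=6 distinct competitor concentrations")
    tracer = curve.tracer

    top0, bot0 = float(resp.max()), float(resp.min())
    half = 0.5 * (top0 + bot0)
    ic50_0 = conc[np.argmin(np.abs(resp - half))]
    ki0 = cheng_prusoff(float(ic50_0), tracer.conc, tracer.kd)

    params = lmfit.Parameters()
    params.add("pki", value=-np.log10(ki0), min=0.0, max=15.0)
    params.add("top", value=top0)
    params.add("bottom", value=bot0)

    def residual(p):
        return _one_site_response(conc, p["pki"].value, p["top"].value, p["bottom"].value, tracer) - resp

    result = lmfit.minimize(residual, params, method="leastsq")
    if not result.success:
        raise FitFailure(f"one-site fit did not converge: {result.message}")

    top = result.params["top"].value
    bottom = result.params["bottom"].value
    noise = float(np.std(result.residual))
    flagged = abs(top - bottom) < 3.0 * noise
    return AffinityEstimate(
        pki=result.params["pki"].value,
        pki_sem=result.params["pki"].stderr,
        top=top,
        bottom=bottom,
        flagged_inestimable=flagged,
    )


def pool_replicates(curve: CompetitionBindingCurve) -> AffinityEstimate:
    """Fit each replicate separately and report mean pKi +/- SEM across fits.

    Mirrors the convention of reporting mean +/- SEM over n independent
    assay repeats rather than SEM from a single pooled fit.
    """
    fits = [fit_one_site_ki(c) for _, c in curve.replicates()]
    pkis = np.array([f.pki for f in fits])
    sem = float(np.std(pkis, ddof=1) / np.sqrt(pkis.size)) if pkis.size > 1 else fits[0].pki_sem
    return AffinityEstimate(
        pki=float(pkis.mean()),
        pki_sem=sem,
        top=float(np.mean([f.top for f in fits])),
        bottom=float(np.mean([f.bottom for f in fits])),
        flagged_inestimable=any(f.flagged_inestimable for f in fits),
    )


def pki_to_ki_nm(pki: float) -> float:
    """Convert pKi (M scale) to Ki in nM: 10**(9 - pKi)."""
    return 10.0 ** (9.0 - pki)


def ki_nm_to_pki(ki_nm: float) -> float:
    """Inverse of :func:`pki_to_ki_nm`."""
    if ki_nm <= 0:
        raise ValueError(f"Ki must be > 0, got {ki_nm}")
    return 9.0 - np.log10(ki_nm)


def delta_pki(pki_mut: float, pki_wt: float) -> float:
    """Affinity change pKi(mutant) - pKi(WT); 10**|delta| is the fold change."""
    if not (np.isfinite(pki_mut) and np.isfinite(pki_wt)):
        raise ValueError("pKi values must be finite")
    return pki_mut - pki_wt
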