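"""Generate the synthetic assay datasets used by the downstream analyses.

Writes equilibrium competition curves, kinetic competition traces, cAMP
dose-response sets, toy alchemical ensembles and metabolic depletion time
courses — each with its ground-truth sidecar — under results/synthetic/.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from a3pharm import alchemy, binding_kinetics as bk, synthgen as sg

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"
OUT.mkdir(parents=True, exist_ok=True)


def main() -> None:
    eq_tracer = bk.TracerParams(conc=5e-9, kd=5e-9)
    grid = np.logspace(-11, -4.5, 12)

    # equilibrium curve for a high-affinity antagonist (true pKi 7.92)
    curve, truth = sg.gen_equilibrium_curve(
        7.92, eq_tracer, grid, sg.NoiseSpec(0.02, SEED), n_replicates=2
    )
    sg.write_curve_csv(OUT / "equilibrium_curve.csv", curve, truth, sg.NoiseSpec(0.02, SEED))
    print(f"equilibrium curve: 2 replicates x {grid.size} concs, true pKi {truth['pki']}")

    # kinetic traces under the canonical acquisition design (true k3/k4 of
    # the fastest, longest-residence compound in the series)
    traces, ktruth = sg.gen_kinetic_traces(
        bk.default_tracer(), 5.95e6, 0.046, 1.0,
        noise=sg.NoiseSpec(0.05, SEED + 1), n_replicates=2,
    )
    wide = pd.DataFrame(
        traces.signal,
        columns=[f"{c:g}|w{i}" for i, c in enumerate(traces.competitor_concs)],
    )
    wide.insert(0, "time_min", traces.times)
    wide.to_csv(OUT / "kinetic_traces.csv", index=False)
    print(f"kinetic traces: {traces.signal.shape[1]} wells x {traces.times.size} reads, "
          f"true kon {ktruth['k3']:.3g}, koff {ktruth['k4']:.3g}")

    # dose-response set for Schild analysis (true pKB 7.95)
    drs, dtruth = sg.gen_dose_response(
        8.0, 100.0, 0.0, 7.95, [0.0, 1e-7, 1e-6, 1e-5],
        sg.FUNCTIONAL_AGONIST_GRID, sg.NoiseSpec(2.0, SEED + 2), n_replicates=2,
    )
    rows = []
    for c in drs.curves:
        for a, r in zip(c.agonist_conc, c.response):
            rows.append({"agonist_conc": a, "response": r, "antagonist_conc": c.antagonist_conc})
    pd.DataFrame(rows).to_csv(OUT / "dose_response.csv", index=False)
    print(f"dose-response: {len(drs.curves)} curves, true pKB {dtruth['pkb']}")

    # toy alchemical ensemble with analytic free energy
    ens, etruth = sg.gen_lambda_ensemble(5, 2000, sg.HarmonicModel(), seed=SEED + 3)
    alchemy.write_ensemble(OUT / "lambda_ensemble.txt", ens)
    print(f"lambda ensemble: 5 states x 2000 samples, analytic dA {etruth['delta_a']:.4f} kcal/mol")

    # metabolic depletion time course (true t1/2 16.9 min)
    df, ptruth = sg.gen_pk_timecourse(16.9, np.arange(0, 61, 15.0), sg.NoiseSpec(1.0, SEED + 4))
    df.to_csv(OUT / "depletion.csv", index=False)
    print(f"depletion time course: {len(df)} points, true t1/2 {ptruth['t_half']} min")

    with open(OUT / "ground_truth.json", "w") as fh:
        json.dump(
            {"seed": SEED, "equilibrium": truth.params, "kinetics": ktruth.params,
             "functional": dtruth.params, "alchemy": etruth.params, "pk": ptruth.params},
            fh, indent=1,
        )


if __name__ == "__main__":
    main()
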