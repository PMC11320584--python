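"""Functional antagonism: logistic fits, dose-ratio pKB and Schild analysis.

Fits the synthetic cAMP dose-response set, derives single-concentration
pKB estimates and the full Schild regression (pA2, slope), and evaluates
the textbook worked example.  Writes results/schild.json.
"""

import json
import sys
from pathlib import Path

import pandas as pd

from a3pharm import functional_pharm as fp

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    df = pd.read_csv(ROOT / "results" / "synthetic" / "dose_response.csv")
    curves = [
        fp.DoseResponseCurve(g["agonist_conc"].to_numpy(), g["response"].to_numpy(), float(b))
        for b, g in df.groupby("antagonist_conc")
    ]
    drs = fp.DoseResponseSet(curves)
    control = fp.fit_logistic3(drs.control)
    print(f"control pEC50 {control.pec50:.2f}")

    pairs, pkbs = [], []
    for c in drs.curves[1:]:
        f = fp.fit_logistic3(c)
        dr = f.ec50 / control.ec50
        pkb = fp.pkb_dose_ratio(f.ec50, control.ec50, c.antagonist_conc)
        pairs.append((c.antagonist_conc, dr))
        pkbs.append(pkb)
        print(f"[B] {c.antagonist_conc:.0e} M: DR {dr:.1f}, pKB {pkb:.2f}")

    schild = fp.schild_regression(pairs)
    print(f"Schild regression: pA2 {schild.pa2:.2f}, slope {schild.slope:.3f} "
          f"({'consistent with' if 0.9 < schild.slope < 1.1 else 'deviating from'} "
          "simple competitive antagonism)")

    worked = fp.schild_regression([(1e-7, 2.0), (1e-6, 11.0), (1e-5, 101.0)])
    print(f"worked example: pA2 {worked.pa2:.3f}, slope {worked.slope:.3f}")

    with open(ROOT / "results" / "schild.json", "w") as fh:
        json.dump(
            {
                "control_pec50": control.pec50,
                "single_conc_pkb": pkbs,
                "pa2": schild.pa2,
                "slope": schild.slope,
                "worked_example": {"pa2": worked.pa2, "slope": worked.slope},
            },
            fh, indent=1,
        )


if __name__ == "__main__":
    main()
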