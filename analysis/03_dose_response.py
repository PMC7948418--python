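#!/usr/bin/env python
"""Concentration-response fits: forskolin-normalized cAMP and PKA-AUC curves.

Simulates matched 5-block cAMP studies for the three receptors with
generating parameters in the range reported for wildtype cells after 10-min
stimulation (Emax 24-54 %FSK, logEC50 -9.4 to -8.7, Hill ~0.9), fits the
4-parameter logistic per block, and summarizes parameters as mean +/- SEM.
Then builds a PKA-style dose-response from simulated FRET kinetic traces via
baseline-corrected AUC and fits the 3-parameter logistic.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from gpcrbias.assaysim import (
    KineticScenario,
    LigandPathwayParams,
    NoiseModel,
    simulate_concentration_response_study,
    simulate_kinetic_trace,
)
from gpcrbias.doseresponse import (
    ConcentrationResponse,
    auc_concentration_response,
    fit_logistic,
)

SEED = 33
OUT = Path("results/doseresponse")

# generating scenarios: (Emax %FSK, logEC50, Hill); tau chosen so the
# operational mean reproduces the stated logistic (n=1 mapping)
CAMP_SCENARIOS = {
    ("GLP-1R", "GLP-1"): (54.0, -9.3),
    ("GIPR", "GIP"): (47.0, -9.4),
    ("GCGR", "GCG"): (24.0, -8.7),
}
PKA_LOG_EC50 = {("GLP-1R", "GLP-1"): -10.9, ("GIPR", "GIP"): -10.1,
                ("GCGR", "GCG"): -10.3}


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, ((rec, lig), (emax, log_ec50)) in enumerate(CAMP_SCENARIOS.items()):
        tau = 3.0  # partial-system agonist: observed Emax = Em * tau/(1+tau)
        Em = emax * (1.0 + tau) / tau
        log_KA = log_ec50 + np.log10(1.0 + tau)
        p = LigandPathwayParams(lig, "cAMP", Em=Em, log_tau=np.log10(tau),
                                log_KA=log_KA)
        study = simulate_concentration_response_study(
            [p], n_blocks=5, noise=NoiseModel(0.05, 0.5, 0.05, seed=SEED + i))
        cr = ConcentrationResponse(lig, "cAMP",
                                   study[["concentration_M", "response", "block"]])
        fit = fit_logistic(cr, 4)
        s = fit.summary.set_index("parameter")
        rows.append((rec, lig, "cAMP_pct_fsk",
                     s.loc["e_max", "mean"], s.loc["e_max", "sem"],
                     s.loc["log_ec50", "mean"], s.loc["log_ec50", "sem"],
                     s.loc["hill", "mean"], s.loc["hill", "sem"]))
        print(f"{rec} + {lig} cAMP: Emax {s.loc['e_max','mean']:.0f} +/- "
              f"{s.loc['e_max','sem']:.0f} %FSK, logEC50 "
              f"{s.loc['log_ec50','mean']:.2f} +/- {s.loc['log_ec50','sem']:.2f}, "
              f"Hill {s.loc['hill','mean']:.2f}")

    for i, ((rec, lig), log_ec50) in enumerate(PKA_LOG_EC50.items()):
        tau = 10.0
        p = LigandPathwayParams(lig, "fret_pka", Em=100.0, log_tau=1.0,
                                log_KA=log_ec50 + np.log10(1.0 + tau))
        sc = KineticScenario(onset_rate=0.3)
        traces = []
        for b in range(1, 6):
            for j, c in enumerate([0.0, *np.logspace(-12, -7, 9)]):
                traces.append(simulate_kinetic_trace(
                    p, sc, c, NoiseModel(0.02, 0.0, 0.0,
                                         seed=SEED + 1000 * i + 20 * b + j),
                    well_id=f"B{b}-W{j}", block_id=f"B{b}"))
        cr = auc_concentration_response(traces, lig, "fret_pka")
        fit = fit_logistic(cr, 3)
        s = fit.summary.set_index("parameter")
        rows.append((rec, lig, "pka_auc_fold",
                     s.loc["e_max", "mean"], s.loc["e_max", "sem"],
                     s.loc["log_ec50", "mean"], s.loc["log_ec50", "sem"],
                     1.0, 0.0))
        print(f"{rec} + {lig} PKA (AUC): logEC50 {s.loc['log_ec50','mean']:.2f} "
              f"+/- {s.loc['log_ec50','sem']:.2f} (generating {log_ec50})")

    pd.DataFrame(rows, columns=[
        "receptor", "ligand", "assay", "e_max", "e_max_sem",
        "log_ec50", "log_ec50_sem", "hill", "hill_sem",
    ]).to_csv(OUT / "logistic_fits.csv", index=False)
    print(f"wrote {OUT}/logistic_fits.csv")


if __name__ == "__main__":
    main()
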