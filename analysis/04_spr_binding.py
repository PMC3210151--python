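#!/usr/bin/env python
"""Direct SPR binding analysis: global kinetic and equilibrium fits.

For each immobilized RON construct × MSPβ variant, simulates the standard
4–512 nM sensorgram series from the reference rate constants (1 RU noise),
runs the global 1:1 Langmuir fit, and separately refits the steady-state
isotherm generated from the reference equilibrium Kd.

Finding: across all four RON constructs the R689C substitution weakens
binding roughly 10-fold (kinetic Kd ~150–230 nM vs ~13–21 nM for wild
type), and the equilibrium-model estimates agree with the kinetic ones to
within the scale expected from their independent estimation.
"""

from pathlib import Path

import pandas as pd

from mechsnp import datasets, spr
from mechsnp import synthetic_data as synth

OUT = Path("results")
CONCS = list(datasets.STANDARD_CONCENTRATIONS_NM)
SCHED = spr.SensorgramSchedule(t_assoc=120.0, t_dissoc=120.0, dt=0.5)


def main() -> None:
    rows = []
    for i, ((construct, variant), (kon, koff, kd_langmuir, kd_eq)) in enumerate(
            datasets.RON_MSP_KINETICS.items()):
        curves = synth.gen_sensorgrams(kon, koff, 100.0, CONCS, SCHED,
                                       noise_sd=1.0, seed=100 + i)
        kin = spr.fit_kinetics_global(curves)
        table = {c: 100.0 * c / (kd_eq + c) for c in CONCS}
        eq = spr.fit_equilibrium(table)
        rows.append({
            "construct": construct, "variant": variant,
            "kon_1e5_per_M_s": round(kin.kon / 1e5, 2),
            "koff_1e-2_per_s": round(kin.koff / 1e-2, 2),
            "kd_kinetic_nM": round(kin.kd_nM, 1),
            "kd_equilibrium_nM": round(eq.kd_nM, 1),
            "scatchard_slope_per_nM": round(eq.scatchard_slope, 5),
        })
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "spr_binding_table.tsv", sep="\t", index=False)
    print("SPR binding table (results/spr_binding_table.tsv):")
    print(table.to_string(index=False))

    wt = table[table.variant == "wt"]["kd_kinetic_nM"]
    mut = table[table.variant == "R689C"]["kd_kinetic_nM"]
    print(f"\nwild-type kinetic Kd: {wt.min():.1f}–{wt.max():.1f} nM; "
          f"R689C: {mut.min():.1f}–{mut.max():.1f} nM "
          f"(~{mut.mean() / wt.mean():.0f}-fold weaker)")


if __name__ == "__main__":
    main()
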