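#!/usr/bin/env python
"""Thermal-stability analysis of the MSPβ variants from DSF melt curves.

Extracts Tm (derivative maximum) from replicate two-state curves generated
at each reference midpoint, tabulates group means and standard deviations,
forms the ΔTm contrasts (mutation effect, glycosylation effect), and
converts the mutation ΔTm into a ΔΔG range and unfolded-fraction fold
change.

Finding: the R689C substitution lowers Tm by ~1.6 K (glycosylated) and
~2.5 K (deglycosylated); pooled, that corresponds to ~0.4–0.8 kcal/mol of
destabilization, i.e. roughly a 3-fold increase in the unfolded population
at 298 K — far below the 2–3 kcal/mol typical of monogenic destabilizing
mutations (~100-fold).
"""

import json
from pathlib import Path

import numpy as np

from mechsnp import datasets, dsf
from mechsnp import synthetic_data as synth

OUT = Path("results")
FLAT = dict(baseline_folded=(0.0, 0.0), baseline_unfolded=(1.0, 0.0))


def melt_group(label: str, seed: int):
    tm, _ = datasets.MSP_MELTING_TEMPERATURES[label]
    params = synth.MeltGenParams(tm_C=tm, noise_sd=0.01, n_replicates=4, **FLAT)
    return [dsf.extract_tm(c, smoothing_window=21)
            for c in synth.gen_melt_curves(params, seed=seed, label=label)]


def main() -> None:
    labels = [l for l in datasets.MSP_MELTING_TEMPERATURES
              if l != "R689C_dimer_glycosylated"]
    groups = {label: melt_group(label, seed=i) for i, label in enumerate(labels)}
    table = dsf.melting_table(groups)
    table.to_csv(OUT / "melting_table.tsv", sep="\t", index=False)
    print("melting table (results/melting_table.tsv):")
    print(table.to_string(index=False))

    contrasts = [
        ("wt_glycosylated", "R689C_glycosylated", "mutation, glycosylated"),
        ("wt_deglycosylated", "R689C_deglycosylated", "mutation, deglycosylated"),
        ("wt_glycosylated", "wt_deglycosylated", "glycosylation, wild type"),
        ("R689C_glycosylated", "R689C_deglycosylated", "glycosylation, R689C"),
    ]
    stability = []
    print("\nΔTm contrasts:")
    for a, b, what in contrasts:
        comp = dsf.compare_groups(groups[a], groups[b])
        est = dsf.stability_estimate(comp.dtm_K)
        stability.append({"contrast": what, "dtm_K": round(comp.dtm_K, 3),
                          "ddg_low_kcal_mol": round(est.ddg_low_kcal, 3),
                          "ddg_high_kcal_mol": round(est.ddg_high_kcal, 3),
                          "fold_change_unfolded": round(est.fold_change_unfolded, 2)})
        print(f"  {what}: ΔTm = {comp.dtm_K:+.2f} K "
              f"-> ΔΔG {est.ddg_low_kcal:.2f}–{est.ddg_high_kcal:.2f} kcal/mol")

    mutation_dtms = [stability[0]["dtm_K"], stability[1]["dtm_K"]]
    low = min(dsf.ddg_from_dtm(d)[0] for d in mutation_dtms)
    high = max(dsf.ddg_from_dtm(d)[1] for d in mutation_dtms)
    mid_fold = dsf.unfolded_fold_change(0.5 * (low + high))
    print(f"\npooled mutation destabilization: {low:.2f}–{high:.2f} kcal/mol, "
          f"~{mid_fold:.1f}-fold more unfolded protein at 298 K")
    print(f"(monogenic scale, 2.73 kcal/mol: "
          f"~{dsf.unfolded_fold_change(2.73):.0f}-fold)")
    (OUT / "stability_report.json").write_text(json.dumps({
        "contrasts": stability,
        "pooled_mutation_ddg_kcal_mol": [round(low, 3), round(high, 3)],
        "fold_change_unfolded_midpoint": round(mid_fold, 2),
    }, indent=2))


if __name__ == "__main__":
    main()
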