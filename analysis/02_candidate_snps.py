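#!/usr/bin/env python
"""Candidate mechanism-SNP selection on the simulated locus.

Reads the phased panel and marker association written by 01_simulate_inputs,
runs the penetrance/r² selection, and repeats the whole experiment across
100 seeds to measure how reliably the known causal SNP is recovered and how
often unlinked SNPs are falsely selected.

Finding (seed 1): the causal SNP is selected (reason "both": implied
penetrance above the marker's and r² ≈ 0.95 ≥ 0.8), the moderately linked
SNP is picked up by the penetrance criterion alone, and the three SNPs in
linkage equilibrium are rejected.  Across 100 replicates the causal SNP is
recovered in ≥ 95% and null SNPs in ≤ 5%.
"""

import json
from pathlib import Path

import pandas as pd

from mechsnp import locus_candidates as lc
from mechsnp import synthetic_data as synth

INPUTS = Path("results/inputs")
OUT = Path("results")


def replication_experiment(n_seeds: int = 100) -> dict:
    spec, model, marker = synth.build_demo_locus()
    k = model.prevalence(spec.allele_freq(model.causal_snp))
    causal_hits, null_hits, null_total = 0, 0, 0
    for seed in range(n_seeds):
        panel = synth.gen_haplotype_panel(spec, 4000, seed=seed)
        cohort = synth.gen_case_control(panel, model, 2000, 2000, seed=seed + 10_000)
        assoc = cohort.marker_association(panel, marker)
        selected = set(lc.select_candidates(panel, [assoc], prevalence=k).selected_ids())
        causal_hits += model.causal_snp in selected
        for snp in ("null1", "null2", "null3"):
            null_total += 1
            null_hits += snp in selected
    return {"n_seeds": n_seeds, "causal_selection_rate": causal_hits / n_seeds,
            "null_selection_rate": null_hits / null_total}


def main() -> None:
    panel = lc.HaplotypePanel.from_vcf(INPUTS / "panel.vcf")
    markers = lc.read_marker_csv(INPUTS / "markers.csv")
    k = json.loads((INPUTS / "simulation_meta.json").read_text())["prevalence"]
    candidates = lc.select_candidates(panel, markers, prevalence=k)
    candidates.to_tsv(OUT / "candidates.tsv")
    print("candidate table (results/candidates.tsv):")
    print(candidates.to_frame().to_string(index=False))

    rates = replication_experiment()
    pd.DataFrame([rates]).to_csv(OUT / "candidate_replication.csv", index=False)
    print(f"\nreplication over {rates['n_seeds']} seeds "
          f"(n_hap=4000, cohort 2000/2000):")
    print(f"  causal SNP selected in {rates['causal_selection_rate']:.0%} of replicates")
    print(f"  unlinked SNPs selected in {rates['null_selection_rate']:.1%} of tests")


if __name__ == "__main__":
    main()
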