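"""Configuration-driven pipeline runs and the ``mechsnp`` command line.

Ties the stages together into reproducible runs: ``simulate`` writes every
synthetic input (phased VCF panel, marker CSV, sensorgram CSVs, melt-curve
CSVs, FASTA), and the analysis stages (``candidates``, ``dsf``,
``spr-kinetics``, ``spr-equilibrium``, ``spr-competition``, ``digest``)
read those files back and append their result tables to a JSON report with
a provenance block (config hash, seed, version).  Stages run independently:
a failing stage is recorded in the report and the run continues.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from . import __version__, datasets, dsf, locus_candidates as lc, proteoforms as pf, spr
from . import synthetic_data as synth

log = logging.getLogger("mechsnp")

STAGES = ("simulate", "candidates", "dsf", "spr-kinetics", "spr-equilibrium",
          "spr-competition", "digest")

_KNOWN_KEYS = {
    "": {"seed", "output_dir", "stages", "simulate", "candidates", "dsf",
         "spr", "digest"},
    "simulate": {"n_hap", "n_case", "n_control", "spr_construct", "spr_variant",
                 "spr_noise_sd_RU", "dsf_groups", "dsf_noise_sd_AU"},
    "candidates": {"prevalence", "r2_threshold"},
    "dsf": {"comparisons", "smoothing_window"},
    "spr": {"competition_a0_nM", "competition_s0_nM", "calibration_conc_nM",
            "initial_rate_window_s"},
    "digest": {"missed_cleavages"},
}


@dataclass
class RunConfig:
    """Validated run parameters; unknown keys are rejected."""

    seed: int = 0
    output_dir: str = "results/pipeline"
    stages: list[str] = field(default_factory=list)
    simulate: dict = field(default_factory=dict)
    candidates: dict = field(default_factory=dict)
    dsf: dict = field(default_factory=dict)
    spr: dict = field(default_factory=dict)
    digest: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _KNOWN_KEYS[""]
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for section in ("simulate", "candidates", "dsf", "spr", "digest"):
            sub = raw.get(section, {})
            bad = set(sub) - _KNOWN_KEYS[section]
            if bad:
                raise ValueError(f"unknown keys in [{section}]: {sorted(bad)}")
        stages = list(raw.get("stages", []))
        for s in stages:
            if s not in STAGES:
                raise ValueError(f"unknown stage {s!r}; choose from {STAGES}")
        return cls(seed=int(raw.get("seed", 0)),
                   output_dir=str(raw.get("output_dir", "results/pipeline")),
                   stages=stages,
                   simulate=dict(raw.get("simulate", {})),
                   candidates=dict(raw.get("candidates", {})),
                   dsf=dict(raw.get("dsf", {})),
                   spr=dict(raw.get("spr", {})),
                   digest=dict(raw.get("digest", {})))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        return {"seed": self.seed, "output_dir": self.output_dir,
                "stages": self.stages, "simulate": self.simulate,
                "candidates": self.candidates, "dsf": self.dsf,
                "spr": self.spr, "digest": self.digest}

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class AnalysisReport:
    """Per-stage result sections plus a provenance block."""

    sections: dict = field(default_factory=dict)
    errors: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {"sections": self.sections, "errors": self.errors,
             "provenance": self.provenance},
            indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload

    @classmethod
    def from_json(cls, path) -> "AnalysisReport":
        raw = json.loads(Path(path).read_text())
        return cls(sections=raw["sections"], errors=raw["errors"],
                   provenance=raw["provenance"])


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: RunConfig, out: Path) -> dict:
    p = cfg.simulate
    n_hap = int(p.get("n_hap", 2000))
    n_case = int(p.get("n_case", 2000))
    n_control = int(p.get("n_control", 2000))
    spec, model, marker_id = synth.build_demo_locus()
    panel = synth.gen_haplotype_panel(spec, n_hap, seed=cfg.seed)
    cohort = synth.gen_case_control(panel, model, n_case, n_control, seed=cfg.seed + 1)
    panel.to_vcf(out / "panel.vcf", chrom="3")
    lc.write_marker_csv([cohort.marker_association(panel, marker_id)],
                        out / "markers.csv")
    prevalence = model.prevalence(spec.allele_freq(model.causal_snp))
    (out / "simulation_meta.json").write_text(json.dumps(
        {"prevalence": prevalence, "causal_snp": model.causal_snp,
         "marker_snp": marker_id, "n_hap": n_hap,
         "n_case": n_case, "n_control": n_control}, indent=2))

    construct = p.get("spr_construct", "SPI")
    variant = p.get("spr_variant", "R689C")
    kon, koff, _, _ = datasets.RON_MSP_KINETICS[(construct, variant)]
    curves = synth.gen_sensorgrams(
        kon, koff, 100.0, list(datasets.STANDARD_CONCENTRATIONS_NM),
        spr.SensorgramSchedule(), noise_sd=float(p.get("spr_noise_sd_RU", 1.0)),
        seed=cfg.seed + 2)
    curves.write_csv(out / "spr", prefix="sensorgram")

    groups = p.get("dsf_groups", ["wt_glycosylated", "R689C_glycosylated"])
    melt_rows = []
    for gi, label in enumerate(groups):
        tm, _ = datasets.MSP_MELTING_TEMPERATURES[label]
        params = synth.MeltGenParams(tm_C=tm,
                                     noise_sd=float(p.get("dsf_noise_sd_AU", 0.01)))
        for ri, curve in enumerate(synth.gen_melt_curves(params, seed=cfg.seed + 10 + gi,
                                                         label=label)):
            name = f"melt_{label}_rep{ri + 1}.csv"
            dsf.write_melt_csv(curve, out / name)
            melt_rows.append({"file": name, "label": label})
    pd.DataFrame(melt_rows).to_csv(out / "melt_manifest.csv", index=False)

    template, _ = synth.gen_msp_beta_analog(seed=cfg.seed)
    wt = pf.apply_substitutions(template, {672: "S"})
    mutant = pf.apply_substitutions(wt, {689: "C"})
    wt = pf.ProteinSequence("MSPbeta_wt_analog", wt.sequence, wt.offset)
    mutant = pf.ProteinSequence("MSPbeta_R689C_analog", mutant.sequence, mutant.offset)
    pf.write_fasta([wt, mutant], out / "mspbeta_analogs.fasta")
    return {"n_hap": n_hap, "n_case": n_case, "n_control": n_control,
            "prevalence": prevalence, "spr_row": f"{construct}/{variant}",
            "dsf_groups": list(groups)}


def _stage_candidates(cfg: RunConfig, out: Path) -> dict:
    panel = lc.HaplotypePanel.from_vcf(out / "panel.vcf")
    markers = lc.read_marker_csv(out / "markers.csv")
    meta_path = out / "simulation_meta.json"
    if cfg.candidates.get("prevalence") is not None:
        prevalence = float(cfg.candidates["prevalence"])
    elif meta_path.exists():
        prevalence = float(json.loads(meta_path.read_text())["prevalence"])
    else:
        prevalence = 0.005
    result = lc.select_candidates(
        panel, markers, prevalence=prevalence,
        r2_threshold=float(cfg.candidates.get("r2_threshold", 0.8)))
    result.to_tsv(out / "candidates.tsv")
    table = result.to_frame()
    table = table.astype(object).where(pd.notna(table), None)   # NaN is not valid JSON
    return {"prevalence": prevalence,
            "n_snps": len(result.records),
            "selected": result.selected_ids(),
            "table": table.to_dict(orient="records")}


def _stage_dsf(cfg: RunConfig, out: Path) -> dict:
    manifest = pd.read_csv(out / "melt_manifest.csv")
    window = int(cfg.dsf.get("smoothing_window", 5))
    groups: dict[str, list[dsf.MeltResult]] = {}
    for _, row in manifest.iterrows():
        curve = dsf.read_melt_csv(out / row["file"], label=row["label"])
        groups.setdefault(row["label"], []).append(dsf.extract_tm(curve, window))
    table = dsf.melting_table(groups)
    table.to_csv(out / "melting_table.tsv", sep="\t", index=False)
    labels = list(groups)
    comparisons = cfg.dsf.get(
        "comparisons", [[labels[0], labels[1]]] if len(labels) >= 2 else [])
    stability = []
    for a, b in comparisons:
        comp = dsf.compare_groups(groups[a], groups[b])
        est = dsf.stability_estimate(comp.dtm_K)
        stability.append({
            "group_a": a, "group_b": b, "dtm_K": comp.dtm_K,
            "ddg_low_kcal_mol": est.ddg_low_kcal, "ddg_high_kcal_mol": est.ddg_high_kcal,
            "fold_change_unfolded": est.fold_change_unfolded,
        })
    (out / "stability_report.json").write_text(json.dumps(stability, indent=2))
    return {"melting_table": table.to_dict(orient="records"),
            "stability": stability}


def _stage_spr_kinetics(cfg: RunConfig, out: Path) -> dict:
    curves = spr.SensorgramSet.read_csv(out / "spr" / "sensorgram_manifest.csv")
    fit = spr.fit_kinetics_global(curves)
    return {"kon_per_M_s": fit.kon, "koff_per_s": fit.koff, "rmax_RU": fit.rmax,
            "kd_nM": fit.kd_nM,
            "residual_rms_RU": {str(k): v for k, v in fit.residual_rms.items()}}


def _stage_spr_equilibrium(cfg: RunConfig, out: Path) -> dict:
    curves = spr.SensorgramSet.read_csv(out / "spr" / "sensorgram_manifest.csv")
    req = {c.conc_nM: spr.steady_state_response(c) for c in curves}
    fit = spr.fit_equilibrium(req)
    return {"kd_nM": fit.kd_nM, "rmax_RU": fit.rmax,
            "scatchard_slope_per_nM": fit.scatchard_slope,
            "ill_conditioned": fit.ill_conditioned}


def _stage_spr_competition(cfg: RunConfig, out: Path) -> dict:
    """Solution-competition workflow on synthetic mixtures: calibrate initial
    rates against concentration, deplete the analyte with a competitor at the
    direct-fit Kd, read free analyte back through the calibration, and fit
    the solution affinity."""
    p = cfg.spr
    curves = spr.SensorgramSet.read_csv(out / "spr" / "sensorgram_manifest.csv")
    kin = spr.fit_kinetics_global(curves)
    window = float(p.get("initial_rate_window_s", 2.0))
    a0 = float(p.get("competition_a0_nM", round(kin.kd_nM, 1)))
    # calibration spans the range where the free analyte will fall (<= A0),
    # so the finite-window rate bias cancels on inversion
    cal_conc = p.get("calibration_conc_nM",
                     [round(f * a0, 3) for f in (0.15, 0.25, 0.4, 0.6, 0.8, 1.0, 1.25)])
    schedule = spr.SensorgramSchedule(t_assoc=30.0, t_dissoc=30.0, dt=0.1)
    rates = [(c, spr.initial_rate(
        spr.langmuir_response(kin.kon, kin.koff, kin.rmax, c, schedule), window))
        for c in cal_conc]
    cal = spr.calibration_fit(rates)
    s0 = np.asarray(p.get("competition_s0_nM",
                          list(np.geomspace(0.1, 10000.0, 12))), dtype=float)
    free_true = spr.solution_free_analyte(a0, s0, kin.kd_nM)
    measured = []
    for f in free_true:
        conc = max(float(f), 1e-3)
        rate = spr.initial_rate(
            spr.langmuir_response(kin.kon, kin.koff, kin.rmax, conc, schedule), window)
        est, _ = cal.conc_for_rate(rate)
        measured.append(min(max(est, 0.0), a0))
    series = spr.CompetitionSeries(a_total_nM=a0, s_total_nM=s0,
                                   free_nM=np.array(measured))
    fit = spr.fit_solution_affinity(series)
    pd.DataFrame({"s0_nM": s0, "free_nM": measured}).to_csv(
        out / "competition_series.csv", index=False)
    return {"kd_solution_nM": fit.kd_nM, "kd_direct_nM": kin.kd_nM,
            "a_total_nM": a0, "ill_conditioned": fit.ill_conditioned}


def _stage_digest(cfg: RunConfig, out: Path) -> dict:
    sequences = pf.read_fasta(out / "mspbeta_analogs.fasta")
    topology = pf.DisulfideTopology(bonds=tuple(datasets.MSP_DISULFIDES))
    mc = int(cfg.digest.get("missed_cleavages", 0))
    section = {}
    for seq in sequences:
        fragments = pf.tryptic_digest(seq, missed_cleavages=mc,
                                      fixed_mods={"C": pf.CARBAMIDOMETHYL_C})
        free = pf.free_cysteines(seq, topology)
        section[seq.identifier] = {
            "n_fragments": len(fragments),
            "free_cysteines": free,
            "sequons": pf.find_sequons(seq),
            "cys_peptides": [
                {"sequence": f.sequence, "start": f.start_label, "end": f.end_label,
                 "mass_mono_Da": round(f.mass_mono, 4)}
                for f in fragments if "C" in f.sequence],
        }
    for label, (measured, calculated) in datasets.MSP_MASSES_DA.items():
        delta = pf.mass_delta(measured, calculated)
        section[f"mass_delta_{label}"] = {
            "measured_Da": measured, "calculated_Da": calculated,
            "delta_Da": delta.delta_Da,
            "sugar_units": [delta.units_low, delta.units_high]}
    return section


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "candidates": _stage_candidates,
    "dsf": _stage_dsf,
    "spr-kinetics": _stage_spr_kinetics,
    "spr-equilibrium": _stage_spr_equilibrium,
    "spr-competition": _stage_spr_competition,
    "digest": _stage_digest,
}


def run_pipeline(config: RunConfig) -> AnalysisReport:
    """Execute the configured stages in order and write ``report.json``.

    Stage errors are captured per stage; independent stages still run.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = AnalysisReport(provenance={
        "config_hash": config.hash(), "seed": config.seed,
        "version": __version__, "config": config.to_dict(),
    })
    for stage in config.stages:
        log.info("running stage %s", stage)
        try:
            report.sections[stage] = _STAGE_FUNCS[stage](config, out)
        except Exception as exc:  # noqa: BLE001 - reported per stage
            log.error("stage %s failed: %s", stage, exc)
            report.errors[stage] = str(exc)
    report.to_json(out / "report.json")
    return report


# ---------------------------------------------------------------------------
# command line
# ---------------------------------------------------------------------------

def _setup_logging(quiet: bool, debug: bool) -> None:
    level = logging.DEBUG if debug else logging.WARNING if quiet else logging.INFO
    logging.basicConfig(stream=sys.stderr, level=level,
                        format="%(levelname)s %(name)s: %(message)s")


@click.group()
@click.option("--quiet", is_flag=True, help="Only warnings and errors.")
@click.option("--debug", is_flag=True, help="Verbose logging.")
def main(quiet: bool, debug: bool) -> None:
    """Candidate mechanism-SNP characterization pipeline."""
    _setup_logging(quiet, debug)


def _run_stages(stages: list[str], config_path, seed, output_dir) -> None:
    if config_path:
        config = RunConfig.from_yaml(config_path)
    else:
        config = RunConfig()
    if seed is not None:
        config.seed = seed
    if output_dir is not None:
        config.output_dir = output_dir
    if stages:
        config.stages = stages
    report = run_pipeline(config)
    if report.errors:
        raise click.ClickException(f"stage errors: {report.errors}")
    click.echo(str(Path(config.output_dir) / "report.json"))


def _stage_command(name: str, help_text: str):
    @main.command(name=name, help=help_text)
    @click.option("--config", "config_path", type=click.Path(exists=True), default=None)
    @click.option("--seed", type=int, default=None)
    @click.option("--output-dir", type=click.Path(), default=None)
    def _cmd(config_path, seed, output_dir, _name=name):
        _run_stages([_name], config_path, seed, output_dir)
    return _cmd


_stage_command("simulate", "Generate all synthetic inputs.")
_stage_command("candidates", "LD/penetrance candidate SNP selection.")
_stage_command("dsf", "Melt-curve Tm extraction and stability comparison.")
_stage_command("spr-kinetics", "Global 1:1 Langmuir kinetic fit.")
_stage_command("spr-equilibrium", "Steady-state isotherm fit.")
_stage_command("spr-competition", "Solution-competition affinity fit.")
_stage_command("digest", "Tryptic digest / sequon / free-cysteine bookkeeping.")


@main.command(name="run")
@click.option("--config", "config_path", type=click.Path(exists=True), required=True)
@click.option("--seed", type=int, default=None)
@click.option("--output-dir", type=click.Path(), default=None)
def run_cmd(config_path, seed, output_dir):
    """Run every stage listed in a YAML config."""
    _run_stages([], config_path, seed, output_dir)


@main.command(name="report")
@click.argument("report_path", type=click.Path(exists=True))
def report_cmd(report_path):
    """Summarize a saved report.json."""
    report = AnalysisReport.from_json(report_path)
    click.echo(f"config hash: {report.provenance.get('config_hash')}")
    click.echo(f"stages: {sorted(report.sections)}")
    for stage, err in report.errors.items():
        click.echo(f"ERROR in {stage}: {err}")


if __name__ == "__main__":
    main()
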