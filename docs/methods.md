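# Methods

This note records the models behind each module, the parameter choices and
their defaults, what the synthetic generators do and do not emulate, and
the numerical decisions a maintainer would want to know.

## Candidate selection from penetrance and LD

**Model.** Penetrance is allele-level throughout: P(D|a) is the probability
of disease given carriage of allele *a* on a haplotype.  From a marker's
case/control allele frequencies and a user-supplied prevalence *K*, Bayes
gives P(m) = K·f_case + (1−K)·f_control, P(D|m) = K·f_case/P(m), and
P(D|m̄) = K·(1−f_case)/(1−P(m)); prevalence conservation
K = P(D|m)P(m) + P(D|m̄)(1−P(m)) is an exact identity of this estimator and
is enforced to 1e-12 in tests.  For each other SNP *c*, the two-equation
system in the README is solved for the penetrance x = P(D|c) that the
candidate would need in order to generate the observed marker signal, with
P(c|m) = h_cm/f_m taken from the phased panel.  A SNP is selected when the
solution is feasible (x and y both in [0,1]) and x ≥ P(D|m) (relative
tolerance 1e-9), or when r² with a marker reaches the threshold
(≥ 0.8, inclusive).

**Why feasibility matters.** For any SNP positively correlated with a risk
marker, x ≥ P(D|m) holds identically whenever P(c|m) > f_c — x decreases
monotonically from +∞ (at independence) to P(D|m) (at complete LD).  The
constraint that y = (K − x·f_c)/(1−f_c) must also be a probability bounds
x ≤ K/f_c and is what rejects unlinked SNPs: at panel size 4000 their
empirical P(c|m) sits several standard errors below the feasibility
boundary.  This behaviour is measured, not assumed: the replication
experiment (100 seeds, n_hap = 4000, 2000/2000 cohort) selects the causal
SNP in ≥ 95% of replicates and unlinked SNPs in ≤ 5% of tests.

**Choices.** The candidate risk allele is oriented per marker as the allele
with D > 0 (positive association with the marker risk allele); r² is
orientation-invariant.  Monomorphic candidates are reported with reason
"none" and a flag, never dropped; a monomorphic marker is an error.  LD
statistics follow the standard definitions D = h_ab − f_a·f_b,
r² = D²/(f_a(1−f_a)f_b(1−f_b)), D′ = D/D_max; for a monomorphic SNP r² is
NaN with a `defined=False` flag rather than 0.  Default prevalence is
0.005 (a Crohn's-like figure) when no study value is supplied; the
pipeline uses the exact prevalence implied by its own disease model.  How
the original penetrance screen estimated P(D|m) is not specified anywhere
we could follow; the Bayes estimator above is one defensible reading and
is documented as such, and no confidence-interval logic is implemented.

## Synthetic population data

Haplotypes are drawn i.i.d. from an explicit haplotype-frequency table, so
every LD statistic has an exact analytic value and panel statistics
converge to it (tested).  Individuals are random haplotype pairs; disease
is dominant with carrier/non-carrier penetrances (x, y), and case/control
cohorts are filled by rejection sampling with a draw bound.  The demo
locus has seven SNPs: marker and causal at allele frequency 0.3 with
r² = 0.95 (matching the near-complete LD of the motivating marker/
mechanism pair), one SNP at r² ≈ 0.52, one rare recombinant, and three
unlinked SNPs; penetrances are x = 0.012, y = 0.0095 (population
prevalence ≈ 1.1%), a weak common-disease-sized effect.  Cohort size
defaults to 2000/2000.  Not emulated: recombination/coalescent structure,
genotyping error, imputation uncertainty, multi-allelic sites — so passing
tests show the selection rule behaves correctly given clean phased data,
not that it is robust to real-panel artifacts.

## SPR binding analysis

**Kinetics.** The 1:1 Langmuir model is used in closed form: association
R(t) = Req(1 − e^(−(konC+koff)t)) with Req = Rmax·konC/(konC+koff), and
single-exponential dissociation.  Agreement with numeric integration of
dR/dt = kon·C(Rmax−R) − koff·R is < 1e-6 RU (tested).  The global fit
shares (kon, koff, Rmax) across all concentrations and both phases,
parameterized as logs so positivity is structural, solved with
trust-region least squares (xtol/ftol/gtol 1e-14).  Initialization is a
linearized estimate (koff from the dissociation log-slope, kon from a
kobs-vs-C regression with kobs from the 63%-of-plateau time, Rmax from
occupancy-corrected plateaus); a fixed 3×3 multi-start grid over
(kon, koff) backs it up and the best solution is kept, so fits are
deterministic.  Kd = koff/kon is exact by construction.  A per-curve bulk
offset and mass-transport or bivalent models are out of scope.

**Equilibrium.** Req = Rmax·C/(Kd+C) is fitted in log-parameters; on
synthetic data Req is the model plateau, on measured-style data the mean
of the last 5 s of association.  The Scatchard regression (Req/C vs Req)
is reported alongside; its slope is −1/Kd for ideal data.  The fit is
flagged ill-conditioned when the concentration series never reaches the
fitted Kd.  The reference table's equilibrium Kd values differ from
koff/kon by design of the source instrument software; each column is
treated on its own terms.

**Competition.** Free analyte in an A + S ⇌ AS mixture is the positive
root A_f = [(A0−S0−Kd) + √((A0−S0−Kd)² + 4·Kd·A0)]/2; mass balance and
detailed balance hold to 1e-9 (property-tested).  The workflow calibrates
initial binding rates (default 2 s window) against concentration over a
range spanning the analyte level — calibrating over the same range where
the free analyte falls makes the finite-window rate bias cancel on
inversion — then fits Kd (log-parameterized) to the free-analyte-vs-S0
series with A0 fixed at its nominal value by default (co-fitting A0 is an
option).  Competitor series default to 0.1–10,000 nM log-spaced.

**Units.** Concentrations are nM at every interface and molar internally;
kon is 1/(M·s), koff 1/s, responses RU.

## DSF thermal-stability analysis

**Tm extraction.** Tm is the maximum of dF/dT.  The derivative is computed
with a Savitzky–Golay quadratic differentiating filter of odd window
(default 5 points; windows < 5 fall back to centered differences), then
smoothed once more with the same window, and the maximum is refined by a
parabola fitted over the contiguous region where the derivative stays
above 75% of its peak.  The default window suits clean curves; for noise
at the percent-of-amplitude scale a ~2 K window (21 points on a 0.2 °C
grid) keeps four-replicate means within 0.2 °C of truth (tested).  A
derivative maximum on the grid boundary is flagged as a truncated
transition.  On noiseless two-state curves with flat baselines the
extractor is accurate to ~0.06 K (the residual comes from the slight
asymmetry of the van't Hoff sigmoid in T); sloped baselines shift the
derivative maximum by up to ~0.2 K for the default generator baselines —
a property of the derivative-max definition itself, which cancels almost
fully in ΔTm between groups.  Derivative traces can be normalized to % of
the experiment-set maximum for display; this never affects Tm.

**Generator.** Curves are two-state van't Hoff melts,
f_u(T) = 1/(1+exp(ΔH/R·(1/T − 1/Tm))) with temperatures in kelvin inside
the exponent, linear folded/unfolded baselines, no ΔCp term, and additive
Gaussian noise; replicates differ only by noise.  Defaults: ΔH = 100
kcal/mol (typical small-domain scale), 30–90 °C grid at 0.2 °C, noise sd
0.01 AU on a unit amplitude, four replicates (matching the replicate count
of the reference melting table).  Aggregation, dye-binding kinetics and
post-transition decay are not modeled, so the tests validate midpoint
extraction, not full-curve thermodynamic fitting.

**Stability conversion.** ΔTm (K) maps to a ΔΔG range via the empirical
3–4 K per kcal/mol conversion: [ΔTm/4, ΔTm/3].  Negative shifts are
converted on magnitude with a "stabilizing" flag.  The unfolded-fraction
fold change is exp(ΔΔG/RT) with R = 1.987e-3 kcal/(mol·K) and reference
T = 298 K (no temperature is stated for this argument in the source; 298 K
is the conventional choice).  Single-number summaries use the range
midpoint.  Note the two mutation contrasts pool to 0.40–0.83 kcal/mol:
the glycosylated shift alone (1.6 K) gives 0.40–0.53, so the often-quoted
0.5–0.8 figure is only reproduced when the deglycosylated shift (2.5 K)
is pooled in; both readings are computable and neither is asserted.  A
1.5-vs-1.6 K discrepancy in the dimer comparison of the source table is
noted and left unresolved; the dimer group is excluded from the analyses.

## Proteoform bookkeeping

Trypsin cleaves C-terminal to Lys/Arg with cleavage suppressed before Pro
(the standard rule; a strict no-protection mode exists).  Missed cleavages
are enumerated up to a requested count; zero-missed fragments partition
the sequence exactly and fragment masses recombine to the intact mass
minus (n−1) waters (both property-tested, and the digest is cross-checked
against an independent cleavage-rule implementation).  Masses use the
standard monoisotopic/average residue tables with water 18.010565/18.0153
Da; carbamidomethyl-Cys (+57.02146 Da) is the supported fixed modification
(no variable-modification enumeration).  Sequon scanning matches N-X-[S/T]
with overlaps reported; the common X ≠ Pro refinement is an opt-in flag,
off by default.  Residue coordinates carry a numbering offset so outputs
on the MSPβ construct (residues 465–711) read "Cys689".  Free cysteines
are the set difference between the sequence's cysteines and the disulfide
topology, with validation that bonds name cysteines and no residue is
double-bonded.  Sugar-unit counting brackets Δmass/unit with unit mass
162.053 Da (anhydro-hexose) by default, 203.079 Da (HexNAc) selectable.
The real MSPβ sequence is not bundled: a synthetic stand-in with the
native cysteine coordinates, the Arg687–Arg696 tryptic context and the
Asn615 sequon is generated under seed (`gen_msp_beta_analog`; labelled
synthetic), which is sufficient for every positional bookkeeping result;
only whole-chain masses of the real construct would differ, and those
enter solely through the measured/calculated constants.  The residue
context (…Trp-Pro-Ala…) is followed for the Cys689 peptide, giving
SCWPAVFTR (688–696).

## Pipeline

Runs are driven by a validated YAML config (unknown keys rejected, every
stochastic step seeded from one seed with fixed offsets).  Reports are
JSON with per-stage sections, per-stage error capture (independent stages
continue), and a provenance block (config hash, seed, version) sufficient
to re-run exactly; payloads are byte-identical under a fixed seed.  NaN is
converted to null on serialization.

## Problem sizes

Defaults were chosen at desk scale: panels of 2000–4000 haplotypes,
2000/2000 cohorts, 100-replicate selection experiments, eight-curve
sensorgram series at 0.5 s sampling, and four-replicate melt curves; the
full test suite and the acceptance script each complete in well under a
minute on one CPU.

## Known limitations

- The penetrance estimator and the diploid-dominant cohort model are
  defensible interpretations, not reconstructions of the original screen;
  no interval/uncertainty logic on penetrance is provided.
- LD is computed within one locus from phased data only; unphased input is
  rejected rather than phased or imputed.
- The SPR models exclude mass transport, bivalent/avidity binding, drift
  beyond an optional linear term, and reference-cell artifacts.
- DSF analysis extracts midpoints only; it does not fit ΔH/ΔCp from data.
- Glycan accounting counts sugar-unit equivalents; no glycan structures.
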