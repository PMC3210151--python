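"""Synthetic inputs for every stage of the pipeline.

Generates, under explicit seeds: phased haplotype panels drawn from an
explicit haplotype-frequency table (so every LD statistic has an exact
analytic value), case/control cohorts under a diploid dominant disease
model, noisy 1:1 Langmuir SPR sensorgrams, replicate two-state DSF melting
curves, and protein sequences with planted cysteines and N-glycosylation
sequons.  These stand in for the study's population panel and raw
instrument data, which have no deposited accessions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dsf import CELSIUS_OFFSET, R_KCAL, MeltCurve
from .locus_candidates import HaplotypePanel, MarkerAssociation
from .proteoforms import AMINO_ACIDS, DisulfideTopology, ProteinSequence
from .spr import Sensorgram, SensorgramSchedule, SensorgramSet, langmuir_response
from . import datasets


# ---------------------------------------------------------------------------
# Haplotype panels and cohorts
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeSpec:
    """A finite haplotype distribution over S biallelic sites."""

    haplotypes: list[str]          # '0'/'1' strings, all length S
    frequencies: np.ndarray        # sum to 1
    snp_ids: list[str]
    positions: np.ndarray          # 1-based coordinates

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        lengths = {len(h) for h in self.haplotypes}
        if len(lengths) != 1:
            raise ValueError("all haplotype strings must have the same length")
        (s,) = lengths
        if set("".join(self.haplotypes)) - {"0", "1"}:
            raise ValueError("haplotype strings must be over {0, 1}")
        if len(self.snp_ids) != s or self.positions.size != s:
            raise ValueError("snp_ids/positions must match haplotype length")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("snp_ids must be unique")
        if np.any(self.frequencies < 0) or np.any(self.frequencies > 1):
            raise ValueError("frequencies must be in [0, 1]")
        if abs(self.frequencies.sum() - 1.0) > 1e-9:
            raise ValueError("frequencies must sum to 1")

    @property
    def n_sites(self) -> int:
        return len(self.snp_ids)

    def allele_matrix(self) -> np.ndarray:
        return np.array([[int(ch) for ch in h] for h in self.haplotypes], dtype=np.uint8)

    def allele_freq(self, snp_id: str) -> float:
        j = self.snp_ids.index(snp_id)
        return float(np.dot(self.frequencies, self.allele_matrix()[:, j]))

    def exact_ld(self, snp_a: str, snp_b: str) -> tuple[float, float]:
        """Analytic (D, r²) from the frequency table — the LD oracle."""
        mat = self.allele_matrix().astype(float)
        ja, jb = self.snp_ids.index(snp_a), self.snp_ids.index(snp_b)
        f_a = float(np.dot(self.frequencies, mat[:, ja]))
        f_b = float(np.dot(self.frequencies, mat[:, jb]))
        h_ab = float(np.dot(self.frequencies, mat[:, ja] * mat[:, jb]))
        d = h_ab - f_a * f_b
        var = f_a * (1 - f_a) * f_b * (1 - f_b)
        return d, d * d / var if var > 0 else math.nan


@dataclass
class DiseaseModel:
    """Dominant diploid disease model with a single causal SNP.

    An individual is a pair of haplotypes; carriers (>= 1 causal allele)
    develop disease with probability ``penetrance_carrier`` (x), others with
    ``penetrance_noncarrier`` (y).
    """

    causal_snp: str
    penetrance_carrier: float
    penetrance_noncarrier: float

    def __post_init__(self) -> None:
        x, y = self.penetrance_carrier, self.penetrance_noncarrier
        if not 0.0 <= y <= x <= 1.0:
            raise ValueError("penetrances must satisfy 0 <= y <= x <= 1")

    def prevalence(self, causal_allele_freq: float) -> float:
        """Population prevalence K = x*q + y*(1-q), with carrier frequency
        q = 1 - (1-f)² under random pairing of haplotypes."""
        q = 1.0 - (1.0 - causal_allele_freq) ** 2
        k = self.penetrance_carrier * q + self.penetrance_noncarrier * (1 - q)
        if not 0.0 < k < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        return k


@dataclass
class CohortTable:
    """Sampled case/control individuals as haplotype index pairs."""

    hap_pairs: np.ndarray          # (n, 2) indices into the panel
    is_case: np.ndarray            # bool per individual

    def __post_init__(self) -> None:
        self.hap_pairs = np.asarray(self.hap_pairs, dtype=np.int64)
        self.is_case = np.asarray(self.is_case, dtype=bool)
        if self.hap_pairs.shape != (self.is_case.size, 2):
            raise ValueError("hap_pairs must be (n, 2) aligned with phenotypes")

    @property
    def n_case(self) -> int:
        return int(self.is_case.sum())

    @property
    def n_control(self) -> int:
        return int((~self.is_case).sum())

    def allele_freq(self, panel: HaplotypePanel, snp_id: str,
                    cases: bool) -> float:
        col = panel.column(snp_id)
        pairs = self.hap_pairs[self.is_case if cases else ~self.is_case]
        return float(col[pairs].mean())

    def marker_association(self, panel: HaplotypePanel, snp_id: str) -> MarkerAssociation:
        return MarkerAssociation(
            snp_id=snp_id,
            f_case=self.allele_freq(panel, snp_id, cases=True),
            f_control=self.allele_freq(panel, snp_id, cases=False),
        )


def gen_haplotype_panel(spec: HaplotypeSpec, n_hap: int, seed: int) -> HaplotypePanel:
    """Sample ``n_hap`` haplotypes i.i.d. from the spec's frequency table."""
    if n_hap < 2:
        raise ValueError("n_hap must be >= 2")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(spec.haplotypes), size=n_hap, p=spec.frequencies)
    return HaplotypePanel(spec.allele_matrix()[idx], list(spec.snp_ids),
                          spec.positions.copy())


def gen_case_control(panel: HaplotypePanel, model: DiseaseModel,
                     n_case: int, n_control: int, seed: int,
                     max_draws: int = 50_000_000) -> CohortTable:
    """Ascertain a case/control cohort by rejection sampling.

    Individuals are random haplotype pairs (with replacement); each develops
    disease with the carrier or non-carrier penetrance, and sampling
    continues until the requested case and control counts are filled.
    Raises after ``max_draws`` attempts when a stratum cannot be filled
    (e.g. zero penetrance with cases requested).
    """
    if model.causal_snp not in panel.snp_ids:
        raise ValueError(f"causal SNP {model.causal_snp} absent from the panel")
    rng = np.random.default_rng(seed)
    causal = panel.column(model.causal_snp)
    case_pairs, control_pairs = [], []
    drawn = 0
    batch = max(10_000, 4 * (n_case + n_control))
    while (len(case_pairs) < n_case or len(control_pairs) < n_control):
        if drawn >= max_draws:
            raise RuntimeError(
                f"could not fill the cohort after {drawn} draws "
                f"(cases {len(case_pairs)}/{n_case}, controls {len(control_pairs)}/{n_control})")
        pairs = rng.integers(0, panel.n_hap, size=(batch, 2))
        drawn += batch
        carrier = (causal[pairs[:, 0]] | causal[pairs[:, 1]]).astype(bool)
        p = np.where(carrier, model.penetrance_carrier, model.penetrance_noncarrier)
        diseased = rng.random(batch) < p
        need_case = n_case - len(case_pairs)
        need_control = n_control - len(control_pairs)
        case_pairs.extend(map(tuple, pairs[diseased][:need_case]))
        control_pairs.extend(map(tuple, pairs[~diseased][:need_control]))
    pairs = np.array(case_pairs + control_pairs, dtype=np.int64).reshape(-1, 2)
    is_case = np.zeros(n_case + n_control, dtype=bool)
    is_case[:n_case] = True
    return CohortTable(hap_pairs=pairs, is_case=is_case)


def build_demo_locus() -> tuple[HaplotypeSpec, DiseaseModel, str]:
    """The default synthetic risk locus: seven SNPs with block LD.

    Layout (positions arbitrary): ``linked1`` in moderate LD (r² ≈ 0.52) with
    the marker; ``marker`` and ``causal`` at allele frequency 0.3 in near-
    complete LD (r² = 0.95, mirroring the reported marker/mechanism pair);
    ``rare1`` a rare recombinant; ``null1..null3`` in linkage equilibrium
    with the block and each other.  Carrier and non-carrier penetrances are
    0.012 and 0.0095 — a weak, common-disease-sized effect.

    Returns (spec, disease model, marker SNP id).
    """
    # Block haplotypes over (linked1, marker, causal, rare1)
    block = [
        ("1110", 0.26523),
        ("0111", 0.02947),
        ("1100", 0.0053),
        ("0010", 0.0053),
        ("0000", 0.5947),
        ("1001", 0.1),
    ]
    # Independent tail SNPs (null1..null3) with allele freqs 0.2, 0.4, 0.1
    tails, tail_freqs = [], []
    for b1 in (0, 1):
        for b2 in (0, 1):
            for b3 in (0, 1):
                tails.append(f"{b1}{b2}{b3}")
                tail_freqs.append(
                    (0.2 if b1 else 0.8) * (0.4 if b2 else 0.6) * (0.1 if b3 else 0.9))
    haplotypes, freqs = [], []
    for hb, fb in block:
        for ht, ft in zip(tails, tail_freqs):
            haplotypes.append(hb + ht)
            freqs.append(fb * ft)
    spec = HaplotypeSpec(
        haplotypes=haplotypes,
        frequencies=np.array(freqs) / np.sum(freqs),
        snp_ids=["linked1", "marker", "causal", "rare1", "null1", "null2", "null3"],
        positions=np.array([1000, 2000, 3000, 4000, 20000, 40000, 60000]),
    )
    model = DiseaseModel(causal_snp="causal", penetrance_carrier=0.012,
                         penetrance_noncarrier=0.0095)
    return spec, model, "marker"


# ---------------------------------------------------------------------------
# SPR sensorgrams
# ---------------------------------------------------------------------------

def gen_sensorgrams(kon: float, koff: float, rmax: float,
                    concentrations_nM: list[float],
                    schedule: SensorgramSchedule,
                    noise_sd: float, seed: int,
                    drift_RU_per_s: float = 0.0) -> SensorgramSet:
    """Model sensorgrams plus i.i.d. Gaussian noise (and optional linear
    drift) at each analyte concentration; ``noise_sd = 0`` gives exact
    model curves."""
    if not concentrations_nM:
        raise ValueError("empty concentration list")
    if min(kon, koff, rmax) <= 0 or min(concentrations_nM) <= 0:
        raise ValueError("rates, Rmax and concentrations must be positive")
    rng = np.random.default_rng(seed)
    curves = []
    for conc in concentrations_nM:
        curve = langmuir_response(kon, koff, rmax, conc, schedule)
        response = curve.response + drift_RU_per_s * curve.time
        if noise_sd > 0:
            response = response + rng.normal(0.0, noise_sd, size=curve.time.size)
        curves.append(Sensorgram(time=curve.time, response=response,
                                 conc_nM=conc, t_assoc_end=schedule.t_assoc))
    return SensorgramSet(curves, schedule)


# ---------------------------------------------------------------------------
# DSF melt curves
# ---------------------------------------------------------------------------

@dataclass
class MeltGenParams:
    """Two-state van't Hoff melting with linear baselines (no ΔCp term)."""

    tm_C: float
    dh_kcal: float = 100.0                     # van't Hoff enthalpy
    baseline_folded: tuple[float, float] = (0.05, 0.001)    # intercept AU, slope AU/°C
    baseline_unfolded: tuple[float, float] = (1.0, -0.003)
    grid_C: np.ndarray = field(default_factory=lambda: np.arange(30.0, 90.01, 0.2))
    noise_sd: float = 0.01
    n_replicates: int = 4

    def __post_init__(self) -> None:
        self.grid_C = np.asarray(self.grid_C, dtype=float)
        if np.any(np.diff(self.grid_C) <= 0):
            raise ValueError("temperature grid must be strictly increasing")
        if not (self.grid_C[0] < self.tm_C < self.grid_C[-1]):
            raise ValueError("Tm must lie inside the temperature grid")
        if self.dh_kcal <= 0:
            raise ValueError("van't Hoff enthalpy must be positive")


def two_state_unfolded_fraction(t_C: np.ndarray, tm_C: float, dh_kcal: float) -> np.ndarray:
    """Unfolded fraction f_u(T) = 1/(1 + exp(ΔH/R·(1/T − 1/Tm))), T in kelvin
    inside the exponent; f_u(Tm) = 1/2 exactly."""
    t_K = np.asarray(t_C, dtype=float) + CELSIUS_OFFSET
    tm_K = tm_C + CELSIUS_OFFSET
    return 1.0 / (1.0 + np.exp(dh_kcal / R_KCAL * (1.0 / t_K - 1.0 / tm_K)))


def gen_melt_curves(params: MeltGenParams, seed: int,
                    label: str = "") -> list[MeltCurve]:
    """Replicate melting curves F(T) = B_f(T)(1−f_u) + B_u(T)f_u + noise;
    replicates differ only by their noise realization."""
    rng = np.random.default_rng(seed)
    t = params.grid_C
    fu = two_state_unfolded_fraction(t, params.tm_C, params.dh_kcal)
    bf = params.baseline_folded[0] + params.baseline_folded[1] * t
    bu = params.baseline_unfolded[0] + params.baseline_unfolded[1] * t
    signal = bf * (1.0 - fu) + bu * fu
    curves = []
    for i in range(params.n_replicates):
        noise = rng.normal(0.0, params.noise_sd, size=t.size) if params.noise_sd > 0 else 0.0
        curves.append(MeltCurve(temperature=t.copy(), fluorescence=signal + noise,
                                label=f"{label}_rep{i + 1}" if label else f"rep{i + 1}"))
    return curves


# ---------------------------------------------------------------------------
# Protein sequences
# ---------------------------------------------------------------------------

_FILLER = "".join(aa for aa in AMINO_ACIDS if aa not in "CN")   # no stray Cys/sequons
_SEQUON_X = "".join(aa for aa in _FILLER if aa != "P")


def gen_protein_sequence(length: int, cys_positions: list[int],
                         sequon_positions: list[int], seed: int,
                         identifier: str = "synthetic", offset: int = 1
                         ) -> ProteinSequence:
    """Random sequence with Cys planted at ``cys_positions`` and an
    N-X-[S/T] sequon starting at each of ``sequon_positions`` (labels in the
    ``offset`` numbering), and no accidental extra cysteines or sequons.
    """
    rng = np.random.default_rng(seed)
    occupied: set[int] = set()

    def claim(labels):
        for lab in labels:
            i = lab - offset
            if not 0 <= i < length:
                raise ValueError(f"position {lab} outside the sequence")
            if i in occupied:
                raise ValueError(f"overlapping motif request at position {lab}")
            occupied.add(i)

    claim(cys_positions)
    for start in sequon_positions:
        claim([start, start + 1, start + 2])

    chars = [str(c) for c in rng.choice(list(_FILLER), size=length)]
    for lab in cys_positions:
        chars[lab - offset] = "C"
    for start in sequon_positions:
        i = start - offset
        chars[i] = "N"
        chars[i + 1] = str(rng.choice(list(_SEQUON_X)))
        chars[i + 2] = str(rng.choice(["S", "T"]))
    return ProteinSequence(identifier, "".join(chars), offset)


def gen_msp_beta_analog(seed: int = 0) -> tuple[ProteinSequence, DisulfideTopology]:
    """Synthetic stand-in for the wild-type MSPβ construct (real sequence not
    bundled): a random sequence spanning the construct numbering with the
    eleven native cysteine positions, the Arg687–Arg696 tryptic context
    (``R SCWPAVFTR``, wild-type Arg689), and the Asn615 glycosylation sequon
    planted at their published coordinates.  Returns the sequence and the
    five-bond native disulfide topology.

    The engineered variants are obtained with
    :func:`mechsnp.proteoforms.apply_substitutions`: C672S for the "wild
    type" construct and additionally R689C for the mutant.
    """
    start, end = datasets.MSP_CONSTRUCT_SPAN
    length = end - start + 1
    seq = gen_protein_sequence(
        length=length,
        cys_positions=list(datasets.MSP_CYSTEINES),
        sequon_positions=[datasets.MSP_GLYCOSYLATION_SITE],
        seed=seed,
        identifier="MSPbeta_analog_synthetic",
        offset=start,
    )
    chars = list(seq.sequence)
    context = "RSRWPAVFTR"          # Arg687 .. Arg696 with wild-type Arg689
    for k, aa in enumerate(context):
        chars[687 - start + k] = aa
    # a few deterministic extra tryptic sites so digests look realistic
    for lab in (500, 540, 580, 620, 650):
        if chars[lab - start] not in "CN" and (lab - start) not in range(687 - start, 697 - start):
            chars[lab - start] = "K" if lab % 2 == 0 else "R"
    seq = ProteinSequence(seq.identifier, "".join(chars), start)
    return seq, DisulfideTopology(bonds=tuple(datasets.MSP_DISULFIDES))
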