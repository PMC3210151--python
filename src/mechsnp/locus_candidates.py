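"""Candidate mechanism-SNP selection from phased haplotypes.

Given a phased haplotype panel for a disease-associated locus and
case/control allele frequencies for the genotyped marker SNPs, this module
computes pairwise linkage-disequilibrium statistics (D, D', r²), estimates
the marker penetrance P(D|m) from the association summary plus a
user-supplied disease prevalence K, solves for the penetrance each other
SNP would need to explain the marker signal, and selects as candidate
mechanism SNPs every SNP whose implied penetrance is at least that of a
marker — or whose r² with a marker reaches a threshold (default 0.8).

Penetrance here is allele-level: P(D|a) is the probability of disease given
carriage of allele a.  The two-equation system

    P(D|m) = x*P(c|m) + y*(1 - P(c|m))
    K      = x*f_c    + y*(1 - f_c)

is solved for the candidate's implied penetrance x = P(D|c) and its
complement y = P(D|not c); a candidate is *feasible* only when both x and y
are valid probabilities, which is what keeps unlinked SNPs from inheriting
the marker signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Relative tolerance for the x >= P(D|m) boundary comparison.
PENETRANCE_RTOL = 1e-9
#: Tolerance below which P(c|m) = f_c counts as candidate/marker independence.
INDEPENDENCE_TOL = 1e-12


@dataclass
class HaplotypePanel:
    """Phased biallelic haplotypes: a (haplotypes × SNPs) 0/1 matrix."""

    alleles: np.ndarray
    snp_ids: list[str]
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.alleles.ndim != 2:
            raise ValueError("allele matrix must be 2-D (haplotypes × SNPs)")
        if not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("allele matrix entries must be 0/1")
        if len(self.snp_ids) != self.alleles.shape[1] or self.positions.size != self.alleles.shape[1]:
            raise ValueError("snp_ids/positions must match the number of SNP columns")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("snp_ids must be unique")

    @property
    def n_hap(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_snp(self) -> int:
        return self.alleles.shape[1]

    @property
    def freqs(self) -> np.ndarray:
        """Per-SNP alternate-allele frequencies."""
        return self.alleles.mean(axis=0)

    def column(self, snp_id: str) -> np.ndarray:
        return self.alleles[:, self.snp_ids.index(snp_id)]

    # ---- I/O -------------------------------------------------------------

    def to_vcf(self, path, chrom: str = "1") -> None:
        """Write the panel as phased VCF v4.2, pairing consecutive haplotypes
        into diploid samples (requires an even haplotype count)."""
        if self.n_hap % 2:
            raise ValueError("VCF output needs an even number of haplotypes")
        n_ind = self.n_hap // 2
        samples = [f"ind{i + 1}" for i in range(n_ind)]
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write(f"##contig=<ID={chrom}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(samples) + "\n")
            for j, (snp_id, pos) in enumerate(zip(self.snp_ids, self.positions)):
                col = self.alleles[:, j]
                gts = "\t".join(f"{col[2 * i]}|{col[2 * i + 1]}" for i in range(n_ind))
                fh.write(f"{chrom}\t{pos}\t{snp_id}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")

    @classmethod
    def from_vcf(cls, path) -> "HaplotypePanel":
        """Read a phased VCF (GT separated by '|'); unphased records are
        rejected."""
        from cyvcf2 import VCF

        snp_ids, positions, columns = [], [], []
        vcf = VCF(str(path))
        for i, variant in enumerate(vcf):
            gts = variant.genotypes  # [[a, b, phased], ...]
            haps = []
            for g in gts:
                if not g[-1]:
                    raise ValueError(
                        f"unphased genotype at {variant.ID or variant.POS}; "
                        "only phased panels are accepted")
                haps.extend(g[:-1])
            snp_ids.append(variant.ID or f"snp{i + 1}")
            positions.append(variant.POS)
            columns.append(haps)
        vcf.close()
        if not columns:
            raise ValueError("no variants in VCF")
        return cls(np.array(columns, dtype=np.uint8).T, snp_ids, np.array(positions))

    def to_text(self, path) -> None:
        """Plain haplotype matrix: two comment lines (ids, positions) then one
        compact 0/1 row per haplotype."""
        with open(path, "w") as fh:
            fh.write("#snp_ids\t" + "\t".join(self.snp_ids) + "\n")
            fh.write("#positions\t" + "\t".join(map(str, self.positions)) + "\n")
            for row in self.alleles:
                fh.write("".join(map(str, row)) + "\n")

    @classmethod
    def from_text(cls, path) -> "HaplotypePanel":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            posline = fh.readline().rstrip("\n").split("\t")
            if header[0] != "#snp_ids" or posline[0] != "#positions":
                raise ValueError("malformed haplotype matrix header")
            snp_ids = header[1:]
            positions = np.array([int(p) for p in posline[1:]])
            rows = [[int(ch) for ch in line.strip()] for line in fh if line.strip()]
        return cls(np.array(rows, dtype=np.uint8), snp_ids, positions)


@dataclass(frozen=True)
class LDStats:
    """Two-locus linkage disequilibrium summary."""

    d: float          # h_ab - f_a*f_b
    d_prime: float
    r2: float
    h_ab: float       # joint alternate-allele haplotype frequency
    f_a: float
    f_b: float
    defined: bool = True   # False when either SNP is monomorphic


def ld_stats(panel: HaplotypePanel, snp_a: str, snp_b: str) -> LDStats:
    """D, D' and r² for two SNPs, computed from the phased haplotype counts.

    For a monomorphic SNP r² and D' are undefined: they are returned as NaN
    with ``defined=False`` rather than 0.
    """
    a = panel.column(snp_a).astype(float)
    b = panel.column(snp_b).astype(float)
    f_a, f_b = float(a.mean()), float(b.mean())
    h_ab = float(np.mean(a * b))
    d = h_ab - f_a * f_b
    var = f_a * (1 - f_a) * f_b * (1 - f_b)
    if var <= 0:
        return LDStats(d=d, d_prime=math.nan, r2=math.nan, h_ab=h_ab,
                       f_a=f_a, f_b=f_b, defined=False)
    r2 = d * d / var
    if d > 0:
        d_max = min(f_a * (1 - f_b), (1 - f_a) * f_b)
    elif d < 0:
        d_max = min(f_a * f_b, (1 - f_a) * (1 - f_b))
    else:
        d_max = math.inf
    d_prime = d / d_max if d != 0 else 0.0
    return LDStats(d=d, d_prime=d_prime, r2=r2, h_ab=h_ab, f_a=f_a, f_b=f_b)


@dataclass(frozen=True)
class MarkerAssociation:
    """Case/control risk-allele frequencies for one genotyped marker."""

    snp_id: str
    f_case: float
    f_control: float

    def __post_init__(self) -> None:
        for f in (self.f_case, self.f_control):
            if not 0.0 <= f <= 1.0:
                raise ValueError("allele frequencies must be in [0, 1]")


@dataclass(frozen=True)
class PenetranceEstimate:
    """Allele-level penetrance P(D|allele) and its complement P(D|no allele)."""

    p_d_given_allele: float
    p_d_given_not: float
    allele_freq: float
    feasible: bool = True


def marker_penetrance(assoc: MarkerAssociation, prevalence: float) -> PenetranceEstimate:
    """Marker penetrance from case/control allele frequencies via Bayes.

    Population allele frequency P(m) = K*f_case + (1-K)*f_control;
    P(D|m) = K*f_case/P(m) and P(D|not m) = K*(1-f_case)/(1-P(m)).
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must be in (0, 1)")
    p_m = prevalence * assoc.f_case + (1 - prevalence) * assoc.f_control
    if p_m <= 0.0 or p_m >= 1.0:
        raise ValueError("population allele frequency of 0 or 1: penetrance undefined")
    x = prevalence * assoc.f_case / p_m
    y = prevalence * (1 - assoc.f_case) / (1 - p_m)
    return PenetranceEstimate(p_d_given_allele=x, p_d_given_not=y, allele_freq=p_m)


def implied_candidate_penetrance(marker_pen: PenetranceEstimate, prevalence: float,
                                 f_c: float, p_cm: float) -> PenetranceEstimate:
    """Penetrance a candidate allele would need to explain the marker signal.

    Solves {P(D|m) = x*p_cm + y*(1-p_cm); K = x*f_c + y*(1-f_c)} for the
    candidate penetrance x = P(D|c) and y = P(D|not c), where f_c is the
    candidate allele frequency and p_cm = P(c|m) its frequency among
    marker-carrying haplotypes.  The estimate is infeasible — never an
    exception — when the candidate is independent of the marker
    (p_cm ≈ f_c) or when x or y leaves [0, 1].
    """
    if not 0.0 < f_c < 1.0:
        raise ValueError("candidate allele frequency must be in (0, 1)")
    if not 0.0 <= p_cm <= 1.0:
        raise ValueError("P(c|m) must be in [0, 1]")
    p_dm = marker_pen.p_d_given_allele
    denom = p_cm - f_c
    if abs(denom) < INDEPENDENCE_TOL:
        return PenetranceEstimate(math.nan, math.nan, f_c, feasible=False)
    x = (p_dm * (1 - f_c) - prevalence * (1 - p_cm)) / denom
    y = (prevalence - x * f_c) / (1 - f_c)
    feasible = 0.0 <= x <= 1.0 and 0.0 <= y <= 1.0
    return PenetranceEstimate(x, y, f_c, feasible=feasible)


@dataclass
class CandidateRecord:
    snp_id: str
    position: int
    best_r2: float
    implied_penetrance: float     # best feasible implied x over markers (NaN if none)
    marker_penetrance: float      # P(D|m) of the marker behind implied_penetrance
    reason: str                   # penetrance | r2 | both | none
    monomorphic: bool = False

    @property
    def selected(self) -> bool:
        return self.reason != "none"


@dataclass
class CandidateSet:
    records: list[CandidateRecord]
    marker_ids: list[str]
    prevalence: float
    r2_threshold: float

    def selected_ids(self) -> list[str]:
        return [r.snp_id for r in self.records if r.selected]

    def record(self, snp_id: str) -> CandidateRecord:
        for r in self.records:
            if r.snp_id == snp_id:
                return r
        raise KeyError(snp_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"snp_id": r.snp_id, "position": r.position, "best_r2": r.best_r2,
              "implied_penetrance": r.implied_penetrance,
              "marker_penetrance": r.marker_penetrance, "reason": r.reason}
             for r in self.records]
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def select_candidates(panel: HaplotypePanel, markers: list[MarkerAssociation],
                      prevalence: float = 0.005,
                      r2_threshold: float = 0.8) -> CandidateSet:
    """Select candidate mechanism SNPs against each marker.

    A SNP is selected when its implied penetrance is feasible and at least
    the marker's P(D|m) for some marker (relative tolerance 1e-9), or when
    r² with some marker reaches ``r2_threshold`` (inclusive).  The candidate
    risk allele is oriented per marker as the allele positively associated
    with the marker risk allele (D > 0).  Monomorphic candidates are kept in
    the output with reason "none" and a flag; a monomorphic *marker* is an
    error because nothing can be conditioned on it.
    """
    marker_stats = []
    for assoc in markers:
        if assoc.snp_id not in panel.snp_ids:
            raise ValueError(f"marker {assoc.snp_id} absent from the panel")
        f_m = float(panel.column(assoc.snp_id).mean())
        if f_m <= 0.0 or f_m >= 1.0:
            raise ValueError(f"marker {assoc.snp_id} is monomorphic in the panel")
        marker_stats.append((assoc, f_m, marker_penetrance(assoc, prevalence)))

    records = []
    for j, snp_id in enumerate(panel.snp_ids):
        col = panel.column(snp_id)
        f_c = float(col.mean())
        mono = f_c <= 0.0 or f_c >= 1.0
        best_r2 = math.nan
        best_x = math.nan
        best_marker_pen = math.nan
        pen_hit = False
        r2_hit = False
        for assoc, f_m, pen_m in marker_stats:
            ld = ld_stats(panel, snp_id, assoc.snp_id)
            if ld.defined and (math.isnan(best_r2) or ld.r2 > best_r2):
                best_r2 = ld.r2
            if ld.defined and ld.r2 >= r2_threshold:
                r2_hit = True
            if mono:
                continue
            # orient the candidate allele to be positively associated with m
            if ld.d >= 0:
                f_c_oriented, h_cm = f_c, ld.h_ab
            else:
                f_c_oriented, h_cm = 1.0 - f_c, f_m - ld.h_ab
            p_cm = h_cm / f_m
            est = implied_candidate_penetrance(pen_m, prevalence, f_c_oriented, p_cm)
            if est.feasible and est.p_d_given_allele >= pen_m.p_d_given_allele * (1 - PENETRANCE_RTOL):
                pen_hit = True
                if math.isnan(best_x) or est.p_d_given_allele > best_x:
                    best_x = est.p_d_given_allele
                    best_marker_pen = pen_m.p_d_given_allele
        if pen_hit and r2_hit:
            reason = "both"
        elif pen_hit:
            reason = "penetrance"
        elif r2_hit:
            reason = "r2"
        else:
            reason = "none"
        records.append(CandidateRecord(
            snp_id=snp_id, position=int(panel.positions[j]), best_r2=best_r2,
            implied_penetrance=best_x, marker_penetrance=best_marker_pen,
            reason=reason, monomorphic=mono,
        ))
    return CandidateSet(records=records, marker_ids=[m.snp_id for m in markers],
                        prevalence=prevalence, r2_threshold=r2_threshold)


def read_marker_csv(path) -> list[MarkerAssociation]:
    """Marker association summaries from a ``snp_id,f_case,f_control`` CSV."""
    df = pd.read_csv(path)
    return [MarkerAssociation(str(r.snp_id), float(r.f_case), float(r.f_control))
            for r in df.itertuples()]


def write_marker_csv(markers: list[MarkerAssociation], path) -> None:
    pd.DataFrame([{"snp_id": m.snp_id, "f_case": m.f_case, "f_control": m.f_control}
                  for m in markers]).to_csv(path, index=False)
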