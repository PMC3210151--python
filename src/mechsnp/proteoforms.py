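"""Sequence-level proteoform bookkeeping.

In-silico tryptic digestion with missed-cleavage enumeration, peptide
monoisotopic/average masses with fixed modifications, N-glycosylation
sequon (Asn-Xaa-Ser/Thr) scanning, disulfide/free-cysteine assignment, and
measured-vs-calculated mass-delta accounting for glycoform analysis.

Residue positions are reported as *labels*: the 1-based index plus an
optional numbering offset, so that outputs on a construct beginning at
residue 465 read "Cys689" rather than "Cys225".
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Monoisotopic and average residue masses [Da] for the 20 standard residues.
RESIDUE_MASS_MONO = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276, "V": 99.06841,
    "T": 101.04768, "C": 103.00919, "L": 113.08406, "I": 113.08406,
    "N": 114.04293, "D": 115.02694, "Q": 128.05858, "K": 128.09496,
    "E": 129.04259, "M": 131.04049, "H": 137.05891, "F": 147.06841,
    "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
RESIDUE_MASS_AVG = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594,
    "N": 114.1038, "D": 115.0886, "Q": 128.1307, "K": 128.1741,
    "E": 129.1155, "M": 131.1926, "H": 137.1411, "F": 147.1766,
    "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
WATER_MONO = 18.010565
WATER_AVG = 18.0153

#: Iodoacetamide alkylation of cysteine (carbamidomethyl), a fixed
#: modification in the free-thiol labelling workflow.
CARBAMIDOMETHYL_C = 57.02146

#: Mean residue mass of an anhydro-hexose sugar unit; HexNAc alternative.
SUGAR_HEXOSE = 162.053
SUGAR_HEXNAC = 203.079


@dataclass(frozen=True)
class ProteinSequence:
    """One-letter protein sequence with an optional numbering offset.

    ``offset`` is the label of the first residue (default 1); residue *i*
    (0-based) carries label ``offset + i``.
    """

    identifier: str
    sequence: str
    offset: int = 1

    def __post_init__(self) -> None:
        bad = set(self.sequence) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"non-standard residues: {sorted(bad)}")
        if self.offset < 0:
            raise ValueError("offset must be >= 0")

    def __len__(self) -> int:
        return len(self.sequence)

    def label_of(self, index0: int) -> int:
        return self.offset + index0

    def index_of(self, label: int) -> int:
        i = label - self.offset
        if not (0 <= i < len(self.sequence)):
            raise ValueError(f"label {label} outside the sequence")
        return i

    def residue(self, label: int) -> str:
        return self.sequence[self.index_of(label)]

    def cysteine_labels(self) -> list[int]:
        return [self.label_of(i) for i, aa in enumerate(self.sequence) if aa == "C"]


def apply_substitutions(seq: ProteinSequence, edits: dict[int, str]) -> ProteinSequence:
    """Return a new sequence with point substitutions given as label -> residue
    (e.g. ``{672: "S", 689: "C"}``)."""
    chars = list(seq.sequence)
    for label, aa in edits.items():
        if aa not in AMINO_ACIDS:
            raise ValueError(f"invalid residue {aa!r}")
        chars[seq.index_of(label)] = aa
    return ProteinSequence(seq.identifier, "".join(chars), seq.offset)


@dataclass
class PeptideFragment:
    """A contiguous tryptic fragment with label-based coordinates."""

    sequence: str
    start_label: int
    end_label: int
    missed_cleavages: int
    mass_mono: float = field(default=0.0)
    mass_avg: float = field(default=0.0)


def peptide_mass(peptide: str, mode: str = "monoisotopic",
                 fixed_mods: dict[str, float] | None = None) -> float:
    """Peptide mass [Da]: sum of residue masses plus one water, plus any fixed
    per-residue modifications (e.g. ``{"C": CARBAMIDOMETHYL_C}``)."""
    if mode == "monoisotopic":
        table, water = RESIDUE_MASS_MONO, WATER_MONO
    elif mode == "average":
        table, water = RESIDUE_MASS_AVG, WATER_AVG
    else:
        raise ValueError("mode must be 'monoisotopic' or 'average'")
    try:
        mass = sum(table[aa] for aa in peptide) + water
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r}") from exc
    if fixed_mods:
        mass += sum(fixed_mods.get(aa, 0.0) for aa in peptide)
    return mass


def tryptic_digest(seq: ProteinSequence, missed_cleavages: int = 0,
                   protect_proline: bool = True,
                   fixed_mods: dict[str, float] | None = None
                   ) -> list[PeptideFragment]:
    """Enumerate tryptic peptides with up to ``missed_cleavages`` missed sites.

    Trypsin cleaves C-terminal to Lys/Arg; with ``protect_proline`` (the
    standard rule, default) a following Pro suppresses the cleavage.  The
    zero-missed-cleavage fragments partition the sequence exactly.
    """
    s = seq.sequence
    cuts = [0]
    for i, aa in enumerate(s[:-1]):
        if aa in "KR" and not (protect_proline and s[i + 1] == "P"):
            cuts.append(i + 1)
    cuts.append(len(s))

    fragments: list[PeptideFragment] = []
    for i in range(len(cuts) - 1):
        for j in range(i + 1, min(i + 2 + missed_cleavages, len(cuts))):
            start, end = cuts[i], cuts[j]
            pep = s[start:end]
            fragments.append(PeptideFragment(
                sequence=pep,
                start_label=seq.label_of(start),
                end_label=seq.label_of(end - 1),
                missed_cleavages=j - i - 1,
                mass_mono=peptide_mass(pep, "monoisotopic", fixed_mods),
                mass_avg=peptide_mass(pep, "average", fixed_mods),
            ))
    return fragments


def find_sequons(seq: ProteinSequence, exclude_proline_x: bool = False) -> list[int]:
    """Start labels of N-X-[S/T] N-glycosylation sequons.

    By default the plain motif is scanned; with ``exclude_proline_x`` the
    common refinement skipping X = Pro is applied.  Overlapping sequons are
    all reported.
    """
    pattern = r"N(?=[^P][ST])" if exclude_proline_x else r"N(?=.[ST])"
    return [seq.label_of(m.start()) for m in re.finditer(pattern, seq.sequence)]


@dataclass(frozen=True)
class DisulfideTopology:
    """A set of disulfide bonds given as pairs of residue labels."""

    bonds: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for a, b in self.bonds:
            if a == b:
                raise ValueError(f"self-bonded residue {a}")
            for r in (a, b):
                if r in seen:
                    raise ValueError(f"residue {r} appears in two bonds")
                seen.add(r)

    def bonded_labels(self) -> set[int]:
        return {r for bond in self.bonds for r in bond}

    def validate_against(self, seq: ProteinSequence) -> None:
        for label in self.bonded_labels():
            if seq.residue(label) != "C":
                raise ValueError(
                    f"bond names residue {label} ({seq.residue(label)}), not a cysteine")


def free_cysteines(seq: ProteinSequence, topology: DisulfideTopology) -> list[int]:
    """Cysteine labels not covered by any disulfide bond, sorted ascending."""
    topology.validate_against(seq)
    bonded = topology.bonded_labels()
    return sorted(set(seq.cysteine_labels()) - bonded)


@dataclass
class MassDelta:
    """Measured-minus-calculated mass with a sugar-unit count bracket."""

    measured_Da: float
    calculated_Da: float
    sugar_unit_mass_Da: float
    units_low: int
    units_high: int

    @property
    def delta_Da(self) -> float:
        return self.measured_Da - self.calculated_Da


def mass_delta(measured_Da: float, calculated_Da: float,
               sugar_unit_mass_Da: float = SUGAR_HEXOSE) -> MassDelta:
    """Account for a glycoform mass excess: delta = measured − calculated, and
    the pair of integers bracketing delta / sugar-unit mass."""
    if measured_Da <= 0 or calculated_Da <= 0:
        raise ValueError("masses must be positive")
    delta = measured_Da - calculated_Da
    ratio = delta / sugar_unit_mass_Da
    return MassDelta(
        measured_Da=measured_Da, calculated_Da=calculated_Da,
        sugar_unit_mass_Da=sugar_unit_mass_Da,
        units_low=math.floor(ratio), units_high=math.ceil(ratio),
    )


def read_fasta(path) -> list[ProteinSequence]:
    from Bio import SeqIO

    sequences = []
    for rec in SeqIO.parse(str(path), "fasta"):
        m = re.search(r"offset=(\d+)", rec.description)
        offset = int(m.group(1)) if m else 1
        sequences.append(ProteinSequence(rec.id, str(rec.seq), offset))
    return sequences


def write_fasta(sequences: list[ProteinSequence], path) -> None:
    with open(path, "w") as fh:
        for seq in sequences:
            fh.write(f">{seq.identifier} offset={seq.offset}\n")
            for i in range(0, len(seq.sequence), 60):
                fh.write(seq.sequence[i:i + 60] + "\n")
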