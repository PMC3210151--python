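"""Reference parameters for the MSPβ–RON system.

Published measurements for the binding of wild-type and R689C macrophage
stimulating protein β-chain (MSPβ) to extracellular constructs of the RON
receptor tyrosine kinase, and for the thermal stability of the MSPβ
variants.  These numbers parameterize the demo analyses and the synthetic
generators; nothing in the library recomputes them from raw instrument data.

Construct abbreviations: S = Sema, SP = Sema-PSI, SPI = Sema-PSI-IPT1,
SPI4 = Sema-PSI-IPT1-4.
"""

from __future__ import annotations

#: Analyte concentration series used across the direct-binding sensorgrams,
#: two-fold dilution steps (nM).
STANDARD_CONCENTRATIONS_NM: tuple[float, ...] = (4, 8, 16, 32, 64, 128, 256, 512)

#: Global 1:1 Langmuir kinetic fits and equilibrium-model fits for each
#: immobilized RON construct and MSPβ analyte variant.
#: (kon [1/(M*s)], koff [1/s], Kd_langmuir [nM], Kd_equilibrium [nM])
RON_MSP_KINETICS: dict[tuple[str, str], tuple[float, float, float, float]] = {
    ("S", "wt"): (23.1e5, 3.1e-2, 13.3, 16.4),
    ("SP", "wt"): (13.3e5, 2.8e-2, 21.2, 32.0),
    ("SPI", "wt"): (17.6e5, 2.7e-2, 15.1, 17.8),
    ("SPI4", "wt"): (16.9e5, 2.3e-2, 13.5, 22.6),
    ("S", "R689C"): (4.8e5, 8.1e-2, 170.0, 139.0),
    ("SP", "R689C"): (2.7e5, 6.2e-2, 233.1, 244.0),
    ("SPI", "R689C"): (8.7e5, 12.9e-2, 148.0, 154.0),
    ("SPI4", "R689C"): (3.5e5, 5.5e-2, 157.0, 158.0),
}

#: DSF melting temperatures of the MSPβ variants: label -> (Tm [°C], sd [°C]).
#: Standard deviations are over four independent melting curves.
MSP_MELTING_TEMPERATURES: dict[str, tuple[float, float]] = {
    "wt_glycosylated": (71.9, 0.5),
    "R689C_glycosylated": (70.3, 0.1),
    "R689C_dimer_glycosylated": (68.7, 0.3),
    "wt_deglycosylated": (68.1, 0.1),
    "R689C_deglycosylated": (65.6, 0.2),
}

#: MALDI-TOF measured vs sequence-calculated masses (Da) of the glycosylated
#: MSPβ constructs.
MSP_MASSES_DA: dict[str, tuple[float, float]] = {
    # label -> (measured, calculated)
    "wt": (29260.0, 28344.0),
    "R689C": (29370.0, 28274.0),
}

#: The five native disulfide bonds of the MSPβ construct (residue labels in
#: MSP numbering).  Cys468 pairs with Cys588 across the α/β chain boundary.
MSP_DISULFIDES: tuple[tuple[int, int], ...] = (
    (468, 588),
    (507, 523),
    (527, 562),
    (602, 667),
    (657, 685),
)

#: All cysteine positions of the wild-type MSPβ construct before engineering
#: (MSP numbering).  Cys672 is unpaired and is mutated to Ser in the
#: recombinant constructs to prevent aberrant disulfide formation.
MSP_CYSTEINES: tuple[int, ...] = (
    468, 507, 523, 527, 562, 588, 602, 657, 667, 672, 685,
)

#: Residue span of the recombinant MSPβ construct (includes 19 residues of
#: the α-chain linker), MSP numbering.
MSP_CONSTRUCT_SPAN: tuple[int, int] = (465, 711)

#: Single N-glycosylation site of MSPβ.
MSP_GLYCOSYLATION_SITE: int = 615

#: Empirical conversion between a melting-temperature shift and a folding
#: free-energy change: 1 kcal/mol corresponds to 3–4 K of ΔTm.
DTM_PER_KCAL_RANGE: tuple[float, float] = (3.0, 4.0)
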