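"""Reported reference values for the six-variant 13-mer duplex system.

The study system is the 13-mer duplex

    5'-TTTGTATCXCAAT-3'
    3'-AAACATAGYGTTA-5'     (bottom strand 5'-ATTGYGATACAAA-3')

whose single internal X·Y pair is one of G·C, D·T, I·C, A·T, G·T or I·T
(D = 2,6-diaminopurine, I = inosine). The constants below are the reported
UV-melting results for that system: duplex stabilities −ΔG°37 at 1 M Na⁺
and the slopes of −ΔG°37 against log₁₀[M] under three solution conditions
(aqueous Na⁺, Na⁺ with 3 M ethanol, and Mg²⁺), in kcal·mol⁻¹ per decade
with their standard errors. They serve as generator settings and regression
inputs for salt and discrimination analyses, not as claims this package
re-measures.
"""

from __future__ import annotations

TOP_TEMPLATE = "TTTGTATCXCAAT"
BOTTOM_TEMPLATE = "ATTGYGATACAAA"

#: The six X·Y variants in reported stability order (most to least stable).
VARIANTS: tuple[str, ...] = ("G·C", "D·T", "I·C", "A·T", "G·T", "I·T")


def variant_strands(variant: str) -> tuple[str, str]:
    """Top and bottom 5'→3' strands of the 13-mer for an X·Y variant."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    x, y = variant.split("·")
    return TOP_TEMPLATE.replace("X", x), BOTTOM_TEMPLATE.replace("Y", y)


#: 0-based position of the X·Y pair on the top strand.
XY_POSITION = 8

#: Reported duplex stabilities −ΔG°37 (kcal·mol⁻¹) at 1 M Na⁺.
MINUS_DG37_1M_NA: dict[str, float] = {
    "G·C": 12.5,
    "D·T": 11.2,
    "I·C": 11.2,
    "A·T": 10.4,
    "G·T": 9.15,
    "I·T": 8.83,
}

#: Reported slopes of −ΔG°37 vs log₁₀[M] (kcal·mol⁻¹ per decade) as
#: (slope, standard error), per solution condition.
SALT_SLOPES: dict[str, dict[str, tuple[float, float]]] = {
    "Na+": {
        "G·C": (3.91, 0.19),
        "D·T": (3.25, 0.32),
        "I·C": (3.21, 0.16),
        "A·T": (2.91, 0.23),
        "G·T": (2.61, 0.18),
        "I·T": (2.55, 0.13),
    },
    "Na+/EtOH3M": {
        "G·C": (3.32, 0.09),
        "D·T": (3.17, 0.21),
        "I·C": (3.19, 0.11),
        "A·T": (2.74, 0.09),
        "G·T": (2.43, 0.17),
        "I·T": (2.41, 0.13),
    },
    "Mg2+": {
        "G·C": (2.63, 0.26),
        "D·T": (2.00, 0.22),
        "I·C": (2.15, 0.16),
        "A·T": (1.92, 0.19),
        "G·T": (1.59, 0.26),
        "I·T": (1.50, 0.26),
    },
}

#: Representative melting enthalpies (kcal·mol⁻¹) used as generator truth
#: for the six variants; 13-mer duplexes melt with ΔH° around −85 to −105
#: kcal·mol⁻¹, ordered here with stability.
DEFAULT_TRUTH_DH: dict[str, float] = {
    "G·C": -105.0,
    "D·T": -101.0,
    "I·C": -99.0,
    "A·T": -95.0,
    "G·T": -89.0,
    "I·T": -85.0,
}
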