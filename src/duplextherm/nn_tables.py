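"""Published nearest-neighbor parameter sets embedded as constants.

Two sets are transcribed:

* the unified Watson-Crick DNA/DNA set (SantaLucia, Proc. Natl. Acad. Sci.
  USA 95:1460-1465, 1998), ten unique dinucleotide steps plus initiation
  terms per terminal pair;
* the internal G·T wobble set (Allawi & SantaLucia, Biochemistry
  36:10581-10594, 1997), eleven unique steps containing a single G·T pair.

Step keys use the slash notation ``XY/ZW`` for the duplex fragment

    5'-X Y-3'
    3'-Z W-5'

i.e. the part after the slash is the bottom strand written 3'→5' under the
top doublet. Each step read from the opposite strand, ``WZ/YX``, is the same
physical stack; the expanded lookup table contains both spellings with
identical values.

Values are (ΔH° kcal·mol⁻¹, ΔS° cal·mol⁻¹·K⁻¹); ΔG°37 is always recomputed
from them rather than transcribed, so every stored triple is exactly
self-consistent.
"""

from __future__ import annotations

from .core import ThermoParams

WC_PROVENANCE = (
    "Unified DNA/DNA nearest-neighbor set: SantaLucia (1998) "
    "Proc Natl Acad Sci USA 95:1460-1465"
)
GT_PROVENANCE = (
    "Internal G.T wobble nearest-neighbor set: Allawi & SantaLucia (1997) "
    "Biochemistry 36:10581-10594"
)

# (dH kcal/mol, dS cal/mol/K) for the 10 unique Watson-Crick steps.
_WC_STEPS: dict[str, tuple[float, float]] = {
    "AA/TT": (-7.9, -22.2),
    "AT/TA": (-7.2, -20.4),
    "TA/AT": (-7.2, -21.3),
    "CA/GT": (-8.5, -22.7),
    "GT/CA": (-8.4, -22.4),
    "CT/GA": (-7.8, -21.0),
    "GA/CT": (-8.2, -22.2),
    "CG/GC": (-10.6, -27.2),
    "GC/CG": (-9.8, -24.4),
    "GG/CC": (-8.0, -19.9),
}

# The 11 unique steps containing one internal G·T wobble pair.
_GT_STEPS: dict[str, tuple[float, float]] = {
    "AG/TT": (1.0, 0.9),
    "AT/TG": (-2.5, -8.3),
    "CG/GT": (-4.1, -11.7),
    "CT/GG": (-2.8, -8.0),
    "GG/CT": (3.3, 10.4),
    "GG/TT": (5.8, 16.3),
    "GT/CG": (-4.4, -12.3),
    "GT/TG": (4.1, 9.5),
    "TG/AT": (-0.1, -1.7),
    "TG/GT": (-1.4, -6.2),
    "TT/AG": (-1.3, -5.3),
}

# Duplex initiation, one term per terminus, keyed by the terminal pair.
_INITIATION: dict[str, tuple[float, float]] = {
    "G·C": (0.1, -2.8),
    "A·T": (2.3, 4.1),
}


def _flip(key: str) -> str:
    """Rewrite a step key from the opposite strand: XY/ZW -> WZ/YX."""
    top, bottom = key.split("/")
    return bottom[::-1] + "/" + top[::-1]


def _expand(steps: dict[str, tuple[float, float]]) -> dict[str, ThermoParams]:
    out: dict[str, ThermoParams] = {}
    for key, (dh, ds) in steps.items():
        params = ThermoParams(dH=dh, dS=ds)
        out[key] = params
        out[_flip(key)] = params
    return out


#: Expanded lookup: every Watson-Crick and internal-G·T step under both of
#: its strand-orientation spellings.
STEP_PARAMS: dict[str, ThermoParams] = {**_expand(_WC_STEPS), **_expand(_GT_STEPS)}

#: Initiation terms, keyed by terminal base pair ("G·C" covers G·C and C·G
#: termini, "A·T" covers A·T and T·A).
INITIATION_PARAMS: dict[str, ThermoParams] = {
    k: ThermoParams(dH=dh, dS=ds) for k, (dh, ds) in _INITIATION.items()
}
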