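"""Nearest-neighbor prediction and trinucleotide-core decomposition.

A duplex is represented by its two strands, both written 5'→3', aligned
antiparallel. The recognized base pairs are the six X·Y variants of the
study system — Watson-Crick G·C and A·T, the wobble G·T, and the
non-canonical inosine (I) and 2,6-diaminopurine (D) pairs I·C, D·T and I·T.
I and D are accepted by sequence validation (they are needed for labeling
and discrimination analyses) but rejected by nearest-neighbor prediction,
for which no published parameters exist.

The trinucleotide-core decomposition isolates what a central base pair and
its two flanking stacks contribute: because the nearest-neighbor total is a
plain sum, subtracting the initiation terms and every step that does not
touch the central pair from a measured (or predicted) whole-duplex value
leaves exactly the two central steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import ThermoParams
from .nn_tables import GT_PROVENANCE, INITIATION_PARAMS, STEP_PARAMS, WC_PROVENANCE

__all__ = [
    "DuplexSequence",
    "NNTable",
    "validate_duplex",
    "nn_predict",
    "nn_trinucleotide",
    "trinucleotide_core_from_measured",
]

ALPHABET = set("ACGTID")

#: Recognized pairs as (top base, bottom base); both orientations listed.
_RECOGNIZED_PAIRS = {
    ("A", "T"), ("T", "A"),
    ("G", "C"), ("C", "G"),
    ("G", "T"), ("T", "G"),
    ("I", "C"), ("C", "I"),
    ("D", "T"), ("T", "D"),
    ("I", "T"), ("T", "I"),
}

_WATSON_CRICK = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}

_WC_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}


class UnsupportedAlphabetError(ValueError):
    """Raised when nearest-neighbor parameters do not exist for a duplex."""


def _pair_label(top: str, bottom: str) -> str:
    """Canonical label of a pair, e.g. G·T and T·G both give 'G·T'."""
    order = "GDIAC TU"
    a, b = sorted((top, bottom), key=lambda x: order.find(x) if x in order else 99)
    return f"{a}·{b}"


@dataclass(frozen=True)
class DuplexSequence:
    """An antiparallel duplex; both strands stored 5'→3'.

    ``pairs[i]`` is the (top base, bottom base) pair at 0-based position
    ``i`` of the top strand; the bottom base comes from the antiparallel
    alignment, ``bottom[n-1-i]``. Human-readable reports use 1-based
    positions; machine output is 0-based.
    """

    top: str
    bottom: str
    pairs: tuple[tuple[str, str], ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.top)

    @property
    def pair_labels(self) -> tuple[str, ...]:
        return tuple(_pair_label(t, b) for t, b in self.pairs)

    def is_watson_crick(self) -> bool:
        return all(p in _WATSON_CRICK for p in self.pairs)

    def is_self_complementary(self) -> bool:
        return self.top == self.bottom and all(
            _WC_COMPLEMENT.get(t) == b for t, b in self.pairs
        )


@dataclass(frozen=True)
class NNTable:
    """A nearest-neighbor parameter table: step terms plus initiation."""

    steps: dict[str, ThermoParams]
    initiation: dict[str, ThermoParams]
    provenance: str

    def step(self, top2: str, bottom2_3to5: str) -> ThermoParams:
        """Look up the step 5'-top2-3' / 3'-bottom2-5'."""
        key = f"{top2}/{bottom2_3to5}"
        try:
            return self.steps[key]
        except KeyError:
            raise UnsupportedAlphabetError(
                f"no nearest-neighbor parameters for step {key}"
            ) from None


#: The default table: unified Watson-Crick set + internal G·T wobble set.
DEFAULT_NN_TABLE = NNTable(
    steps=STEP_PARAMS,
    initiation=INITIATION_PARAMS,
    provenance=f"{WC_PROVENANCE}; {GT_PROVENANCE}",
)


def validate_duplex(top: str, bottom: str) -> DuplexSequence:
    """Validate and pair two 5'→3' strands into a :class:`DuplexSequence`.

    Raises
    ------
    ValueError
        On empty input, length mismatch, characters outside {A,C,G,T,I,D},
        or any position whose (top, bottom) combination is not a recognized
        pair — e.g. two strands given in parallel orientation.
    """
    top = top.strip().upper()
    bottom = bottom.strip().upper()
    if not top or not bottom:
        raise ValueError("both strands must be non-empty")
    if len(top) != len(bottom):
        raise ValueError(
            f"strand lengths differ: top {len(top)} vs bottom {len(bottom)}"
        )
    for name, seq in (("top", top), ("bottom", bottom)):
        bad = set(seq) - ALPHABET
        if bad:
            raise ValueError(f"{name} strand contains unrecognized bases {sorted(bad)}")
    n = len(top)
    pairs = []
    for i in range(n):
        t, b = top[i], bottom[n - 1 - i]
        if (t, b) not in _RECOGNIZED_PAIRS:
            raise ValueError(
                f"unrecognized pair {t}·{b} at top-strand position {i} "
                "(0-based; strands must be antiparallel)"
            )
        pairs.append((t, b))
    duplex = DuplexSequence(top=top, bottom=bottom, pairs=tuple(pairs))
    if duplex.is_self_complementary():
        raise ValueError(
            "self-complementary duplex: only bimolecular non-self-complementary "
            "molecularity is supported"
        )
    return duplex


def _initiation_key(pair: tuple[str, str]) -> str:
    label = _pair_label(*pair)
    if label not in ("G·C", "A·T"):
        raise UnsupportedAlphabetError(
            f"no initiation parameters for terminal pair {label}"
        )
    return label


def _step_params(duplex: DuplexSequence, i: int, table: NNTable) -> ThermoParams:
    """Parameters of the stack between top positions i and i+1."""
    top2 = duplex.top[i : i + 2]
    bottom2 = duplex.pairs[i][1] + duplex.pairs[i + 1][1]  # written 3'->5'
    return table.step(top2, bottom2)


def _check_nn_supported(duplex: DuplexSequence) -> None:
    if any(base in "ID" for base in duplex.top + duplex.bottom):
        raise UnsupportedAlphabetError(
            "no published nearest-neighbor parameters for inosine (I) or "
            "2,6-diaminopurine (D)"
        )
    n = len(duplex)
    non_wc = [i for i, p in enumerate(duplex.pairs) if p not in _WATSON_CRICK]
    if any(i in (0, n - 1) for i in non_wc):
        raise UnsupportedAlphabetError("terminal mismatches are not supported")
    if len(non_wc) > 1:
        raise UnsupportedAlphabetError(
            f"at most one internal G·T wobble is supported, found mismatches at {non_wc}"
        )


def nn_predict(duplex: DuplexSequence, table: NNTable = DEFAULT_NN_TABLE) -> ThermoParams:
    """Whole-duplex nearest-neighbor prediction.

    Returns the sum of the two terminal initiation terms and all
    ``len(duplex) - 1`` dinucleotide step terms. Supports Watson-Crick
    duplexes with at most one internal G·T wobble; I/D-containing duplexes
    raise :class:`UnsupportedAlphabetError`.
    """
    _check_nn_supported(duplex)
    total = table.initiation[_initiation_key(duplex.pairs[0])]
    total = total + table.initiation[_initiation_key(duplex.pairs[-1])]
    for i in range(len(duplex) - 1):
        total = total + _step_params(duplex, i, table)
    return total


def nn_trinucleotide(
    tri_top: str, tri_bottom: str, table: NNTable = DEFAULT_NN_TABLE
) -> ThermoParams:
    """Nearest-neighbor sum of the two steps spanning a trinucleotide.

    The central pair may be a G·T wobble; the flanking pairs must be
    Watson-Crick. No initiation terms are included — the result is the
    contribution the central pair and its two stacks make inside a longer
    duplex, e.g. CGC/GTG for a central G·T flanked by C·G pairs.
    """
    duplex = validate_duplex(tri_top, tri_bottom)
    if len(duplex) != 3:
        raise ValueError(f"expected a trinucleotide, got length {len(duplex)}")
    for i in (0, 2):
        if duplex.pairs[i] not in _WATSON_CRICK:
            raise UnsupportedAlphabetError(
                f"flanking pair {_pair_label(*duplex.pairs[i])} must be Watson-Crick"
            )
    return _step_params(duplex, 0, table) + _step_params(duplex, 1, table)


def trinucleotide_core_from_measured(
    measured: ThermoParams,
    duplex: DuplexSequence,
    center: int,
    table: NNTable = DEFAULT_NN_TABLE,
) -> ThermoParams:
    """Attribute a measured whole-duplex value to its central trinucleotide.

    Subtracts from ``measured`` the initiation terms and every
    nearest-neighbor step that does not touch the central pair (0-based
    ``center`` on the top strand); the remainder is attributed to the two
    steps flanking the center. All non-central pairs must be Watson-Crick
    with available parameters; the central pair itself may be anything
    (G·T, I·T, ...), since its steps are never looked up.
    """
    n = len(duplex)
    if not 0 < center < n - 1:
        raise ValueError(f"center {center} must be interior to the duplex (0 < c < {n - 1})")
    for i, p in enumerate(duplex.pairs):
        if i != center and p not in _WATSON_CRICK:
            raise UnsupportedAlphabetError(
                f"non-central pair {_pair_label(*p)} at position {i} has no "
                "nearest-neighbor parameters"
            )
    remainder = measured
    remainder = remainder - table.initiation[_initiation_key(duplex.pairs[0])]
    remainder = remainder - table.initiation[_initiation_key(duplex.pairs[-1])]
    for i in range(n - 1):
        if i in (center - 1, center):
            continue  # the two steps touching the central pair stay in the core
        remainder = remainder - _step_params(duplex, i, table)
    return remainder
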