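"""Core nucleotide-string operations.

IUPAC-aware reverse complement, ambiguity-weighted GC content,
nearest-neighbor melting temperature, and aligned mismatch counting —
the primitives on which diagnostic-window search, primer construction
and in-silico PCR are built.

All sequences are DNA over the IUPAC alphabet (U is normalized to T on
input); the gap symbol is ``'-'`` only.
"""

from __future__ import annotations

import itertools
import math
import textwrap
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Iterator, Union

from Bio import SeqIO

from .errors import (
    AlignmentContractError,
    InvalidSequenceError,
    UnsupportedOligoError,
)

GAP = "-"

#: Expansion set of every IUPAC nucleotide symbol (gap expands to itself).
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
    GAP: frozenset(GAP),
}

#: IUPAC complement, closed over ambiguity classes (R<->Y, B<->V, D<->H ...).
COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N", GAP: GAP,
}

#: Fraction of each symbol's expansion set that is G or C.
GC_WEIGHT: dict[str, float] = {
    sym: sum(b in "GC" for b in bases) / len(bases)
    for sym, bases in IUPAC_SETS.items()
    if sym != GAP
}


def _normalize(residues: str, *, context: str = "sequence") -> str:
    out = residues.upper().replace("U", "T")
    for pos, ch in enumerate(out, start=1):
        if ch not in IUPAC_SETS:
            raise InvalidSequenceError(
                f"{context}: invalid residue {ch!r} at position {pos}"
            )
    return out


@dataclass(frozen=True)
class NucSequence:
    """An identified nucleotide string over the IUPAC alphabet.

    Residues are stored uppercase with U normalized to T; ``'-'`` is the
    only gap symbol accepted.
    """

    residues: str
    id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "residues", _normalize(self.residues, context=self.id or "sequence")
        )
        if len(self.residues) == 0:
            raise InvalidSequenceError(f"{self.id or 'sequence'}: empty sequence")

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues

    @property
    def is_gapped(self) -> bool:
        return GAP in self.residues

    def ungapped(self) -> "NucSequence":
        return NucSequence(self.residues.replace(GAP, "") or GAP, self.id)


SeqLike = Union[NucSequence, str]


def as_sequence(seq: SeqLike, id: str = "") -> NucSequence:
    """Coerce a plain string to :class:`NucSequence` (validating it)."""
    if isinstance(seq, NucSequence):
        return seq
    return NucSequence(seq, id)


def reverse_complement(seq: SeqLike) -> NucSequence:
    """IUPAC-aware reverse complement; gaps map to gaps.

    Ambiguity codes map to their complement class (R<->Y, S<->S, W<->W,
    K<->M, B<->V, D<->H, N<->N), so the operation is an involution.
    """
    s = as_sequence(seq)
    return NucSequence("".join(COMPLEMENT[c] for c in reversed(s.residues)), s.id)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (the convention used for reported
    GC% and prevalence percentages)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def gc_content(seq: SeqLike) -> float:
    """Percent G+C of an ungapped oligo, ambiguity-weighted.

    Unambiguous G and C count 1; an ambiguity code contributes the
    fraction of its expansion set that is G or C (S=1, R=Y=K=M=N=0.5,
    W=0, B=V=2/3, D=H=1/3). Returned rounded half-up to one decimal.
    """
    s = as_sequence(seq)
    if s.is_gapped:
        raise InvalidSequenceError(
            f"{s.id or 'sequence'}: GC content is defined on ungapped oligos"
        )
    weight = sum(GC_WEIGHT[c] for c in s.residues)
    return round_half_up(100.0 * weight / len(s))


# SantaLucia (1998) unified nearest-neighbor parameters.
# Keys are the top-strand dinucleotide; values (dH kcal/mol, dS cal/mol/K).
_NN_SANTALUCIA98: dict[str, tuple[float, float]] = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
# Duplex-initiation terms for a terminal G·C / A·T pair.
_INIT_GC = (0.1, -2.8)
_INIT_AT = (2.3, 4.1)
_R_GAS = 1.987  # cal / (mol K)

NN_TABLES = {"santalucia98": _NN_SANTALUCIA98}


@dataclass(frozen=True)
class ThermoParams:
    """Conditions for nearest-neighbor Tm prediction.

    monovalent_mm
        Monovalent cation concentration (mM). Default 50.
    divalent_mm
        Divalent cation concentration (mM), folded into an equivalent
        sodium concentration as [Na+] + 120*sqrt([Mg2+]). Default 0.
    oligo_um
        Total oligo concentration (µM). The effective duplex
        concentration entering the Tm formula is half of this (one
        strand in modest excess over its complement, the convention of
        common primer-analysis calculators). Default 0.25.
    """

    nn_parameter_set: str = "santalucia98"
    monovalent_mm: float = 50.0
    divalent_mm: float = 0.0
    oligo_um: float = 0.25

    def __post_init__(self) -> None:
        if self.nn_parameter_set not in NN_TABLES:
            raise UnsupportedOligoError(
                f"unknown nearest-neighbor parameter set {self.nn_parameter_set!r}"
            )
        if self.monovalent_mm < 0 or self.divalent_mm < 0:
            raise UnsupportedOligoError("salt concentrations must be >= 0")
        if self.oligo_um <= 0:
            raise UnsupportedOligoError("oligo concentration must be > 0")

    @property
    def sodium_equivalent_m(self) -> float:
        return (self.monovalent_mm + 120.0 * math.sqrt(self.divalent_mm)) / 1000.0

    @property
    def duplex_conc_m(self) -> float:
        return self.oligo_um * 1e-6 / 2.0


DEFAULT_THERMO = ThermoParams()

_MAX_EXPANSIONS = 64
# Preference order when collapsing ambiguity codes to their most stable base.
_STABILITY_ORDER = "GCAT"


def _expansions(residues: str) -> Iterator[str]:
    pools = [sorted(IUPAC_SETS[c]) for c in residues]
    for combo in itertools.product(*pools):
        yield "".join(combo)


def _n_expansions(residues: str) -> int:
    n = 1
    for c in residues:
        n *= len(IUPAC_SETS[c])
    return n


def _tm_unambiguous(residues: str, params: ThermoParams) -> float:
    table = NN_TABLES[params.nn_parameter_set]
    dh, ds = 0.0, 0.0
    for end in (residues[0], residues[-1]):
        h, s = _INIT_GC if end in "GC" else _INIT_AT
        dh += h
        ds += s
    for i in range(len(residues) - 1):
        h, s = table[residues[i : i + 2]]
        dh += h
        ds += s
    # Entropy salt correction (SantaLucia 1998): 0.368 * (N-1) * ln[Na+].
    ds += 0.368 * (len(residues) - 1) * math.log(params.sodium_equivalent_m)
    return 1000.0 * dh / (ds + _R_GAS * math.log(params.duplex_conc_m)) - 273.15


def melting_temp(seq: SeqLike, params: ThermoParams = DEFAULT_THERMO) -> float:
    """Nearest-neighbor duplex melting temperature in °C.

    Ambiguity codes are handled by averaging the Tm over all expansions
    when there are at most 64; beyond that each ambiguous position is
    collapsed to its most stable member (G before C before A before T).
    """
    s = as_sequence(seq)
    if s.is_gapped:
        raise UnsupportedOligoError(f"{s.id or 'oligo'}: gapped oligo has no Tm")
    if len(s) < 8:
        raise UnsupportedOligoError(
            f"{s.id or 'oligo'}: length {len(s)} < 8 is below the supported range"
        )
    if _n_expansions(s.residues) == 1:
        return _tm_unambiguous(s.residues, params)
    if _n_expansions(s.residues) <= _MAX_EXPANSIONS:
        tms = [_tm_unambiguous(e, params) for e in _expansions(s.residues)]
        return sum(tms) / len(tms)
    collapsed = "".join(
        min(IUPAC_SETS[c], key=_STABILITY_ORDER.index) for c in s.residues
    )
    return _tm_unambiguous(collapsed, params)


def bases_compatible(a: str, b: str) -> bool:
    """True when the expansion sets of two IUPAC symbols intersect
    (e.g. R is compatible with A, G, and any code containing them)."""
    return not IUPAC_SETS[a].isdisjoint(IUPAC_SETS[b])


def count_differences(primer: SeqLike, window: SeqLike) -> int:
    """Differences (mismatches plus indel columns) between two aligned
    strings of equal length.

    An ambiguity code matches any member of its expansion set, so a
    column counts as a difference only when the two expansion sets are
    disjoint; a column pairing a base with a gap counts 1, and a column
    where both strings have gaps counts 0.
    """
    p = as_sequence(primer)
    w = as_sequence(window)
    if len(p) != len(w):
        raise AlignmentContractError(
            f"aligned strings differ in length ({len(p)} vs {len(w)})"
        )
    return sum(not bases_compatible(a, b) for a, b in zip(p.residues, w.residues))


# ---------------------------------------------------------------------------
# FASTA I/O

def read_fasta(path: Union[str, Path]) -> list[NucSequence]:
    """Read a (possibly aligned) FASTA file into NucSequences."""
    records = [
        NucSequence(str(rec.seq), rec.id) for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise InvalidSequenceError(f"{path}: no FASTA records found")
    return records


def write_fasta(seqs: Iterable[NucSequence], path: Union[str, Path]) -> None:
    """Write sequences as FASTA, wrapped at 70 columns."""
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            fh.write(textwrap.fill(s.residues, 70))
            fh.write("\n")
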